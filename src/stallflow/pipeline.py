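"""End-to-end orchestration: synthesize -> detect -> kinetics -> simulate -> stats.

A single YAML-configurable entry point (:func:`run_all`) runs every stage on
synthetic data with fully seeded randomness and writes per-stage CSV/JSON
artifacts plus a manifest.  One top-level seed derives independent per-stage
seeds by stable hashing, so any stage can be rerun in isolation and identical
configs produce identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bolus import arteriovenous_mtt, compute_kinetics
from .flowsim import DEFAULT_FRACTION_GRID, apply_stalls, sweep_stall_fractions, transit_summary
from .stalls import detect_stalls_in_stack
from .stats import correlate_stalls_vs_mtt, two_sample_ttest
from .synthetic import AngiogramSpec, BolusSpec, NetworkSpec, generate_angiogram, generate_bolus, generate_network

__all__ = ["RunConfig", "validate_config", "run_all", "simulate_cohort", "derive_seed"]

log = logging.getLogger("stallflow")
FLOAT_FORMAT = "%.12g"


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("stallflow")
    except Exception:
        return "unknown"


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the top-level seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class DetectionParams:
    alpha: float = 0.5
    min_duration_frames: int = 3


@dataclass
class SweepParams:
    fractions: tuple = DEFAULT_FRACTION_GRID
    n_seeds: int = 3


@dataclass
class CohortParams:
    n_control: int = 5
    n_lps: int = 5
    control_fraction_range: tuple = (0.01, 0.03)
    lps_fraction_range: tuple = (0.04, 0.10)


@dataclass
class RunConfig:
    """All tunables of a full pipeline run, round-trippable through YAML."""

    seed: int = 0
    angiogram: AngiogramSpec = field(default_factory=AngiogramSpec)
    bolus: BolusSpec = field(default_factory=BolusSpec)
    network: NetworkSpec = field(default_factory=NetworkSpec)
    detection: DetectionParams = field(default_factory=DetectionParams)
    sweep: SweepParams = field(default_factory=SweepParams)
    cohort: CohortParams = field(default_factory=CohortParams)
    save_stacks: bool = False
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("network", "sweep", "cohort"):
            for k, v in d[key].items():
                if isinstance(v, tuple):
                    d[key][k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def _tup(block, key):
            if key in block and isinstance(block[key], list):
                block[key] = tuple(block[key])

        d = {k: (dict(v) if isinstance(v, dict) else v) for k, v in d.items()}
        if "network" in d:
            _tup(d["network"], "lattice_dims")
        if "sweep" in d:
            _tup(d["sweep"], "fractions")
        if "cohort" in d:
            _tup(d["cohort"], "control_fraction_range")
            _tup(d["cohort"], "lps_fraction_range")
        kwargs = dict(d)
        for key, typ in (
            ("angiogram", AngiogramSpec),
            ("bolus", BolusSpec),
            ("network", NetworkSpec),
            ("detection", DetectionParams),
            ("sweep", SweepParams),
            ("cohort", CohortParams),
        ):
            if key in kwargs:
                kwargs[key] = typ(**kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of problems; empty iff the config is usable."""
    problems = []
    if config.seed is None:
        problems.append("seed: an explicit top-level seed is required")
    if not 0 < config.detection.alpha < 1:
        problems.append(f"detection.alpha: threshold fraction must be in (0, 1), got {config.detection.alpha}")
    if config.detection.min_duration_frames < 1:
        problems.append("detection.min_duration_frames: must be >= 1")
    if any(f < 0 or f > 1 for f in config.sweep.fractions):
        problems.append("sweep.fractions: all fractions must lie in [0, 1]")
    if config.sweep.n_seeds < 1:
        problems.append("sweep.n_seeds: must be >= 1")
    for name, rng in (
        ("cohort.control_fraction_range", config.cohort.control_fraction_range),
        ("cohort.lps_fraction_range", config.cohort.lps_fraction_range),
    ):
        if not (0 <= rng[0] <= rng[1] <= 1):
            problems.append(f"{name}: must be an ordered pair within [0, 1]")
    for name, typ, block in (
        ("angiogram", AngiogramSpec, config.angiogram),
        ("bolus", BolusSpec, config.bolus),
        ("network", NetworkSpec, config.network),
    ):
        try:
            typ(**dataclasses.asdict(block))
        except (ValueError, TypeError) as exc:
            problems.append(f"{name}: {exc}")
    return problems


def simulate_cohort(
    cohort: CohortParams | None = None,
    network_spec: NetworkSpec | None = None,
    bolus_spec: BolusSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a cohort with known stalls -> transit coupling.

    Each animal gets its own vascular network (per-animal seed), a programmed
    capillary stall fraction drawn from its group's range, a simulated
    arteriovenous MTT from the flow model, and bolus kinetics from a dye pair
    whose arteriovenous delay equals the simulated MTT.  Returns a group
    table with one row per animal.
    """
    cohort = cohort or CohortParams()
    network_spec = network_spec or NetworkSpec()
    bolus_spec = bolus_spec or BolusSpec()
    rng = np.random.default_rng(seed)
    rows = []
    groups = [("control", cohort.control_fraction_range)] * cohort.n_control + [
        ("LPS", cohort.lps_fraction_range)
    ] * cohort.n_lps
    for i, (group, frange) in enumerate(groups):
        fraction = float(rng.uniform(*frange))
        net_seed = int(rng.integers(2**31))
        net = generate_network(dataclasses.replace(network_spec, seed=net_seed))
        stalled, assign = apply_stalls(net, fraction, seed=int(rng.integers(2**31)))
        res, _ = transit_summary(stalled, stall_fraction=fraction)
        realized = len(assign.blocked_edges) / max(len(net.capillary_edges()), 1)
        # stall duration coupled positively to severity, as seen in vivo
        duration_frames = float(4.0 + 25.0 * fraction + rng.normal(0, 0.4))
        b_spec = dataclasses.replace(
            bolus_spec, av_delay_s=max(res.mean_transit_s, 0.1), seed=int(rng.integers(2**31))
        )
        artery, vein, _ = generate_bolus(b_spec)
        rows.append(
            {
                "animal_id": f"m{i:02d}",
                "group": group,
                "sex": "F" if i % 2 else "M",
                "stall_proportion": realized,
                "mean_stall_duration_frames": duration_frames,
                "mtt_s": res.mean_transit_s,
                "bfi_artery": compute_kinetics(artery).BFI,
                "bfi_vein": compute_kinetics(vein).BFI,
                "phase": "post",
            }
        )
    return pd.DataFrame(rows)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def run_all(config: RunConfig, out_dir) -> dict:
    """Execute every pipeline stage and write artifacts + manifest to out_dir."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    report: dict = {"stages": {}, "outputs": []}
    t_start = time.time()

    def _stage(name):
        log.info("stage %s ...", name)
        report["stages"][name] = {"t_start_s": round(time.time() - t_start, 3)}

    # -- stall detection on one stack per group -----------------------------
    _stage("stalls")
    try:
        stall_rows = []
        for group, frange in (
            ("control", config.cohort.control_fraction_range),
            ("LPS", config.cohort.lps_fraction_range),
        ):
            spec = dataclasses.replace(
                config.angiogram,
                stall_fraction=float(np.mean(frange)),
                seed=derive_seed(config.seed, f"angiogram_{group}"),
            )
            stack, seg_truth, schedule = generate_angiogram(spec)
            if config.save_stacks:
                stack.to_tiff(out / f"angiogram_{group}.tif")
            seg, record, metrics = detect_stalls_in_stack(
                stack,
                alpha=config.detection.alpha,
                min_duration=config.detection.min_duration_frames,
            )
            seg.to_tiff(out / f"segments_{group}.tif")
            record.to_json(out / f"stall_record_{group}.json")
            schedule.to_json(out / f"stall_truth_{group}.json")
            stall_rows.append(
                {
                    "group": group,
                    "true_fraction": spec.stall_fraction,
                    "n_detected_segments": seg.n_segments,
                    "proportion_stalled": metrics.proportion_stalled,
                    "mean_duration_frames": metrics.mean_duration_frames,
                    "mean_duration_s": metrics.mean_duration_s,
                    "n_events": metrics.n_events,
                }
            )
        stall_df = pd.DataFrame(stall_rows)
        _write_csv(stall_df, out / "stall_metrics.csv")
    except Exception as exc:
        raise RuntimeError(f"stage 'stalls' failed: {exc}") from exc

    # -- bolus kinetics ------------------------------------------------------
    _stage("bolus")
    try:
        b_spec = dataclasses.replace(config.bolus, seed=derive_seed(config.seed, "bolus"))
        artery, vein, truth = generate_bolus(b_spec)
        artery.to_csv(out / "bolus_artery.csv")
        vein.to_csv(out / "bolus_vein.csv")
        kin = pd.DataFrame([vars(compute_kinetics(tr)) | {"roi_kind": tr.roi_kind} for tr in (artery, vein)])
        _write_csv(kin, out / "bolus_kinetics.csv")
        tm = arteriovenous_mtt(artery, vein)
        _write_csv(
            pd.DataFrame(
                [{"mtt_s": tm.mtt_s, "artery_t_half": tm.artery_t_half, "vein_t_half": tm.vein_t_half,
                  "true_av_delay_s": truth["av_delay_s"]}]
            ),
            out / "bolus_transit.csv",
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'bolus' failed: {exc}") from exc

    # -- simulation sweep ----------------------------------------------------
    _stage("sweep")
    try:
        net = generate_network(
            dataclasses.replace(config.network, seed=derive_seed(config.seed, "network"))
        )
        net.to_json(out / "network.json")
        sweep_df = sweep_stall_fractions(
            net,
            fractions=config.sweep.fractions,
            n_seeds=config.sweep.n_seeds,
            base_seed=derive_seed(config.seed, "sweep"),
        )
        _write_csv(sweep_df, out / "sweep.csv")
    except Exception as exc:
        raise RuntimeError(f"stage 'sweep' failed: {exc}") from exc

    # -- cohort + stats ------------------------------------------------------
    _stage("cohort")
    try:
        table = simulate_cohort(
            config.cohort, config.network, config.bolus, seed=derive_seed(config.seed, "cohort")
        )
        _write_csv(table, out / "cohort.csv")
    except Exception as exc:
        raise RuntimeError(f"stage 'cohort' failed: {exc}") from exc

    _stage("stats")
    try:
        ctrl = table.loc[table["group"] == "control", "mtt_s"]
        lps = table.loc[table["group"] == "LPS", "mtt_s"]
        t_stat, p_val = two_sample_ttest(ctrl, lps)
        fit_prop, fit_dur = correlate_stalls_vs_mtt(table)
        stats_report = {
            "mtt_mean_control_s": float(ctrl.mean()),
            "mtt_mean_lps_s": float(lps.mean()),
            "ttest_t": t_stat,
            "ttest_p": p_val,
            "fit_mtt_vs_proportion": vars(fit_prop),
            "fit_mtt_vs_duration": vars(fit_dur),
        }
        with open(out / "stats_report.json", "w") as fh:
            json.dump(stats_report, fh, indent=1)
        _write_csv(
            pd.DataFrame(
                [
                    {"comparison": "mtt_control_vs_lps", "t": t_stat, "p": p_val},
                    {"comparison": "mtt_vs_proportion_slope", "t": float("nan"), "p": fit_prop.p_value},
                    {"comparison": "mtt_vs_duration_slope", "t": float("nan"), "p": fit_dur.p_value},
                ]
            ),
            out / "stats_tests.csv",
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'stats' failed: {exc}") from exc

    manifest = {
        "version": _package_version(),
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stage_seeds": {s: derive_seed(config.seed, s) for s in
                        ("angiogram_control", "angiogram_LPS", "bolus", "network", "sweep", "cohort")},
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"),
        "elapsed_s": round(time.time() - t_start, 3),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    report.update(
        stall_metrics=stall_rows,
        mtt_s=tm.mtt_s,
        stats=stats_report,
        manifest=manifest,
    )
    return report
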