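"""Synthetic angiograms, bolus traces and vascular networks with ground truth.

Every downstream stage of the pipeline is validated against data generated
here, where the truth is known by construction:

* :func:`generate_angiogram` draws a few hundred curvilinear capillary tubes
  (random-walk centerlines, 2-4 px wide) on a dark background and schedules
  intensity dropouts (stalls) in a seeded subset of them, returning the frame
  stack together with the true label map and stall schedule.
* :func:`generate_bolus` produces an arterial gamma-variate dye curve and a
  venous copy delayed by a known arteriovenous transit, with optional
  dispersion and additive noise, returning the true kinetic parameters.
* :func:`generate_network` builds a cortex-like vessel graph: a branching
  arteriole tree feeding one face of a 3-D capillary lattice and a venule
  tree draining the opposite face, with labeled measurement points and
  boundary pressures.

Geometry, noise and stall selection use independent seeded RNG streams, so
noise can be varied while holding geometry fixed.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk

from .bolus import BolusTrace
from .flowsim import VascularNetwork
from .stalls import AngiogramStack, SegmentMap, StallEvent

__all__ = [
    "AngiogramSpec",
    "BolusSpec",
    "NetworkSpec",
    "StallSchedule",
    "generate_angiogram",
    "generate_bolus",
    "generate_network",
    "gamma_variate",
]


@dataclass
class StallSchedule:
    """Ground-truth stall events: (segment_id, start_frame, duration_frames)."""

    events: list[StallEvent]
    n_frames: int

    def __post_init__(self) -> None:
        by_seg: dict[int, list[StallEvent]] = {}
        for e in self.events:
            if e.start_frame + e.duration_frames > self.n_frames:
                raise ValueError(f"event {e} exceeds the stack length")
            by_seg.setdefault(e.segment_id, []).append(e)
        for seg, evs in by_seg.items():
            evs = sorted(evs, key=lambda e: e.start_frame)
            for a, b in zip(evs, evs[1:]):
                if a.start_frame + a.duration_frames > b.start_frame:
                    raise ValueError(f"overlapping events for segment {seg}")

    @property
    def stalled_segments(self) -> set[int]:
        return {e.segment_id for e in self.events}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "n_frames": self.n_frames,
                    "events": [
                        {"segment_id": e.segment_id, "start_frame": e.start_frame, "duration_frames": e.duration_frames}
                        for e in self.events
                    ],
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "StallSchedule":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            [StallEvent(e["segment_id"], e["start_frame"], e["duration_frames"]) for e in d["events"]],
            n_frames=d["n_frames"],
        )


@dataclass
class AngiogramSpec:
    """Parameters of a synthetic angiogram stack (defaults: 60 frames of
    512x512 px at 9 s/frame with ~250 capillary segments)."""

    n_frames: int = 60
    height: int = 512
    width: int = 512
    frame_interval_s: float = 9.0
    n_segments: int = 250
    stall_fraction: float = 0.0
    mean_stall_frames: float = 5.0
    noise_cv: float = 0.10
    vessel_level: float = 1.0
    background_level: float = 0.15
    background_noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if not 0 <= self.stall_fraction <= 1:
            raise ValueError("stall_fraction must be in [0, 1]")
        if self.mean_stall_frames < 3:
            raise ValueError("mean_stall_frames must be >= 3 (the minimum-duration rule)")


def _walk_centerline(rng, x0, y0, lo, hi, n_steps, step=1.4, jitter=0.12):
    """Random-walk centerline confined to the box [lo, hi] in both axes."""
    theta = rng.uniform(0, 2 * math.pi)
    pts = [(x0, y0)]
    x, y = x0, y0
    for _ in range(n_steps):
        theta += rng.normal(0, jitter)
        nx_, ny_ = x + step * math.cos(theta), y + step * math.sin(theta)
        if not (lo <= nx_ <= hi):
            theta = math.pi - theta
            nx_ = x + step * math.cos(theta)
        if not (lo <= ny_ <= hi):
            theta = -theta
            ny_ = y + step * math.sin(theta)
        x, y = min(max(nx_, lo), hi), min(max(ny_, lo), hi)
        pts.append((x, y))
    return pts


def generate_angiogram(spec: AngiogramSpec) -> tuple[AngiogramStack, SegmentMap, StallSchedule]:
    """Render a synthetic angiogram stack with a known stall schedule.

    Tubes are placed one per cell of a regular grid (which keeps them
    disjoint); stalled segments drop to the background level during their
    scheduled frames.
    """
    geom_ss, noise_ss, stall_ss = np.random.SeedSequence(spec.seed).spawn(3)
    rng_geom = np.random.default_rng(geom_ss)
    rng_noise = np.random.default_rng(noise_ss)
    rng_stall = np.random.default_rng(stall_ss)

    n_per_side = math.ceil(math.sqrt(spec.n_segments))
    cell = min(spec.height, spec.width) // n_per_side
    if cell < 12:
        raise ValueError("image too small for the requested number of segments")
    margin = 4
    cells = [(r, c) for r in range(n_per_side) for c in range(n_per_side)]
    order = rng_geom.permutation(len(cells))[: spec.n_segments]

    labels = np.zeros((spec.height, spec.width), dtype=np.int64)
    footprints = [disk(1), disk(1), disk(2)]  # widths ~2-4 px
    for k, ci in enumerate(order, start=1):
        r, c = cells[ci]
        lo, hi = margin, cell - 1 - margin
        n_steps = max(8, int(0.7 * (hi - lo)))
        x0 = rng_geom.uniform(lo, hi)
        y0 = rng_geom.uniform(lo, hi)
        pts = _walk_centerline(rng_geom, x0, y0, lo, hi, n_steps)
        tube = np.zeros((cell, cell), dtype=bool)
        for (xa, ya), (xb, yb) in zip(pts, pts[1:]):
            rr, cc = draw_line(int(round(ya)), int(round(xa)), int(round(yb)), int(round(xb)))
            tube[rr, cc] = True
        tube = dilation(tube, footprints[rng_geom.integers(len(footprints))])
        sl = (slice(r * cell, r * cell + cell), slice(c * cell, c * cell + cell))
        labels[sl][tube] = k

    seg = SegmentMap(labels)

    # stall schedule: floor(f * n) segments, one event each
    n_stall = int(spec.stall_fraction * spec.n_segments)
    if spec.stall_fraction > 0 and n_stall == 0:
        warnings.warn("stall_fraction rounds to zero stalled segments", stacklevel=2)
    stalled_ids = sorted(rng_stall.choice(spec.n_segments, size=n_stall, replace=False) + 1) if n_stall else []
    events = []
    for sid in stalled_ids:
        duration = 3 + int(rng_stall.poisson(spec.mean_stall_frames - 3))
        duration = min(duration, spec.n_frames)
        start = int(rng_stall.integers(0, spec.n_frames - duration + 1))
        events.append(StallEvent(segment_id=int(sid), start_frame=start, duration_frames=duration))
    schedule = StallSchedule(events, n_frames=spec.n_frames)

    # per-segment baseline intensities
    base = spec.vessel_level * rng_geom.uniform(0.8, 1.2, size=spec.n_segments)
    level = np.tile(base[:, None], (1, spec.n_frames))
    for e in events:
        level[e.segment_id - 1, e.start_frame : e.start_frame + e.duration_frames] = spec.background_level

    mask = labels > 0
    lab_flat = labels[mask] - 1
    frames = np.empty((spec.n_frames, spec.height, spec.width), dtype=float)
    for t in range(spec.n_frames):
        frame = spec.background_level + rng_noise.normal(0.0, spec.background_noise_sd, size=labels.shape)
        vals = level[lab_flat, t] * (1.0 + rng_noise.normal(0.0, spec.noise_cv, size=lab_flat.size))
        frame[mask] = vals
        frames[t] = np.clip(frame, 0.0, None)
    return AngiogramStack(frames, frame_interval_s=spec.frame_interval_s), seg, schedule


# ---------------------------------------------------------------------------
# bolus
# ---------------------------------------------------------------------------

@dataclass
class BolusSpec:
    """Parameters of a synthetic bolus pair (defaults: 33.3 ms sampling over
    45 s, dye arriving in the artery at 5 s and in the vein av_delay_s later)."""

    dt_s: float = 0.0333
    total_s: float = 45.0
    t0_artery_s: float = 5.0
    av_delay_s: float = 1.5
    gamma_alpha: float = 3.0
    gamma_beta: float = 1.5
    amplitude: float = 1.0
    noise_sd: float = 0.02
    dispersion_s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if self.av_delay_s < 0:
            raise ValueError("av_delay_s must be >= 0")
        rise = self.gamma_alpha * self.gamma_beta
        if self.total_s < self.t0_artery_s + self.av_delay_s + rise:
            raise ValueError("bolus does not fit acquisition window")


def gamma_variate(t: np.ndarray, t0: float, alpha: float, beta: float, amplitude: float = 1.0) -> np.ndarray:
    """Peak-normalized gamma-variate A*((t-t0)/(a*b))^a * exp(a - (t-t0)/b).

    Zero for t <= t0; maximum ``amplitude`` attained at t = t0 + alpha*beta.
    """
    t = np.asarray(t, dtype=float)
    x = np.where(t > t0, t - t0, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = amplitude * (x / (alpha * beta)) ** alpha * np.exp(alpha - x / beta)
    return np.where(t > t0, y, 0.0)


def generate_bolus(spec: BolusSpec) -> tuple[BolusTrace, BolusTrace, dict]:
    """Arterial gamma-variate trace and a delayed venous copy, plus truth.

    The vein trace is the artery kernel shifted by ``av_delay_s`` (evaluated
    analytically, so the delay is exact), optionally dispersed by a Gaussian
    kernel of width ``dispersion_s``, then both traces receive independent
    additive Gaussian noise and are clipped at zero.
    """
    t = np.arange(0.0, spec.total_s, spec.dt_s)
    artery_clean = gamma_variate(t, spec.t0_artery_s, spec.gamma_alpha, spec.gamma_beta, spec.amplitude)
    vein_clean = gamma_variate(
        t, spec.t0_artery_s + spec.av_delay_s, spec.gamma_alpha, spec.gamma_beta, spec.amplitude
    )
    if spec.dispersion_s > 0:
        half = int(math.ceil(4 * spec.dispersion_s / spec.dt_s))
        kt = np.arange(-half, half + 1) * spec.dt_s
        kernel = np.exp(-0.5 * (kt / spec.dispersion_s) ** 2)
        kernel /= kernel.sum()
        vein_clean = np.convolve(np.pad(vein_clean, half, mode="edge"), kernel, mode="same")[half:-half]

    rng_a, rng_v = (np.random.default_rng(s) for s in np.random.SeedSequence(spec.seed).spawn(2))
    artery = artery_clean + (rng_a.normal(0, spec.noise_sd, t.size) if spec.noise_sd > 0 else 0.0)
    vein = vein_clean + (rng_v.normal(0, spec.noise_sd, t.size) if spec.noise_sd > 0 else 0.0)
    truth = {
        "t0_artery_s": spec.t0_artery_s,
        "av_delay_s": spec.av_delay_s,
        "dispersion_s": spec.dispersion_s,
        "I_arrival": 0.0,
        "T_arrival": spec.t0_artery_s,
        "I_peak": spec.amplitude,
        "T_peak": spec.t0_artery_s + spec.gamma_alpha * spec.gamma_beta,
    }
    return (
        BolusTrace(t, np.clip(artery, 0, None), roi_kind="artery"),
        BolusTrace(t, np.clip(vein, 0, None), roi_kind="vein"),
        truth,
    )


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

@dataclass
class NetworkSpec:
    """Parameters of the cortex-like synthetic network: an arteriole tree
    feeding a 3-D capillary lattice drained by a venule tree."""

    lattice_dims: tuple[int, int, int] = (10, 8, 8)
    capillary_diam_um: float = 4.0
    capillary_len_um: float = 60.0
    arteriole_diam_um: float = 15.0
    venule_diam_um: float = 20.0
    tree_min_diam_um: float = 8.0  # penetrating-vessel caliber floor
    tree_segment_len_um: float = 80.0
    n_penetrating_per_side: int = 16  # arteriole/venule tree leaves feeding the bed
    inlet_pressure_mmHg: float = 60.0
    outlet_pressure_mmHg: float = 10.0
    n_measure_points: int = 6
    jitter: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_measure_points < 1:
            raise ValueError("n_measure_points must be >= 1")
        if min(self.lattice_dims) < 2:
            raise ValueError("lattice_dims must all be >= 2")


def _add_tree(g, rng, prefix, root_kind, leaf_face_nodes, vessel_kind, root_diam, spec, x_root):
    """Binary tree from one root to len(leaf_face_nodes) lattice face nodes."""
    n_leaves = len(leaf_face_nodes)
    depth = max(1, math.ceil(math.log2(n_leaves)))
    root = f"{prefix}_root"
    g.add_node(root, pos=(x_root, 0.0, 0.0), kind=root_kind)
    level_nodes = [root]
    for lev in range(1, depth + 1):
        # Murray-like taper, floored at penetrating-vessel caliber
        diam = max(root_diam * 2 ** (-lev / 3.0), spec.tree_min_diam_um)
        new_nodes = []
        for parent in level_nodes:
            for b in range(2):
                node = f"{prefix}_{lev}_{len(new_nodes)}"
                px, py, pz = g.nodes[parent]["pos"]
                g.add_node(node, pos=(px + (x_root < 0) * 60 - (x_root > 0) * 60, py + 30 * (b * 2 - 1), pz), kind="internal")
                g.add_edge(
                    parent,
                    node,
                    length_um=spec.tree_segment_len_um * rng.uniform(1 - spec.jitter, 1 + spec.jitter),
                    diameter_um=diam,
                    kind=vessel_kind,
                    stall_factor=1.0,
                )
                new_nodes.append(node)
        level_nodes = new_nodes
    leaf_diam = max(root_diam * 2 ** (-(depth + 1) / 3.0), spec.tree_min_diam_um)
    leaves = level_nodes[:n_leaves]
    for leaf, face in zip(leaves, leaf_face_nodes):
        g.add_edge(
            leaf,
            face,
            length_um=spec.tree_segment_len_um * rng.uniform(1 - spec.jitter, 1 + spec.jitter),
            diameter_um=leaf_diam,
            kind=vessel_kind,
            stall_factor=1.0,
        )
    return root, leaves


def generate_network(spec: NetworkSpec) -> VascularNetwork:
    """Build the arteriole-tree / capillary-lattice / venule-tree graph.

    ``n_measure_points`` arteriole-side and venule-side tree leaves are
    labeled as measurement points; the tree roots carry the inlet and outlet
    boundary pressures.
    """
    rng = np.random.default_rng(spec.seed)
    nx_, ny_, nz_ = spec.lattice_dims
    g = nx.Graph()
    L = spec.capillary_len_um

    for i in range(nx_):
        for j in range(ny_):
            for k in range(nz_):
                g.add_node(f"c_{i}_{j}_{k}", pos=(i * L, j * L, k * L), kind="internal")
    for i in range(nx_):
        for j in range(ny_):
            for k in range(nz_):
                for di, dj, dk in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
                    ii, jj, kk = i + di, j + dj, k + dk
                    if ii < nx_ and jj < ny_ and kk < nz_:
                        g.add_edge(
                            f"c_{i}_{j}_{k}",
                            f"c_{ii}_{jj}_{kk}",
                            length_um=L * rng.uniform(1 - spec.jitter, 1 + spec.jitter),
                            diameter_um=spec.capillary_diam_um * rng.uniform(1 - spec.jitter, 1 + spec.jitter),
                            kind="capillary",
                            stall_factor=1.0,
                        )

    # Dilute the full 6-neighbour lattice toward cortical branching statistics
    # (mean capillary degree ~3-4): drop alternate transverse edges in a
    # deterministic checkerboard, guarding degrees so no dead ends appear.
    for u, v in sorted(g.edges):
        d = g.edges[u, v]
        if d["kind"] != "capillary":
            continue
        iu = tuple(map(int, u.split("_")[1:]))
        iv = tuple(map(int, v.split("_")[1:]))
        di, dj, dk = (b - a for a, b in zip(iu, iv))
        i, j, k = iu
        drop = (dj == 1 and (i + k) % 2 == 1) or (dk == 1 and (i + j) % 2 == 1)
        if drop and g.degree(u) > 2 and g.degree(v) > 2:
            g.remove_edge(u, v)

    n_caps = sum(1 for *_, d in g.edges(data=True) if d["kind"] == "capillary")
    if n_caps < 200:
        warnings.warn(f"capillary edge count {n_caps} < 200; small stall fractions may block nothing", stacklevel=2)

    n_leaves = 2 ** max(1, math.ceil(math.log2(max(spec.n_measure_points, spec.n_penetrating_per_side, 2))))
    face = ny_ * nz_
    if n_leaves > face:
        raise ValueError("lattice face too small for the requested measurement points")
    # penetrating vessels are quasi-regularly spaced: attach leaves at evenly
    # spaced face positions, venous side staggered by half a spacing
    a_face_idx = [int((m + 0.25) * face / n_leaves) for m in range(n_leaves)]
    v_face_idx = [int((m + 0.75) * face / n_leaves) for m in range(n_leaves)]
    a_faces = [f"c_0_{idx // nz_}_{idx % nz_}" for idx in a_face_idx]
    v_faces = [f"c_{nx_ - 1}_{idx // nz_}_{idx % nz_}" for idx in v_face_idx]

    a_root, a_leaves = _add_tree(g, rng, "a", "inlet", a_faces, "arteriole", spec.arteriole_diam_um, spec, -3 * L)
    v_root, v_leaves = _add_tree(g, rng, "v", "outlet", v_faces, "venule", spec.venule_diam_um, spec, (nx_ + 2) * L)

    # spread the measurement points evenly over the penetrating vessels
    meas_idx = [int((m + 0.5) * len(a_leaves) / spec.n_measure_points) for m in range(spec.n_measure_points)]
    for m in meas_idx:
        g.nodes[a_leaves[m]]["kind"] = "artery_meas"
        g.nodes[v_leaves[m]]["kind"] = "vein_meas"

    assert nx.is_connected(g), "network generator produced a disconnected graph"
    return VascularNetwork(
        g, {a_root: spec.inlet_pressure_mmHg, v_root: spec.outlet_pressure_mmHg}
    )
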