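"""Steady Poiseuille flow and tracer transit on vascular network graphs.

The vasculature is an undirected graph whose edges are cylindrical vessel
segments with hydraulic conductance g = pi * d^4 / (128 * mu * L).  Fixing
pressures at inlet/outlet boundary nodes, mass conservation at every interior
node yields a sparse linear system for the nodal pressures; edge flows follow
from Ohm's-law analogy.  Capillary stalling is modeled by scaling the
conductance of randomly chosen capillary edges by 1e-6 (near-total blockage
that keeps the system nonsingular).

A tracer bolus injected at the inlet is advected through the solved flow
field: each edge is a plug-flow delay line with transit tau = volume / |flow|,
and at each node the outgoing concentration is the flow-weighted average of
the delayed incoming concentrations (complete mixing).  Arteriovenous transit
is then measured exactly as in the bolus-tracking experiment: the difference
of half-maximum rise times between paired venous and arterial measurement
points.

Internal units: micrometres, seconds, mPa*s.  Boundary pressures are given in
mmHg and converted once (1 mmHg = 133322.4 mPa); conductances are in
um^3 s^-1 mPa^-1 so that flow = g * dP is in um^3/s.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve

from .bolus import BolusTrace, half_max_rise

__all__ = [
    "VascularNetwork",
    "FlowSolution",
    "StallAssignment",
    "TransitResult",
    "edge_conductance",
    "solve_flow",
    "apply_stalls",
    "simulate_tracer",
    "measure_transit",
    "transit_summary",
    "sweep_stall_fractions",
    "perturb_pressure",
    "DEFAULT_FRACTION_GRID",
]

MMHG_TO_MPA = 133_322.387415  # 1 mmHg in millipascal
DEFAULT_VISCOSITY_MPAS = 2.0
STALL_CONDUCTANCE_FACTOR = 1e-6
#: default stall-fraction grid: six control-like and six inflammation-like
#: blockage proportions.
DEFAULT_FRACTION_GRID = (0.0, 0.005, 0.01, 0.02, 0.025, 0.03, 0.04, 0.06, 0.07, 0.08, 0.09, 0.10)
DEFAULT_BOLUS_START_S = 0.5
DEFAULT_BOLUS_DURATION_S = 0.7
#: edges carrying less than this fraction of the maximum |flow| transmit no tracer
FLOW_FLOOR_REL = 1e-9


def edge_conductance(length_um: float, diameter_um: float, viscosity_mPas: float = DEFAULT_VISCOSITY_MPAS) -> float:
    """Poiseuille conductance pi*d^4/(128*mu*L) in um^3 s^-1 mPa^-1."""
    if length_um <= 0 or diameter_um <= 0 or viscosity_mPas <= 0:
        raise ValueError("length, diameter and viscosity must be positive")
    return math.pi * diameter_um**4 / (128.0 * viscosity_mPas * length_um)


@dataclass
class VascularNetwork:
    """Vessel graph with hydraulic edge attributes and boundary pressures.

    Node attributes: ``pos`` (xyz, um), ``kind`` in {inlet, outlet,
    artery_meas, vein_meas, internal}.  Edge attributes: ``length_um``,
    ``diameter_um``, ``kind`` in {arteriole, capillary, venule}, and
    ``stall_factor`` (conductance multiplier, 1.0 = open).
    """

    graph: nx.Graph
    boundary_pressures_mmHg: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.graph.number_of_nodes() and not nx.is_connected(self.graph):
            raise ValueError("vascular network must be connected")
        for u, v, d in self.graph.edges(data=True):
            if d["length_um"] <= 0 or d["diameter_um"] <= 0:
                raise ValueError(f"edge ({u},{v}) has nonpositive geometry")
        if self.boundary_pressures_mmHg:
            kinds = nx.get_node_attributes(self.graph, "kind")
            if not any(kinds.get(n) == "inlet" for n in self.boundary_pressures_mmHg):
                raise ValueError("need at least one pressure-fixed inlet")
            if not any(kinds.get(n) == "outlet" for n in self.boundary_pressures_mmHg):
                raise ValueError("need at least one pressure-fixed outlet")

    def nodes_of_kind(self, kind: str) -> list:
        return [n for n, d in self.graph.nodes(data=True) if d.get("kind") == kind]

    @property
    def artery_measure_nodes(self) -> list:
        return self.nodes_of_kind("artery_meas")

    @property
    def vein_measure_nodes(self) -> list:
        return self.nodes_of_kind("vein_meas")

    def capillary_edges(self) -> list[tuple]:
        return sorted(
            (tuple(sorted((u, v))) for u, v, d in self.graph.edges(data=True) if d["kind"] == "capillary")
        )

    def copy(self) -> "VascularNetwork":
        return VascularNetwork(self.graph.copy(), dict(self.boundary_pressures_mmHg))

    # -- serialization ------------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "nodes": [
                {"id": n, "xyz": list(map(float, d.get("pos", (0, 0, 0)))), "kind": d.get("kind", "internal")}
                for n, d in self.graph.nodes(data=True)
            ],
            "edges": [
                {
                    "u": u,
                    "v": v,
                    "length_um": float(d["length_um"]),
                    "diameter_um": float(d["diameter_um"]),
                    "kind": d["kind"],
                    "stall_factor": float(d.get("stall_factor", 1.0)),
                }
                for u, v, d in self.graph.edges(data=True)
            ],
            "boundary_pressures_mmHg": {str(k): float(v) for k, v in self.boundary_pressures_mmHg.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "VascularNetwork":
        with open(path) as fh:
            d = json.load(fh)
        g = nx.Graph()
        for nd in d["nodes"]:
            g.add_node(nd["id"], pos=tuple(nd["xyz"]), kind=nd["kind"])
        for ed in d["edges"]:
            g.add_edge(
                ed["u"],
                ed["v"],
                length_um=ed["length_um"],
                diameter_um=ed["diameter_um"],
                kind=ed["kind"],
                stall_factor=ed.get("stall_factor", 1.0),
            )
        return cls(g, dict(d["boundary_pressures_mmHg"]))

    def to_graphml(self, path) -> None:
        g = self.graph.copy()
        for n, d in g.nodes(data=True):
            if "pos" in d:
                x, y, z = d.pop("pos")
                d.update(x=float(x), y=float(y), z=float(z))
            d["pressure_mmHg"] = float(self.boundary_pressures_mmHg.get(n, float("nan")))
        nx.write_graphml(g, path)


@dataclass
class FlowSolution:
    """Solved pressures (mmHg), signed edge flows (um^3/s) and velocities."""

    pressures_mmHg: dict
    edge_flows: dict  # (u, v) -> flow from u to v, um^3/s
    edge_velocities: dict  # (u, v) -> um/s
    conductances: dict  # (u, v) -> um^3 s^-1 mPa^-1 (stall factor included)
    isolated_nodes: list = field(default_factory=list)

    def conservation_residual(self, net: VascularNetwork) -> float:
        """Max |net flow| at interior nodes, relative to the mean |edge flow|."""
        imbalance: dict = {n: 0.0 for n in net.graph.nodes}
        for (u, v), q in self.edge_flows.items():
            imbalance[u] -= q
            imbalance[v] += q
        interior = [
            n
            for n in net.graph.nodes
            if n not in net.boundary_pressures_mmHg and n not in self.isolated_nodes
        ]
        flows = np.array([abs(q) for q in self.edge_flows.values()])
        scale = flows.mean() if flows.size and flows.mean() > 0 else 1.0
        worst = max((abs(imbalance[n]) for n in interior), default=0.0)
        return worst / scale


def solve_flow(net: VascularNetwork, viscosity_mPas: float = DEFAULT_VISCOSITY_MPAS) -> FlowSolution:
    """Solve the sparse linear system for nodal pressures and edge flows."""
    if not net.boundary_pressures_mmHg:
        raise ValueError("network has no boundary pressures")
    nodes = list(net.graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n_nodes = len(nodes)

    cond = {}
    for u, v, d in net.graph.edges(data=True):
        g = edge_conductance(d["length_um"], d["diameter_um"], viscosity_mPas) * d.get("stall_factor", 1.0)
        cond[(u, v)] = g

    # components with no boundary node are hydraulically isolated: zero flow
    rows, cols, vals = [], [], []
    for (u, v), g in cond.items():
        i, j = index[u], index[v]
        rows += [i, j, i, j]
        cols += [j, i, i, j]
        vals += [-g, -g, g, g]
    lap = coo_matrix((vals, (rows, cols)), shape=(n_nodes, n_nodes)).tocsr()
    n_comp, comp = connected_components(lap != 0, directed=False)
    boundary_comps = {comp[index[n]] for n in net.boundary_pressures_mmHg}
    isolated = [n for n in nodes if comp[index[n]] not in boundary_comps]

    fixed = dict(net.boundary_pressures_mmHg)
    for n in isolated:
        fixed[n] = 0.0
    free = [n for n in nodes if n not in fixed]
    free_idx = {n: i for i, n in enumerate(free)}

    if free:
        rows, cols, vals = [], [], []
        b = np.zeros(len(free))
        for (u, v), g in cond.items():
            for a, bnode in ((u, v), (v, u)):
                if a in free_idx:
                    ia = free_idx[a]
                    rows.append(ia)
                    cols.append(ia)
                    vals.append(g)
                    if bnode in free_idx:
                        rows.append(ia)
                        cols.append(free_idx[bnode])
                        vals.append(-g)
                    else:
                        b[ia] += g * fixed[bnode]
        A = coo_matrix((vals, (rows, cols)), shape=(len(free), len(free))).tocsr()
        p_free = spsolve(A, b)
    else:
        p_free = np.array([])

    pressures = dict(fixed)
    for n, i in free_idx.items():
        pressures[n] = float(p_free[i])

    flows, velocities = {}, {}
    for (u, v), g in cond.items():
        q = g * (pressures[u] - pressures[v]) * MMHG_TO_MPA
        flows[(u, v)] = q
        d_um = net.graph.edges[u, v]["diameter_um"]
        velocities[(u, v)] = q / (math.pi * (d_um / 2.0) ** 2)
    return FlowSolution(pressures, flows, velocities, cond, isolated)


@dataclass
class StallAssignment:
    stall_fraction: float
    blocked_edges: list[tuple]
    seed: int


def apply_stalls(net: VascularNetwork, stall_fraction: float, seed: int) -> tuple[VascularNetwork, StallAssignment]:
    """Block a random subset of capillary edges (conductance x 1e-6).

    ``round(stall_fraction * n_capillaries)`` capillaries are drawn uniformly
    without replacement from the capillary edge list sorted by id; arterioles
    and venules are never blocked.
    """
    if not 0 <= stall_fraction <= 1:
        raise ValueError("stall_fraction must be in [0, 1]")
    caps = net.capillary_edges()
    n_block = round(stall_fraction * len(caps))
    if stall_fraction > 0 and n_block == 0:
        warnings.warn("stall_fraction rounds to zero blocked capillaries", stacklevel=2)
    rng = np.random.default_rng(seed)
    chosen = [caps[i] for i in sorted(rng.choice(len(caps), size=n_block, replace=False))] if n_block else []
    out = net.copy()
    for u, v in chosen:
        out.graph.edges[u, v]["stall_factor"] = (
            out.graph.edges[u, v].get("stall_factor", 1.0) * STALL_CONDUCTANCE_FACTOR
        )
    return out, StallAssignment(stall_fraction=stall_fraction, blocked_edges=chosen, seed=seed)


def rect_bolus(t: np.ndarray, start_s: float = DEFAULT_BOLUS_START_S, duration_s: float = DEFAULT_BOLUS_DURATION_S,
               amplitude: float = 1.0) -> np.ndarray:
    """Rectangular inlet bolus profile (default 0.7 s pulse)."""
    return np.where((t >= start_s) & (t < start_s + duration_s), amplitude, 0.0)


def simulate_tracer(
    net: VascularNetwork,
    flow: FlowSolution,
    inlet_bolus,
    dt_s: float,
    t_max_s: float,
) -> tuple[np.ndarray, dict]:
    """Advect a tracer bolus through the solved flow field.

    Each edge is a plug-flow delay line (delay = volume / |flow|, rounded to
    time steps); nodal mixing is flow-weighted and complete.  ``inlet_bolus``
    is either a callable c(t) or an array of length ``ceil(t_max_s/dt_s)``.
    Returns (t, {node: concentration array}).
    """
    t = np.arange(0.0, t_max_s, dt_s)
    n_steps = t.size
    if callable(inlet_bolus):
        bolus = np.asarray(inlet_bolus(t), dtype=float)
    else:
        bolus = np.asarray(inlet_bolus, dtype=float)
        if bolus.size != n_steps:
            raise ValueError("inlet_bolus array length must match the time grid")

    qmax = max((abs(q) for q in flow.edge_flows.values()), default=0.0)
    if qmax == 0:
        raise ValueError("no flow in the network")
    floor = FLOW_FLOOR_REL * qmax

    # orient transmitting edges downstream and compute integer delays
    in_edges: dict = {n: [] for n in net.graph.nodes}
    tau_min, tau_min_edge = np.inf, None
    for (u, v), q in flow.edge_flows.items():
        if abs(q) <= floor:
            continue  # zero-flow (or stalled) edges transmit nothing
        src, dst = (u, v) if q > 0 else (v, u)
        d = net.graph.edges[u, v]
        vol = math.pi * (d["diameter_um"] / 2.0) ** 2 * d["length_um"]
        tau = vol / abs(q)
        if tau < tau_min:
            tau_min, tau_min_edge = tau, (u, v)
        in_edges[dst].append((src, abs(q), tau))
    if tau_min < dt_s:
        raise ValueError(
            f"dt_s={dt_s:g} s coarser than the fastest edge transit {tau_min:g} s on edge {tau_min_edge}"
        )

    inlets = set(net.nodes_of_kind("inlet"))
    order = sorted(net.graph.nodes, key=lambda n: -flow.pressures_mmHg[n])
    conc = {}
    for n in order:
        if n in inlets:
            conc[n] = bolus.copy()
            continue
        incoming = in_edges[n]
        if not incoming:
            conc[n] = np.zeros(n_steps)
            continue
        num = np.zeros(n_steps)
        den = 0.0
        for src, q, tau in incoming:
            lag = int(round(tau / dt_s))
            shifted = np.zeros(n_steps)
            if lag < n_steps:
                shifted[lag:] = conc[src][: n_steps - lag]
            num += q * shifted
            den += q
        conc[n] = num / den
    return t, conc


@dataclass
class TransitResult:
    """Per artery-vein pair transit times plus their mean/SD summary."""

    pair_transits_s: dict  # (artery_node, vein_node) -> transit (s)
    invalid_pairs: list
    mean_transit_s: float
    sd_transit_s: float
    stall_fraction: float = 0.0
    seed: int | None = None

    @property
    def n_valid_pairs(self) -> int:
        return len(self.pair_transits_s)


def measure_transit(
    t: np.ndarray,
    conc: dict,
    net: VascularNetwork,
    stall_fraction: float = 0.0,
    seed: int | None = None,
) -> TransitResult:
    """Transit per (artery, vein) measurement-point pair via half-max rise.

    Transit is the venous half-maximum rise time minus the arterial one, the
    same estimator applied to the experimental bolus traces.  Pairs whose vein
    point is never reached are flagged invalid and excluded from the summary.
    """
    arteries = net.artery_measure_nodes
    veins = net.vein_measure_nodes
    if not arteries or not veins:
        raise ValueError("network lacks measurement points")
    peak_scale = max(float(np.max(c)) for c in conc.values())

    def _t_half(node):
        series = conc[node]
        if float(np.max(series)) < 1e-6 * peak_scale:
            return None
        try:
            # simulated curves are noiseless: no smoothing, zero baseline
            return half_max_rise(BolusTrace(t, series, roi_kind="sim"), baseline=0.0, smooth_window_s=0.0)
        except ValueError:
            return None

    t_half_cache = {n: _t_half(n) for n in set(arteries) | set(veins)}
    transits, invalid = {}, []
    for a in arteries:
        for v in veins:
            ta, tv = t_half_cache[a], t_half_cache[v]
            if ta is None or tv is None:
                invalid.append((a, v))
            else:
                transits[(a, v)] = tv - ta
    vals = np.array(list(transits.values()))
    return TransitResult(
        pair_transits_s=transits,
        invalid_pairs=invalid,
        mean_transit_s=float(vals.mean()) if vals.size else float("nan"),
        sd_transit_s=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        stall_fraction=stall_fraction,
        seed=seed,
    )


def transit_summary(
    net: VascularNetwork,
    viscosity_mPas: float = DEFAULT_VISCOSITY_MPAS,
    dt_s: float | None = None,
    t_max_s: float | None = None,
    bolus_start_s: float = DEFAULT_BOLUS_START_S,
    bolus_duration_s: float = DEFAULT_BOLUS_DURATION_S,
    stall_fraction: float = 0.0,
    seed: int | None = None,
) -> tuple[TransitResult, FlowSolution]:
    """Solve flow, advect a bolus and measure arteriovenous transit.

    When ``dt_s`` is not given it is set just below the fastest transmitting
    edge transit time, so the discretization scales automatically with the
    flow magnitude (e.g. under boundary-pressure perturbation).
    """
    flow = solve_flow(net, viscosity_mPas)
    qmax = max(abs(q) for q in flow.edge_flows.values())
    floor = FLOW_FLOOR_REL * qmax
    taus, total_vol = [], 0.0
    for (u, v), q in flow.edge_flows.items():
        d = net.graph.edges[u, v]
        vol = math.pi * (d["diameter_um"] / 2.0) ** 2 * d["length_um"]
        total_vol += vol
        if abs(q) > floor:
            taus.append(vol / abs(q))
    q_in = sum(
        abs(q) for (u, v), q in flow.edge_flows.items() if u in net.boundary_pressures_mmHg or v in net.boundary_pressures_mmHg
    ) / 2.0
    if dt_s is None:
        dt_s = 0.45 * min(taus)
    if t_max_s is None:
        # generously cover fill + washout of the whole network volume
        t_max_s = bolus_start_s + bolus_duration_s + 12.0 * total_vol / max(q_in, 1e-12)
    t, conc = simulate_tracer(
        net, flow, lambda tt: rect_bolus(tt, bolus_start_s, bolus_duration_s), dt_s, t_max_s
    )
    result = measure_transit(t, conc, net, stall_fraction=stall_fraction, seed=seed)
    return result, flow


def sweep_stall_fractions(
    net: VascularNetwork,
    fractions=DEFAULT_FRACTION_GRID,
    n_seeds: int = 1,
    base_seed: int = 0,
    **sim_kwargs,
) -> pd.DataFrame:
    """One transit summary row per (stall fraction, seed).

    Returns a table with columns fraction, seed, mean_transit_s, sd_transit_s,
    n_valid_pairs.
    """
    if any(f < 0 or f > 1 for f in fractions):
        raise ValueError("fractions must lie in [0, 1]")
    rows = []
    for s in range(n_seeds):
        for f in fractions:
            stalled, assign = apply_stalls(net, f, seed=base_seed + s)
            res, _ = transit_summary(stalled, stall_fraction=f, seed=assign.seed, **sim_kwargs)
            rows.append(
                {
                    "fraction": f,
                    "seed": assign.seed,
                    "mean_transit_s": res.mean_transit_s,
                    "sd_transit_s": res.sd_transit_s,
                    "n_valid_pairs": res.n_valid_pairs,
                }
            )
    return pd.DataFrame(rows)


def perturb_pressure(net: VascularNetwork, scale: float) -> VascularNetwork:
    """Multiply the inlet-outlet pressure difference by ``scale`` (outlet fixed)."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    kinds = nx.get_node_attributes(net.graph, "kind")
    outlet_ps = [p for n, p in net.boundary_pressures_mmHg.items() if kinds.get(n) == "outlet"]
    ref = float(np.mean(outlet_ps))
    out = net.copy()
    for n, p in out.boundary_pressures_mmHg.items():
        if kinds.get(n) != "outlet":
            out.boundary_pressures_mmHg[n] = ref + scale * (p - ref)
    return out
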