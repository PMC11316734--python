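"""One-dimensional Poiseuille flow and fluorescein bolus transport.

The closed retinal network has one arterial inlet and one venous outlet, so
a single pair of pressure boundary conditions determines the whole flow
field.  Each segment acts as a Poiseuille resistor, R = ∫ 8µ/(π r⁴) dl along
its path; node pressures solve the resulting linear conservation system and
segment flows follow from q = g Δp.

Fluorescein input at the inlet is modelled as two Gaussian passes plus an
exponential systemic washout,

    C(t) = s1 G(t; t1, σ1) + s2 G(t; t2, σ2) + α H(t−t3) e^{−β (t−t3)},

normalised to unit peak, and propagated through the network by delaying each
segment's curve by the cumulative transit time along the dominant-flow path
and scaling its amplitude by the product of flow fractions at branch points
(amounts partition with flow; amplitudes of daughters sum to the parent's).

Units: pressures mmHg, flows µL/min, velocities mm/s, times s; SI is used
internally (1 mmHg = 133.322 Pa, 1 m³/s = 6×10¹⁰ µL/min).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .parameters import SimulationParameters
from .vascular_graph import VascularNetwork

log = logging.getLogger(__name__)

MMHG_TO_PA = 133.322
M3S_TO_ULMIN = 6.0e10


@dataclass
class FlowBoundaryConditions:
    inlet_pressure_mmhg: float
    outlet_pressure_mmhg: float
    viscosity_model: str = "constant"
    viscosity_mpa_s: float = 3.5

    @classmethod
    def from_parameters(cls, params: SimulationParameters) -> "FlowBoundaryConditions":
        bc = cls(params["arterial_inlet_pressure_mmhg"],
                 params["venous_outlet_pressure_mmhg"],
                 viscosity_mpa_s=params["viscosity_mpa_s"])
        if bc.inlet_pressure_mmhg <= bc.outlet_pressure_mmhg:
            raise ValueError("inlet pressure must exceed outlet pressure")
        return bc


@dataclass
class FlowSolution:
    node_pressure_mmhg: dict[int, float]
    segment_flow_ul_min: dict[int, float]   # signed along path orientation
    segment_velocity_mm_s: dict[int, float]
    total_inlet_flow_ul_min: float

    def flow(self, sid: int) -> float:
        return self.segment_flow_ul_min[sid]


def segment_conductance(seg, viscosity_pa_s: float) -> float:
    """Poiseuille conductance g = 1/R with R = ∫ 8µ/(π r⁴) dl (SI)."""
    path_m = seg.path * 1e-3
    r_m = seg.radii * 1e-6
    dl = np.linalg.norm(np.diff(path_m, axis=0), axis=1)
    inv_r4 = 0.5 * (1.0 / r_m[:-1] ** 4 + 1.0 / r_m[1:] ** 4)
    R = float(np.sum(8.0 * viscosity_pa_s / math.pi * dl * inv_r4))
    # floor degenerate (near-zero-length) paths at a 1 µm equivalent so the
    # linear system stays well conditioned
    R_floor = 8.0 * viscosity_pa_s / math.pi * 1e-6 / float(np.max(r_m)) ** 4
    return 1.0 / max(R, R_floor)


def solve_poiseuille(net: VascularNetwork,
                     bc: FlowBoundaryConditions) -> FlowSolution:
    """Solve the linear pressure system with Dirichlet conditions at the
    inlet and outlet.  Raises on a network whose inlet and outlet are
    disconnected (names the stranded components)."""
    if net.inlet_id is None or net.outlet_id is None:
        raise ValueError("network must designate an inlet and an outlet")
    node_ids = sorted(net.nodes)
    index = {nid: i for i, nid in enumerate(node_ids)}
    n = len(node_ids)

    # connectivity check
    seen = {net.inlet_id}
    stack = [net.inlet_id]
    while stack:
        nid = stack.pop()
        for other, _seg in net.neighbors(nid):
            if other not in seen:
                seen.add(other)
                stack.append(other)
    if net.outlet_id not in seen:
        raise ValueError("singular system: inlet component has "
                         f"{len(seen)} nodes and excludes the outlet "
                         f"(network has {n} nodes)")
    stray = set(node_ids) - seen
    if stray:
        raise ValueError("singular system: nodes disconnected from the "
                         f"inlet, e.g. {sorted(stray)[:5]}")

    mu = bc.viscosity_mpa_s * 1e-3
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    conduct = {}
    for sid, seg in net.segments.items():
        g = segment_conductance(seg, mu)
        conduct[sid] = g
        a, b = index[seg.nodes[0]], index[seg.nodes[1]]
        diag[a] += g
        diag[b] += g
        rows += [a, b]
        cols += [b, a]
        vals += [-g, -g]
    lap = sp.coo_matrix((vals + list(diag),
                         (rows + list(range(n)), cols + list(range(n)))),
                        shape=(n, n)).tocsr()

    p = np.zeros(n)
    fixed = np.zeros(n, dtype=bool)
    p[index[net.inlet_id]] = bc.inlet_pressure_mmhg * MMHG_TO_PA
    p[index[net.outlet_id]] = bc.outlet_pressure_mmhg * MMHG_TO_PA
    fixed[[index[net.inlet_id], index[net.outlet_id]]] = True
    free = ~fixed
    # Conductances span many orders of magnitude (capillaries vs arteries)
    # and node pressure differences can sit far below the pressure level,
    # where float64 subtraction cancels.  The LU factorisation stays in
    # float64 (symmetric Jacobi scaling for conditioning) but residuals for
    # iterative refinement — and the final q = g Δp evaluation — run in
    # extended precision so per-node mass balance survives the cancellation.
    if not free.any():
        p_ld = np.asarray(p, dtype=np.longdouble)
        return _finalize_solution(net, p, p_ld, index, conduct, node_ids)
    A = lap[free][:, free].tocsc()
    b_vec = -lap[free][:, fixed] @ p[fixed]
    d = np.sqrt(A.diagonal())
    d[d == 0] = 1.0
    Dinv = sp.diags(1.0 / d)
    As = (Dinv @ A @ Dinv).tocsr()
    bs = Dinv @ b_vec
    lu = spla.splu(As.tocsc())
    y = lu.solve(bs).astype(np.longdouble)
    data_ld = As.data.astype(np.longdouble)
    bs_ld = bs.astype(np.longdouble)

    def residual_ld(vec):
        prod = data_ld * vec[As.indices]
        rows = np.add.reduceat(prod, As.indptr[:-1])
        return bs_ld - rows

    bscale = float(np.max(np.abs(bs))) or 1.0
    for _ in range(20):
        r = residual_ld(y)
        if float(np.max(np.abs(r))) <= 1e-18 * bscale:
            break
        y = y + lu.solve(r.astype(np.float64)).astype(np.longdouble)

    p_ld = np.asarray(p, dtype=np.longdouble)
    p_ld[free] = y / d
    p[free] = (y / d).astype(np.float64)
    return _finalize_solution(net, p, p_ld, index, conduct, node_ids)


def _finalize_solution(net, p, p_ld, index, conduct, node_ids) -> FlowSolution:
    pressures = {nid: float(p[index[nid]] / MMHG_TO_PA) for nid in node_ids}
    flows = {}
    velocities = {}
    for sid, seg in net.segments.items():
        a, b = seg.nodes
        q = float(conduct[sid] * (p_ld[index[a]] - p_ld[index[b]]))  # m³/s
        flows[sid] = q * M3S_TO_ULMIN
        r_m = float(np.mean(seg.radii)) * 1e-6
        velocities[sid] = q / (math.pi * r_m ** 2) * 1e3  # mm/s
    sol = FlowSolution(pressures, flows, velocities, 0.0)
    sol.total_inlet_flow_ul_min = total_inlet_flow(sol, net)
    return sol


def total_inlet_flow(sol: FlowSolution, net: VascularNetwork) -> float:
    """Sum of signed flows leaving the inlet node (µL/min); equals the
    outlet sum by mass conservation."""
    total = 0.0
    for seg in net.segments_at(net.inlet_id):
        q = sol.segment_flow_ul_min[seg.id]
        total += q if seg.nodes[0] == net.inlet_id else -q
    return total


def mass_conservation_residual(sol: FlowSolution, net: VascularNetwork) -> float:
    """Max over interior nodes of |Σ signed flows| / node throughflow.

    Dead-end nodes whose throughflow is at rounding level (below 1e-9 × the
    largest segment flow) are skipped: their flows are zero up to the
    solver's floating-point noise and the ratio is meaningless there.
    """
    worst = 0.0
    scale = max((abs(q) for q in sol.segment_flow_ul_min.values()),
                default=0.0)
    floor = 1e-9 * scale
    for nid in net.nodes:
        if nid in (net.inlet_id, net.outlet_id):
            continue
        net_q = 0.0
        through = 0.0
        for seg in net.segments_at(nid):
            q = sol.segment_flow_ul_min[seg.id]
            net_q += q if seg.nodes[0] == nid else -q
            through += abs(q)
        if through > floor:
            worst = max(worst, abs(net_q) / through)
    return worst


# -- fluorescein bolus -----------------------------------------------------

@dataclass
class BolusModel:
    """Two-pass + washout fluorescein input function (times in seconds)."""
    s1: float = 0.833
    s2: float = 0.336
    alpha: float = 1.064
    t1_s: float = 0.171 * 60.0
    t2_s: float = 0.364 * 60.0
    t3_s: float = 0.482 * 60.0
    sigma1_s: float = 10.0
    sigma2_s: float = 25.0
    beta_per_s: float = 0.043 / 60.0
    _norm: float = field(default=0.0, repr=False)

    def __post_init__(self):
        if min(self.t1_s, self.t2_s, self.t3_s, self.sigma1_s,
               self.sigma2_s) <= 0:
            raise ValueError("all times and widths must be positive")
        self._norm = float(np.max(self._raw(np.linspace(0.0, 600.0, 60001))))

    def _raw(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        c = (self.s1 * np.exp(-0.5 * ((t - self.t1_s) / self.sigma1_s) ** 2)
             + self.s2 * np.exp(-0.5 * ((t - self.t2_s) / self.sigma2_s) ** 2))
        wash = self.alpha * np.exp(-self.beta_per_s * (t - self.t3_s))
        return c + np.where(t >= self.t3_s, wash, 0.0)

    def concentration(self, t) -> np.ndarray:
        """Inlet concentration, normalised to unit peak."""
        return self._raw(t) / self._norm


def bolus_concentration(t, model: BolusModel | None = None) -> np.ndarray:
    """Unit-peak inlet fluorescein concentration at time t (seconds)."""
    model = model or BolusModel()
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    return model.concentration(t)


@dataclass
class TimeCourseSet:
    time_s: np.ndarray
    curves: dict[int, np.ndarray]          # segment id -> concentration curve
    delays_s: dict[int, float]             # transit delay at segment exit
    amplitudes: dict[int, float]           # flow-partition amplitude
    inlet_curve: np.ndarray
    excluded_segments: list[int] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({f"seg_{sid}": c for sid, c in self.curves.items()},
                            index=pd.Index(self.time_s, name="time_s"))


def propagate_bolus(net: VascularNetwork, sol: FlowSolution,
                    model: BolusModel | None = None,
                    time_s: np.ndarray | None = None,
                    min_flow_ul_min: float = 1e-9) -> TimeCourseSet:
    """Advect the inlet bolus through the solved network.

    Each segment's curve is the inlet curve delayed by the cumulative
    transit time Σ l/|v| along the dominant-flow (max-|q|) path from the
    inlet to the segment's exit, with amplitude equal to the product of flow
    fractions q_child/q_parent along that path; at merges the incoming
    amplitudes (tracer amounts) add.  Segments with |q| below the floor are
    excluded with a warning.
    """
    model = model or BolusModel()
    if time_s is None:
        time_s = np.linspace(0.0, 120.0, 1201)
    excluded = [sid for sid, q in sol.segment_flow_ul_min.items()
                if abs(q) <= min_flow_ul_min]
    if excluded:
        log.warning("propagate_bolus: excluding %d zero-flow segments",
                    len(excluded))
    live = {sid for sid in net.segments if sid not in set(excluded)}

    # directed flow graph: edge u -> v where flow runs from u to v
    out_edges: dict[int, list[int]] = {}
    in_deg: dict[int, int] = {nid: 0 for nid in net.nodes}
    head: dict[int, int] = {}
    tail: dict[int, int] = {}
    for sid in live:
        seg = net.segments[sid]
        a, b = seg.nodes
        if sol.segment_flow_ul_min[sid] >= 0:
            u, v = a, b
        else:
            u, v = b, a
        tail[sid], head[sid] = u, v
        out_edges.setdefault(u, []).append(sid)
        in_deg[v] += 1

    # Kahn topological order from the inlet
    delay_node: dict[int, float] = {net.inlet_id: 0.0}
    amp_node: dict[int, float] = {net.inlet_id: 1.0}
    best_in: dict[int, tuple[float, float]] = {}
    amp_in: dict[int, float] = {}
    ready = [net.inlet_id]
    delays: dict[int, float] = {}
    amps: dict[int, float] = {}
    order_guard = 0
    while ready:
        order_guard += 1
        if order_guard > 10 * max(1, len(net.nodes)):
            break
        u = ready.pop(0)
        if u not in amp_node:
            # merge: amplitudes add; delay from the dominant (max-q) input
            amp_node[u] = amp_in.get(u, 0.0)
            delay_node[u] = best_in.get(u, (0.0, 0.0))[1]
        q_out_total = sum(abs(sol.segment_flow_ul_min[s])
                          for s in out_edges.get(u, ()))
        for sid in out_edges.get(u, ()):
            q = abs(sol.segment_flow_ul_min[sid])
            seg = net.segments[sid]
            v_mm_s = abs(sol.segment_velocity_mm_s[sid])
            transit = seg.length_mm / v_mm_s if v_mm_s > 0 else 0.0
            d = delay_node[u] + transit
            a = amp_node[u] * (q / q_out_total if q_out_total > 0 else 0.0)
            delays[sid] = d
            amps[sid] = a
            v = head[sid]
            amp_in[v] = amp_in.get(v, 0.0) + a
            if v not in best_in or q > best_in[v][0]:
                best_in[v] = (q, d)
            in_deg[v] -= 1
            if in_deg[v] == 0 and v != net.inlet_id:
                ready.append(v)

    inlet_curve = model.concentration(time_s)
    curves = {}
    for sid in live:
        if sid not in delays:
            excluded.append(sid)
            continue
        shifted = np.clip(time_s - delays[sid], 0.0, None)
        c = model.concentration(shifted)
        c = np.where(time_s >= delays[sid], c, 0.0)
        curves[sid] = amps[sid] * c
    return TimeCourseSet(time_s, curves, delays, amps, inlet_curve,
                         sorted(set(excluded)))


def _half_max_time(time_s: np.ndarray, curve: np.ndarray) -> float:
    peak = float(np.max(curve))
    if peak <= 0:
        raise ValueError("curve never rises above zero")
    half = 0.5 * peak
    idx = int(np.argmax(curve >= half))
    if idx == 0:
        return float(time_s[0])
    t0, t1 = time_s[idx - 1], time_s[idx]
    c0, c1 = curve[idx - 1], curve[idx]
    if c1 == c0:
        return float(t1)
    return float(t0 + (half - c0) * (t1 - t0) / (c1 - c0))


def arteriovenous_delay(tc: TimeCourseSet, net: VascularNetwork) -> float:
    """Delay (s) between arterial and venous filling: half-max time of the
    outlet-adjacent vein curve minus half-max time of the inlet curve."""
    outlet_segs = [s for s in net.segments_at(net.outlet_id)
                   if s.id in tc.curves]
    if not outlet_segs:
        raise ValueError("no perfused outlet-adjacent vein curve")
    vein_curve = tc.curves[outlet_segs[0].id]
    return (_half_max_time(tc.time_s, vein_curve)
            - _half_max_time(tc.time_s, tc.inlet_curve))
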