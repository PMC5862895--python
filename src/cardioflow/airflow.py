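"""Regional expansion -> signed airway flow, volume metrics, and the
bulk/pendelluft decomposition.

Sign convention: positive flow is directed from the trachea toward the
periphery, everywhere in the tree.  With that convention, at a bifurcation
with parent flow Q_A and daughter flows Q_B, Q_C, continuity reads
Q_A = Q_B + Q_C, and the flow decomposition is

    Q_tot  = |Q_A| + |Q_B| + |Q_C|      (total internal flow)
    Q_bulk = |Q_A + Q_B + Q_C|          (trachea <-> periphery transport)
    Q_pend = Q_tot - Q_bulk >= 0        (sibling <-> sibling redistribution)

Pure bulk flow (q, q/2, q/2) gives Q_pend = 0; pure pendelluft (0, q, -q)
gives Q_bulk = 0, Q_pend = 2q.

Units throughout: volumes mm^3, time ms, flows mm^3/ms which is numerically
identical to ml/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tree import AirwayTree

__all__ = [
    "FlowSeries",
    "FlowDecomposition",
    "VolumeMetrics",
    "assign_regions_to_terminals",
    "compute_terminal_flows",
    "propagate_flows",
    "compute_volume_metrics",
    "decompose_bifurcation_flow",
    "aggregate_flow_decomposition",
]


@dataclass
class FlowSeries:
    """Signed time-resolved flow per airway segment (ml/s).

    ``flows[airway_id]`` is Q(t) at ``times`` (ms).  If ``period_ms`` is set
    the series is treated as one cycle of a periodic signal and ``sample``
    wraps time and interpolates linearly across the cycle seam.
    """

    times: np.ndarray
    flows: dict[int, np.ndarray] = field(default_factory=dict)
    period_ms: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)

    @property
    def airway_ids(self) -> list[int]:
        return sorted(self.flows)

    def sample(self, airway_id: int, t) -> np.ndarray:
        """Linearly interpolated Q at arbitrary times (wrapping if periodic)."""
        t = np.asarray(t, dtype=float)
        q = self.flows[airway_id]
        if self.period_ms is not None:
            tt = np.mod(t - self.times[0], self.period_ms) + self.times[0]
            xp = np.concatenate([self.times, [self.times[0] + self.period_ms]])
            qp = np.concatenate([q, [q[0]]])
            return np.interp(tt, xp, qp)
        return np.interp(t, self.times, q)

    def __add__(self, other: "FlowSeries") -> "FlowSeries":
        if not np.array_equal(self.times, other.times):
            raise ValueError("flow series must share a time base to be summed")
        ids = set(self.flows) | set(other.flows)
        return FlowSeries(
            times=self.times.copy(),
            flows={
                i: self.flows.get(i, 0.0) + other.flows.get(i, 0.0) for i in ids
            },
            period_ms=self.period_ms,
        )

    def scaled(self, factor: float) -> "FlowSeries":
        return FlowSeries(
            times=self.times.copy(),
            flows={i: factor * q for i, q in self.flows.items()},
            period_ms=self.period_ms,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in self.airway_ids:
            rows.append(
                pd.DataFrame(
                    {"airway_id": i, "time_ms": self.times, "Q_ml_per_s": self.flows[i]}
                )
            )
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, period_ms: float | None = None) -> "FlowSeries":
        df = pd.read_csv(path)
        times = np.sort(df.time_ms.unique())
        flows = {}
        for i, g in df.groupby("airway_id"):
            g = g.sort_values("time_ms")
            flows[int(i)] = g.Q_ml_per_s.to_numpy(float)
        return cls(times=times, flows=flows, period_ms=period_ms)


@dataclass
class FlowDecomposition:
    """Per-bifurcation and whole-tree time-averaged flow components (ml/s)."""

    per_bifurcation: pd.DataFrame   # parent_id, generation, q_tot, q_bulk, q_pend
    q_tot: float
    q_bulk: float
    q_pend: float

    @property
    def pendelluft_fraction(self) -> float:
        return self.q_pend / self.q_tot if self.q_tot > 0 else 0.0

    @property
    def per_generation(self) -> pd.DataFrame:
        return (
            self.per_bifurcation.groupby("generation")[["q_tot", "q_bulk", "q_pend"]]
            .sum()
            .reset_index()
        )


@dataclass
class VolumeMetrics:
    lung_volume_ml: np.ndarray      # per phase
    tidal_volume_ml: float
    minute_volume_ml: float
    fractional_tidal_volume: np.ndarray   # per region
    displacement_um: np.ndarray | None    # per region path length, if trackable


def assign_regions_to_terminals(region_centers: np.ndarray, tree: AirwayTree) -> np.ndarray:
    """Map each region to its closest supplying (terminal) airway.

    Distance is Euclidean to the terminal's distal end-point; exact ties go
    to the lower airway id.  Returns an array of airway ids per region.
    """
    centers = np.atleast_2d(np.asarray(region_centers, dtype=float))
    if centers.size == 0:
        raise ValueError("region set must not be empty")
    term = tree.terminal_ids  # sorted ascending: argmin ties pick the lowest id
    if not term:
        raise ValueError("tree has no terminal airways")
    endpoints = np.array([tree[i].distal_point for i in term])
    d = np.linalg.norm(centers[:, None, :] - endpoints[None, :, :], axis=2)
    return np.asarray(term)[np.argmin(d, axis=1)]


def compute_terminal_flows(
    region_volumes: np.ndarray,
    phase_times: np.ndarray,
    assignment: np.ndarray,
    period_ms: float | None = None,
) -> FlowSeries:
    """Terminal airway flow = d/dt of the summed volume of its regions.

    ``region_volumes`` is (n_regions, n_phases) in mm^3.  The derivative uses
    central differences; if ``period_ms`` is given the cycle wraps
    periodically (non-uniform phase spacing is handled by ``np.gradient``'s
    local difference weights), otherwise end points use one-sided
    differences.  Positive flow during regional inflation.
    """
    v = np.asarray(region_volumes, dtype=float)
    t = np.asarray(phase_times, dtype=float)
    if v.ndim != 2 or v.shape[1] != len(t):
        raise ValueError("region_volumes must be (n_regions, n_phases)")
    if v.shape[1] < 2:
        raise ValueError("at least two phases are required")
    assignment = np.asarray(assignment)

    flows: dict[int, np.ndarray] = {}
    for term_id in np.unique(assignment):
        vt = v[assignment == term_id].sum(axis=0)
        if period_ms is not None:
            text = np.concatenate([[t[-1] - period_ms], t, [t[0] + period_ms]])
            vext = np.concatenate([[vt[-1]], vt, [vt[0]]])
            q = np.gradient(vext, text)[1:-1]
        else:
            q = np.gradient(vt, t)
        flows[int(term_id)] = q
    return FlowSeries(times=t, flows=flows, period_ms=period_ms)


def propagate_flows(tree: AirwayTree, terminal_flows: FlowSeries) -> FlowSeries:
    """Fill the whole tree by continuity: Q_parent(t) = sum of daughter flows.

    Post-order traversal; the root trace is the total tracheal flow.  Every
    terminal airway must carry a flow trace.
    """
    flows: dict[int, np.ndarray] = {}
    for i in tree.postorder():
        seg = tree[i]
        if not seg.child_ids:
            if i not in terminal_flows.flows:
                raise ValueError(f"missing flow trace for terminal airway {i}")
            flows[i] = np.asarray(terminal_flows.flows[i], dtype=float)
        else:
            flows[i] = sum(flows[c] for c in seg.child_ids)
    return FlowSeries(
        times=terminal_flows.times.copy(),
        flows=flows,
        period_ms=terminal_flows.period_ms,
    )


def compute_volume_metrics(
    region_volumes: np.ndarray,
    phase_times: np.ndarray,
    cycle_frequency_per_min: float,
    region_displacements: np.ndarray | None = None,
) -> VolumeMetrics:
    """Whole-lung and per-region volume metrics over one cycle.

    Tidal volume is max - min of the summed lung-volume trace; minute volume
    is tidal volume times the cycle frequency.  Fractional tidal volume per
    region is (max - min)/initial.  If per-phase region centre positions are
    supplied (n_regions, n_phases, 3, in um) the per-region displacement is
    the translation path length over the cycle.
    """
    v = np.asarray(region_volumes, dtype=float)
    lung = v.sum(axis=0)
    tidal = float(lung.max() - lung.min())
    frac = (v.max(axis=1) - v.min(axis=1)) / v[:, 0]
    disp = None
    if region_displacements is not None:
        steps = np.diff(np.asarray(region_displacements, dtype=float), axis=1)
        disp = np.linalg.norm(steps, axis=2).sum(axis=1)
    return VolumeMetrics(
        lung_volume_ml=lung / 1000.0,
        tidal_volume_ml=tidal / 1000.0,
        minute_volume_ml=tidal / 1000.0 * cycle_frequency_per_min,
        fractional_tidal_volume=frac,
        displacement_um=disp,
    )


def decompose_bifurcation_flow(
    q_a,
    q_b,
    q_c,
    continuity_tol: float = 1e-6,
    check_continuity: bool = True,
    label: str = "",
):
    """(Q_tot, Q_bulk, Q_pend) at a bifurcation; vectorised over time.

    Flows follow the positive-toward-periphery convention, so continuity is
    Q_A = Q_B + Q_C and is asserted to a relative tolerance before
    decomposing.
    """
    q_a = np.asarray(q_a, dtype=float)
    q_b = np.asarray(q_b, dtype=float)
    q_c = np.asarray(q_c, dtype=float)
    if check_continuity:
        scale = np.maximum(np.max(np.abs([q_a, q_b, q_c])), 1e-300)
        resid = np.max(np.abs(q_a - q_b - q_c))
        if resid > continuity_tol * scale:
            raise ValueError(
                f"continuity violated at bifurcation {label or '?'}: "
                f"|Q_A - Q_B - Q_C| = {resid:.3g} (scale {scale:.3g})"
            )
    q_tot = np.abs(q_a) + np.abs(q_b) + np.abs(q_c)
    q_bulk = np.abs(q_a + q_b + q_c)
    return q_tot, q_bulk, q_tot - q_bulk


def aggregate_flow_decomposition(
    flow_series: FlowSeries,
    tree: AirwayTree,
    continuity_tol: float = 1e-6,
) -> FlowDecomposition:
    """Time-averaged Q_tot/Q_bulk/Q_pend per bifurcation and whole-tree sums.

    Each component is integrated over the cycle by the trapezoidal rule
    (closing the periodic seam when the series has a period) and divided by
    the cycle duration; whole-tree values sum every bifurcation.
    """
    t = flow_series.times
    if flow_series.period_ms is not None:
        duration = flow_series.period_ms
        tt = np.concatenate([t, [t[0] + duration]])
        wrap = True
    else:
        duration = t[-1] - t[0]
        tt = t
        wrap = False
    if duration <= 0:
        raise ValueError("cycle duration must be positive")

    def cyc(q):
        return np.concatenate([q, [q[0]]]) if wrap else q

    rows = []
    for pid in tree.bifurcation_ids:
        b, c = tree[pid].child_ids
        q_tot, q_bulk, q_pend = decompose_bifurcation_flow(
            flow_series.flows[pid],
            flow_series.flows[b],
            flow_series.flows[c],
            continuity_tol=continuity_tol,
            label=str(pid),
        )
        rows.append(
            dict(
                parent_id=pid,
                generation=tree[pid].generation,
                q_tot=np.trapezoid(cyc(q_tot), tt) / duration,
                q_bulk=np.trapezoid(cyc(q_bulk), tt) / duration,
                q_pend=np.trapezoid(cyc(q_pend), tt) / duration,
            )
        )
    df = pd.DataFrame(rows)
    return FlowDecomposition(
        per_bifurcation=df,
        q_tot=float(df.q_tot.sum()) if len(df) else 0.0,
        q_bulk=float(df.q_bulk.sum()) if len(df) else 0.0,
        q_pend=float(df.q_pend.sum()) if len(df) else 0.0,
    )
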