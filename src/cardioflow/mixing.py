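"""Washout states (DIFF/CARD/VENT/BOTH), concentration curves and mixing ratios.

The four states isolate the two flow sources digitally: DIFF has zero flow
(molecular diffusion only), CARD carries the cardiogenic flows alone, VENT
the mechanical-ventilation flows alone, and BOTH their superposition (the
terminal flow traces are summed before propagation; flow propagation is
linear so this equals summing everywhere).  Diffusion is on in all states.

A washout starts with the lung full of Type A (resident gas); fresh gas
entering the trachea is Type B.  The lung-resident Type A fraction, sampled
once per ventilation cycle at end inspiration (the instant of maximum lung
volume; DIFF and CARD use the same clock instants for comparability), is the
simulated analogue of an inert-gas washout curve.  Mixing enhancement is the
ratio of Type B fractions with versus without cardiogenic oscillations
(CARD:DIFF and BOTH:VENT).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .airflow import FlowSeries, assign_regions_to_terminals, propagate_flows
from .geometry import TransportGeometry, attach_trumpet_model, simplify_geometry
from .synthetic import (
    CardiacParams,
    ExpansionField,
    VentilationParams,
    generate_airway_tree,
    generate_expansion_field,
)
from .transport import Simulation, TransportConfig
from .tree import AirwayTree

__all__ = [
    "WASHOUT_STATES",
    "ConcentrationCurve",
    "MixingRatio",
    "run_washout_state",
    "mixing_enhancement_ratio",
    "MouseScenario",
    "build_mouse_scenario",
    "flows_from_field",
]

WASHOUT_STATES = ("DIFF", "CARD", "VENT", "BOTH")


@dataclass
class ConcentrationCurve:
    """Lung-resident gas-type fractions sampled once per cycle."""

    state: str
    sample_times: np.ndarray
    fraction_a: np.ndarray
    fraction_b: np.ndarray
    n_lung: np.ndarray
    expired_a: np.ndarray
    expired_b: np.ndarray
    injected: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": self.state,
                "time_ms": self.sample_times,
                "fraction_A": self.fraction_a,
                "fraction_B": self.fraction_b,
                "n_lung": self.n_lung,
                "expired_A": self.expired_a,
                "expired_B": self.expired_b,
                "injected_B": self.injected,
            }
        )


@dataclass
class MixingRatio:
    times: np.ndarray
    ratio: np.ndarray
    valid: np.ndarray   # False where 0/0 or x/0


def run_washout_state(
    state: str,
    geometry: TransportGeometry,
    flows: FlowSeries | None,
    config: TransportConfig,
    n_cycles: int,
    cycle_period_ms: float,
    sample_offset_ms: float | None = None,
) -> ConcentrationCurve:
    """Run a full transport simulation and sample the washout curve.

    ``flows`` must be None (or identically zero) for DIFF and a periodic
    FlowSeries matching ``cycle_period_ms`` otherwise.  Samples are taken at
    t = k*T + offset for k = 0..n_cycles-1, plus an initial sample at t=0
    (where the Type A fraction is 1 by construction).
    """
    if state not in WASHOUT_STATES:
        raise ValueError(f"unknown state {state!r}; expected one of {WASHOUT_STATES}")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if state == "DIFF":
        if flows is not None and any(np.any(q != 0) for q in flows.flows.values()):
            raise ValueError("DIFF requires zero flow everywhere")
        flows = None
    else:
        if flows is None:
            raise ValueError(f"state {state} requires a flow series")
        if flows.period_ms is None or abs(flows.period_ms - cycle_period_ms) > 1e-6:
            raise ValueError("flow series period must equal cycle_period_ms")
    if sample_offset_ms is None:
        sample_offset_ms = _end_inspiration_offset(flows, cycle_period_ms)

    sim = Simulation(geometry, flows, config)
    sim.seed_tracers()

    times = [0.0]
    rows = [_sample(sim)]
    for k in range(n_cycles):
        sim.run_until(k * cycle_period_ms + sample_offset_ms)
        times.append(sim.t)
        rows.append(_sample(sim))
    sim.run_until(n_cycles * cycle_period_ms)

    arr = np.array(rows)
    return ConcentrationCurve(
        state=state,
        sample_times=np.array(times),
        fraction_a=arr[:, 0],
        fraction_b=arr[:, 1],
        n_lung=arr[:, 2],
        expired_a=arr[:, 3],
        expired_b=arr[:, 4],
        injected=arr[:, 5],
    )


def _sample(sim: Simulation) -> list[float]:
    n_a, n_b = sim.lung_counts
    tot = n_a + n_b
    return [
        n_a / tot if tot else np.nan,
        n_b / tot if tot else np.nan,
        tot,
        float(sim.n_expired[0]),
        float(sim.n_expired[1]),
        float(sim.n_injected + sim.n_exchanged),
    ]


def _end_inspiration_offset(flows: FlowSeries | None, period_ms: float) -> float:
    """Instant of maximum lung volume in the cycle (from the root flow)."""
    if flows is None:
        return 0.0
    root_id = min(flows.flows)  # caller passes propagated series; root has lowest id
    t = np.linspace(0, period_ms, 800, endpoint=False)
    q = flows.sample(root_id, t)
    v = np.cumsum(q) * (t[1] - t[0])
    return float(t[np.argmax(v)])


def mixing_enhancement_ratio(
    curve_with: ConcentrationCurve, curve_without: ConcentrationCurve
) -> MixingRatio:
    """Fresh-gas concentration ratio with/without cardiogenic oscillations.

    ratio(t) = fraction_B_with(t) / fraction_B_without(t) on the
    ``curve_with`` time base (the other curve is linearly resampled onto it
    if needed).  0/0 points are NaN and flagged; x/0 with x > 0 is +inf and
    flagged.
    """
    t = curve_with.sample_times
    num = curve_with.fraction_b
    if np.array_equal(t, curve_without.sample_times):
        den = curve_without.fraction_b
    else:
        den = np.interp(t, curve_without.sample_times, curve_without.fraction_b)
    ratio = np.full_like(num, np.nan, dtype=float)
    valid = np.zeros(len(num), dtype=bool)
    nz = den != 0
    ratio[nz] = num[nz] / den[nz]
    valid[nz] = True
    both_zero = (den == 0) & (num == 0)
    ratio[(den == 0) & (num > 0)] = np.inf
    ratio[both_zero] = np.nan
    return MixingRatio(times=t, ratio=ratio, valid=valid)


# ---------------------------------------------------------------------------
# scenario assembly
# ---------------------------------------------------------------------------

def flows_from_field(
    field_: ExpansionField,
    tree: AirwayTree,
    n_samples: int = 60,
) -> FlowSeries:
    """Terminal flows from the field's exact dV/dt, propagated up the tree."""
    t = np.linspace(0, field_.period_ms, n_samples, endpoint=False)
    dv = field_.dvdt(t)
    assignment = assign_regions_to_terminals(field_.region_centers, tree)
    flows: dict[int, np.ndarray] = {}
    for term in tree.terminal_ids:
        sel = assignment == term
        flows[term] = dv[sel].sum(axis=0) if sel.any() else np.zeros(len(t))
    terminal = FlowSeries(times=t, flows=flows, period_ms=field_.period_ms)
    return propagate_flows(tree, terminal)


@dataclass
class MouseScenario:
    """Scaled-down mouse-like washout scenario with known ground truth.

    Holds the synthetic tree, transport geometry (trumpets + compartments
    rescaled so total gas volume matches the target FRC), the ventilation-
    and cardiac-only expansion fields, and propagated flow series per state.
    """

    tree: AirwayTree
    geometry: TransportGeometry
    field_vent: ExpansionField
    field_card: ExpansionField
    flows: dict[str, FlowSeries | None]
    cycle_period_ms: float
    sample_offset_ms: float
    seed: int
    frc_ml: float
    tlc_ml: float = 1.0

    def state_flows(self, state: str) -> FlowSeries | None:
        return self.flows[state]


def build_mouse_scenario(
    seed: int = 0,
    n_generations: int = 5,
    frc_ml: float = 0.5,
    tidal_volume_ml: float = 0.2,
    cardiac_tidal_ml: float = 0.06,
    cardiac_frequency_ratio: float = 3.0,
    n_flow_samples: int = 60,
) -> MouseScenario:
    """Assemble the bundled mouse-like scenario.

    A 5-generation synthetic tree stands in for the full segmented tree;
    acinar compartment volumes are rescaled so that conduits + compartments
    total ``frc_ml``.  The ventilation field is calibrated to a 0.2 ml tidal
    volume (pressure-controlled, 120/280 ms); the cardiac field to a summed
    regional tidal volume of 0.06 ml (~6% of a ~1 ml total lung capacity),
    localised near the heart locus with a travelling phase lag.
    """
    tree = generate_airway_tree(n_generations=n_generations, seed=seed)
    geo = attach_trumpet_model(simplify_geometry(tree))
    conduit_vol = float(geo.conduit_volumes.sum())
    target = frc_ml * 1000.0
    if target <= conduit_vol:
        raise ValueError("FRC target smaller than conduit volume; enlarge frc_ml")
    geo.comp_volume *= (target - conduit_vol) / geo.comp_volume.sum()

    vent = generate_expansion_field(
        tree,
        VentilationParams(tidal_volume_ml=tidal_volume_ml),
        CardiacParams(amplitude=0.0, frequency_ratio=cardiac_frequency_ratio),
        baseline_lung_volume=target,
        seed=seed,
    )
    card = generate_expansion_field(
        tree,
        VentilationParams(tidal_volume_ml=0.0),
        CardiacParams(
            frequency_ratio=cardiac_frequency_ratio,
            tidal_volume_ml=cardiac_tidal_ml,
        ),
        baseline_lung_volume=target,
        seed=seed,
    )
    f_vent = flows_from_field(vent, tree, n_flow_samples)
    f_card = flows_from_field(card, tree, n_flow_samples)
    flows = {
        "DIFF": None,
        "CARD": f_card,
        "VENT": f_vent,
        "BOTH": f_vent + f_card,
    }
    period = vent.period_ms
    return MouseScenario(
        tree=tree,
        geometry=geo,
        field_vent=vent,
        field_card=card,
        flows=flows,
        cycle_period_ms=period,
        sample_offset_ms=_end_inspiration_offset(f_vent, period),
        seed=seed,
        frc_ml=frc_ml,
    )
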