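"""Synthetic inputs with known ground truth.

Everything the analysis pipeline consumes can be generated here: a
bifurcating airway tree at mouse scale, 4D regional expansion fields that
combine a pressure-controlled ventilation waveform with heart-localised
cardiogenic oscillations, speckle image-volume pairs warped by a known
displacement field (for velocimetry validation), and an acquisition log with
ventilation triggers, ECG R-peaks and an airway-pressure trace (for gating).

Units: mm for space, ms for time, mm^3 for volume (1 mm^3/ms == 1 ml/s),
cmH2O for pressure.  Every generator takes a ``seed`` and is bit-reproducible
for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq

from .tree import AirwaySegment, AirwayTree

__all__ = [
    "VentilationParams",
    "CardiacParams",
    "ExpansionField",
    "SpeckleVolumePair",
    "AcquisitionLog",
    "generate_airway_tree",
    "generate_expansion_field",
    "generate_speckle_volume_pair",
    "generate_acquisition_log",
]


# ---------------------------------------------------------------------------
# airway tree
# ---------------------------------------------------------------------------

def generate_airway_tree(
    n_generations: int = 15,
    trachea_radius: float = 0.6,
    radius_ratio: float = 0.83,
    branch_angle: float = np.deg2rad(35.0),
    trachea_length: float = 3.0,
    length_ratio: float = 0.8,
    angle_jitter: float = 0.1,
    seed: int = 0,
) -> AirwayTree:
    """Build a full binary airway tree of ``n_generations`` levels.

    ``n_generations=1`` is a single trachea segment (generation 0, no
    bifurcations); ``n_generations=15`` spans generations 0..14, and the
    defaults place terminal diameters at ``2 * 0.6 * 0.83**14 ~ 88 um``,
    inside the 85-100 um band typical of the deepest airways resolvable in
    high-resolution mouse lung CT.

    Radii and lengths shrink geometrically; each bifurcation tilts the two
    daughters by ``branch_angle`` about a seeded random azimuth, with a small
    seeded jitter so the tree fills space rather than collapsing to a plane.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    if trachea_radius <= 0:
        raise ValueError("trachea_radius must be > 0")
    if not 0 < radius_ratio < 1:
        raise ValueError("radius_ratio must lie in (0, 1)")

    rng = np.random.default_rng(seed)
    segments: dict[int, AirwaySegment] = {}
    root = AirwaySegment(
        id=0,
        parent_id=None,
        child_ids=[],
        proximal_point=np.zeros(3),
        distal_point=np.array([0.0, 0.0, -trachea_length]),
        radius=trachea_radius,
        generation=0,
    )
    segments[0] = root
    next_id = 1
    frontier = [root]
    for gen in range(1, n_generations):
        radius = trachea_radius * radius_ratio**gen
        length = trachea_length * length_ratio**gen
        new_frontier = []
        for parent in frontier:
            d = parent.direction
            # orthonormal frame around the parent direction
            ref = np.array([1.0, 0.0, 0.0])
            if abs(d @ ref) > 0.9:
                ref = np.array([0.0, 1.0, 0.0])
            e1 = np.cross(d, ref)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(d, e1)
            phi0 = rng.uniform(0, 2 * np.pi)
            for k in (0, 1):
                theta = branch_angle * (1 + angle_jitter * rng.standard_normal())
                phi = phi0 + k * np.pi
                direction = (
                    np.cos(theta) * d
                    + np.sin(theta) * (np.cos(phi) * e1 + np.sin(phi) * e2)
                )
                child = AirwaySegment(
                    id=next_id,
                    parent_id=parent.id,
                    child_ids=[],
                    proximal_point=parent.distal_point.copy(),
                    distal_point=parent.distal_point + length * direction,
                    radius=radius,
                    generation=gen,
                )
                segments[next_id] = child
                parent.child_ids.append(next_id)
                new_frontier.append(child)
                next_id += 1
        frontier = new_frontier
    return AirwayTree(segments)


# ---------------------------------------------------------------------------
# ventilation waveform
# ---------------------------------------------------------------------------

@dataclass
class VentilationParams:
    """Pressure-controlled ventilation: exponential rise during inspiration,
    exponential decay during expiration, in periodic steady state.

    ``t_insp``/``t_exp`` in ms; pressures in cmH2O.  ``tidal_volume_ml`` is
    the requested total-lung tidal volume (sum over regions of max - min
    volume); set it to 0 for a cardiac-only field.  Time constants default to
    a third of each phase so the waveform nearly completes each transition.
    """

    t_insp: float = 120.0
    t_exp: float = 280.0
    inflation_pressure: float = 10.0
    peep: float = 2.0
    tidal_volume_ml: float = 0.2
    tau_insp: float | None = None
    tau_exp: float | None = None

    @property
    def period(self) -> float:
        return self.t_insp + self.t_exp

    def _taus(self) -> tuple[float, float]:
        return (
            self.tau_insp if self.tau_insp is not None else self.t_insp / 3.0,
            self.tau_exp if self.tau_exp is not None else self.t_exp / 3.0,
        )

    def waveform(self, t) -> np.ndarray:
        """Normalised volume drive w(t) in [0, 1]; w(0)=0, w(t_insp)=1.

        Periodic steady state of a first-order system driven by a square
        pressure wave: x' = (P(t) - x)/tau with different inspiratory and
        expiratory time constants.
        """
        ti, te = self.t_insp, self.t_exp
        taui, taue = self._taus()
        t = np.asarray(t, dtype=float) % self.period
        x1 = (1 - np.exp(-ti / taui)) / (1 - np.exp(-ti / taui - te / taue))
        x0 = x1 * np.exp(-te / taue)
        insp = t < ti
        x = np.where(
            insp,
            1 + (x0 - 1) * np.exp(-t / taui),
            x1 * np.exp(-(t - ti) / taue),
        )
        return (x - x0) / (x1 - x0)

    def waveform_derivative(self, t) -> np.ndarray:
        """dw/dt in 1/ms."""
        ti, te = self.t_insp, self.t_exp
        taui, taue = self._taus()
        t = np.asarray(t, dtype=float) % self.period
        x1 = (1 - np.exp(-ti / taui)) / (1 - np.exp(-ti / taui - te / taue))
        x0 = x1 * np.exp(-te / taue)
        insp = t < ti
        dx = np.where(
            insp,
            (1 - x0) * np.exp(-t / taui) / taui,
            -x1 * np.exp(-(t - ti) / taue) / taue,
        )
        return dx / (x1 - x0)

    def pressure(self, t) -> np.ndarray:
        """Airway pressure trace in cmH2O (PEEP at end expiration)."""
        return self.peep + (self.inflation_pressure - self.peep) * self.waveform(t)


@dataclass
class CardiacParams:
    """Cardiogenic oscillation of regional volume.

    The fractional-volume amplitude decays as exp(-d/decay_length) with
    distance d (mm) from the heart locus, and the oscillation phase lags by
    ``phase_lag_per_mm * d`` radians: the beating heart compresses adjacent
    tissue first and the displaced gas reaches remote regions later.  The
    phase lag is what makes near- and far-field regions move out of phase and
    hence drives pendelluft; with ``phase_lag_per_mm=0`` the cardiac field is
    synchronous and produces none.

    ``frequency_ratio`` is the heart rate over the ventilation rate (~3 in
    the ventilated mouse); an integer ratio makes the composite field
    periodic over one ventilation cycle, a slightly incommensurate value
    (e.g. 3.07) decorrelates the two phases.  ``amplitude`` is the fractional
    volume excursion at the heart locus; if ``tidal_volume_ml`` is given the
    amplitude is calibrated so the summed regional cardiac tidal volume
    matches it.
    """

    frequency_ratio: float = 3.0
    amplitude: float = 0.05
    decay_length: float = 3.0
    phase_lag_per_mm: float = 1.5
    heart_locus: np.ndarray | None = None
    tidal_volume_ml: float | None = None

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("cardiac amplitude must be >= 0")


# ---------------------------------------------------------------------------
# expansion field
# ---------------------------------------------------------------------------

@dataclass
class ExpansionField:
    """Regional lung-volume traces over one composite cycle.

    ``region_volumes[i, j]`` is region i's volume (mm^3) at ``phase_times[j]``;
    phase times span [0, period_ms).  The analytic generating model is kept so
    volumes and their exact time derivatives can be evaluated at any time.
    """

    region_centers: np.ndarray          # (n_regions, 3) mm
    phase_times: np.ndarray             # (n_phases,) ms
    region_volumes: np.ndarray          # (n_regions, n_phases) mm^3
    heart_locus: np.ndarray
    ventilation_params: VentilationParams
    cardiac_params: CardiacParams
    baseline_volumes: np.ndarray = field(repr=False, default=None)
    vent_weights: np.ndarray = field(repr=False, default=None)
    vent_delays: np.ndarray = field(repr=False, default=None)
    vent_scale: float = 0.0
    cardiac_amplitude: float = 0.0
    period_ms: float = 400.0
    seed: int = 0

    @property
    def n_regions(self) -> int:
        return self.region_centers.shape[0]

    def _heart_distance(self) -> np.ndarray:
        return np.linalg.norm(self.region_centers - self.heart_locus, axis=1)

    def _cardiac_omega(self) -> float:
        return 2 * np.pi * self.cardiac_params.frequency_ratio / self.period_ms

    def evaluate(self, times) -> np.ndarray:
        """Region volumes (mm^3) at arbitrary times, shape (n_regions, n_times)."""
        t = np.atleast_1d(np.asarray(times, dtype=float))
        vp, cp = self.ventilation_params, self.cardiac_params
        w = vp.waveform(t[None, :] - self.vent_delays[:, None])
        d = self._heart_distance()[:, None]
        amp = self.cardiac_amplitude * np.exp(-d / cp.decay_length)
        card = amp * np.sin(self._cardiac_omega() * t[None, :] - cp.phase_lag_per_mm * d)
        vent = self.vent_scale * self.vent_weights[:, None] * w
        return self.baseline_volumes[:, None] * (1.0 + vent + card)

    def dvdt(self, times) -> np.ndarray:
        """Exact dV/dt (mm^3/ms == ml/s), shape (n_regions, n_times)."""
        t = np.atleast_1d(np.asarray(times, dtype=float))
        vp, cp = self.ventilation_params, self.cardiac_params
        dw = vp.waveform_derivative(t[None, :] - self.vent_delays[:, None])
        d = self._heart_distance()[:, None]
        amp = self.cardiac_amplitude * np.exp(-d / cp.decay_length)
        om = self._cardiac_omega()
        dcard = amp * om * np.cos(om * t[None, :] - cp.phase_lag_per_mm * d)
        dvent = self.vent_scale * self.vent_weights[:, None] * dw
        return self.baseline_volumes[:, None] * (dvent + dcard)

    def total_tidal_volume(self, n_samples: int = 400) -> float:
        """Sum over regions of (max - min) volume over the cycle, mm^3."""
        t = np.linspace(0, self.period_ms, n_samples, endpoint=False)
        v = self.evaluate(t)
        return float(np.sum(v.max(axis=1) - v.min(axis=1)))

    def global_tidal_volume(self, n_samples: int = 400) -> float:
        """Max - min of the summed (whole-lung) volume trace, mm^3."""
        t = np.linspace(0, self.period_ms, n_samples, endpoint=False)
        v = self.evaluate(t).sum(axis=0)
        return float(v.max() - v.min())

    def to_csv(self, path) -> None:
        n, p = self.region_volumes.shape
        df = pd.DataFrame(
            {
                "region": np.repeat(np.arange(n), p),
                "x_mm": np.repeat(self.region_centers[:, 0], p),
                "y_mm": np.repeat(self.region_centers[:, 1], p),
                "z_mm": np.repeat(self.region_centers[:, 2], p),
                "time_ms": np.tile(self.phase_times, n),
                "volume_mm3": self.region_volumes.ravel(),
            }
        )
        df.to_csv(path, index=False)


def generate_expansion_field(
    tree: AirwayTree,
    ventilation_params: VentilationParams | None = None,
    cardiac_params: CardiacParams | None = None,
    n_phases: int = 19,
    baseline_lung_volume: float = 500.0,
    heterogeneity: float = 0.2,
    vent_time_jitter_ms: float = 3.0,
    center_jitter: float = 0.3,
    seed: int = 0,
) -> ExpansionField:
    """Generate regional volume traces over one composite cycle.

    One tissue region is placed at (a jittered copy of) each terminal
    airway's distal end-point; baselines split ``baseline_lung_volume`` (mm^3,
    default 0.5 ml ~ mouse FRC at PEEP) with seeded log-normal heterogeneity.
    The ventilation component is calibrated so the total tidal volume matches
    ``ventilation_params.tidal_volume_ml`` to well within 1%; the cardiac
    amplitude is either taken directly or calibrated against
    ``cardiac_params.tidal_volume_ml`` with ventilation off.

    ``vent_time_jitter_ms`` gives each region a small seeded time shift of
    the ventilation waveform, emulating regional time-constant
    (compliance/resistance) heterogeneity; it is the source of the small but
    non-zero pendelluft seen under pure mechanical ventilation.
    """
    vp = ventilation_params if ventilation_params is not None else VentilationParams()
    cp = cardiac_params if cardiac_params is not None else CardiacParams()
    if vp.tidal_volume_ml < 0:
        raise ValueError("ventilation tidal volume must be >= 0")
    if cp.amplitude < 0:
        raise ValueError("cardiac amplitude must be >= 0")

    rng = np.random.default_rng(seed)
    term = tree.terminal_ids
    centers = np.array([tree[i].distal_point for i in term], dtype=float)
    centers = centers + center_jitter * rng.standard_normal(centers.shape)

    weights = np.exp(heterogeneity * rng.standard_normal(len(term)))
    baselines = baseline_lung_volume * weights / weights.sum()
    vent_weights = np.exp(heterogeneity * rng.standard_normal(len(term)))
    vent_weights /= vent_weights.mean()
    vent_delays = vent_time_jitter_ms * rng.standard_normal(len(term))

    if cp.heart_locus is None:
        # off-centre locus near the mid-lung, mimicking the heart's position
        lo, hi = centers.min(axis=0), centers.max(axis=0)
        heart = lo + np.array([0.3, 0.5, 0.55]) * (hi - lo)
    else:
        heart = np.asarray(cp.heart_locus, dtype=float)

    period = vp.period
    phase_times = np.linspace(0.0, period, n_phases, endpoint=False)
    f = ExpansionField(
        region_centers=centers,
        phase_times=phase_times,
        region_volumes=np.empty((len(term), n_phases)),
        heart_locus=heart,
        ventilation_params=vp,
        cardiac_params=cp,
        baseline_volumes=baselines,
        vent_weights=vent_weights,
        vent_delays=vent_delays,
        vent_scale=0.0,
        cardiac_amplitude=cp.amplitude,
        period_ms=period,
        seed=seed,
    )

    if cp.tidal_volume_ml is not None:
        target = cp.tidal_volume_ml * 1000.0
        if target == 0:
            f.cardiac_amplitude = 0.0
        else:
            def card_miss(a):
                f.cardiac_amplitude = a
                return f.total_tidal_volume() - target

            f.cardiac_amplitude = brentq(card_miss, 0.0, 1.0, xtol=1e-12)

    if vp.tidal_volume_ml > 0:
        target = vp.tidal_volume_ml * 1000.0

        def vent_miss(s):
            f.vent_scale = s
            return f.total_tidal_volume() - target

        # total tidal volume is monotone in the ventilation scale
        hi = 2.0 * target / baseline_lung_volume + 1.0
        f.vent_scale = brentq(vent_miss, 0.0, hi, xtol=1e-12)

    f.region_volumes = f.evaluate(phase_times)
    if np.any(f.region_volumes <= 0):
        raise ValueError("generated volumes not strictly positive; reduce amplitudes")
    return f


# ---------------------------------------------------------------------------
# speckle phantom
# ---------------------------------------------------------------------------

@dataclass
class SpeckleVolumePair:
    """Reference/deformed 3D speckle volumes with known ground truth.

    The deformed volume is the reference resampled through the displacement
    field u (voxels): ``deformed(x) = reference(x - u(x))``, i.e. a feature at
    x in the reference appears near ``x + u`` in the deformed volume, so
    velocimetry measuring deformed-relative-to-reference should recover +u.
    """

    reference_volume: np.ndarray
    deformed_volume: np.ndarray
    voxel_size_um: float
    true_displacement: np.ndarray   # (3,) + shape, voxels
    seed: int = 0


def generate_speckle_volume_pair(
    shape: tuple[int, int, int],
    true_displacement,
    noise_level: float = 0.0,
    voxel_size_um: float = 15.0,
    blob_sigma: tuple[float, float] = (1.5, 3.5),
    seed: int = 0,
) -> SpeckleVolumePair:
    """Band-passed random speckle (blob scale ~4-8 voxels) warped by a known
    displacement field.

    ``true_displacement`` may be a length-3 vector (uniform motion) or a
    ``(3,) + shape`` field in voxels.  Warping uses cubic-spline resampling
    with grid wrapping, so a uniform integer shift reproduces ``np.roll``
    exactly.
    """
    shape = tuple(int(s) for s in shape)
    u = np.asarray(true_displacement, dtype=float)
    if u.shape == (3,):
        u = np.broadcast_to(u[:, None, None, None], (3,) + shape).copy()
    if u.shape != (3,) + shape:
        raise ValueError(
            f"displacement field shape {u.shape} does not match (3,)+{shape}"
        )
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(shape)
    ref = ndimage.gaussian_filter(white, blob_sigma[0]) - ndimage.gaussian_filter(
        white, blob_sigma[1]
    )
    ref /= ref.std()
    grid = np.indices(shape, dtype=float)
    deformed = ndimage.map_coordinates(ref, grid - u, order=3, mode="grid-wrap")
    if noise_level > 0:
        deformed = deformed + noise_level * rng.standard_normal(shape)
    return SpeckleVolumePair(
        reference_volume=ref,
        deformed_volume=deformed,
        voxel_size_um=voxel_size_um,
        true_displacement=u,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# acquisition log
# ---------------------------------------------------------------------------

@dataclass
class AcquisitionLog:
    """Frame clock, ventilation triggers, ECG R-peaks and airway pressure."""

    frame_times: np.ndarray             # ms
    ventilation_trigger_times: np.ndarray
    ecg_rpeak_times: np.ndarray
    airway_pressure: np.ndarray         # cmH2O, one per frame
    seed: int = 0

    def to_csv(self, path) -> None:
        """Long-format CSV: columns time_ms, event, pressure_cmH2O."""
        frames = pd.DataFrame(
            {
                "time_ms": self.frame_times,
                "event": "frame",
                "pressure_cmH2O": self.airway_pressure,
            }
        )
        trig = pd.DataFrame(
            {
                "time_ms": self.ventilation_trigger_times,
                "event": "vent_trigger",
                "pressure_cmH2O": np.nan,
            }
        )
        ecg = pd.DataFrame(
            {
                "time_ms": self.ecg_rpeak_times,
                "event": "ecg_rpeak",
                "pressure_cmH2O": np.nan,
            }
        )
        pd.concat([frames, trig, ecg]).sort_values("time_ms").to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "AcquisitionLog":
        df = pd.read_csv(path)
        frames = df[df.event == "frame"]
        return cls(
            frame_times=frames.time_ms.to_numpy(float),
            ventilation_trigger_times=df[df.event == "vent_trigger"].time_ms.to_numpy(float),
            ecg_rpeak_times=df[df.event == "ecg_rpeak"].time_ms.to_numpy(float),
            airway_pressure=frames.pressure_cmH2O.to_numpy(float),
        )


def generate_acquisition_log(
    duration_ms: float,
    ventilation_period_ms: float = 400.0,
    heart_period_ms: float = 130.0,
    frame_rate_hz: float = 50.0,
    ventilation_params: VentilationParams | None = None,
    jitter_ms: float = 0.0,
    pressure_noise: float = 0.0,
    seed: int = 0,
) -> AcquisitionLog:
    """Simulate an imaging run: frames at fixed rate, periodic ventilation
    triggers, quasi-periodic R-peaks with Gaussian jitter, and a
    pressure-controlled airway-pressure trace cycling between PEEP and the
    inflation pressure."""
    if heart_period_ms <= 0:
        raise ValueError("heart_period_ms must be > 0")
    if duration_ms < 2 * ventilation_period_ms:
        raise ValueError("duration must cover at least two ventilation cycles")
    vp = ventilation_params if ventilation_params is not None else VentilationParams()
    if abs(vp.period - ventilation_period_ms) > 1e-9:
        vp = VentilationParams(
            t_insp=vp.t_insp * ventilation_period_ms / vp.period,
            t_exp=vp.t_exp * ventilation_period_ms / vp.period,
            inflation_pressure=vp.inflation_pressure,
            peep=vp.peep,
        )
    rng = np.random.default_rng(seed)
    frame_dt = 1000.0 / frame_rate_hz
    n_frames = int(np.floor(duration_ms / frame_dt))
    frame_times = np.arange(n_frames) * frame_dt
    triggers = np.arange(0.0, duration_ms, ventilation_period_ms)
    n_beats = int(np.ceil(duration_ms / heart_period_ms)) + 1
    intervals = heart_period_ms + jitter_ms * rng.standard_normal(n_beats)
    rpeaks = np.concatenate([[0.0], np.cumsum(intervals)])
    rpeaks = rpeaks[rpeaks < duration_ms]
    pressure = vp.pressure(frame_times)
    if pressure_noise > 0:
        pressure = pressure + pressure_noise * rng.standard_normal(n_frames)
    return AcquisitionLog(
        frame_times=frame_times,
        ventilation_trigger_times=triggers,
        ecg_rpeak_times=rpeaks,
        airway_pressure=pressure,
        seed=seed,
    )
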