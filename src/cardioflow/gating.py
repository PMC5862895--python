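"""Retrospective cardiorespiratory double-gating.

Acquisition frames are binned twice, independently: into ventilation-phase
bins from the ventilator trigger train, and into cardiac-phase bins from the
ECG R-peak train.  Cardiac binning additionally applies a pressure filter —
only frames acquired at airway pressure strictly below a threshold (default
4 cmH2O) enter cardiac bins, which restricts the cardiac data to
approximately end-expiratory lung inflation and suppresses ventilation
motion blur.

Phase is the elapsed fraction of the frame's own cycle, computed in [0, 1)
with a half-open convention (a frame exactly on the next trigger starts the
next cycle); bin = floor(fraction * n_bins).  Frames after the final trigger
extrapolate their phase with the median cycle length (wrapped modulo 1) and
are flagged; frames before the first trigger cannot be phased and are
reported, not dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .synthetic import AcquisitionLog

__all__ = ["GatingResult", "double_gate_frames"]


@dataclass
class GatingResult:
    ventilation_bins: list[list[int]]
    cardiac_bins: list[list[int]]
    excluded_from_cardiac: list[int]       # pressure >= threshold
    unbinnable: list[int]                  # before the first ventilation trigger
    cardiac_unassigned: list[int]          # before the first R-peak (and not excluded)
    extrapolated: list[int] = field(default_factory=list)  # after final trigger/R-peak
    n_frames: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "n_frames": self.n_frames,
                    "ventilation_bins": self.ventilation_bins,
                    "cardiac_bins": self.cardiac_bins,
                    "excluded_from_cardiac": self.excluded_from_cardiac,
                    "unbinnable": self.unbinnable,
                    "cardiac_unassigned": self.cardiac_unassigned,
                    "extrapolated": self.extrapolated,
                },
                fh,
            )


def _phase_fractions(times: np.ndarray, triggers: np.ndarray):
    """Elapsed cycle fraction in [0,1) for each time, given a trigger train.

    Returns (fraction, before_first, extrapolated) arrays.  The last cycle
    (after the final trigger) uses the median inter-trigger interval.
    """
    triggers = np.asarray(triggers, dtype=float)
    idx = np.searchsorted(triggers, times, side="right") - 1
    before = idx < 0
    last = idx == len(triggers) - 1
    idx_safe = np.clip(idx, 0, len(triggers) - 1)
    starts = triggers[idx_safe]
    if len(triggers) >= 2:
        lengths = np.diff(triggers)
        median_len = float(np.median(lengths))
        cycle_len = np.where(last, median_len, lengths[np.clip(idx_safe, 0, len(lengths) - 1)])
    else:
        median_len = np.nan
        cycle_len = np.full_like(starts, np.nan)
    frac = (times - starts) / cycle_len
    frac = np.mod(frac, 1.0)
    return frac, before, last & ~before


def double_gate_frames(
    log: AcquisitionLog,
    n_vent_bins: int = 19,
    n_card_bins: int = 8,
    pressure_threshold: float = 4.0,
) -> GatingResult:
    """Assign every frame to one ventilation bin and at most one cardiac bin.

    Every frame lands in exactly one of ``n_vent_bins`` ventilation bins
    (unless it precedes the first trigger, in which case it is listed as
    unbinnable).  Cardiac bins only accept frames with airway pressure
    strictly below ``pressure_threshold`` cmH2O.
    """
    t = np.asarray(log.frame_times, dtype=float)
    if len(log.ventilation_trigger_times) < 1:
        raise ValueError("log must contain at least one ventilation trigger")
    if len(log.ecg_rpeak_times) < 2:
        raise ValueError("log must contain at least two R-peaks")

    res = GatingResult(
        ventilation_bins=[[] for _ in range(n_vent_bins)],
        cardiac_bins=[[] for _ in range(n_card_bins)],
        excluded_from_cardiac=[],
        unbinnable=[],
        cardiac_unassigned=[],
        n_frames=len(t),
    )

    vfrac, vbefore, vextrap = _phase_fractions(t, log.ventilation_trigger_times)
    vbins = np.floor(vfrac * n_vent_bins).astype(int)
    vbins = np.minimum(vbins, n_vent_bins - 1)

    cfrac, cbefore, cextrap = _phase_fractions(t, log.ecg_rpeak_times)
    cbins = np.floor(cfrac * n_card_bins).astype(int)
    cbins = np.minimum(cbins, n_card_bins - 1)

    pressure_ok = np.asarray(log.airway_pressure, dtype=float) < pressure_threshold

    extrap = set()
    for i in range(len(t)):
        if vbefore[i]:
            res.unbinnable.append(i)
        else:
            res.ventilation_bins[vbins[i]].append(i)
            if vextrap[i]:
                extrap.add(i)
        if not pressure_ok[i]:
            res.excluded_from_cardiac.append(i)
        elif cbefore[i]:
            res.cardiac_unassigned.append(i)
        else:
            res.cardiac_bins[cbins[i]].append(i)
            if cextrap[i]:
                extrap.add(i)
    res.extrapolated = sorted(extrap)
    return res
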