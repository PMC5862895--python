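"""3D cross-correlation velocimetry and volumetric expansion.

Displacement between two successive gated volumes is measured per cubic
interrogation window (default 32^3 voxels at 16-voxel pitch; at 15 um voxels
that is a 480 um window every 240 um) as the offset of the cross-correlation
peak of the mean-subtracted windows, refined to sub-voxel precision with a
three-point Gaussian fit per axis.  Expansion (fractional volume change) is
det(I + grad u) - 1 from central finite differences of the displacement on
the region lattice — exact for finite strains and reducing to the divergence
for small ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft

__all__ = [
    "RegionGrid",
    "cross_correlate_displacement",
    "expansion_from_displacement",
    "region_volumes_from_expansion",
]


@dataclass
class RegionGrid:
    """Lattice of interrogation regions with per-region displacement.

    ``displacement`` is in voxels (deformed relative to reference; sub-voxel
    refined); ``displacement_int`` is the raw integer correlation-peak offset.
    ``valid`` is False for windows that are flat, masked out, or whose peak
    could not be measured.  Arrays are shaped ``grid_shape + trailing``.
    """

    centers_vox: np.ndarray        # grid_shape + (3,)
    window: int
    spacing: int
    voxel_size_um: float
    displacement: np.ndarray       # grid_shape + (3,), voxels
    displacement_int: np.ndarray   # grid_shape + (3,), voxels
    valid: np.ndarray              # grid_shape, bool
    expansion: np.ndarray | None = None
    expansion_valid: np.ndarray | None = None

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.valid.shape

    @property
    def displacement_um(self) -> np.ndarray:
        return self.displacement * self.voxel_size_um

    @property
    def centers_um(self) -> np.ndarray:
        return self.centers_vox * self.voxel_size_um


def _gaussian_subvoxel(corr: np.ndarray, peak: tuple[int, ...]) -> np.ndarray:
    """Three-point Gaussian peak interpolation along each axis.

    Falls back to 0 on an axis whose neighbours are non-positive or whose fit
    is degenerate (|delta| >= 1).
    """
    delta = np.zeros(3)
    for ax in range(3):
        n = corr.shape[ax]
        idx = list(peak)
        c0 = corr[tuple(idx)]
        idx[ax] = (peak[ax] - 1) % n
        cm = corr[tuple(idx)]
        idx[ax] = (peak[ax] + 1) % n
        cp = corr[tuple(idx)]
        if c0 <= 0 or cm <= 0 or cp <= 0:
            continue
        denom = 2 * (np.log(cm) + np.log(cp) - 2 * np.log(c0))
        if denom >= 0:
            continue
        d = (np.log(cm) - np.log(cp)) / denom
        if abs(d) < 1:
            delta[ax] = d
    return delta


def cross_correlate_displacement(
    vol_a: np.ndarray,
    vol_b: np.ndarray,
    window: int = 32,
    spacing: int = 16,
    mask: np.ndarray | None = None,
    min_mask_fraction: float = 0.5,
    subvoxel: bool = True,
) -> RegionGrid:
    """Per-window modal displacement of ``vol_b`` relative to ``vol_a``.

    Windows are mean-subtracted and correlated in the frequency domain
    (circular correlation; valid while displacements are well below half the
    window).  Equal correlation maxima break ties toward the lowest offset
    norm.  Zero-variance windows, and windows whose masked-in fraction is
    below ``min_mask_fraction``, are flagged invalid rather than returned as
    zero.
    """
    vol_a = np.asarray(vol_a, dtype=float)
    vol_b = np.asarray(vol_b, dtype=float)
    if vol_a.shape != vol_b.shape:
        raise ValueError("volumes must have the same shape")
    if any(window > s for s in vol_a.shape):
        raise ValueError("window does not fit inside the volume")
    if spacing > window:
        raise ValueError("spacing must be <= window")

    starts = [np.arange(0, s - window + 1, spacing) for s in vol_a.shape]
    gshape = tuple(len(s) for s in starts)
    centers = np.zeros(gshape + (3,))
    disp = np.full(gshape + (3,), np.nan)
    disp_int = np.zeros(gshape + (3,), dtype=int)
    valid = np.zeros(gshape, dtype=bool)

    # signed offsets corresponding to FFT correlation lags
    lag = np.arange(window)
    lag = np.where(lag > window // 2, lag - window, lag)

    for ii, i0 in enumerate(starts[0]):
        for jj, j0 in enumerate(starts[1]):
            for kk, k0 in enumerate(starts[2]):
                sl = (slice(i0, i0 + window), slice(j0, j0 + window), slice(k0, k0 + window))
                centers[ii, jj, kk] = [i0 + window / 2, j0 + window / 2, k0 + window / 2]
                if mask is not None and mask[sl].mean() < min_mask_fraction:
                    continue
                a = vol_a[sl]
                b = vol_b[sl]
                a = a - a.mean()
                b = b - b.mean()
                if not a.any() or not b.any():
                    continue  # flat window: invalid, not zero
                corr = sp_fft.irfftn(
                    np.conj(sp_fft.rfftn(a)) * sp_fft.rfftn(b), s=a.shape
                )
                peak_val = corr.max()
                cand = np.argwhere(np.isclose(corr, peak_val, rtol=0, atol=0))
                if len(cand) > 1:
                    norms = np.sum(lag[cand] ** 2, axis=1)
                    peak = tuple(cand[np.argmin(norms)])
                else:
                    peak = tuple(cand[0])
                offset = lag[list(peak)].astype(float)
                disp_int[ii, jj, kk] = offset.astype(int)
                if subvoxel:
                    offset = offset + _gaussian_subvoxel(corr, peak)
                disp[ii, jj, kk] = offset
                valid[ii, jj, kk] = True

    return RegionGrid(
        centers_vox=centers,
        window=window,
        spacing=spacing,
        voxel_size_um=15.0,
        displacement=disp,
        displacement_int=disp_int,
        valid=valid,
    )


def expansion_from_displacement(
    displacement: np.ndarray,
    spacing: float,
    valid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fractional volume change det(I + grad u) - 1 per lattice region.

    ``displacement`` is ``grid_shape + (3,)`` in voxels on a lattice of pitch
    ``spacing`` voxels.  Gradients use central differences in the interior
    and one-sided differences at lattice edges (``np.gradient``).  Invalid
    regions poison their finite-difference neighbours: the returned validity
    mask is False wherever any stencil input was invalid (an isolated valid
    region therefore comes back invalid too).

    Returns ``(expansion, valid_out)``.
    """
    u = np.asarray(displacement, dtype=float).copy()
    if u.ndim != 4 or u.shape[-1] != 3:
        raise ValueError("displacement must have shape grid_shape + (3,)")
    if valid is not None:
        u[~valid] = np.nan
    grad = np.empty(u.shape[:3] + (3, 3))
    for i in range(3):
        gi = np.gradient(u[..., i], spacing, axis=(0, 1, 2))
        for j in range(3):
            grad[..., i, j] = gi[j]
    f_mat = grad + np.eye(3)
    finite = np.all(np.isfinite(f_mat), axis=(-2, -1))
    # a region with no displacement of its own has no expansion either, even
    # if the central-difference stencil happens to skip it
    finite &= np.all(np.isfinite(u), axis=-1)
    expansion = np.full(u.shape[:3], np.nan)
    if finite.any():
        expansion[finite] = np.linalg.det(f_mat[finite]) - 1.0
    return expansion, finite


def region_volumes_from_expansion(
    expansion_steps: np.ndarray,
    window: int = 32,
    voxel_size_um: float = 15.0,
) -> np.ndarray:
    """Per-region volume traces (mm^3) from phase-to-phase expansions.

    ``expansion_steps`` is (n_steps,) + grid_shape, the fractional volume
    change between successive gated phases.  Each region starts at the
    interrogation-window volume and compounds multiplicatively:
    V_0 = (window * voxel)^3, V_{p+1} = V_p * (1 + e_p).  Returns an array of
    shape (n_steps + 1,) + grid_shape.
    """
    e = np.asarray(expansion_steps, dtype=float)
    v0 = (window * voxel_size_um / 1000.0) ** 3
    vols = np.empty((e.shape[0] + 1,) + e.shape[1:])
    vols[0] = v0
    for p in range(e.shape[0]):
        vols[p + 1] = vols[p] * (1.0 + e[p])
    return vols
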