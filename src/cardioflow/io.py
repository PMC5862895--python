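"""Volume i/o helpers: NIfTI (via nibabel) or .npy, chosen by extension."""

from __future__ import annotations

from pathlib import Path

import numpy as np


def save_volume(path, volume: np.ndarray, voxel_size_um: float = 15.0) -> None:
    """Write a 3D scalar volume as NIfTI (.nii/.nii.gz) or .npy.

    NIfTI affines carry the isotropic voxel size in mm.
    """
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, volume)
        return
    import nibabel as nib

    affine = np.diag([voxel_size_um / 1000.0] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))


def load_volume(path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".npy":
        return np.load(path)
    import nibabel as nib

    return np.asarray(nib.load(str(path)).dataobj, dtype=float)
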