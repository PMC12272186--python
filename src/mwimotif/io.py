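"""NIfTI / HDF5 / JSON input-output helpers.

Maps travel as NIfTI-1 with the geometry of the input volume; phantom
outputs get an identity affine scaled by the declared voxel size.  The
single-T2 dictionary round-trips through HDF5 with its grids, curve array
and a JSON metadata block (sequence, backend, normalization), so a fit can
be reproduced without re-simulating.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .simulate import SequenceParams, SingleT2Dictionary

__all__ = [
    "save_map",
    "load_map",
    "save_dictionary",
    "load_dictionary",
    "save_manifest",
]


def save_map(
    path: str | Path,
    data: np.ndarray,
    affine: np.ndarray | None = None,
    voxel_size_mm: float = 1.0,
) -> None:
    """Write a 2-D/3-D map as NIfTI-1 (identity affine scaled by voxel size
    when none is given)."""
    data = np.asarray(data, dtype=np.float64)
    if affine is None:
        affine = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
    if data.ndim == 2:
        data = data[:, :, None]
    nib.save(nib.Nifti1Image(data, affine), str(path))


def load_map(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI map; returns (array, affine) with singleton axes kept."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), img.affine


def save_dictionary(path: str | Path, dictionary: SingleT2Dictionary) -> None:
    meta = {
        "seq": dataclasses.asdict(dictionary.seq),
        "backend": dictionary.backend,
        "normalization_mode": dictionary.normalization_mode,
    }
    with h5py.File(str(path), "w") as f:
        f.create_dataset("t2_grid", data=dictionary.t2_grid)
        f.create_dataset("b1_grid", data=dictionary.b1_grid)
        f.create_dataset("curves", data=dictionary.curves)
        f.attrs["meta"] = json.dumps(meta)


def load_dictionary(path: str | Path) -> SingleT2Dictionary:
    with h5py.File(str(path), "r") as f:
        meta = json.loads(f.attrs["meta"])
        return SingleT2Dictionary(
            t2_grid=f["t2_grid"][()],
            b1_grid=f["b1_grid"][()],
            curves=f["curves"][()],
            seq=SequenceParams(**meta["seq"]),
            backend=meta["backend"],
            normalization_mode=meta["normalization_mode"],
        )


def save_manifest(path: str | Path, params: dict) -> None:
    """Write a reproducibility manifest (every parameter actually used)."""
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(params, indent=2, default=default, sort_keys=True))
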