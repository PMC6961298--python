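"""NIfTI and dataset I/O.

Parameter maps are written as float32 NIfTI-1 volumes sharing the input
affine; the fit-status map is integer-coded.  Simulated cohorts are laid
out as one 4-D DWI volume and one mask per patient next to a shared
.bval file, a true-value cohort CSV, a diameter-trajectory CSV and a
manifest recording the config, seed and SHA-256 of every written file.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .models import BValueScheme
from .simulate import CohortSim, TrajectoryConfig, generate_trajectories

__all__ = [
    "load_volume",
    "save_map",
    "save_maps",
    "write_cohort_dataset",
    "file_sha256",
]


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_map(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    """Write one parameter map as float32 NIfTI (int16 for status maps)."""
    dtype = np.int16 if np.issubdtype(np.asarray(data).dtype, np.integer) else np.float32
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), affine)
    nib.save(img, str(path))


def save_maps(maps: dict[str, np.ndarray], affine: np.ndarray, out_dir: str | Path,
              prefix: str = "") -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, data in maps.items():
        path = out_dir / f"{prefix}{name}.nii"
        save_map(data, affine, path)
        written.append(path)
    return written


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_cohort_dataset(sim: CohortSim, out_dir: str | Path,
                         tconfig: TrajectoryConfig = TrajectoryConfig()) -> Path:
    """Write a simulated cohort to disk and return the manifest path.

    Layout: <out>/scheme.bval, <out>/dwi/<pid>_dwi.nii + <pid>_mask.nii,
    <out>/cohort_true.csv, <out>/trajectories.csv, <out>/manifest.json.
    Trajectory randomness is derived from the cohort seed, so the whole
    dataset is a pure function of the simulation config.
    """
    out = Path(out_dir)
    (out / "dwi").mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    written: list[Path] = []

    bval = out / "scheme.bval"
    sim.scheme.to_bval(bval)
    written.append(bval)

    for pid, vol, mask in zip(sim.cohort["patient_id"], sim.volumes, sim.masks):
        for name, data in ((f"{pid}_dwi.nii", vol.astype(np.float32)),
                           (f"{pid}_mask.nii", mask.astype(np.int16))):
            p = out / "dwi" / name
            save_map(data, affine, p)
            written.append(p)

    cohort_csv = out / "cohort_true.csv"
    sim.cohort.to_csv(cohort_csv, index=False)
    written.append(cohort_csv)

    traj = generate_trajectories(sim.cohort[["patient_id", "category"]], tconfig,
                                 seed=sim.config.seed + 1)
    traj_csv = out / "trajectories.csv"
    traj.to_csv(traj_csv, index=False)
    written.append(traj_csv)

    manifest = {
        "seed": sim.config.seed,
        "config": {
            "n_responders": sim.config.n_responders,
            "n_nonresponders": sim.config.n_nonresponders,
            "snr_b0": None if np.isinf(sim.config.snr_b0) else sim.config.snr_b0,
            "voxels_per_patient": sim.config.voxels_per_patient,
            "n_slices": sim.config.n_slices,
            "model": sim.config.model,
            "within_tumor_cv": sim.config.within_tumor_cv,
            "b_values": list(sim.scheme.b_values),
            "nex": list(sim.scheme.nex),
        },
        "files": {str(p.relative_to(out)): file_sha256(p) for p in sorted(written)},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest_path
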