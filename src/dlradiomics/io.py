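"""Reading and writing the pipeline's on-disk artifacts.

Volumes, masks and probability maps travel as NIfTI (via nibabel) with
axis order (z, y, x) and nonzero mask voxels meaning tumor.  The cohort
manifest is a CSV with header ``case_id,label,diagnosis_time,
channel_paths,mask_path`` (channel paths separated by ``;``).  Feature
matrices and reports are CSV; filter-response sets are NumPy archives
with a JSON sidecar.  Every artifact round-trips to an equal in-memory
object.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .features import FilterResponseSet
from .phantom import LabeledVolume

__all__ = [
    "write_volume",
    "read_volume",
    "write_cohort",
    "load_cohort",
    "save_responses",
    "load_responses",
    "save_feature_matrix",
    "load_feature_matrix",
    "ManifestError",
]

MANIFEST_COLUMNS = ["case_id", "label", "diagnosis_time", "channel_paths", "mask_path"]


class ManifestError(ValueError):
    """The manifest or a file it references is invalid."""


def write_volume(array: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(array, dtype=np.float64), np.eye(4)), str(path))


def read_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)


def write_cohort(cohort: list[LabeledVolume], out_dir) -> Path:
    """Write per-channel NIfTIs, masks and the manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for vol in cohort:
        chans = []
        for c in range(vol.n_channels):
            p = out_dir / f"{vol.case_id}_ch{c}.nii.gz"
            write_volume(vol.intensities[c], p)
            chans.append(p.name)
        mask_path = out_dir / f"{vol.case_id}_mask.nii.gz"
        write_volume(vol.mask.astype(np.float64), mask_path)
        rows.append(
            {
                "case_id": vol.case_id,
                "label": vol.label,
                "diagnosis_time": vol.diagnosis_time,
                "channel_paths": ";".join(chans),
                "mask_path": mask_path.name,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def load_cohort(manifest_path) -> list[LabeledVolume]:
    """Load every case listed in a manifest, validating as we go."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    missing_cols = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ManifestError(f"manifest missing columns {sorted(missing_cols)}")
    if df["case_id"].duplicated().any():
        dupes = df.loc[df["case_id"].duplicated(), "case_id"].tolist()
        raise ManifestError(f"duplicate case_ids {dupes}")
    base = manifest_path.parent
    cohort = []
    for row in df.itertuples():
        if row.label not in (0, 1):
            raise ManifestError(f"case {row.case_id}: label {row.label} not in {{0,1}}")
        chan_paths = [base / p for p in str(row.channel_paths).split(";")]
        mask_path = base / str(row.mask_path)
        for p in [*chan_paths, mask_path]:
            if not p.exists():
                raise ManifestError(f"case {row.case_id}: missing file {p}")
        channels = [read_volume(p) for p in chan_paths]
        shapes = {c.shape for c in channels}
        if len(shapes) != 1:
            raise ManifestError(f"case {row.case_id}: channel shapes differ: {shapes}")
        mask = read_volume(mask_path)
        if mask.shape != channels[0].shape:
            raise ManifestError(
                f"case {row.case_id}: mask shape {mask.shape} != channel shape "
                f"{channels[0].shape}"
            )
        cohort.append(
            LabeledVolume(
                intensities=np.stack(channels),
                mask=(mask != 0).astype(np.uint8),
                label=int(row.label),
                case_id=str(row.case_id),
                diagnosis_time=int(row.diagnosis_time),
            )
        )
    return cohort


def save_responses(rset: FilterResponseSet, path) -> None:
    """Response archive plus a JSON sidecar describing the pooling order."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), responses=rset.responses)
    sidecar = {
        "case_id": rset.case_id,
        "n_filters": rset.n_filters,
        "length": rset.length,
        "ordering": "slice-major, then scale, then row-major pixels",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_responses(path) -> FilterResponseSet:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as data:
        responses = data["responses"]
    return FilterResponseSet(case_id=sidecar["case_id"], responses=responses)


def save_feature_matrix(values: np.ndarray, case_ids, path, layout: str = "fko-v1") -> None:
    """Cases x features CSV; header is the feature index, layout versioned."""
    df = pd.DataFrame(values, index=pd.Index(case_ids, name=f"case_id[{layout}]"))
    df.to_csv(path)


def load_feature_matrix(path):
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=np.float64), df.index.to_list()
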