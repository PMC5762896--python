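"""NIfTI and manifest plumbing.

Volumes and masks travel as ``.nii.gz`` with an RAS affine whose diagonal
carries the voxel spacing in mm.  A cohort is described by a CSV manifest
with one row per lesion: ``lesion_id, pre_path, post1_path, post2_path,
post3_path, mask_path, label`` (label 0 = no re-excision, 1 = re-excision).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ValidationError
from .phantom import SCAN_TAGS, Lesion

MANIFEST_COLUMNS = [
    "lesion_id", "pre_path", "post1_path", "post2_path", "post3_path",
    "mask_path", "label",
]


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_volume(path: Path, values: np.ndarray, spacing) -> None:
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), _affine(spacing))
    nib.save(img, str(path))


def load_volume(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata(), dtype=np.float64), spacing


def write_cohort(lesions, out_dir: Path) -> Path:
    """Write every lesion's volumes + mask and the manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for lesion in lesions:
        row = {"lesion_id": lesion.lesion_id, "label": lesion.label}
        for tag in SCAN_TAGS:
            p = out_dir / f"{lesion.lesion_id}_{tag}.nii.gz"
            save_volume(p, lesion.volumes[tag], lesion.spacing)
            row[f"{tag}_path"] = p.name
        mask_path = out_dir / f"{lesion.lesion_id}_mask.nii.gz"
        save_volume(mask_path, lesion.mask.astype(np.uint8), lesion.spacing)
        row["mask_path"] = mask_path.name
        rows.append(row)
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def read_cohort(manifest_path: Path) -> list[Lesion]:
    """Load a cohort back from its manifest (paths relative to the manifest)."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"manifest missing columns: {sorted(missing)}")
    lesions = []
    for _, row in df.iterrows():
        volumes = {}
        spacing = (1.0, 1.0, 1.0)
        for tag in SCAN_TAGS:
            path = base / row[f"{tag}_path"]
            if not path.exists():
                raise ValidationError(f"missing volume file: {path}")
            volumes[tag], spacing = load_volume(path)
        mask_arr, _ = load_volume(base / row["mask_path"])
        lesions.append(
            Lesion(
                lesion_id=str(row["lesion_id"]),
                volumes=volumes,
                mask=mask_arr > 0.5,
                label=int(row["label"]),
                spacing=spacing,
            )
        )
    return lesions
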