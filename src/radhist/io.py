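"""Reading and writing the package's standard formats.

* Volumes/masks: NIfTI (.nii / .nii.gz) through nibabel, NRRD (.nrrd)
  through SimpleITK.  Arrays are returned in array-index order with the
  matching per-axis spacing in mm; masks are written as 0/1 volumes.
* Feature tables: delimited text (TSV by default) whose first two columns
  are ``sample_id`` and ``label``, followed by feature columns.
* Configs: YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .image import ImageVolume, TumorMask

__all__ = [
    "read_volume", "write_volume", "read_mask", "write_mask",
    "read_feature_table", "write_feature_table", "split_xy",
    "read_yaml", "write_yaml",
]


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_volume(path) -> ImageVolume:
    path = Path(path)
    if _is_nifti(path):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return ImageVolume(data, spacing)
    if path.suffix.lower() == ".nrrd":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img).astype(float)  # (z, y, x)
        spacing = tuple(reversed([float(s) for s in img.GetSpacing()]))
        return ImageVolume(data, spacing)
    raise ValueError(f"unsupported volume format: {path.name}")


def write_volume(volume: ImageVolume, path) -> None:
    path = Path(path)
    if _is_nifti(path):
        import nibabel as nib

        affine = np.diag(list(volume.spacing) + [1.0])
        nib.save(nib.Nifti1Image(volume.values, affine), str(path))
        return
    if path.suffix.lower() == ".nrrd":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(volume.values)
        img.SetSpacing(tuple(reversed(volume.spacing)))
        sitk.WriteImage(img, str(path))
        return
    raise ValueError(f"unsupported volume format: {path.name}")


def read_mask(path) -> TumorMask:
    vol = read_volume(path)
    return TumorMask((vol.values > 0.5).astype(np.uint8))


def write_mask(mask: TumorMask, path, spacing=(1.0, 1.0, 1.0)) -> None:
    write_volume(ImageVolume(mask.flags.astype(float), spacing), path)


def write_feature_table(table: pd.DataFrame, path, sep: str = "\t") -> None:
    cols = list(table.columns)
    if cols[:2] != ["sample_id", "label"]:
        raise ValueError("feature table must start with sample_id, label columns")
    table.to_csv(path, sep=sep, index=False)


def read_feature_table(path, sep: str = "\t") -> pd.DataFrame:
    table = pd.read_csv(path, sep=sep)
    if list(table.columns[:2]) != ["sample_id", "label"]:
        raise ValueError("feature table must start with sample_id, label columns")
    return table


def split_xy(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Split a feature table into (features frame, label array)."""
    X = table.drop(columns=["sample_id", "label"])
    return X, table["label"].to_numpy()


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
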