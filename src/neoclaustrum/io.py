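"""Standard-format I/O: NIfTI volumes (nibabel), TSV tables, JSON reports."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .rois import LabelVolume, MetricVolume
from .scheme import LabelScheme

COHORT_NUMERIC = ("birth_age", "scan_age")
COHORT_REQUIRED = ("subject_id", "session_id", "group", "birth_age", "scan_age", "sex")


def _voxel_size(img) -> tuple:
    return tuple(float(z) for z in img.header.get_zooms()[:3])


def read_label_volume(path, scheme: LabelScheme) -> LabelVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.allclose(data, np.round(data)):
        raise ValueError(f"{path}: label volume contains non-integer values")
    return LabelVolume(
        data.astype(np.int32), _voxel_size(img), scheme, affine=np.asarray(img.affine)
    )


def write_label_volume(vol: LabelVolume, path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.int16), vol.affine)
    img.header.set_zooms(vol.voxel_size)
    nib.save(img, str(path))


def read_metric_volume(path, metric: str) -> MetricVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    return MetricVolume(data, metric, _voxel_size(img), affine=np.asarray(img.affine))


def write_metric_volume(vol: MetricVolume, path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    img.header.set_zooms(vol.voxel_size)
    nib.save(img, str(path))


def read_cohort_table(path) -> pd.DataFrame:
    """Read and schema-check a cohort TSV (tab-separated, header row)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COHORT_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: cohort table lacks columns {missing}")
    for col in COHORT_NUMERIC:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric {col!r} in row(s) {list(bad + 2)} "
                "(1-based, counting the header)"
            )
        df[col] = coerced
    bad_group = set(df["group"].dropna().unique()) - {"preterm", "term"}
    if bad_group:
        raise ValueError(f"{path}: unknown group value(s) {sorted(bad_group)}")
    return df


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
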