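"""Claustrum ROI operators: control masks, volumetry, and metric extraction.

The claustrum is a thin grey-matter sheet between the extreme and external
capsule; at neonatal diffusion resolution its boundary voxels mix with
surrounding white matter.  Two derived masks address this:

* the *claustrum frame* — insular white matter immediately surrounding the
  claustrum: (claustrum dilated by a Chebyshev radius of 2 voxels,
  intersected with insular WM) minus the claustrum itself;
* the *claustrum-controlled* mask — interior claustrum voxels whose
  26-neighbourhood is at least 90 % same-side claustrum.

All morphology operates in 0-based voxel index space with the 3x3x3
structuring element; voxel anisotropy is deliberately ignored for the
structuring element and the affine is carried only for I/O fidelity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .scheme import LabelScheme

log = logging.getLogger(__name__)

_NEIGHBOURHOOD_26 = np.ones((3, 3, 3), dtype=np.int16)
_NEIGHBOURHOOD_26[1, 1, 1] = 0


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class LabelVolume:
    """3D integer parcellation with voxel dimensions in mm."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    scheme: LabelScheme
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("label volume must be 3D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label volume must hold integers")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        present = set(np.unique(self.data).tolist())
        unknown = present - set(self.scheme.labels)
        if unknown:
            raise ValueError(f"grid contains ids absent from the scheme: {sorted(unknown)}")
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size, 1.0])

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))


@dataclass
class MetricVolume:
    """3D scalar map (MD in 10^-3 mm^2/s or FA, unitless), voxel-aligned
    with its companion label volume.

    FA maps are clipped to [0, 1] on construction; the number of clipped
    voxels is recorded in ``n_clipped`` and logged.
    """

    data: np.ndarray
    metric: str  # "md" | "fa"
    voxel_size: tuple[float, float, float]
    affine: np.ndarray | None = None
    n_clipped: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("metric volume must be 3D")
        if self.metric not in ("md", "fa"):
            raise ValueError(f"metric must be 'md' or 'fa', got {self.metric!r}")
        if self.metric == "fa":
            out = (self.data < 0) | (self.data > 1)
            self.n_clipped = int(out.sum())
            if self.n_clipped:
                log.warning("clipped %d FA voxels to [0, 1]", self.n_clipped)
                self.data = np.clip(self.data, 0.0, 1.0)
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size, 1.0])


@dataclass
class Mask:
    """Boolean voxel mask with a provenance tag."""

    data: np.ndarray
    tag: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)

    def __and__(self, other: "Mask") -> "Mask":
        return Mask(self.data & other.data, f"({self.tag})&({other.tag})")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


# ---------------------------------------------------------------------------
# Volumetry
# ---------------------------------------------------------------------------

def label_mask(vol: LabelVolume, label_id: int, tag: str | None = None) -> Mask:
    if label_id not in vol.scheme.labels:
        raise ValueError(f"unknown label id {label_id}")
    return Mask(vol.data == label_id, tag or vol.scheme.labels[label_id].name)


def labels_mask(vol: LabelVolume, label_ids, tag: str) -> Mask:
    for lid in label_ids:
        if lid not in vol.scheme.labels:
            raise ValueError(f"unknown label id {lid}")
    return Mask(np.isin(vol.data, list(label_ids)), tag)


def label_volume_mm3(vol: LabelVolume, label_id: int) -> float:
    """Volume of one label: voxel count x voxel volume (mm^3)."""
    return label_mask(vol, label_id).n_voxels * vol.voxel_volume_mm3


def total_brain_volume(vol: LabelVolume) -> float:
    """Intracranial volume in mm^3: all labels (brainstem included) except
    background, CSF, and ventricles."""
    return labels_mask(vol, vol.scheme.tbv_ids(), "tbv").n_voxels * vol.voxel_volume_mm3


def relative_volume(left_mm3: float, right_mm3: float, tbv_mm3: float) -> float:
    """Combined TBV-relative claustrum volume: (left + right) / TBV.

    Per-side relative volumes are simply ``side / tbv``; the combined
    outcome is the sum of the per-side ratios.
    """
    if tbv_mm3 <= 0:
        raise ValueError(f"TBV must be positive, got {tbv_mm3}")
    return (left_mm3 + right_mm3) / tbv_mm3


def combine_sides(left_value: float, right_value: float, outcome_kind: str = "mean") -> float:
    """Combined bilateral outcome: the arithmetic mean of the two sides
    (used for absolute volume, MD, and FA; relative volume combines by
    summing the per-side ratios, see :func:`relative_volume`).
    """
    if outcome_kind not in ("mean",):
        raise ValueError("combine_sides only implements the arithmetic-mean convention")
    if _missing(left_value) or _missing(right_value):
        return math.nan
    return 0.5 * (left_value + right_value)


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


# ---------------------------------------------------------------------------
# Morphological control masks
# ---------------------------------------------------------------------------

def dilate_chebyshev(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary dilation with the Chebyshev ball of the given voxel radius
    (equivalently `radius` iterations of 3x3x3 dilation); out-of-bounds is
    treated as empty."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return np.asarray(mask, dtype=bool).copy()
    size = 2 * radius + 1
    return (
        ndimage.maximum_filter(
            np.asarray(mask, dtype=np.uint8), size=size, mode="constant", cval=0
        )
        > 0
    )


def neighbour_count_26(mask: np.ndarray) -> np.ndarray:
    """Per-voxel count of True values among the 26 neighbours (3x3x3 minus
    centre); voxels outside the grid count as False."""
    return ndimage.correlate(
        np.asarray(mask, dtype=np.int16), _NEIGHBOURHOOD_26, mode="constant", cval=0
    )


def build_claustrum_frame(vol: LabelVolume, side: str, radius: int = 2) -> Mask:
    """White-matter 'frame' around one claustrum: the claustrum dilated by
    ~2 voxels on all sides, intersected with insular WM, minus every
    claustrum voxel.

    Returns an empty mask (with a logged warning) when insular WM does not
    touch the dilated claustrum; raises if the claustrum itself is empty.
    """
    cla = label_mask(vol, vol.scheme.claustrum_id(side))
    if cla.n_voxels == 0:
        raise ValueError(f"claustrum_{side} label is empty")
    insular_wm = labels_mask(vol, vol.scheme.role_ids("insular_wm"), "insular_wm")
    both_cla = label_mask(vol, vol.scheme.claustrum_id("left")).data | label_mask(
        vol, vol.scheme.claustrum_id("right")
    ).data
    frame = dilate_chebyshev(cla.data, radius) & insular_wm.data & ~both_cla
    if not frame.any():
        log.warning("claustrum frame (%s) is empty", side)
    return Mask(frame, f"frame_{side}")


def build_claustrum_controlled(vol: LabelVolume, side: str, fraction: float = 0.9) -> Mask:
    """Interior claustrum mask: claustrum voxels whose 26-neighbourhood
    contains at least ``fraction`` same-side claustrum voxels (the default
    0.9 requires >= 24 of 26; out-of-bounds neighbours count as
    non-claustrum).  Always a subset of the claustrum mask; may be empty.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    cla = label_mask(vol, vol.scheme.claustrum_id(side))
    counts = neighbour_count_26(cla.data)
    # small epsilon so fraction*26 landing exactly on an integer keeps it
    controlled = cla.data & (counts >= fraction * 26 - 1e-9)
    if not controlled.any():
        log.warning("claustrum-controlled mask (%s) is empty", side)
    return Mask(controlled, f"controlled_{side}")


# ---------------------------------------------------------------------------
# Metric extraction
# ---------------------------------------------------------------------------

def roi_mean(metric: MetricVolume, mask: Mask) -> float:
    """Mean metric intensity over the mask; NaN (missing) for an empty mask."""
    if metric.data.shape != mask.data.shape:
        raise ValueError(
            f"shape mismatch: metric {metric.data.shape} vs mask {mask.data.shape}"
        )
    if mask.n_voxels == 0:
        log.warning("roi_mean on empty mask %s -> missing", mask.tag)
        return math.nan
    return float(metric.data[mask.data].mean())


def gm_average(metric: MetricVolume, vol: LabelVolume) -> float:
    """Voxel-weighted mean over all cortical and subcortical grey matter
    (claustra included as deep GM)."""
    gm = labels_mask(vol, vol.scheme.gm_ids(), "gm")
    if gm.n_voxels == 0:
        raise ValueError("no grey-matter voxels in volume")
    return roi_mean(metric, gm)


# ---------------------------------------------------------------------------
# Per-subject extraction
# ---------------------------------------------------------------------------

#: every numeric field an extraction produces, in output column order
ROI_METRIC_FIELDS = (
    "volume_left", "volume_right", "volume_mean",
    "tbv",
    "relvol_left", "relvol_right", "relvol_total",
    "md_left", "md_right", "md_mean",
    "fa_left", "fa_right", "fa_mean",
    "controlled_md_left", "controlled_md_right", "controlled_md_mean",
    "controlled_fa_left", "controlled_fa_right", "controlled_fa_mean",
    "frame_md_left", "frame_md_right", "frame_md_mean",
    "frame_fa_left", "frame_fa_right", "frame_fa_mean",
    "thalamus_volume", "caudate_volume",
    "thalamus_relvol", "caudate_relvol",
    "lentiform_fa", "insular_cortex_fa",
    "gm_md", "gm_fa",
)


@dataclass
class ROIMetricsRow:
    """All macro- and microstructural outcomes for one scan session.

    Missing values (e.g. diffusion outcomes when no MD/FA map was supplied,
    or metrics of an empty controlled mask) are NaN and listed in
    ``missing``.
    """

    subject_id: str
    session_id: str
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k in ROI_METRIC_FIELDS:
            self.values.setdefault(k, math.nan)
        vol_fields = [f for f in self.values if "volume" in f or f == "tbv"]
        for f in vol_fields:
            v = self.values[f]
            if not _missing(v) and v < 0:
                raise ValueError(f"{f} must be >= 0, got {v}")

    @property
    def missing(self) -> tuple[str, ...]:
        return tuple(k for k in ROI_METRIC_FIELDS if _missing(self.values[k]))

    def to_dict(self) -> dict:
        d = {"subject_id": self.subject_id, "session_id": self.session_id}
        d.update({k: self.values[k] for k in ROI_METRIC_FIELDS})
        return d


def _check_registration(vol: LabelVolume, metric: MetricVolume) -> None:
    if metric.data.shape != vol.data.shape:
        raise ValueError(
            f"metric map shape {metric.data.shape} does not match label grid "
            f"{vol.data.shape}; maps must be resampled to label space upstream"
        )
    if metric.affine is not None and vol.affine is not None:
        if not np.allclose(metric.affine, vol.affine, atol=1e-4):
            raise ValueError("metric and label affines differ; volumes are not co-registered")


def _assert_mask_invariants(vol: LabelVolume, side: str, frame: Mask, controlled: Mask) -> None:
    cla = label_mask(vol, vol.scheme.claustrum_id(side)).data
    both = cla | label_mask(vol, vol.scheme.claustrum_id("left" if side == "right" else "right")).data
    insular_wm = labels_mask(vol, vol.scheme.role_ids("insular_wm"), "insular_wm").data
    assert not (controlled.data & ~cla).any(), "controlled mask escapes the claustrum"
    assert not (frame.data & both).any(), "frame overlaps the claustrum"
    assert not (frame.data & ~insular_wm).any(), "frame escapes insular WM"


def extract_subject_metrics(
    vol: LabelVolume,
    md: MetricVolume | None = None,
    fa: MetricVolume | None = None,
    subject_id: str = "",
    session_id: str = "",
    controlled_fraction: float = 0.9,
    frame_radius: int = 2,
) -> ROIMetricsRow:
    """Extract the full ROI outcome row for one scan.

    Macrostructure comes from the label volume alone; MD/FA outcomes are
    NaN when the corresponding map is not supplied.  Mask invariants
    (controlled within claustrum, frame disjoint from claustrum and inside
    insular WM) are asserted on every call.
    """
    v: dict[str, float] = {}
    sides = ("left", "right")
    cla_ids = {s: vol.scheme.claustrum_id(s) for s in sides}
    for s in sides:
        if not (vol.data == cla_ids[s]).any():
            raise ValueError(f"claustrum_{s} label missing from volume")

    vols = {s: label_volume_mm3(vol, cla_ids[s]) for s in sides}
    tbv = total_brain_volume(vol)
    v["volume_left"], v["volume_right"] = vols["left"], vols["right"]
    v["volume_mean"] = combine_sides(vols["left"], vols["right"])
    v["tbv"] = tbv
    v["relvol_left"] = vols["left"] / tbv
    v["relvol_right"] = vols["right"] / tbv
    v["relvol_total"] = relative_volume(vols["left"], vols["right"], tbv)

    def _role_volume(role: str) -> float:
        return sum(label_volume_mm3(vol, lid) for lid in vol.scheme.role_ids(role))

    v["thalamus_volume"] = _role_volume("thalamus")
    v["caudate_volume"] = _role_volume("caudate")
    v["thalamus_relvol"] = v["thalamus_volume"] / tbv
    v["caudate_relvol"] = v["caudate_volume"] / tbv

    frames = {s: build_claustrum_frame(vol, s, radius=frame_radius) for s in sides}
    controlled = {
        s: build_claustrum_controlled(vol, s, fraction=controlled_fraction) for s in sides
    }
    for s in sides:
        _assert_mask_invariants(vol, s, frames[s], controlled[s])

    for name, metric in (("md", md), ("fa", fa)):
        if metric is None:
            continue
        _check_registration(vol, metric)
        for s in sides:
            v[f"{name}_{s}"] = roi_mean(metric, label_mask(vol, cla_ids[s]))
            v[f"controlled_{name}_{s}"] = roi_mean(metric, controlled[s])
            v[f"frame_{name}_{s}"] = roi_mean(metric, frames[s])
        for fam in (name, f"controlled_{name}", f"frame_{name}"):
            v[f"{fam}_mean"] = combine_sides(v[f"{fam}_left"], v[f"{fam}_right"])
        v[f"gm_{name}"] = gm_average(metric, vol)
    if fa is not None:
        v["lentiform_fa"] = roi_mean(
            fa, labels_mask(vol, vol.scheme.role_ids("lentiform"), "lentiform")
        )
        v["insular_cortex_fa"] = roi_mean(
            fa, labels_mask(vol, vol.scheme.role_ids("insular_cortex"), "insular_cortex")
        )

    return ROIMetricsRow(subject_id=subject_id, session_id=session_id, values=v)
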