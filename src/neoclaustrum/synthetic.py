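"""Synthetic dHCP-like cohorts, regional metric tables, and voxel phantoms.

The generator emulates the statistical structure of a neonatal MRI study of
the claustrum: two groups (preterm, term) with published group means/SDs of
claustrum volume, TBV, MD, and FA; linear scan-age trajectories; paired
longitudinal sessions sharing a subject-level random intercept; a
region x subject table with controllable region-claustrum correlations; and
a small geometric brain phantom for voxel-level testing of the mask
operators.

Conventions
-----------
* Specified per-group SDs are *marginal* within-group SDs; the residual SD
  is derived by subtracting the variance explained by the scan-age slope
  (and, longitudinally, the subject-intercept variance), so that the
  generated outcome reproduces the specified marginal moments.
* All randomness flows from a single ``numpy`` Generator; identical
  spec + seed yields bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import defaults as D
from .rois import LabelVolume, MetricVolume
from .scheme import LabelScheme, phantom_scheme

# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

GROUPS = ("preterm", "term")


@dataclass(frozen=True)
class CohortSpec:
    """Demographic layout of a simulated cohort.

    ``scan_age`` / ``birth_age`` map group -> (mean, SD) in GA weeks; birth
    ages are truncated to ``birth_age_bounds`` (preterm < 37 wk by
    definition, term 37-42 wk) and scan ages to ``scan_age_window`` when
    one is given.  ``second_scan_age`` switches on the longitudinal layout.
    """

    n_preterm: int = D.N_MATCHED
    n_term: int = D.N_MATCHED
    scan_age: dict = field(
        default_factory=lambda: {
            "term": D.TERM_SCAN_AGE,
            "preterm": D.PRETERM_MATCHED_SCAN_AGE,
        }
    )
    birth_age: dict = field(
        default_factory=lambda: {
            "term": D.TERM_BIRTH_AGE,
            "preterm": D.PRETERM_BIRTH_AGE,
        }
    )
    birth_age_bounds: dict = field(
        default_factory=lambda: {
            "term": D.TERM_BIRTH_AGE_BOUNDS,
            "preterm": D.PRETERM_BIRTH_AGE_BOUNDS,
        }
    )
    scan_age_window: tuple | None = D.MATCHED_SCAN_AGE_WINDOW
    second_scan_age: tuple | None = None
    sex_ratio: float = D.SEX_RATIO_MALE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_preterm < 0 or self.n_term < 0:
            raise ValueError("group sizes must be >= 0")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must be in [0, 1]")
        for g in GROUPS:
            if self.scan_age[g][1] < 0 or self.birth_age[g][1] < 0:
                raise ValueError("SDs must be >= 0")
        lo, hi = self.birth_age_bounds["preterm"]
        if hi >= 37:
            raise ValueError("preterm birth ages must stay below GA 37")


@dataclass(frozen=True)
class OutcomeEffect:
    """Group means/SDs, scan-age slope, and within-subject intercept SD for
    one generated outcome."""

    term_mean: float
    term_sd: float
    preterm_mean: float
    preterm_sd: float
    slope: float = 0.0
    intercept_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.term_sd < 0 or self.preterm_sd < 0 or self.intercept_sd < 0:
            raise ValueError("SDs must be >= 0")

    def group(self, group: str) -> tuple[float, float]:
        if group == "term":
            return self.term_mean, self.term_sd
        if group == "preterm":
            return self.preterm_mean, self.preterm_sd
        raise ValueError(f"unknown group {group!r}")


@dataclass(frozen=True)
class EffectParams:
    """The full outcome model: one :class:`OutcomeEffect` per generated
    column plus the left/right residual correlation."""

    outcomes: dict
    side_correlation: float = D.SIDE_CORRELATION

    def __post_init__(self) -> None:
        if not -1 < self.side_correlation < 1:
            raise ValueError("side correlation must be in (-1, 1)")
        for name, eff in self.outcomes.items():
            if name.startswith("fa_"):
                for m in (eff.term_mean, eff.preterm_mean):
                    if not 0 < m < 1:
                        raise ValueError(f"FA mean for {name} must be in (0, 1)")


def default_effects(include_controls: bool = False) -> EffectParams:
    """Cross-sectional defaults: published group moments and term-spectrum
    scan-age slopes; ``include_controls`` adds the control-analysis
    outcomes (thalamus/caudate relative volume, GM and neighbour-region
    diffusion metrics)."""
    spec = dict(D.OUTCOMES)
    if include_controls:
        spec.update(D.CONTROL_OUTCOMES)
    return EffectParams(
        outcomes={
            name: OutcomeEffect(
                term_mean=p["term"][0],
                term_sd=p["term"][1],
                preterm_mean=p["preterm"][0],
                preterm_sd=p["preterm"][1],
                slope=p["slope"],
            )
            for name, p in spec.items()
        }
    )


def null_effects() -> EffectParams:
    """Both groups share the term parameters and slopes are zero — the null
    generator used for type-I-error calibration."""
    eff = default_effects()
    return EffectParams(
        outcomes={
            name: replace(o, preterm_mean=o.term_mean, preterm_sd=o.term_sd, slope=0.0)
            for name, o in eff.outcomes.items()
        },
        side_correlation=eff.side_correlation,
    )


def default_longitudinal_effects() -> EffectParams:
    """Longitudinal preterm defaults: mixed-model scan-age slopes and free
    within-subject intercept SDs; marginal moments anchored at the second
    (term-equivalent) scan."""
    eff = default_effects()
    return EffectParams(
        outcomes={
            name: replace(
                o,
                slope=D.LONGITUDINAL_SLOPES[name],
                intercept_sd=D.INTERCEPT_SD[name],
            )
            for name, o in eff.outcomes.items()
        },
        side_correlation=eff.side_correlation,
    )


# ---------------------------------------------------------------------------
# Sampling helpers
# ---------------------------------------------------------------------------

def _trunc_normal(rng, mean, sd, bounds, size):
    if sd == 0:
        return np.full(size, float(mean))
    if bounds is None:
        return rng.normal(mean, sd, size)
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _trunc_normal_upper_array(rng, mean, sd, bounds, upper, n):
    """Truncated-normal draws with a per-element upper bound (the subject's
    scan age) in addition to the group bounds."""
    lo, hi = bounds
    hi_eff = np.minimum(hi, np.asarray(upper, dtype=float))
    hi_eff = np.maximum(hi_eff, lo + 1e-6)
    if sd == 0:
        return np.minimum(np.full(n, float(mean)), hi_eff)
    a = (lo - mean) / sd
    b = (hi_eff - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _trunc_var(mean, sd, bounds):
    """Variance of the (possibly truncated) scan-age distribution; used to
    derive residual SDs under the marginal-SD convention."""
    if sd == 0:
        return 0.0
    if bounds is None:
        return sd**2
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return float(sps.truncnorm.var(a, b, loc=mean, scale=sd))


def _residual_sd(marginal_sd, slope, age_var, intercept_sd=0.0, context=""):
    resid_var = marginal_sd**2 - slope**2 * age_var - intercept_sd**2
    if resid_var < 0:
        raise ValueError(
            f"marginal SD {marginal_sd} too small for slope {slope} "
            f"(age variance {age_var:.3f}){' for ' + context if context else ''}: "
            "residual variance would be negative"
        )
    return math.sqrt(resid_var)


_SIDE_FAMILIES = (("volume_left", "volume_right"), ("md_left", "md_right"), ("fa_left", "fa_right"))


def _draw_outcomes(rng, effects, group, scan_ages, age_mean, age_var):
    """Draw all outcome columns for one group, honouring the left/right
    residual correlation and the marginal-SD convention."""
    n = len(scan_ages)
    centred = scan_ages - age_mean
    out = {}
    rho = effects.side_correlation
    paired = set()
    for left, right in _SIDE_FAMILIES:
        if left not in effects.outcomes or right not in effects.outcomes:
            continue
        paired |= {left, right}
        el, er = effects.outcomes[left], effects.outcomes[right]
        sdl = _residual_sd(el.group(group)[1], el.slope, age_var, context=left)
        sdr = _residual_sd(er.group(group)[1], er.slope, age_var, context=right)
        cov = np.array(
            [[sdl**2, rho * sdl * sdr], [rho * sdl * sdr, sdr**2]]
        )
        eps = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")
        out[left] = el.group(group)[0] + el.slope * centred + eps[:, 0]
        out[right] = er.group(group)[0] + er.slope * centred + eps[:, 1]
    for name, eff in effects.outcomes.items():
        if name in paired:
            continue
        sd = _residual_sd(eff.group(group)[1], eff.slope, age_var, context=name)
        out[name] = eff.group(group)[0] + eff.slope * centred + rng.normal(0, sd, n)
    return out


def _derived_columns(df: pd.DataFrame) -> pd.DataFrame:
    if {"volume_left", "volume_right"} <= set(df.columns):
        df["volume_mean"] = 0.5 * (df["volume_left"] + df["volume_right"])
    for m in ("md", "fa"):
        if {f"{m}_left", f"{m}_right"} <= set(df.columns):
            df[f"{m}_mean"] = 0.5 * (df[f"{m}_left"] + df[f"{m}_right"])
    if {"volume_left", "volume_right", "tbv"} <= set(df.columns):
        df["relvol_left"] = df["volume_left"] / df["tbv"]
        df["relvol_right"] = df["volume_right"] / df["tbv"]
        df["relvol_total"] = (df["volume_left"] + df["volume_right"]) / df["tbv"]
    return df


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(
    spec: CohortSpec, effects: EffectParams | None = None, rng=None
) -> pd.DataFrame:
    """One cross-sectional row per subject: demographics plus drawn ROI
    outcomes.  Outcome = group mean + slope * (scan age - group mean age)
    + Gaussian residual whose SD keeps the marginal within-group SD at the
    specified value."""
    effects = effects or default_effects()
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    frames = []
    counter = 0
    for group, n in (("preterm", spec.n_preterm), ("term", spec.n_term)):
        if n == 0:
            continue
        am, asd = spec.scan_age[group]
        bm, bsd = spec.birth_age[group]
        bounds = spec.birth_age_bounds[group]
        scan = _trunc_normal(rng, am, asd, spec.scan_age_window, n)
        # a scan can never precede birth: birth age is drawn truncated below
        # each subject's scan age, which preserves the marginal scan-age
        # (hence outcome) moments exactly
        birth = _trunc_normal_upper_array(rng, bm, bsd, bounds, scan, n)
        sex = np.where(rng.random(n) < spec.sex_ratio, "male", "female")
        age_var = _trunc_var(am, asd, spec.scan_age_window)
        out = _draw_outcomes(rng, effects, group, scan, am, age_var)
        df = pd.DataFrame(
            {
                "subject_id": [f"sub-{counter + i:04d}" for i in range(n)],
                "session_id": "ses-1",
                "group": group,
                "birth_age": birth,
                "scan_age": scan,
                "sex": sex,
                **out,
            }
        )
        counter += n
        frames.append(df)
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return _derived_columns(table)


def generate_longitudinal_cohort(
    spec: CohortSpec, effects: EffectParams | None = None, rng=None, max_retries: int = 100
) -> pd.DataFrame:
    """Two rows per preterm subject (sessions 1 and 2) sharing a
    subject-level random intercept.

    First/second scan ages come from ``spec.scan_age['preterm']`` and
    ``spec.second_scan_age``; pairs with second <= first are resampled
    (bounded retries).  Marginal moments are anchored at the second-scan
    mean age, so term-equivalent rows reproduce the specified group SDs.
    """
    effects = effects or default_longitudinal_effects()
    if spec.second_scan_age is None:
        raise ValueError("longitudinal generation needs spec.second_scan_age")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n = spec.n_preterm
    am1, asd1 = spec.scan_age["preterm"]
    am2, asd2 = spec.second_scan_age
    bm, bsd = spec.birth_age["preterm"]
    first = _trunc_normal(rng, am1, asd1, None, n)
    birth = _trunc_normal_upper_array(rng, bm, bsd, spec.birth_age_bounds["preterm"], first, n)
    second = _trunc_normal(rng, am2, asd2, None, n)
    for _ in range(max_retries):
        bad = second <= first
        if not bad.any():
            break
        second[bad] = _trunc_normal(rng, am2, asd2, None, int(bad.sum()))
    if (second <= first).any():
        raise RuntimeError("could not sample second scan ages after first scans")
    sex = np.where(rng.random(n) < spec.sex_ratio, "male", "female")
    age_var2 = asd2**2

    rows = {
        "subject_id": np.repeat([f"sub-{i:04d}" for i in range(n)], 2),
        "session_id": np.tile(["ses-1", "ses-2"], n),
        "group": "preterm",
        "birth_age": np.repeat(birth, 2),
        "scan_age": np.column_stack([first, second]).ravel(),
        "sex": np.repeat(sex, 2),
    }
    ages = np.asarray(rows["scan_age"])
    out = {}
    rho = effects.side_correlation
    paired = set()
    for left, right in _SIDE_FAMILIES:
        if left not in effects.outcomes or right not in effects.outcomes:
            continue
        paired |= {left, right}
        el, er = effects.outcomes[left], effects.outcomes[right]
        sdl = _residual_sd(el.preterm_sd, el.slope, age_var2, el.intercept_sd, left)
        sdr = _residual_sd(er.preterm_sd, er.slope, age_var2, er.intercept_sd, right)
        bl = rng.normal(0, el.intercept_sd, n)
        br = rng.normal(0, er.intercept_sd, n)
        cov = np.array([[sdl**2, rho * sdl * sdr], [rho * sdl * sdr, sdr**2]])
        eps = rng.multivariate_normal([0.0, 0.0], cov, size=2 * n, method="cholesky")
        out[left] = el.preterm_mean + el.slope * (ages - am2) + np.repeat(bl, 2) + eps[:, 0]
        out[right] = er.preterm_mean + er.slope * (ages - am2) + np.repeat(br, 2) + eps[:, 1]
    for name, eff in effects.outcomes.items():
        if name in paired:
            continue
        sd = _residual_sd(eff.preterm_sd, eff.slope, age_var2, eff.intercept_sd, name)
        b = rng.normal(0, eff.intercept_sd, n)
        out[name] = (
            eff.preterm_mean + eff.slope * (ages - am2) + np.repeat(b, 2)
            + rng.normal(0, sd, 2 * n)
        )
    return _derived_columns(pd.DataFrame({**rows, **out}))


# ---------------------------------------------------------------------------
# Regional covariance tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionDef:
    region_id: str
    tissue_class: str  # cortical_gm | subcortical_gm | wm


@dataclass(frozen=True)
class RegionalCovSpec:
    """One-factor covariance layout: per group and metric, each region's
    value loads on the (standardised) claustrum value with loading
    lambda = rho, giving population region-claustrum correlation rho."""

    regions: tuple
    rho: dict  # (group, metric) -> {region_id: rho}
    region_scale: dict  # (region_id, metric) -> (mean, sd)
    metrics: tuple = ("md", "fa")
    side: str = "right"

    def __post_init__(self) -> None:
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValueError("region ids must be unique")
        for r in self.regions:
            if r.tissue_class not in ("cortical_gm", "subcortical_gm", "wm"):
                raise ValueError(f"bad tissue class {r.tissue_class!r} for {r.region_id}")
        for key, per_region in self.rho.items():
            for rid, rho in per_region.items():
                if not abs(rho) < 1:
                    raise ValueError(f"|rho| must be < 1 (region {rid}, {key}: {rho})")

    def class_of(self) -> dict:
        return {r.region_id: r.tissue_class for r in self.regions}


def default_regions() -> tuple:
    """Emulated parcellation: 34 cortical GM, 12 subcortical GM, and 33 WM
    regions (claustra, CSF, and background excluded)."""
    regions = []
    for cls, n in (
        ("cortical_gm", D.N_CORTICAL_GM_REGIONS),
        ("subcortical_gm", D.N_SUBCORTICAL_GM_REGIONS),
        ("wm", D.N_WM_REGIONS),
    ):
        regions.extend(RegionDef(f"{cls}_{i + 1:02d}", cls) for i in range(n))
    return tuple(regions)


_REGION_SCALES = {
    ("md", "cortical_gm"): (1.20, 0.08),
    ("md", "subcortical_gm"): (1.10, 0.06),
    ("md", "wm"): (1.45, 0.10),
    ("fa", "cortical_gm"): (0.15, 0.02),
    ("fa", "subcortical_gm"): (0.20, 0.03),
    ("fa", "wm"): (0.25, 0.04),
    ("volume", "cortical_gm"): (8000.0, 1200.0),
    ("volume", "subcortical_gm"): (3000.0, 500.0),
    ("volume", "wm"): (6000.0, 1000.0),
    ("relative_volume", "cortical_gm"): (0.022, 0.003),
    ("relative_volume", "subcortical_gm"): (0.008, 0.001),
    ("relative_volume", "wm"): (0.017, 0.003),
}

_CLASS_ORDER = ("cortical_gm", "subcortical_gm", "wm")


def default_regional_spec(metrics=("md", "fa"), side: str = "right") -> RegionalCovSpec:
    """Target correlations derived from the published per-tissue-class mean
    covariance z-scores (rho = tanh(z))."""
    regions = default_regions()
    rho = {}
    for metric in metrics:
        for group in GROUPS:
            zs = D.COVARIANCE_Z[metric][group]
            per_class = dict(zip(_CLASS_ORDER, np.tanh(zs)))
            rho[(group, metric)] = {
                r.region_id: float(per_class[r.tissue_class]) for r in regions
            }
    scale = {
        (r.region_id, metric): _REGION_SCALES[(metric, r.tissue_class)]
        for r in regions
        for metric in metrics
    }
    return RegionalCovSpec(regions=regions, rho=rho, region_scale=scale, metrics=tuple(metrics), side=side)


_CLAUSTRUM_COLUMN = {
    "md": "md_{side}",
    "fa": "fa_{side}",
    "volume": "volume_{side}",
    "relative_volume": "relvol_{side}",
}


def generate_regional_table(
    cov_spec: RegionalCovSpec, cohort: pd.DataFrame, rng=None, seed: int = 0
) -> pd.DataFrame:
    """Per subject and metric: the claustrum value plus one column per
    region, built by the one-factor model

        region = rho * z(claustrum) + sqrt(1 - rho^2) * noise

    (standardisation within group), then rescaled to the region's
    mean/SD so the population region-claustrum correlation equals rho.
    Region columns are named ``<region_id>__<metric>``.
    """
    if cohort.empty:
        raise ValueError("cohort table is empty")
    rng = np.random.default_rng(seed) if rng is None else rng
    out = cohort[["subject_id", "group"]].copy()
    for metric in cov_spec.metrics:
        col = _CLAUSTRUM_COLUMN[metric].format(side=cov_spec.side)
        if col not in cohort.columns:
            raise ValueError(f"cohort lacks claustrum column {col!r} for metric {metric!r}")
        out[f"claustrum__{metric}"] = cohort[col].to_numpy()
    new_cols = {}
    for metric in cov_spec.metrics:
        x = out[f"claustrum__{metric}"].to_numpy()
        z = np.empty_like(x)
        for group in GROUPS:
            m = (out["group"] == group).to_numpy()
            if not m.any():
                continue
            z[m] = (x[m] - x[m].mean()) / x[m].std()
        for r in cov_spec.regions:
            vals = np.empty_like(x)
            for group in GROUPS:
                m = (out["group"] == group).to_numpy()
                if not m.any():
                    continue
                rho = cov_spec.rho[(group, metric)][r.region_id]
                noise = rng.normal(0.0, 1.0, int(m.sum()))
                latent = rho * z[m] + math.sqrt(1 - rho**2) * noise
                mean, sd = cov_spec.region_scale[(r.region_id, metric)]
                vals[m] = mean + sd * latent
            new_cols[f"{r.region_id}__{metric}"] = vals
    return pd.concat([out, pd.DataFrame(new_cols, index=out.index)], axis=1)


# ---------------------------------------------------------------------------
# Voxel phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and tissue parameters of the synthetic brain phantom.

    The phantom is a deliberately schematic brain: an ellipsoid with CSF rim
    and cortical shell, ventricles, deep GM spheres, a brainstem, and —
    per side — an insular WM block containing a thin claustrum sheet with a
    guaranteed >= 2-voxel insular-WM margin on all sides.
    """

    shape: tuple = (64, 64, 48)
    voxel_size_mm: float = D.PHANTOM_VOXEL_MM
    claustrum_thickness: int = 3
    insular_margin: int = 3
    md_noise_sd: float = 0.02
    fa_noise_sd: float = 0.01
    tissue_values: dict = field(default_factory=lambda: dict(D.PHANTOM_TISSUE_VALUES))

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape) or self.voxel_size_mm <= 0:
            raise ValueError("phantom dimensions must be positive")
        if self.claustrum_thickness < 1:
            raise ValueError("claustrum sheet must be at least one voxel thick")


@dataclass
class PhantomBundle:
    labels: LabelVolume
    md: MetricVolume
    fa: MetricVolume
    provenance: dict
    expected: dict

    def __post_init__(self) -> None:
        shapes = {self.labels.data.shape, self.md.data.shape, self.fa.data.shape}
        if len(shapes) != 1:
            raise ValueError("phantom grids must share one shape")


def _sphere(shape, centre, radius):
    idx = np.indices(shape)
    d2 = sum((idx[k] - centre[k]) ** 2 for k in range(3))
    return d2 <= radius**2


def _box(shape, centre, half):
    idx = np.indices(shape)
    m = np.ones(shape, dtype=bool)
    for k in range(3):
        m &= (idx[k] >= centre[k] - half[k]) & (idx[k] <= centre[k] + half[k])
    return m


def _paint_labels(spec: PhantomSpec, scheme: LabelScheme) -> np.ndarray:
    nx, ny, nz = spec.shape
    c = np.array([nx / 2, ny / 2, nz / 2])
    semi = np.array([0.42 * nx, 0.42 * ny, 0.42 * nz])
    idx = np.indices(spec.shape)
    r = np.sqrt(sum(((idx[k] - c[k]) / semi[k]) ** 2 for k in range(3)))

    grid = np.zeros(spec.shape, dtype=np.int16)          # background
    grid[r <= 1.0] = 1                                    # csf rim
    grid[r <= 0.92] = 3                                   # cortical shell
    grid[r <= 0.80] = 4                                   # white matter
    grid[_sphere(spec.shape, c + [0, -0.05 * ny, 0], 0.07 * min(spec.shape))] = 2  # ventricles
    grid[_sphere(spec.shape, c + [0, 0.16 * ny, 0], 0.08 * min(spec.shape))] = 9   # thalamus
    grid[_sphere(spec.shape, c + [0, -0.20 * ny, 0], 0.06 * min(spec.shape))] = 10  # caudate
    for sx in (-1, 1):
        grid[_sphere(spec.shape, c + [sx * 0.16 * nx, 0.05 * ny, 0], 0.05 * min(spec.shape))] = 11
    grid[_sphere(spec.shape, c + [0, 0, -0.30 * nz], 0.07 * min(spec.shape))] = 12  # brainstem

    box_half = np.array(
        [max(int(0.07 * nx), spec.insular_margin + (spec.claustrum_thickness + 1) // 2),
         int(0.10 * ny), int(0.10 * nz)]
    )
    for sx, cla_label in ((-1, 7), (1, 8)):  # left, right
        bc = np.rint(c + [sx * 0.26 * nx, 0, 0]).astype(int)
        grid[_box(spec.shape, bc, box_half)] = 6          # insular WM block
        # insular cortex slab lateral to the block
        slab_c = bc.copy()
        slab_c[0] = bc[0] + sx * (box_half[0] + 2)
        grid[_box(spec.shape, slab_c, [1, box_half[1], box_half[2]])] = 5
        cla_half = np.array(
            [
                (spec.claustrum_thickness - 1) // 2,
                box_half[1] - spec.insular_margin,
                box_half[2] - spec.insular_margin,
            ]
        )
        if (cla_half < 0).any():
            raise ValueError("claustrum sheet has zero extent on this grid")
        m = _box(spec.shape, bc, cla_half)
        if not m.any():
            raise ValueError("claustrum sheet contains zero voxels on this grid")
        grid[m] = cla_label
    return grid


def _expected_values(spec, grid, scheme, row_values):
    """Expected extraction results for the noise-free phantom, computed
    directly from the painted grid and the assigned tissue values."""
    vv = spec.voxel_size_mm**3
    counts = {lid: int((grid == lid).sum()) for lid in scheme.labels}
    name_of = {lid: scheme.labels[lid].name for lid in scheme.labels}
    md_of, fa_of = {}, {}
    for lid in scheme.labels:
        name = name_of[lid]
        if lid == 7:
            md_of[lid], fa_of[lid] = row_values["md_left"], row_values["fa_left"]
        elif lid == 8:
            md_of[lid], fa_of[lid] = row_values["md_right"], row_values["fa_right"]
        else:
            md_of[lid], fa_of[lid] = spec.tissue_values[name]
    tbv = sum(counts[lid] for lid in scheme.tbv_ids()) * vv
    gm_ids = scheme.gm_ids()
    gm_n = sum(counts[lid] for lid in gm_ids)
    exp = {
        "volume_left": counts[7] * vv,
        "volume_right": counts[8] * vv,
        "volume_mean": 0.5 * (counts[7] + counts[8]) * vv,
        "tbv": tbv,
        "relvol_left": counts[7] * vv / tbv,
        "relvol_right": counts[8] * vv / tbv,
        "relvol_total": (counts[7] + counts[8]) * vv / tbv,
        "md_left": md_of[7], "md_right": md_of[8],
        "md_mean": 0.5 * (md_of[7] + md_of[8]),
        "fa_left": fa_of[7], "fa_right": fa_of[8],
        "fa_mean": 0.5 * (fa_of[7] + fa_of[8]),
        "controlled_md_left": md_of[7], "controlled_md_right": md_of[8],
        "controlled_md_mean": 0.5 * (md_of[7] + md_of[8]),
        "controlled_fa_left": fa_of[7], "controlled_fa_right": fa_of[8],
        "controlled_fa_mean": 0.5 * (fa_of[7] + fa_of[8]),
        "frame_md_left": md_of[6], "frame_md_right": md_of[6],
        "frame_md_mean": md_of[6],
        "frame_fa_left": fa_of[6], "frame_fa_right": fa_of[6],
        "frame_fa_mean": fa_of[6],
        "thalamus_volume": counts[9] * vv,
        "caudate_volume": counts[10] * vv,
        "thalamus_relvol": counts[9] * vv / tbv,
        "caudate_relvol": counts[10] * vv / tbv,
        "lentiform_fa": fa_of[11],
        "insular_cortex_fa": fa_of[5],
        "gm_md": sum(counts[lid] * md_of[lid] for lid in gm_ids) / gm_n,
        "gm_fa": sum(counts[lid] * fa_of[lid] for lid in gm_ids) / gm_n,
    }
    return exp


def generate_phantom(
    pspec: PhantomSpec, row=None, effects: EffectParams | None = None, seed: int = 0
) -> PhantomBundle:
    """Build label/MD/FA volumes for one subject.

    Geometry is deterministic given the spec; only the voxel noise depends
    on the seed.  Claustrum voxels carry the subject's tabulated MD/FA
    values (from ``row``, a cohort-table row; tissue defaults otherwise);
    all other labels carry their tissue means.  With zero noise the ROI
    means equal the tabulated values exactly.
    """
    scheme = phantom_scheme()
    grid = _paint_labels(pspec, scheme)
    rng = np.random.default_rng(seed)

    tissue_default = pspec.tissue_values.get("claustrum", (1.15, 0.20))
    row_values = {
        "md_left": tissue_default[0], "md_right": tissue_default[0],
        "fa_left": tissue_default[1], "fa_right": tissue_default[1],
    }
    if row is not None:
        getter = row.get if hasattr(row, "get") else lambda k, d=None: getattr(row, k, d)
        for k in row_values:
            val = getter(k)
            if val is not None and not (isinstance(val, float) and math.isnan(val)):
                row_values[k] = float(val)

    md = np.zeros(pspec.shape, dtype=float)
    fa = np.zeros(pspec.shape, dtype=float)
    for lid, ldef in scheme.labels.items():
        m = grid == lid
        if lid == 7:
            md[m], fa[m] = row_values["md_left"], row_values["fa_left"]
        elif lid == 8:
            md[m], fa[m] = row_values["md_right"], row_values["fa_right"]
        else:
            tmd, tfa = pspec.tissue_values[ldef.name]
            md[m], fa[m] = tmd, tfa
    if pspec.md_noise_sd > 0:
        md += rng.normal(0, pspec.md_noise_sd, pspec.shape)
    if pspec.fa_noise_sd > 0:
        fa += rng.normal(0, pspec.fa_noise_sd, pspec.shape)

    vx = (pspec.voxel_size_mm,) * 3
    labels = LabelVolume(grid, vx, scheme)
    expected = _expected_values(pspec, grid, scheme, row_values)
    prov = {
        "seed": seed,
        "shape": list(pspec.shape),
        "voxel_size_mm": pspec.voxel_size_mm,
        "claustrum_thickness": pspec.claustrum_thickness,
        "md_noise_sd": pspec.md_noise_sd,
        "fa_noise_sd": pspec.fa_noise_sd,
        "claustrum_values": row_values,
    }
    return PhantomBundle(
        labels=labels,
        md=MetricVolume(md, "md", vx),
        fa=MetricVolume(fa, "fa", vx),
        provenance=prov,
        expected=expected,
    )
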