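"""Default study parameters for the synthetic dHCP-like cohort.

Every number here is either a published group statistic for the neonatal
claustrum around term-equivalent age (means, SDs, growth slopes, covariance
z-scores) or a labelled free default for a quantity the literature does not
print (noise SDs, within-subject intercept SDs, tissue means for the
geometric phantom).  Downstream modules read these values; nothing in the
analysis code hard-codes them.

Units: volumes mm^3, MD 10^-3 mm^2/s, FA unitless, ages GA weeks.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Scan-age and birth-age distributions (GA weeks, mean/SD)
# ---------------------------------------------------------------------------

#: term-born spectrum and matched term controls
TERM_SCAN_AGE = (41.1, 1.7)
#: preterm subjects included in the matched term-equivalent comparison
PRETERM_MATCHED_SCAN_AGE = (41.1, 1.7)
#: longitudinal preterm cohort, first and second scan
LONGITUDINAL_FIRST_SCAN_AGE = (34.3, 1.9)
LONGITUDINAL_SECOND_SCAN_AGE = (41.2, 1.5)

#: scan-age analysis window of the matched term-equivalent comparison
MATCHED_SCAN_AGE_WINDOW = (37.4, 44.9)
#: term-born developmental-spectrum window
TERM_SPECTRUM_WINDOW = (38.0, 45.0)

# Birth-age distributions are not printed as mean/SD; free defaults chosen to
# be demographically plausible and respecting the preterm (<37 wk) / term
# (37-42 wk) definitions.
TERM_BIRTH_AGE = (40.0, 1.2)          # truncated to [37, 42]
PRETERM_BIRTH_AGE = (32.0, 3.0)       # truncated to [24, 36.9]
TERM_BIRTH_AGE_BOUNDS = (37.0, 42.0)
PRETERM_BIRTH_AGE_BOUNDS = (24.0, 36.9)

SEX_RATIO_MALE = 0.5

# ---------------------------------------------------------------------------
# Per-outcome group parameters (term-equivalent matched comparison)
# ---------------------------------------------------------------------------
# (term_mean, term_sd, preterm_mean, preterm_sd, scan-age slope per week)
# Slopes for claustrum outcomes are the term-spectrum per-side regression
# coefficients; the TBV slope is back-derived from the relative-volume slope
# (free default, see docs/methods.md).

OUTCOMES = {
    "volume_right": dict(term=(341.0, 51.0), preterm=(363.0, 58.0), slope=17.1),
    "volume_left": dict(term=(325.0, 55.0), preterm=(357.0, 56.0), slope=12.1),
    "md_right": dict(term=(1.08, 0.04), preterm=(1.09, 0.05), slope=-0.012),
    "md_left": dict(term=(1.09, 0.05), preterm=(1.10, 0.04), slope=-0.014),
    "fa_right": dict(term=(0.216, 0.026), preterm=(0.187, 0.028), slope=0.0050),
    "fa_left": dict(term=(0.219, 0.027), preterm=(0.199, 0.029), slope=0.0060),
    # TBV means back-derived from combined relative volumes
    # (term 666/0.00187, preterm 720/0.00195); SDs free defaults.
    "tbv": dict(term=(356100.0, 29000.0), preterm=(369200.0, 29000.0), slope=17000.0),
}

# Control-analysis outcomes (no per-side split).  Group means/SDs are free
# defaults: the study prints only p-values and effect sizes for these, so the
# values below are chosen to be anatomically plausible and directionally
# consistent (smaller relative thalamus/caudate volumes, higher GM MD, lower
# GM/neighbour FA after preterm birth).
CONTROL_OUTCOMES = {
    "thalamus_relvol": dict(term=(0.0235, 0.002), preterm=(0.0224, 0.002), slope=0.0),
    "caudate_relvol": dict(term=(0.0100, 0.0012), preterm=(0.00952, 0.0012), slope=0.0),
    "gm_md": dict(term=(1.15, 0.05), preterm=(1.17, 0.05), slope=-0.010),
    "gm_fa": dict(term=(0.150, 0.015), preterm=(0.140, 0.015), slope=0.004),
    "lentiform_fa": dict(term=(0.230, 0.025), preterm=(0.215, 0.025), slope=0.0),
    "insular_cortex_fa": dict(term=(0.150, 0.020), preterm=(0.140, 0.020), slope=0.0),
    "frame_md": dict(term=(1.25, 0.05), preterm=(1.27, 0.05), slope=0.0),
    "frame_fa": dict(term=(0.300, 0.030), preterm=(0.270, 0.030), slope=0.0),
    "controlled_md_mean": dict(term=(1.08, 0.040), preterm=(1.10, 0.045), slope=0.0),
    "controlled_fa_mean": dict(term=(0.225, 0.025), preterm=(0.200, 0.027), slope=0.0),
}

#: correlation of left/right residuals within an outcome family; free default
#: derived so per-side SDs reproduce the printed combined SDs (e.g. volume
#: sides 51/55 -> combined 51 requires rho ~ 0.9).
SIDE_CORRELATION = 0.9

# ---------------------------------------------------------------------------
# Longitudinal preterm development
# ---------------------------------------------------------------------------
# Mixed-model per-side scan-age slopes for the preterm longitudinal cohort.
LONGITUDINAL_SLOPES = {
    "volume_right": 17.8,
    "volume_left": 15.1,
    "md_right": -0.014,
    "md_left": -0.015,
    "fa_right": 0.0062,
    "fa_left": 0.0071,
    "tbv": 17000.0,
}

# Within-subject random-intercept SDs (free defaults; unprinted).  The volume
# value of 40 mm^3 combined with the marginal-SD convention implies a paired
# first/second-scan t statistic close to the published one.
INTERCEPT_SD = {
    "volume_right": 40.0,
    "volume_left": 40.0,
    "md_right": 0.025,
    "md_left": 0.025,
    "fa_right": 0.015,
    "fa_left": 0.015,
    "tbv": 10000.0,
}

# ---------------------------------------------------------------------------
# Structural covariance (right-claustrum z-scores per tissue class)
# ---------------------------------------------------------------------------
# mean Fisher z across regions of each tissue class, per group and metric.
COVARIANCE_Z = {
    # metric: {group: (cortical_gm, subcortical_gm, wm)}
    "volume": {"preterm": (0.44, 0.57, 0.49), "term": (0.43, 0.59, 0.43)},
    "relative_volume": {"preterm": (-0.15, 0.12, 0.20), "term": (-0.17, 0.24, 0.09)},
    "md": {"preterm": (0.08, 0.70, 0.68), "term": (0.40, 1.03, 0.99)},
    "fa": {"preterm": (0.61, 0.72, 0.89), "term": (0.17, 0.44, 0.74)},
}

#: region counts per tissue class in the emulated parcellation
N_CORTICAL_GM_REGIONS = 34
N_SUBCORTICAL_GM_REGIONS = 12
N_WM_REGIONS = 33

# ---------------------------------------------------------------------------
# Sample sizes of the emulated analyses
# ---------------------------------------------------------------------------
N_TERM_SPECTRUM = 377
N_TERM_SPECTRUM_DWI = 326
N_LONGITUDINAL = 53
N_LONGITUDINAL_DWI = 45
N_MATCHED = 83            # per group, T2 outcomes
N_MATCHED_DWI = 72        # per group, diffusion outcomes

# ---------------------------------------------------------------------------
# Phantom tissue values (free defaults; MD 10^-3 mm^2/s, FA unitless)
# ---------------------------------------------------------------------------
PHANTOM_TISSUE_VALUES = {
    "background": (0.0, 0.0),
    "csf": (3.0, 0.05),
    "ventricles": (3.0, 0.05),
    "cortical_gm": (1.20, 0.15),
    "wm": (1.45, 0.20),
    "insular_cortex": (1.18, 0.16),
    "insular_wm": (1.40, 0.25),
    "thalamus": (1.10, 0.20),
    "caudate": (1.15, 0.15),
    "lentiform": (1.10, 0.20),
    "brainstem": (1.00, 0.30),
}

PHANTOM_VOXEL_MM = 0.5
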