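"""End-to-end orchestration: simulate -> extract/stats -> covariance -> report.

The pipeline mirrors the structure of a term-equivalent claustrum study:

1. *context 1* — claustrum outcomes across the term-born spectrum,
   regressed on scan age (sex and birth age as covariates);
2. *context 2* — longitudinal preterm development: paired first/second-scan
   t-tests and random-intercept mixed models;
3. *main comparison* — preterm vs scan-age-matched term controls, GLMs per
   outcome with scan age and sex covariates, plus control analyses
   (other deep-GM volumes, controlled masks, neighbour-FA covariates);
4. *covariance* — regional structural covariance per metric, group
   comparison after Fisher transformation, FDR, tissue-class summaries.

Everything is deterministic given the configured seed; the config hash and
seed are recorded in every artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import defaults as D
from . import io as nio
from .covariance import compare_covariance, tissue_summary
from .stats import (
    GLMSpec,
    MatchResult,
    fit_glm,
    fit_random_intercept_model,
    match_controls,
    paired_t,
)
from .synthetic import (
    CohortSpec,
    default_effects,
    default_longitudinal_effects,
    default_regional_spec,
    generate_cohort,
    generate_longitudinal_cohort,
    generate_regional_table,
)

log = logging.getLogger(__name__)

MAIN_OUTCOMES = (
    "volume_mean", "volume_right", "volume_left",
    "relvol_total", "relvol_right", "relvol_left",
    "md_mean", "md_right", "md_left",
    "fa_mean", "fa_right", "fa_left",
)
CONTEXT_OUTCOMES = ("volume_mean", "relvol_total", "md_mean", "fa_mean")
DIFFUSION_PREFIXES = ("md", "fa", "controlled", "frame", "gm_md", "gm_fa",
                      "lentiform", "insular")


@dataclass
class PipelineConfig:
    mode: str = "simulate"
    seed: int = 0
    out_dir: str | None = None
    q_threshold: float = 0.05
    n_term_spectrum: int = D.N_TERM_SPECTRUM
    n_term_spectrum_dwi: int = D.N_TERM_SPECTRUM_DWI
    n_longitudinal: int = D.N_LONGITUDINAL
    n_longitudinal_dwi: int = D.N_LONGITUDINAL_DWI
    n_matched: int = D.N_MATCHED
    n_matched_dwi: int = D.N_MATCHED_DWI
    analyses: dict = field(
        default_factory=lambda: {
            "context_term": True,
            "longitudinal": True,
            "matched": True,
            "controls": True,
            "covariance": True,
        }
    )
    # real-data inputs
    cohort_tsv: str | None = None
    regional_term_tsv: str | None = None
    regional_preterm_tsv: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "real-data"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "simulate" and self.seed is None:
            raise ValueError("simulate mode requires a seed")
        if self.mode == "real-data":
            for p in (self.cohort_tsv, self.regional_term_tsv, self.regional_preterm_tsv):
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(p)
            if self.cohort_tsv is None:
                raise ValueError("real-data mode requires cohort_tsv")

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "mode", "seed", "out_dir", "q_threshold",
                "n_term_spectrum", "n_term_spectrum_dwi",
                "n_longitudinal", "n_longitudinal_dwi",
                "n_matched", "n_matched_dwi", "analyses",
                "cohort_tsv", "regional_term_tsv", "regional_preterm_tsv",
            )
        }

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig(**raw)
    return cfg


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _drop_dwi(table: pd.DataFrame, keep_n: int, rng, by_subject: bool = False) -> pd.DataFrame:
    """Blank diffusion outcomes for all but ``keep_n`` subjects, emulating
    scans that failed diffusion quality control."""
    table = table.copy()
    subjects = table["subject_id"].unique()
    if keep_n >= len(subjects):
        return table
    dropped = rng.choice(subjects, size=len(subjects) - keep_n, replace=False)
    cols = [c for c in table.columns if c.startswith(DIFFUSION_PREFIXES)]
    table.loc[table["subject_id"].isin(dropped), cols] = np.nan
    return table


def _group_stats(table: pd.DataFrame, outcome: str) -> dict:
    out = {}
    for g in ("preterm", "term"):
        vals = table.loc[table["group"] == g, outcome].dropna()
        out[g] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1)),
                  "n": int(len(vals))}
    return out


def _matched_glm_block(table, outcome, covariates=("scan_age", "sex")):
    res = fit_glm(table, GLMSpec(outcome=outcome, group="group", covariates=tuple(covariates)))
    g = res.terms["group"]
    return {
        "outcome": outcome,
        "covariates": list(covariates),
        "groups": _group_stats(table, outcome),
        "coef": g.coef, "t": g.t, "p": g.p,
        "partial_eta_sq": g.partial_eta_sq,
        "df_resid": res.df_resid, "n": res.n, "n_dropped": res.n_dropped,
    }


# ---------------------------------------------------------------------------
# Input loading
# ---------------------------------------------------------------------------

def load_inputs(config: PipelineConfig, rng=None):
    """Return (cohort table, matched table or None, regional tables or None).

    In simulate mode everything is generated from the seed; in real-data
    mode the cohort TSV (with extracted ROI outcome columns) and optional
    regional tables are read and schema-checked.
    """
    if config.mode == "real-data":
        cohort = nio.read_cohort_table(config.cohort_tsv)
        regional = None
        if config.regional_term_tsv and config.regional_preterm_tsv:
            regional = (
                nio.read_tsv(config.regional_term_tsv),
                nio.read_tsv(config.regional_preterm_tsv),
            )
        return cohort, regional
    rng = rng or np.random.default_rng(config.seed)
    spec = CohortSpec(
        n_preterm=config.n_matched,
        n_term=config.n_term_spectrum,
        seed=config.seed,
    )
    cohort = generate_cohort(spec, default_effects(include_controls=True), rng=rng)
    return cohort, None


# ---------------------------------------------------------------------------
# Analysis stages
# ---------------------------------------------------------------------------

def _context_term_block(config, rng) -> dict:
    spec = CohortSpec(
        n_preterm=0,
        n_term=config.n_term_spectrum,
        scan_age={"term": D.TERM_SCAN_AGE, "preterm": D.PRETERM_MATCHED_SCAN_AGE},
        scan_age_window=D.TERM_SPECTRUM_WINDOW,
        seed=config.seed,
    )
    table = generate_cohort(spec, default_effects(include_controls=True), rng=rng)
    table = _drop_dwi(table, config.n_term_spectrum_dwi, rng)
    block = {}
    for outcome in CONTEXT_OUTCOMES:
        res = fit_glm(
            table, GLMSpec(outcome=outcome, group=None, covariates=("scan_age", "sex", "birth_age"))
        )
        sa = res.terms["scan_age"]
        block[outcome] = {
            "coef": sa.coef, "t": sa.t, "p": sa.p,
            "partial_eta_sq": sa.partial_eta_sq, "n": res.n,
        }
    # GM-adjusted microstructure models
    for outcome, gm in (("md_mean", "gm_md"), ("fa_mean", "gm_fa")):
        res = fit_glm(
            table,
            GLMSpec(outcome=outcome, group=None,
                    covariates=("scan_age", "sex", "birth_age", gm)),
        )
        sa = res.terms["scan_age"]
        block[f"{outcome}_adj_{gm}"] = {
            "coef": sa.coef, "t": sa.t, "p": sa.p,
            "partial_eta_sq": sa.partial_eta_sq, "n": res.n,
        }
    return {"table": table, "results": block}


def _longitudinal_block(config, rng) -> dict:
    spec = CohortSpec(
        n_preterm=config.n_longitudinal,
        n_term=0,
        scan_age={"term": D.TERM_SCAN_AGE, "preterm": D.LONGITUDINAL_FIRST_SCAN_AGE},
        second_scan_age=D.LONGITUDINAL_SECOND_SCAN_AGE,
        scan_age_window=None,
        seed=config.seed + 1,
    )
    table = generate_longitudinal_cohort(spec, default_longitudinal_effects(), rng=rng)
    table = _drop_dwi(table, config.n_longitudinal_dwi, rng)
    block = {"paired_t": {}, "mixed_models": {}}
    wide = table.pivot(index="subject_id", columns="session_id")
    for outcome in CONTEXT_OUTCOMES:
        first = wide[(outcome, "ses-1")]
        second = wide[(outcome, "ses-2")]
        ok = first.notna() & second.notna()
        block["paired_t"][outcome] = paired_t(first[ok], second[ok]).to_dict()
        block["mixed_models"][outcome] = fit_random_intercept_model(
            table, outcome, fixed_terms=("scan_age", "birth_age", "sex")
        ).to_dict()
    return {"table": table, "results": block}


def _matched_block(config, cohort: pd.DataFrame, rng) -> dict:
    preterm = cohort[cohort["group"] == "preterm"]
    term_pool = cohort[cohort["group"] == "term"]
    match = match_controls(preterm, term_pool)
    matched_term_ids = [t for _, t in match.pairs]
    matched = pd.concat(
        [preterm, term_pool[term_pool["subject_id"].isin(matched_term_ids)]],
        ignore_index=True,
    )
    matched = _drop_dwi_per_group(matched, config.n_matched_dwi, rng)
    block = {
        "matching": {
            "n_pairs": len(match.pairs),
            "mean_scan_age_gap": match.mean_gap,
            "max_scan_age_gap": float(np.max(match.gaps)),
        },
        "glms": {o: _matched_glm_block(matched, o) for o in MAIN_OUTCOMES},
    }
    if config.analyses.get("controls", True):
        ctrl = {}
        for outcome in ("thalamus_relvol", "caudate_relvol",
                        "controlled_md_mean", "controlled_fa_mean"):
            ctrl[outcome] = _matched_glm_block(matched, outcome)
        for extra in ("gm_md",):
            ctrl[f"md_mean_adj_{extra}"] = _matched_glm_block(
                matched, "md_mean", covariates=("scan_age", "sex", extra)
            )
        for extra in ("gm_fa", "insular_cortex_fa", "lentiform_fa", "frame_fa"):
            ctrl[f"fa_mean_adj_{extra}"] = _matched_glm_block(
                matched, "fa_mean", covariates=("scan_age", "sex", extra)
            )
        block["control_analyses"] = ctrl
    return {"table": matched, "match": match, "results": block}


def _drop_dwi_per_group(table, keep_n, rng):
    parts = []
    for g in ("preterm", "term"):
        parts.append(_drop_dwi(table[table["group"] == g], keep_n, rng))
    return pd.concat(parts, ignore_index=True)


def _covariance_block(config, matched: pd.DataFrame, rng) -> dict:
    entries_all = []
    for metrics, source in ((("volume", "relative_volume"), matched),
                            (("md", "fa"), matched.dropna(subset=["md_right"]))):
        cov_spec = default_regional_spec(metrics=metrics, side="right")
        regional = generate_regional_table(cov_spec, source, rng=rng)
        cls = cov_spec.class_of()
        for metric in metrics:
            entries = compare_covariance(
                regional[regional["group"] == "term"],
                regional[regional["group"] == "preterm"],
                metric=metric,
                side="right",
                tissue_class=cls,
                q_threshold=config.q_threshold,
            )
            entries_all.append(entries)
    entries = pd.concat(entries_all, ignore_index=True)
    summary = tissue_summary(entries)
    return {"entries": entries, "summary": summary}


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Run every enabled analysis; returns the report dict (tables under
    the ``_tables`` key are exported by :func:`write_report`)."""
    from . import __version__

    rng = np.random.default_rng(config.seed)
    report = {
        "provenance": {
            "config": config.to_dict(),
            "config_hash": config.config_hash,
            "seed": config.seed,
            "version": __version__,
        }
    }
    tables: dict[str, pd.DataFrame] = {}

    cohort, regional = load_inputs(config, rng=rng)
    tables["cohort"] = cohort

    if config.analyses.get("context_term", True) and config.mode == "simulate":
        ctx = _context_term_block(config, rng)
        report["context_term_spectrum"] = ctx["results"]
    else:
        report["context_term_spectrum"] = None

    if config.analyses.get("longitudinal", True) and config.mode == "simulate":
        lon = _longitudinal_block(config, rng)
        report["longitudinal_preterm"] = lon["results"]
        tables["longitudinal"] = lon["table"]
    else:
        report["longitudinal_preterm"] = None

    matched_table = None
    if config.analyses.get("matched", True):
        mb = _matched_block(config, cohort, rng)
        report["matched_comparison"] = mb["results"]
        matched_table = mb["table"]
        tables["matched"] = matched_table
    else:
        report["matched_comparison"] = None

    if config.analyses.get("covariance", True):
        if config.mode == "real-data" and regional is not None:
            term_tab, preterm_tab = regional
            cov_spec = default_regional_spec()
            entries = pd.concat(
                [
                    compare_covariance(term_tab, preterm_tab, metric=m, side="right",
                                       tissue_class=cov_spec.class_of(),
                                       q_threshold=config.q_threshold)
                    for m in cov_spec.metrics
                ],
                ignore_index=True,
            )
            cov = {"entries": entries, "summary": tissue_summary(entries)}
        elif config.mode == "simulate" and matched_table is not None:
            cov = _covariance_block(config, matched_table, rng)
        else:
            cov = None
        if cov is not None:
            report["covariance"] = {
                "summary": cov["summary"].to_dict(orient="records"),
                "n_significant": int(cov["entries"]["significant"].sum()),
                "n_regions_tested": int(len(cov["entries"])),
            }
            tables["covariance_entries"] = cov["entries"]
            tables["covariance_summary"] = cov["summary"]
        else:
            report["covariance"] = None
    else:
        report["covariance"] = None

    report["_tables"] = tables
    return report


def _table2_layout(matched_block: dict) -> pd.DataFrame:
    rows = []
    for outcome, res in matched_block["glms"].items():
        g = res["groups"]
        rows.append(
            {
                "outcome": outcome,
                "term_mean": g["term"]["mean"], "term_sd": g["term"]["sd"],
                "preterm_mean": g["preterm"]["mean"], "preterm_sd": g["preterm"]["sd"],
                "p": res["p"], "partial_eta_sq": res["partial_eta_sq"],
                "n": res["n"],
            }
        )
    return pd.DataFrame(rows)


def write_report(report: dict, outdir) -> list[str]:
    """Write report JSON plus TSV tables (stable column order); returns the
    list of files written.  Empty optional blocks stay null in the JSON and
    are omitted from the TSV exports."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    tables = report.get("_tables", {})
    serialisable = {k: v for k, v in report.items() if k != "_tables"}
    nio.write_json(serialisable, outdir / "report.json")
    written.append("report.json")
    for name, df in tables.items():
        nio.write_tsv(df, outdir / f"{name}.tsv")
        written.append(f"{name}.tsv")
    if report.get("matched_comparison"):
        nio.write_tsv(_table2_layout(report["matched_comparison"]), outdir / "matched_glms.tsv")
        written.append("matched_glms.tsv")
    log.info("wrote %s to %s", ", ".join(written), outdir)
    return written
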