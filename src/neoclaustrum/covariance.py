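"""Structural covariance of the claustrum with all brain regions.

Across-subject Pearson correlations between a claustrum outcome and each
parcellation region are Fisher r-to-z transformed and compared between the
preterm and term groups with the two-independent-sample z test

    Z = (z_PT - z_FT) / sqrt(1/(n_PT - 3) + 1/(n_FT - 3)),

with Benjamini-Hochberg FDR correction across the regions of one
(metric, side) family and per-tissue-class summaries.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

#: sample correlations are clamped to +/- (1 - CLAMP_EPS) before atanh
CLAMP_EPS = 1e-7


def fisher_z(r: float):
    """Fisher r-to-z transformation, atanh(r); odd in r."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| must be < 1 (clamp sample correlations first)")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def clamp_r(r, eps: float = CLAMP_EPS):
    """Clamp correlations into the open interval (-1, 1), logging how many
    values were touched."""
    r = np.asarray(r, dtype=float)
    n = int(np.sum(np.abs(r) >= 1 - eps))
    if n:
        log.warning("clamped %d correlation(s) to +/-(1-%.0e)", n, eps)
    return np.clip(r, -1 + eps, 1 - eps)


def _region_columns(table: pd.DataFrame, metric: str) -> list[str]:
    suffix = f"__{metric}"
    return [
        c for c in table.columns
        if c.endswith(suffix) and not c.startswith("claustrum__")
    ]


def region_claustrum_correlations(
    table: pd.DataFrame, metric: str, claustrum_col: str | None = None
) -> pd.Series:
    """Pearson r between the claustrum column and every region column of
    one metric, pairwise-complete.  Zero-variance regions yield NaN
    (missing) with a logged warning.
    """
    claustrum_col = claustrum_col or f"claustrum__{metric}"
    if claustrum_col not in table.columns:
        raise ValueError(f"table lacks claustrum column {claustrum_col!r}")
    cols = _region_columns(table, metric)
    if not cols:
        raise ValueError(f"no region columns for metric {metric!r}")
    x = table[claustrum_col]
    names = [c.removesuffix(f"__{metric}") for c in cols]
    sub = table[[claustrum_col, *cols]]
    if not sub.isna().to_numpy().any():
        # complete table: one vectorised pass
        if len(sub) < 4:
            raise ValueError("fewer than 4 complete rows")
        arr = sub.to_numpy(dtype=float)
        centred = arr - arr.mean(axis=0)
        ss = np.sqrt((centred**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (centred[:, 0] @ centred[:, 1:]) / (ss[0] * ss[1:])
        zero_var = ss[1:] == 0
        if ss[0] == 0:
            r[:] = np.nan
            zero_var[:] = True
        if zero_var.any():
            log.warning("%d zero-variance region column(s) -> missing", int(zero_var.sum()))
            r[zero_var] = np.nan
        return pd.Series(r, index=names, name=f"r_{metric}")
    out = {}
    for c in cols:
        pair = pd.concat([x, table[c]], axis=1).dropna()
        if len(pair) < 4:
            raise ValueError(f"fewer than 4 complete rows for region {c!r}")
        a, b = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
        if a.std() == 0 or b.std() == 0:
            log.warning("zero-variance column for region %s -> missing", c)
            out[c.removesuffix(f"__{metric}")] = math.nan
            continue
        out[c.removesuffix(f"__{metric}")] = float(np.corrcoef(a, b)[0, 1])
    return pd.Series(out, name=f"r_{metric}")


def _complete_n(table: pd.DataFrame, metric: str) -> pd.Series:
    claustrum_col = f"claustrum__{metric}"
    cols = _region_columns(table, metric)
    ok = table[[claustrum_col, *cols]].notna().to_numpy()
    counts = (ok[:, 1:] & ok[:, [0]]).sum(axis=0)
    return pd.Series(counts, index=[c.removesuffix(f"__{metric}") for c in cols])


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values):
    order-preserving and q >= p."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def compare_covariance(
    term: pd.DataFrame,
    preterm: pd.DataFrame,
    metric: str,
    side: str = "right",
    tissue_class: dict | None = None,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-region covariance comparison between groups for one
    (metric, side) family.

    Returns one row per region: group correlations and Fisher z values,
    the z-difference statistic, its normal p-value, the BH-FDR q across
    this family, and the significance flag (q < threshold).
    """
    r_t = region_claustrum_correlations(term, metric)
    r_p = region_claustrum_correlations(preterm, metric)
    if set(r_t.index) != set(r_p.index):
        diff = set(r_t.index) ^ set(r_p.index)
        raise ValueError(f"region sets differ between groups: {sorted(diff)}")
    regions = list(r_t.index)
    n_t = _complete_n(term, metric).reindex(regions)
    n_p = _complete_n(preterm, metric).reindex(regions)
    if (n_t < 4).any() or (n_p < 4).any():
        raise ValueError("need at least 4 complete rows per group")
    z_t = np.arctanh(clamp_r(r_t.reindex(regions).to_numpy()))
    z_p = np.arctanh(clamp_r(r_p.reindex(regions).to_numpy()))
    se = np.sqrt(1.0 / (n_p.to_numpy() - 3) + 1.0 / (n_t.to_numpy() - 3))
    zdiff = (z_p - z_t) / se
    p = 2 * sps.norm.sf(np.abs(zdiff))
    q = bh_fdr(p)
    entries = pd.DataFrame(
        {
            "region": regions,
            "tissue_class": [
                (tissue_class or {}).get(r, "unknown") for r in regions
            ],
            "metric": metric,
            "side": side,
            "n_term": n_t.to_numpy(),
            "n_preterm": n_p.to_numpy(),
            "r_term": r_t.reindex(regions).to_numpy(),
            "r_preterm": r_p.reindex(regions).to_numpy(),
            "z_term": z_t,
            "z_preterm": z_p,
            "z_diff": zdiff,
            "p": p,
            "q": q,
            "significant": q < q_threshold,
        }
    )
    return entries


def tissue_summary(entries: pd.DataFrame) -> pd.DataFrame:
    """Per tissue class, group, and metric: mean +/- SD of the Fisher z
    across regions and the significant/total region count (reported as
    ``n_sig/n_total``)."""
    if entries.empty:
        raise ValueError("no covariance entries to summarise")
    if (entries["tissue_class"] == "unknown").any():
        bad = entries.loc[entries["tissue_class"] == "unknown", "region"].tolist()
        raise ValueError(f"regions without a tissue class: {bad}")
    rows = []
    for (metric, side, cls), grp in entries.groupby(
        ["metric", "side", "tissue_class"], sort=True
    ):
        n_sig = int(grp["significant"].sum())
        n_total = len(grp)
        for group, zcol in (("preterm", "z_preterm"), ("term", "z_term")):
            z = grp[zcol].to_numpy()
            rows.append(
                {
                    "metric": metric,
                    "side": side,
                    "group": group,
                    "tissue_class": cls,
                    "mean_z": float(z.mean()),
                    "sd_z": float(z.std(ddof=1)) if len(z) > 1 else 0.0,
                    "n_significant": n_sig,
                    "n_regions": n_total,
                    "sig_label": f"{n_sig}/{n_total}",
                }
            )
    return pd.DataFrame(rows)
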