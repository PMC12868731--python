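"""Paired tumor-vs-normal differential expression on log-CPM.

Per gene, a moderated paired t-statistic is computed on the within-patient
tumor minus NBT log-CPM differences.  Gene-wise variances are shrunk toward a
common prior by empirical Bayes: the prior degrees of freedom ``d0`` and prior
variance ``s0^2`` are estimated by method of moments on the log sample
variances (the scaled-F model: ``s_g^2 ~ s0^2 * F(n-1, d0)``), giving
posterior variances ``s~_g^2 = (d0*s0^2 + (n-1)*s_g^2) / (d0 + n - 1)`` and a
t reference with ``d0 + n - 1`` degrees of freedom.

Candidate signature genes are the genes passing the study's three filters —
log2 fold change > 1, BH-adjusted FDR < 0.05, average log2-CPM > 3 — ranked
by fold change descending (ties: smaller p, then gene id).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError

__all__ = ["bh_adjust", "paired_moderated_test", "filter_and_rank", "pair_columns"]

log = logging.getLogger(__name__)

_TISSUE_SUFFIX = re.compile(r"_(T|N)$")


def pair_columns(tumor_cols, nbt_cols) -> list[str]:
    """Match tumor and NBT sample ids into patient order.

    Ids of the form ``<patient>_T`` / ``<patient>_N`` are paired by patient;
    otherwise the columns are paired positionally.  Returns the patient ids
    in tumor-column order.
    """
    if len(tumor_cols) != len(nbt_cols):
        raise DataError(
            f"unpaired columns: {len(tumor_cols)} tumor vs {len(nbt_cols)} NBT samples"
        )
    t_pat = [_TISSUE_SUFFIX.sub("", c) for c in tumor_cols]
    n_pat = [_TISSUE_SUFFIX.sub("", c) for c in nbt_cols]
    if set(t_pat) != set(n_pat):
        missing = sorted(set(t_pat) ^ set(n_pat))[:5]
        raise DataError(f"tumor/NBT patient sets differ, e.g. {missing}")
    return t_pat


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _fit_f_dist(log_s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) for the scaled-F variance model.

    Under s^2 ~ s0^2 F(df, d0):
      E[log s^2]   = log s0^2 + psi(df/2) - log(df/2) - psi(d0/2) + log(d0/2)
      Var[log s^2] = psi'(df/2) + psi'(d0/2)
    """
    z = log_s2[np.isfinite(log_s2)]
    if z.size < 2:
        return np.inf, float(np.exp(np.mean(z))) if z.size else 1.0
    evar = np.var(z, ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        d0 = np.inf
        log_s0_sq = np.mean(z) - special.digamma(df / 2.0) + np.log(df / 2.0)
    else:
        # invert trigamma(d0/2) = evar by Newton on x = d0/2
        x = 0.5 + 1.0 / evar  # good starting point: trigamma(x) ~ 1/x for large x
        for _ in range(50):
            delta = special.polygamma(1, x) - evar
            step = delta / special.polygamma(2, x)
            x -= step
            x = max(x, 1e-8)
            if abs(step) < 1e-12 * max(1.0, x):
                break
        d0 = 2.0 * x
        log_s0_sq = (
            np.mean(z)
            - special.digamma(df / 2.0) + np.log(df / 2.0)
            + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
        )
    return float(d0), float(np.exp(log_s0_sq))


def paired_moderated_test(
    log2cpm_tumor: pd.DataFrame,
    log2cpm_nbt: pd.DataFrame,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Moderated paired t-test per gene on log-CPM differences.

    Returns a table indexed by gene with ``log2fc`` (mean paired difference),
    ``t``, ``p_value``, ``fdr``, the posterior variance and the shared prior
    ``(d0, s0^2)``.  ``d0_override=0`` disables moderation (ordinary paired t).
    """
    if not log2cpm_tumor.index.equals(log2cpm_nbt.index):
        raise DataError("tumor and NBT matrices must share gene order")
    pair_columns(list(log2cpm_tumor.columns), list(log2cpm_nbt.columns))
    n = log2cpm_tumor.shape[1]
    if n < 3:
        raise DataError(f"paired test needs at least 3 pairs, got {n}")

    d = log2cpm_tumor.to_numpy(dtype=float) - log2cpm_nbt.to_numpy(dtype=float)
    mean_d = d.mean(axis=1)
    s2 = d.var(axis=1, ddof=1)
    df = n - 1

    with np.errstate(divide="ignore"):
        log_s2 = np.log(s2)
    if d0_override is not None:
        d0 = float(d0_override)
        _, s0_sq = _fit_f_dist(log_s2, df) if d0 > 0 else (None, 1.0)
    else:
        d0, s0_sq = _fit_f_dist(log_s2, df)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = 1e9  # effectively normal reference
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df

    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_d / np.sqrt(s2_post / n)
    t = np.where(s2_post > 0, t, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)

    out = pd.DataFrame(
        {
            "log2fc": mean_d,
            "t": t,
            "p_value": p,
            "fdr": bh_adjust(p),
            "s2_post": s2_post,
        },
        index=log2cpm_tumor.index,
    )
    out.attrs["d0"] = d0
    out.attrs["s0_sq"] = s0_sq
    out.attrs["n_pairs"] = n
    return out


def filter_and_rank(
    deg: pd.DataFrame,
    avg_log2cpm: pd.Series,
    lfc_min: float = 1.0,
    fdr_max: float = 0.05,
    alogcpm_min: float = 3.0,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the three DEG filters and rank passing genes by fold change.

    A gene passes iff ``log2fc > lfc_min`` (strict), ``fdr < fdr_max`` and
    ``avg_log2cpm > alogcpm_min``.  Passing genes are ordered by log2fc
    descending, ties by smaller p then gene id; ``fc_rank`` numbers them 1..m.
    Returns (ordered gene list, annotated table).
    """
    table = deg.copy()
    table["avg_log2cpm"] = avg_log2cpm.reindex(table.index)
    table["passes_filter"] = (
        (table["log2fc"] > lfc_min)
        & (table["fdr"] < fdr_max)
        & (table["avg_log2cpm"] > alogcpm_min)
    )
    passing = table[table["passes_filter"]]
    order = passing.reset_index(names="gene_id").sort_values(
        by=["log2fc", "p_value", "gene_id"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    ranked = order["gene_id"].tolist()
    table["fc_rank"] = pd.Series(
        np.arange(1, len(ranked) + 1), index=ranked, dtype="Int64"
    ).reindex(table.index)
    if not ranked:
        log.warning("no gene passes the DEG filters")
    return ranked, table
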