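"""Between-sample library normalization: TMM factors and (log-)CPM.

TMM (trimmed mean of M-values) estimates one scaling factor per library from
doubly trimmed, precision-weighted log ratios against a reference sample, so
that CPM values are comparable across libraries of different composition.
Constants follow the canonical defaults: 30% trim on the M (log-ratio) tails,
5% on the A (log-abundance) tails, inverse asymptotic-variance weights, and
factors rescaled to geometric mean 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConfigError, DataError

__all__ = ["NormFactors", "tmm_factors", "cpm", "average_log2cpm"]


@dataclass
class NormFactors:
    factors: pd.Series          # f_j > 0, geometric mean 1
    reference_sample: str

    def aligned_to(self, counts: pd.DataFrame) -> np.ndarray:
        try:
            return self.factors.loc[counts.columns].to_numpy(dtype=float)
        except KeyError as exc:
            raise DataError(f"normalization factors missing for sample: {exc}") from exc


def _validate_counts(counts: pd.DataFrame) -> None:
    if counts.columns.duplicated().any():
        dup = counts.columns[counts.columns.duplicated()][0]
        raise DataError(f"duplicate sample id: {dup!r}")
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][0]
        raise DataError(f"duplicate gene id: {dup!r}")
    if (counts.to_numpy() < 0).any():
        raise DataError("negative counts are not allowed")


def _tmm_pair(
    y: np.ndarray, y_ref: np.ndarray, lib: float, lib_ref: float,
    logratio_trim: float = 0.3, abundance_trim: float = 0.05,
) -> float:
    """TMM factor of one sample against the reference (unrescaled)."""
    keep = (y > 0) & (y_ref > 0)
    y, y_ref = y[keep].astype(float), y_ref[keep].astype(float)
    if y.size == 0:
        return 1.0
    p, p_ref = y / lib, y_ref / lib_ref
    m = np.log2(p / p_ref)
    a = 0.5 * np.log2(p * p_ref)
    # inverse asymptotic variance of M (delta method, binomial sampling)
    w = (lib - y) / (lib * y) + (lib_ref - y_ref) / (lib_ref * y_ref)

    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abundance_trim) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    kept = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not kept.any():
        return 1.0
    f = 2.0 ** (np.sum(m[kept] / w[kept]) / np.sum(1.0 / w[kept]))
    if not np.isfinite(f) or f <= 0:
        return 1.0
    return float(f)


def tmm_factors(counts: pd.DataFrame) -> NormFactors:
    """Trimmed-mean-of-M-values normalization factors, one per sample.

    The reference is the sample whose upper-quartile CPM is closest to the
    mean upper-quartile across samples.  Genes with a zero count in either
    the target or the reference are excluded from each pairwise estimate.
    """
    _validate_counts(counts)
    if counts.shape[1] < 2:
        raise ConfigError("TMM requires at least two samples")
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    zero = np.where(lib <= 0)[0]
    if zero.size:
        raise DataError(f"sample {counts.columns[zero[0]]!r} has all-zero counts")

    uq = np.array([np.quantile(mat[:, j] / lib[j], 0.75) for j in range(mat.shape[1])]) * 1e6
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))

    f = np.array([
        1.0 if j == ref_idx else _tmm_pair(mat[:, j], mat[:, ref_idx], lib[j], lib[ref_idx])
        for j in range(mat.shape[1])
    ])
    f /= np.exp(np.mean(np.log(f)))  # rescale to geometric mean 1
    return NormFactors(
        factors=pd.Series(f, index=counts.columns, name="tmm_factor"),
        reference_sample=str(counts.columns[ref_idx]),
    )


def cpm(
    counts: pd.DataFrame,
    factors: NormFactors | None = None,
    log: bool = False,
    prior_count: float = 2.0,
) -> pd.DataFrame:
    """Counts per million over effective library sizes ``N_j * f_j``.

    With ``log=True`` a library-size-scaled prior count is added before the
    log2, so low counts are damped proportionally to library depth:
    ``log2((y + pc_j) / (L_j + 2 pc_j) * 1e6)`` with
    ``pc_j = prior_count * L_j / mean(L)``.
    """
    _validate_counts(counts)
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    f = np.ones(mat.shape[1]) if factors is None else factors.aligned_to(counts)
    eff = lib * f
    if not log:
        out = mat / eff[None, :] * 1e6
    else:
        if prior_count <= 0:
            raise ConfigError("prior_count must be positive for log-CPM")
        pc = prior_count * eff / eff.mean()
        out = np.log2((mat + pc[None, :]) / (eff + 2 * pc)[None, :] * 1e6)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def average_log2cpm(
    counts: pd.DataFrame,
    factors: NormFactors | None = None,
    prior_count: float = 2.0,
) -> pd.Series:
    """Per-gene mean log2-CPM across all samples (tumor and NBT pooled)."""
    lc = cpm(counts, factors, log=True, prior_count=prior_count)
    out = lc.mean(axis=1)
    out.name = "avg_log2cpm"
    return out
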