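"""Paired tumor/NBT microbiome resemblance statistics on genus count tables.

Implements the community-level comparisons used to ask whether a patient's
normal-tissue microbiome resembles the paired tumor microbiome: relative
abundance, Bray-Curtis beta diversity with PCoA ordination and PERMANOVA,
Berger-Parker dominance as the alpha index (its reciprocal is reported
alongside, since higher dominance means *lower* evenness), and per-genus
paired Wilcoxon signed-rank tests with Benjamini-Hochberg adjustment.

PERMANOVA follows the distance-based pseudo-F:

    SS_total  = (1/N) sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) sum_{i<j in g} d_ij^2
    F = ((SS_total - SS_within)/(a-1)) / (SS_within/(N-a))

with the permutation p-value using the add-one convention; when the number
of distinct label arrangements is no larger than the requested permutation
count the null distribution is enumerated exhaustively.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import wilcoxon

from .deg import bh_adjust
from .errors import DataError

__all__ = [
    "PermanovaResult",
    "relative_abundance",
    "bray_curtis",
    "pcoa",
    "permanova",
    "berger_parker",
    "paired_genus_tests",
    "paired_alpha_test",
]

log = logging.getLogger(__name__)


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    group_sizes: dict[str, int]
    exhaustive: bool
    seed: int | None


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample genus proportions (columns sum to one)."""
    mat = table.to_numpy(dtype=float)
    if (mat < 0).any():
        raise DataError("negative counts in genus table")
    totals = mat.sum(axis=0)
    zero = np.where(totals == 0)[0]
    if zero.size:
        raise DataError(f"sample {table.columns[zero[0]]!r} has zero total count")
    return pd.DataFrame(mat / totals[None, :], index=table.index, columns=table.columns)


def bray_curtis(rel: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity matrix between sample columns.

    ``BC_ij = 1 - 2 sum_t min(p_ti, p_tj) / (sum_t p_ti + sum_t p_tj)``.
    The formula applies to any non-negative abundance profiles; the pipeline
    feeds relative abundances (so compositional differences, not sequencing
    depth, drive the distances), but raw counts are accepted as well.
    """
    if rel.shape[1] < 2:
        raise DataError("Bray-Curtis needs at least two samples")
    d = squareform(pdist(rel.to_numpy(dtype=float).T, metric="braycurtis"))
    return pd.DataFrame(d, index=rel.columns, columns=rel.columns)


def pcoa(dist: pd.DataFrame, n_axes: int = 2):
    """Classical scaling (principal coordinates) of a distance matrix.

    Delegates to scikit-bio's eigendecomposition of the Gower-centered
    ``-1/2 D∘D`` matrix, then keeps axes with positive eigenvalues only and
    reports the proportion explained against the positive-eigenvalue total.
    Returns (coordinates DataFrame, eigenvalues, proportion_explained).
    """
    from skbio.stats.distance import DistanceMatrix
    from skbio.stats.ordination import pcoa as _skbio_pcoa

    dm = DistanceMatrix(dist.to_numpy(dtype=float), ids=[str(c) for c in dist.columns])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns on negative eigenvalues
        res = _skbio_pcoa(dm, method="eigh")
    eig = res.eigvals.to_numpy()
    pos = eig > 1e-12 * max(eig.max(), 1.0)
    n_pos = int(pos.sum())
    if n_axes > n_pos:
        log.warning("pcoa: only %d positive eigenvalues, truncating from %d",
                    n_pos, n_axes)
        n_axes = n_pos
    coords = res.samples.iloc[:, :n_axes].copy()
    coords.index = dist.columns
    coords.columns = [f"PC{i + 1}" for i in range(n_axes)]
    eig_pos = eig[pos][:n_axes]
    prop = eig_pos / eig[pos].sum()
    return coords, eig_pos, prop


def _pseudo_f(d2: np.ndarray, groups: np.ndarray, group_ids: np.ndarray) -> float:
    n = d2.shape[0]
    a = group_ids.size
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for gid in group_ids:
        idx = np.where(groups == gid)[0]
        ss_within += d2[np.ix_(idx, idx)][np.triu_indices(idx.size, 1)].sum() / idx.size
    denom = ss_within / (n - a)
    if denom == 0:
        return math.inf
    return ((ss_total - ss_within) / (a - 1)) / denom


def _n_arrangements(counts: list[int]) -> int:
    n = sum(counts)
    total = math.factorial(n)
    for c in counts:
        total //= math.factorial(c)
    return total


def permanova(
    dist: pd.DataFrame,
    labels,
    n_perm: int = 999,
    seed: int | None = 0,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    ``labels`` assigns each sample (matrix order) to a group.  With more
    distinct label arrangements than ``n_perm`` the p-value is the seeded
    Monte-Carlo estimate ``(1 + #{F_perm >= F_obs}) / (n_perm + 1)``;
    otherwise all arrangements are enumerated and the p-value is the exact
    fraction (the identity arrangement counts, so p is never zero).
    """
    labels = np.asarray(labels)
    d = dist.to_numpy(dtype=float)
    if labels.size != d.shape[0]:
        raise DataError("labels must match the distance matrix order")
    group_ids, group_idx = np.unique(labels, return_inverse=True)
    if group_ids.size < 2:
        raise DataError("PERMANOVA needs at least two groups")
    sizes = np.bincount(group_idx)
    if sizes.min() < 2:
        small = group_ids[np.argmin(sizes)]
        raise DataError(f"group {small!r} has fewer than two samples")
    if not d.any():
        raise DataError("degenerate distances: all zero")

    d2 = d**2
    gids = np.arange(group_ids.size)
    f_obs = _pseudo_f(d2, group_idx, gids)

    total = _n_arrangements(sizes.tolist())
    exhaustive = total <= n_perm
    if exhaustive:
        count = 0
        n = labels.size
        if group_ids.size == 2:
            n1 = sizes[1]
            for members in combinations(range(n), int(n1)):
                perm = np.zeros(n, dtype=int)
                perm[list(members)] = 1
                if _pseudo_f(d2, perm, gids) >= f_obs - 1e-12:
                    count += 1
            p = count / total
            n_used = total
        else:
            from sympy.utilities.iterables import multiset_permutations

            for arrangement in multiset_permutations(group_idx.tolist()):
                if _pseudo_f(d2, np.array(arrangement), gids) >= f_obs - 1e-12:
                    count += 1
            p = count / total
            n_used = total
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(group_idx)
            if _pseudo_f(d2, perm, gids) >= f_obs - 1e-12:
                count += 1
        p = (1 + count) / (n_perm + 1)
        n_used = n_perm
    return PermanovaResult(
        pseudo_f=float(f_obs),
        p_value=float(p),
        n_permutations=int(n_used),
        group_sizes={str(g): int(s) for g, s in zip(group_ids, sizes)},
        exhaustive=exhaustive,
        seed=seed,
    )


def berger_parker(table: pd.DataFrame) -> pd.DataFrame:
    """Berger-Parker dominance d = n_max/N per sample, with its reciprocal.

    d is a *dominance* measure: larger values mean a community dominated by
    one genus.  The reciprocal 1/d is the evenness-oriented reading; both are
    emitted so no directional interpretation is hard-coded.
    """
    mat = table.to_numpy(dtype=float)
    totals = mat.sum(axis=0)
    zero = np.where(totals == 0)[0]
    if zero.size:
        raise DataError(f"sample {table.columns[zero[0]]!r} has zero total count")
    d = mat.max(axis=0) / totals
    return pd.DataFrame(
        {"berger_parker": d, "berger_parker_reciprocal": 1.0 / d}, index=table.columns
    )


def _paired_wilcoxon(diff: np.ndarray) -> tuple[float, float, bool]:
    """Signed-rank test on paired differences per the small-sample convention.

    Zero differences are dropped; the exact null is used for <= 25 nonzero
    pairs, the normal approximation with continuity correction above.
    Returns (statistic, p, degenerate_flag).
    """
    nz = diff[diff != 0]
    if nz.size == 0:
        return math.nan, 1.0, True
    method = "exact" if nz.size <= 25 else "approx"
    try:
        res = wilcoxon(nz, zero_method="wilcox", correction=(method == "approx"),
                       method=method)
    except ValueError:
        res = wilcoxon(nz, zero_method="wilcox", correction=True, method="approx")
    return float(res.statistic), float(res.pvalue), False


def _split_pairs(values: pd.DataFrame | pd.Series, pairing: pd.DataFrame):
    """Align per-sample values into (tumor, nbt) blocks in shared patient order.

    ``pairing`` maps sample_id -> patient_id, tissue ('tumor'/'NBT', case
    insensitive; 'T'/'N' accepted).
    """
    pairing = pairing.copy()
    tissue = pairing["tissue"].astype(str).str.upper().str[0]  # 'T' or 'N'
    if not set(tissue) <= {"T", "N"}:
        raise DataError("tissue must be tumor/NBT (or T/N)")
    tum = pairing[tissue == "T"].set_index("patient_id")["sample_id"] \
        if "sample_id" in pairing.columns else None
    if tum is None:
        raise DataError("pairing table needs columns sample_id, patient_id, tissue")
    nbt = pairing[tissue == "N"].set_index("patient_id")["sample_id"]
    patients = sorted(set(tum.index) & set(nbt.index))
    if len(patients) < len(set(pairing["patient_id"])):
        raise DataError("pairing incomplete: some patients lack one tissue")
    return tum.loc[patients].tolist(), nbt.loc[patients].tolist(), patients


def paired_genus_tests(rel: pd.DataFrame, pairing: pd.DataFrame) -> pd.DataFrame:
    """Per-genus paired Wilcoxon (tumor vs NBT relative abundance) with BH.

    Genera whose paired differences are all zero get p = 1 and a flag.
    Returns a table indexed by genus: statistic, p_value, q_value, n_pairs,
    all_zero.
    """
    tum_cols, nbt_cols, patients = _split_pairs(rel, pairing)
    if len(patients) < 5:
        log.warning("only %d pairs; signed-rank tests will have little power",
                    len(patients))
    t = rel[tum_cols].to_numpy(dtype=float)
    n_ = rel[nbt_cols].to_numpy(dtype=float)
    diffs = t - n_
    rows = []
    for g, genus in enumerate(rel.index):
        stat, p, degenerate = _paired_wilcoxon(diffs[g])
        rows.append(dict(genus=genus, statistic=stat, p_value=p,
                         n_pairs=len(patients), all_zero=degenerate))
    out = pd.DataFrame(rows).set_index("genus")
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out


def paired_alpha_test(
    alpha: pd.Series, pairing: pd.DataFrame, groups: pd.Series | None = None
) -> pd.DataFrame:
    """Paired Wilcoxon on an alpha-diversity index (NBT vs tumor), per group.

    ``alpha`` is indexed by sample id; ``groups`` (optional) maps patient id
    to TSM/HM — when given, the test runs within each group, otherwise once
    over all pairs ('all').
    """
    tum_cols, nbt_cols, patients = _split_pairs(alpha, pairing)
    a_t = alpha.loc[tum_cols].to_numpy(dtype=float)
    a_n = alpha.loc[nbt_cols].to_numpy(dtype=float)
    memberships = (
        {"all": np.ones(len(patients), dtype=bool)}
        if groups is None
        else {
            g: np.array([groups.get(p) == g for p in patients])
            for g in sorted(set(groups.loc[groups.index.intersection(patients)]))
        }
    )
    rows = []
    for gname, mask in memberships.items():
        if mask.sum() == 0:
            continue
        stat, p, degenerate = _paired_wilcoxon((a_n - a_t)[mask])
        rows.append(dict(group=gname, statistic=stat, p_value=p,
                         n_pairs=int(mask.sum()), all_zero=degenerate))
    return pd.DataFrame(rows).set_index("group")
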