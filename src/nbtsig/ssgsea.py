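"""Single-sample GSEA scoring, the prognostic signature-size sweep, and
mean-cutoff TSM/HM classification.

For each sample the genes are traversed in descending expression order and
the enrichment score is the sum over all positions of the difference between
the weighted in-set ECDF and the uniform out-of-set ECDF:

    ES_j = sum_i [ P_in(i) - P_out(i) ],
    P_in(i)  = sum_{set genes at positions <= i} rho^alpha / sum_{set} rho^alpha,
    P_out(i) = #{non-set genes at positions <= i} / (G - |S|),

where rho is a gene's ascending-expression rank (the most expressed gene has
rho = G) and alpha >= 0 weights high-expression set genes (default 0.25).
Raw (unnormalized) scores are reported by default; optional normalization
divides by the cohort score range.  Ranks depend only on expression order, so
scores are invariant to any strictly monotone per-sample transform; ties are
broken by stable input gene order.

The signature-size sweep scores NBT samples on the top-k fold-change-ranked
tumor-overexpressed genes for each k (default 10..50), splits the cohort at
the per-k cohort-mean score (score > mean -> TSM), fits a single-covariate
Cox model on the chosen endpoint, and selects the k with the highest hazard
ratio (ties: fewest genes); selection by smallest p-value is also available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, NumericalError
from .survival import CoxFit, cox_fit

__all__ = [
    "SsgseaParams",
    "Classification",
    "SweepResult",
    "ssgsea_score",
    "sweep_signature_size",
    "classify",
]

log = logging.getLogger(__name__)


@dataclass
class SsgseaParams:
    weight_exponent: float = 0.25   # alpha
    normalize: bool = False

    def validate(self) -> None:
        if self.weight_exponent < 0:
            raise DataError("weight_exponent must be >= 0")


@dataclass
class Classification:
    """Per-patient TSM/HM call from NBT signature scores."""

    labels: pd.Series       # 'TSM' / 'HM'
    scores: pd.Series
    cutoff: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"score": self.scores, "label": self.labels, "cutoff": self.cutoff}
        )


@dataclass
class SweepResult:
    table: pd.DataFrame            # k, hr, p, n_tsm, n_hm, cutoff, note, selected
    selected_k: int
    selected_genes: list[str]
    cutoff: float
    classification: Classification
    cox: CoxFit
    objective: str = "hr"


def _rank_weights(expr: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """Descending-order gene indices and rho^alpha weights, per sample.

    Returns (order, weights) each of shape (G, n): ``order[i, j]`` is the gene
    index at descending-expression position i in sample j, and ``weights`` the
    corresponding rho^alpha with rho = G - i (stable tie-break by input order).
    """
    G, n = expr.shape
    order = np.argsort(-expr, axis=0, kind="stable")
    rho = (G - np.arange(G, dtype=float))[:, None]
    weights = np.broadcast_to(rho**alpha, (G, n)).copy()
    return order, weights


def _es_from_order(
    order: np.ndarray, weights: np.ndarray, in_set: np.ndarray
) -> np.ndarray:
    """Enrichment scores for one gene-set mask over precomputed sample orders."""
    G, n = order.shape
    mask = in_set[order]                    # (G, n), set membership in traversal order
    w = np.where(mask, weights, 0.0)
    denom_in = w.sum(axis=0)
    s = int(in_set.sum())
    if s == 0 or s >= G:
        raise DataError("gene set must be a nonempty proper subset of the genes")
    p_in = np.cumsum(w, axis=0) / denom_in[None, :]
    p_out = np.cumsum(~mask, axis=0) / float(G - s)
    return (p_in - p_out).sum(axis=0)


def ssgsea_score(
    expr: pd.DataFrame,
    gene_set,
    params: SsgseaParams | None = None,
) -> pd.Series:
    """Per-sample enrichment score of ``gene_set`` in ``expr`` (genes x samples).

    ``expr`` is any per-sample monotone expression measure (log-CPM in the
    pipeline).  Raises when no set member is present among the rows or when
    gene ids are duplicated.
    """
    params = params or SsgseaParams()
    params.validate()
    if expr.index.duplicated().any():
        raise DataError("duplicate gene ids in expression matrix")
    if expr.shape[0] < 2:
        raise DataError("need at least two genes")
    members = set(gene_set)
    if not members:
        raise DataError("empty gene set")
    in_set = expr.index.isin(members)
    if not in_set.any():
        raise DataError("gene set has no overlap with the expression matrix")
    if in_set.all():
        raise DataError("gene set covers every gene; enrichment is undefined")

    order, weights = _rank_weights(expr.to_numpy(dtype=float), params.weight_exponent)
    es = _es_from_order(order, weights, in_set)
    if params.normalize:
        rng_ = es.max() - es.min()
        if rng_ == 0:
            raise NumericalError("cannot normalize: all enrichment scores equal")
        es = es / rng_
    return pd.Series(es, index=expr.columns, name="score")


def classify(scores: pd.Series, cutoff: float | str = "mean") -> Classification:
    """Dichotomize signature scores: score > cutoff -> TSM, else HM.

    ``cutoff='mean'`` uses the cohort mean (the study-population rule); a
    numeric cutoff supports applying a fixed criterion to an external cohort.
    """
    if scores.empty:
        raise DataError("no scores to classify")
    if isinstance(cutoff, str):
        if cutoff != "mean":
            raise DataError(f"unknown cutoff rule {cutoff!r}")
        if scores.size < 2:
            raise DataError("cohort-mean cutoff needs at least two patients")
        mu = float(scores.mean())
    else:
        mu = float(cutoff)
    labels = pd.Series(
        np.where(scores.to_numpy() > mu, "TSM", "HM"), index=scores.index, name="label"
    )
    return Classification(labels=labels, scores=scores, cutoff=mu)


def sweep_signature_size(
    deg_ranked: list[str],
    nbt_expr: pd.DataFrame,
    clinical: pd.DataFrame,
    k_range=range(10, 51),
    endpoint: str = "rfs",
    objective: str = "hr",
    params: SsgseaParams | None = None,
) -> SweepResult:
    """Prognostically optimized signature size over fold-change-ranked genes.

    For each k in ``k_range`` the NBT samples are scored on the top-k genes,
    split at the per-k cohort-mean score, and a single-covariate Cox model of
    the endpoint (``rfs`` or ``os``) is fit on the TSM indicator.  k values
    whose split leaves a group empty, or whose fit fails, are recorded and
    skipped.  Selection: ``objective='hr'`` takes the highest hazard ratio
    (ties -> fewest genes); ``objective='p'`` the smallest p-value.
    """
    params = params or SsgseaParams()
    if objective not in ("hr", "p"):
        raise DataError(f"unknown sweep objective {objective!r}")
    ks = [k for k in k_range if k <= len(deg_ranked)]
    if not ks:
        raise DataError(
            f"only {len(deg_ranked)} ranked genes; none of the requested sizes fit"
        )
    time_col, event_col = f"time_{endpoint}", f"event_{endpoint}"
    for col in (time_col, event_col):
        if col not in clinical.columns:
            raise DataError(f"clinical table lacks column {col!r}")
    if (clinical[time_col] <= 0).any():
        raise DataError("non-positive survival times")

    patients = [c[:-2] if c.endswith("_N") else c for c in nbt_expr.columns]
    if set(patients) - set(clinical.index):
        missing = sorted(set(patients) - set(clinical.index))[:5]
        raise DataError(f"NBT samples without clinical records, e.g. {missing}")
    clin = clinical.loc[patients]

    order, weights = _rank_weights(
        nbt_expr.to_numpy(dtype=float), params.weight_exponent
    )
    rows = []
    for k in ks:
        genes_k = deg_ranked[:k]
        in_set = nbt_expr.index.isin(genes_k)
        es = _es_from_order(order, weights, in_set)
        scores = pd.Series(es, index=patients)
        mu = float(scores.mean())
        is_tsm = scores > mu
        n_tsm, n_hm = int(is_tsm.sum()), int((~is_tsm).sum())
        if n_tsm == 0 or n_hm == 0:
            rows.append(dict(k=k, hr=np.nan, p=np.nan, n_tsm=n_tsm, n_hm=n_hm,
                             cutoff=mu, note="degenerate split"))
            log.warning("sweep k=%d skipped: one group empty", k)
            continue
        x = pd.DataFrame({"tsm": is_tsm.astype(float).to_numpy()}, index=patients)
        try:
            fit = cox_fit(x, clin[time_col], clin[event_col])
        except Exception as exc:  # recorded, not fatal
            rows.append(dict(k=k, hr=np.nan, p=np.nan, n_tsm=n_tsm, n_hm=n_hm,
                             cutoff=mu, note=f"cox failed: {exc}"))
            log.warning("sweep k=%d skipped: %s", k, exc)
            continue
        rows.append(dict(
            k=k,
            hr=float(fit.summary.loc["tsm", "hr"]),
            p=float(fit.summary.loc["tsm", "p"]),
            n_tsm=n_tsm, n_hm=n_hm, cutoff=mu, note="",
        ))
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["hr"])
    if valid.empty:
        raise NumericalError("signature-size sweep: no k produced a valid fit")

    if objective == "hr":
        best = valid.loc[valid["hr"].idxmax()]
        best = valid[valid["hr"] == best["hr"]].iloc[0]  # ties: smallest k (row order)
    else:
        best = valid.loc[valid["p"].idxmin()]
        best = valid[valid["p"] == best["p"]].iloc[0]
    selected_k = int(best["k"])
    selected_genes = deg_ranked[:selected_k]

    final_scores = pd.Series(
        _es_from_order(order, weights, nbt_expr.index.isin(selected_genes)),
        index=patients, name="score",
    )
    classification = classify(final_scores, "mean")
    x = pd.DataFrame(
        {"tsm": (classification.labels == "TSM").astype(float).to_numpy()},
        index=patients,
    )
    cox = cox_fit(x, clin[time_col], clin[event_col])
    table["selected"] = table["k"] == selected_k
    return SweepResult(
        table=table,
        selected_k=selected_k,
        selected_genes=selected_genes,
        cutoff=classification.cutoff,
        classification=classification,
        cox=cox,
        objective=objective,
    )
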