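"""Synthetic paired tumor/normal cohorts with planted ground truth.

The generator emulates the structure of a paired bulk RNA-seq study of
resected colorectal cancer: for every patient one tumor sample and one
histologically normal sample from the furthest resection margin (NBT,
non-tumor-bearing tissue).  A latent per-patient label splits the cohort into
a tumor-supportive-microenvironment (TSM) subgroup — whose NBT partially
expresses the planted tumor-overexpressed genes — and a healthy-microenvironment
(HM) subgroup whose NBT does not.  Survival follows a proportional-hazards
model driven only by the latent label, and genus-level microbial count tables
make TSM NBTs compositionally resemble their paired tumors while HM NBTs are
drawn from a distinct, more even community.

Every quantity a downstream stage is supposed to recover (planted gene set,
latent labels, true log hazard ratio, per-gene effect sizes) is recorded in a
:class:`TruthRecord`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "SyntheticCohort",
    "simulate_labels",
    "simulate_expression",
    "simulate_survival",
    "simulate_microbiome",
    "simulate_cohort",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults correspond to a cohort of 300 patients, 2000 genes with 25
    planted tumor-overexpressed genes at log2 effects Delta ~ U(2, 4), a TSM
    NBT leak of delta = 0.6 (TSM NBTs express planted genes at
    ``2**(delta*Delta)`` over baseline), a true TSM log hazard ratio of
    ln 2.3 with ~35% independent censoring, and a TSM prevalence of 0.388.
    """

    n_patients: int = 300
    n_genes: int = 2000
    n_signature: int = 25
    tsm_fraction: float = 0.388
    tumor_log2_effect: tuple[float, float] = (2.0, 4.0)
    nbt_leak: float = 0.6
    dispersion: float = 0.1
    lib_size_range: tuple[int, int] = (500_000, 2_000_000)
    baseline_hazard: float = 0.01          # events per month
    log_hazard_tsm: float = math.log(2.3)
    censor_rate: float = 0.35
    n_genera: int = 60
    dm_concentration: float = 25.0         # theta: Dirichlet concentration
    dm_concentration_paired: float = 300.0  # theta_high: TSM NBT around tumor
    seq_depth: int = 10_000
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.tsm_fraction < 1.0:
            raise ConfigError("tsm_fraction must lie strictly in (0, 1)")
        if self.n_signature >= self.n_genes:
            raise ConfigError(
                f"n_signature ({self.n_signature}) must be smaller than "
                f"n_genes ({self.n_genes})"
            )
        if np.any(np.asarray(self.dispersion) <= 0):
            raise ConfigError("dispersion must be positive")
        if not 0.0 <= self.nbt_leak <= 1.0:
            raise ConfigError("nbt_leak must lie in [0, 1]")
        if self.lib_size_range[0] <= 0 or self.lib_size_range[1] < self.lib_size_range[0]:
            raise ConfigError("lib_size_range must be a positive, ordered pair")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be positive")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ConfigError("censor_rate must lie in [0, 1)")
        if min(self.n_patients, self.n_genes, self.n_genera, self.seq_depth) <= 0:
            raise ConfigError("counts in the configuration must be positive")

    def substreams(self) -> dict[str, np.random.Generator]:
        """Expand the global seed into named, independent substreams.

        Each component (labels, expression, survival, microbiome) owns a
        substream so that any one can be re-simulated without disturbing the
        others.
        """
        root = np.random.SeedSequence(self.seed)
        names = ("labels", "expression", "survival", "microbiome")
        children = root.spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tumor_log2_effect"] = list(self.tumor_log2_effect)
        d["lib_size_range"] = list(self.lib_size_range)
        return d


@dataclass
class TruthRecord:
    """Ground truth planted into a synthetic cohort."""

    planted_genes: list[str]
    labels: pd.Series                # patient id -> 'TSM' / 'HM'
    beta_true: float
    nbt_leak: float
    effect_sizes: pd.Series = field(default=None)  # Delta per planted gene

    @property
    def tsm_fraction_realized(self) -> float:
        return float((self.labels == "TSM").mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"patient_id": self.labels.index, "latent_label": self.labels.values}
        )


@dataclass
class SyntheticCohort:
    tumor_counts: pd.DataFrame
    nbt_counts: pd.DataFrame
    clinical: pd.DataFrame
    genus_tumor: pd.DataFrame
    genus_nbt: pd.DataFrame
    truth: TruthRecord
    config: SimulationConfig


def _patient_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"P{i + 1:0{width}d}" for i in range(n)]


def simulate_labels(config: SimulationConfig, rng: np.random.Generator) -> pd.Series:
    """Draw latent TSM/HM labels (independent Bernoulli(tsm_fraction))."""
    patients = _patient_ids(config.n_patients)
    is_tsm = rng.random(config.n_patients) < config.tsm_fraction
    return pd.Series(np.where(is_tsm, "TSM", "HM"), index=patients, name="latent_label")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: np.ndarray) -> np.ndarray:
    """NB(mean, phi) with variance = mean + phi * mean^2, via gamma-Poisson."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_expression(
    config: SimulationConfig,
    labels: pd.Series | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Paired tumor/NBT count matrices with planted tumor-overexpressed genes.

    Counts are negative binomial around ``lib_size * q_g * effect`` where the
    baseline relative abundances ``q_g`` are log-normal (normalised to sum 1),
    effect is ``2**Delta_g`` in tumors for planted genes, ``2**(delta*Delta_g)``
    in TSM NBTs for planted genes, and 1 otherwise.
    """
    config.validate()
    streams = config.substreams()
    if rng is None:
        rng = streams["expression"]
    if labels is None:
        labels = simulate_labels(config, streams["labels"])

    G, n = config.n_genes, config.n_patients
    width = max(4, len(str(G)))
    genes = [f"G{i + 1:0{width}d}" for i in range(G)]
    patients = list(labels.index)

    # baseline relative abundances, log-normal then normalised
    q = np.exp(rng.normal(0.0, 1.2, size=G))
    q /= q.sum()

    planted_idx = np.sort(rng.choice(G, size=config.n_signature, replace=False))
    lo, hi = config.tumor_log2_effect
    delta_big = rng.uniform(lo, hi, size=config.n_signature)  # Delta per planted gene

    lib_lo, lib_hi = config.lib_size_range
    lib_tumor = rng.integers(lib_lo, lib_hi + 1, size=n)
    lib_nbt = rng.integers(lib_lo, lib_hi + 1, size=n)

    effect_tumor = np.ones((G, n))
    effect_tumor[planted_idx, :] = 2.0 ** delta_big[:, None]
    effect_nbt = np.ones((G, n))
    is_tsm = (labels.values == "TSM")
    leak = 2.0 ** (config.nbt_leak * delta_big)
    effect_nbt[np.ix_(planted_idx, np.where(is_tsm)[0])] = leak[:, None]

    dispersion = np.broadcast_to(
        np.asarray(config.dispersion, dtype=float).reshape(-1, 1), (G, n)
    ) if np.ndim(config.dispersion) else np.full((G, n), float(config.dispersion))

    mean_tumor = lib_tumor[None, :] * q[:, None] * effect_tumor
    mean_nbt = lib_nbt[None, :] * q[:, None] * effect_nbt
    tumor = _nb_draw(rng, mean_tumor, dispersion)
    nbt = _nb_draw(rng, mean_nbt, dispersion)

    tumor_df = pd.DataFrame(tumor, index=genes, columns=[f"{p}_T" for p in patients])
    nbt_df = pd.DataFrame(nbt, index=genes, columns=[f"{p}_N" for p in patients])
    tumor_df.index.name = nbt_df.index.name = "gene_id"

    planted = [genes[i] for i in planted_idx]
    truth = TruthRecord(
        planted_genes=planted,
        labels=labels,
        beta_true=config.log_hazard_tsm,
        nbt_leak=config.nbt_leak,
        effect_sizes=pd.Series(delta_big, index=planted, name="log2_effect"),
    )
    return tumor_df, nbt_df, truth


def simulate_survival(
    labels: pd.Series,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Proportional-hazards survival with independent exponential censoring.

    Event times are exponential with hazard ``lambda0 * exp(beta * 1[TSM])``;
    the censoring hazard is tuned so the marginal censoring probability equals
    ``censor_rate``.  Both an RFS-like and an OS-like endpoint are emitted
    (independent draws, the OS baseline hazard is 0.7 * lambda0), alongside
    two noise covariates (tumor stage II/III and MSI status).
    """
    config.validate()
    if rng is None:
        rng = config.substreams()["survival"]
    n = len(labels)
    beta = config.log_hazard_tsm
    z = (labels.values == "TSM").astype(float)

    def endpoint(lam0: float) -> tuple[np.ndarray, np.ndarray]:
        haz = lam0 * np.exp(beta * z)
        t_event = rng.exponential(1.0 / haz)
        if config.censor_rate == 0:
            return t_event, np.ones(n, dtype=int)
        # competing exponential censoring: P(censor) = lam_c / (lam_c + lam_e)
        mean_haz = lam0 * float(np.mean(np.exp(beta * z)))
        lam_c = config.censor_rate / (1.0 - config.censor_rate) * mean_haz
        t_cens = rng.exponential(1.0 / lam_c, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        return time, event

    time_rfs, event_rfs = endpoint(config.baseline_hazard)
    time_os, event_os = endpoint(0.7 * config.baseline_hazard)

    stage = rng.choice(["II", "III"], size=n)
    msi = rng.choice(["MSS", "MSI-H"], size=n, p=[0.88, 0.12])
    return pd.DataFrame(
        {
            "patient_id": labels.index,
            "latent_label": labels.values,
            "time_rfs": time_rfs,
            "event_rfs": event_rfs,
            "time_os": time_os,
            "event_os": event_os,
            "stage": stage,
            "msi": msi,
        }
    ).set_index("patient_id")


def simulate_microbiome(
    labels: pd.Series,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired genus-level count tables (tumor, NBT) via Dirichlet-multinomial.

    Tumor compositions scatter around an uneven base community; TSM NBTs are
    drawn tightly around their paired tumor composition
    (``Dirichlet(theta_high * tumor_comp)``) so the two tissues resemble each
    other, while HM NBTs come from a distinct and more even base community.
    """
    config.validate()
    if rng is None:
        rng = config.substreams()["microbiome"]
    T, n = config.n_genera, len(labels)
    genera = [f"g{i + 1:02d}" for i in range(T)]
    theta = config.dm_concentration
    theta_high = config.dm_concentration_paired

    # uneven tumor base (few dominant genera) vs a more even healthy base
    base_tumor = rng.dirichlet(np.full(T, 0.3))
    base_healthy = rng.dirichlet(np.full(T, 5.0))
    floor = 1e-8

    tumor_counts = np.empty((T, n), dtype=int)
    nbt_counts = np.empty((T, n), dtype=int)
    for j, patient in enumerate(labels.index):
        comp_t = rng.dirichlet(np.maximum(theta * base_tumor, floor))
        if labels.iloc[j] == "TSM":
            comp_n = rng.dirichlet(np.maximum(theta_high * comp_t, floor))
        else:
            comp_n = rng.dirichlet(np.maximum(theta * base_healthy, floor))
        tumor_counts[:, j] = rng.multinomial(config.seq_depth, comp_t)
        nbt_counts[:, j] = rng.multinomial(config.seq_depth, comp_n)

    cols_t = [f"{p}_T" for p in labels.index]
    cols_n = [f"{p}_N" for p in labels.index]
    gt = pd.DataFrame(tumor_counts, index=genera, columns=cols_t)
    gn = pd.DataFrame(nbt_counts, index=genera, columns=cols_n)
    gt.index.name = gn.index.name = "genus"
    return gt, gn


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a complete cohort (expression, survival, microbiome, truth)."""
    config.validate()
    streams = config.substreams()
    labels = simulate_labels(config, streams["labels"])
    tumor, nbt, truth = simulate_expression(config, labels, streams["expression"])
    clinical = simulate_survival(labels, config, streams["survival"])
    genus_t, genus_n = simulate_microbiome(labels, config, streams["microbiome"])
    return SyntheticCohort(
        tumor_counts=tumor,
        nbt_counts=nbt,
        clinical=clinical,
        genus_tumor=genus_t,
        genus_nbt=genus_n,
        truth=truth,
        config=config,
    )
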