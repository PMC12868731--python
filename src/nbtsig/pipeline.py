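"""End-to-end orchestration: normalize -> DEG -> signature sweep -> classify
-> survival -> microbiome, with all stage outputs and a run manifest on disk.

The manifest (JSON) records the configuration snapshot, package version,
seeds, per-stage record counts, the selected signature size and cutoff, group
sizes, and SHA-256 checksums of every written artifact — enough to re-run the
analysis bit-identically and to verify that a re-run did.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from . import io as nio
from .deg import filter_and_rank, paired_moderated_test
from .errors import ConfigError, DataError
from .microbiome import (
    berger_parker,
    bray_curtis,
    paired_alpha_test,
    paired_genus_tests,
    pcoa,
    permanova,
    relative_abundance,
)
from .normalization import average_log2cpm, cpm, tmm_factors
from .simulate import SimulationConfig, simulate_cohort
from .ssgsea import SsgseaParams, sweep_signature_size
from .survival import km_estimate, logrank_test, screen_then_multivariate, survival_at

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "analyze_cohort"]


def analyze_cohort(
    tumor: pd.DataFrame,
    nbt: pd.DataFrame,
    clinical: pd.DataFrame,
    lfc_min: float = 1.0,
    fdr_max: float = 0.05,
    alogcpm_min: float = 3.0,
    k_range=range(10, 51),
    endpoint: str = "rfs",
    objective: str = "hr",
    params: SsgseaParams | None = None,
):
    """Core expression analysis without file I/O.

    Pooled TMM/log-CPM normalization, paired moderated DEG testing, the three
    filters with fold-change ranking, and the prognostic signature-size
    sweep.  Returns (ranked gene list, annotated DEG table, SweepResult).
    """
    pooled = pd.concat([tumor, nbt], axis=1)
    factors = tmm_factors(pooled)
    logcpm = cpm(pooled, factors, log=True)
    deg = paired_moderated_test(logcpm[tumor.columns], logcpm[nbt.columns])
    ranked, deg_table = filter_and_rank(
        deg, average_log2cpm(pooled, factors), lfc_min, fdr_max, alogcpm_min
    )
    sweep = sweep_signature_size(
        ranked, logcpm[nbt.columns], clinical,
        k_range=k_range, endpoint=endpoint, objective=objective, params=params,
    )
    return ranked, deg_table, sweep


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (exactly one input mode active)."""

    # input mode A: files
    tumor_counts: str | None = None
    nbt_counts: str | None = None
    clinical: str | None = None
    genus: str | None = None
    pairing: str | None = None
    # input mode B: simulation
    simulation: SimulationConfig | None = None
    # analysis parameters
    lfc_min: float = 1.0
    fdr_max: float = 0.05
    alogcpm_min: float = 3.0
    k_min: int = 10
    k_max: int = 50
    sweep_objective: str = "hr"
    ssgsea_alpha: float = 0.25
    ssgsea_normalize: bool = False
    endpoint: str = "rfs"
    n_permutations: int = 999
    seed: int = 0
    outdir: str = "nbtsig_out"
    make_plots: bool = True

    def validate(self) -> None:
        has_files = self.tumor_counts is not None
        has_sim = self.simulation is not None
        if has_files == has_sim:
            raise ConfigError(
                "exactly one of input files or a simulation block must be given"
            )
        if has_files and (self.nbt_counts is None or self.clinical is None):
            raise ConfigError("file mode needs tumor_counts, nbt_counts and clinical")
        if min(self.lfc_min, self.fdr_max, self.alogcpm_min) <= 0:
            raise ConfigError("DEG thresholds must be positive")
        if not (0 < self.k_min <= self.k_max):
            raise ConfigError("sweep range must satisfy 0 < k_min <= k_max")
        if self.endpoint not in ("rfs", "os"):
            raise ConfigError(f"unknown endpoint {self.endpoint!r}")
        if has_sim:
            self.simulation.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            for key in ("tumor_log2_effect", "lib_size_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            cfg.simulation = SimulationConfig(**sim)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "simulation"}
        d["simulation"] = self.simulation.to_dict() if self.simulation else None
        # store the run directory relocatably so identical runs into
        # differently-located directories produce identical manifests
        d["outdir"] = Path(self.outdir).name
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _encode_covariates(clinical: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Numeric design for the screening Cox models (TSM + clinical covariates)."""
    cov = pd.DataFrame(index=clinical.index)
    cov["tsm"] = (labels.reindex(clinical.index) == "TSM").astype(float)
    if "stage" in clinical.columns:
        cov["stage_iii"] = (clinical["stage"].astype(str) == "III").astype(float)
    if "msi" in clinical.columns:
        cov["msi_high"] = (clinical["msi"].astype(str) == "MSI-H").astype(float)
    return cov


def _load_inputs(config: PipelineConfig):
    if config.simulation is not None:
        cohort = simulate_cohort(config.simulation)
        pairing = pd.DataFrame(
            {
                "sample_id": list(cohort.genus_tumor.columns)
                + list(cohort.genus_nbt.columns),
                "patient_id": [c[:-2] for c in cohort.genus_tumor.columns]
                + [c[:-2] for c in cohort.genus_nbt.columns],
                "tissue": ["tumor"] * cohort.genus_tumor.shape[1]
                + ["NBT"] * cohort.genus_nbt.shape[1],
            }
        )
        genus = pd.concat([cohort.genus_tumor, cohort.genus_nbt], axis=1)
        return (cohort.tumor_counts, cohort.nbt_counts, cohort.clinical,
                genus, pairing, cohort.truth)
    tumor = nio.read_counts(config.tumor_counts)
    nbt = nio.read_counts(config.nbt_counts)
    clinical = nio.read_clinical(config.clinical)
    genus = nio.read_genus(config.genus) if config.genus else None
    pairing = nio.read_pairing(config.pairing) if config.pairing else None
    if genus is not None and pairing is None:
        raise ConfigError("genus table given without a pairing sidecar")
    return tumor, nbt, clinical, genus, pairing, None


def _km_tables(clinical, labels, endpoint, outdir, plots):
    """KM per group + log-rank + 5-year survival; returns summary dict."""
    time_col, event_col = f"time_{endpoint}", f"event_{endpoint}"
    groups = {}
    for g in ("TSM", "HM"):
        members = labels.index[labels == g]
        sub = clinical.loc[clinical.index.intersection(members)]
        if sub.empty:
            continue
        groups[g] = sub
    times = [g[time_col].to_numpy() for g in groups.values()]
    events = [g[event_col].to_numpy() for g in groups.values()]
    lr = logrank_test(times, events)
    summary = {"logrank_chi2": lr.chi_square, "logrank_p": lr.p_value,
               "five_year": {}}
    curves = {}
    for name, sub in groups.items():
        km = km_estimate(sub[time_col], sub[event_col])
        km.table.to_csv(outdir / f"km_{endpoint}_{name.lower()}.tsv",
                        sep="\t", index=False)
        summary["five_year"][name] = survival_at(km, 60.0)
        curves[name] = km
    if plots:
        _plot_km(curves, endpoint, outdir)
    return summary


def _plot_km(curves, endpoint, outdir):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, km in curves.items():
        t = np.concatenate([[0.0], km.table["time"].to_numpy()])
        s = np.concatenate([[1.0], km.table["survival"].to_numpy()])
        ax.step(t, s, where="post", label=name)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    ax.set_title(f"Kaplan-Meier ({endpoint.upper()})")
    fig.tight_layout()
    fig.savefig(outdir / f"km_{endpoint}.png", dpi=100,
                metadata={"Software": None})
    plt.close(fig)


def _plot_sweep(table, outdir):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(6, 5), sharex=True)
    ax1.bar(table["k"], table["hr"], color="#777")
    ax1.set_ylabel("hazard ratio")
    sel = table[table["selected"]]
    if not sel.empty:
        ax1.bar(sel["k"], sel["hr"], color="#c33")
    with np.errstate(divide="ignore"):
        ax2.bar(table["k"], -np.log10(table["p"]), color="#777")
    ax2.set_ylabel("-log10 p")
    ax2.set_xlabel("signature size k")
    fig.tight_layout()
    fig.savefig(outdir / "sweep.png", dpi=100, metadata={"Software": None})
    plt.close(fig)


def _plot_pcoa(coords, pairing, outdir, group_name):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tissue = pairing.set_index("sample_id")["tissue"].reindex(coords.index)
    fig, ax = plt.subplots(figsize=(5, 4))
    for t, marker in (("tumor", "o"), ("NBT", "^")):
        mask = tissue.astype(str).str.upper().str[0] == t[0].upper()
        ax.scatter(coords.loc[mask, "PC1"], coords.loc[mask, "PC2"],
                   marker=marker, label=t, alpha=0.7)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend()
    ax.set_title(f"PCoA (Bray-Curtis), {group_name}")
    fig.tight_layout()
    fig.savefig(outdir / f"pcoa_{group_name.lower()}.png", dpi=100,
                metadata={"Software": None})
    plt.close(fig)


def _microbiome_stage(genus, pairing, labels, config, outdir, manifest):
    rel = relative_abundance(genus)
    rel.to_csv(outdir / "genus_relative_abundance.tsv", sep="\t")
    alpha = berger_parker(genus)
    alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t")

    pairing = pairing.copy()
    pairing["group"] = labels.reindex(pairing["patient_id"]).to_numpy()
    results = {}
    for gname in ("TSM", "HM"):
        sub = pairing[pairing["group"] == gname]
        if sub["patient_id"].nunique() < 2:
            manifest["stages"]["microbiome"].setdefault("skipped", []).append(
                f"{gname}: fewer than two patients")
            continue
        cols = sub["sample_id"].tolist()
        rel_g = rel[cols]
        dist = bray_curtis(rel_g)
        nio.write_distance(dist, outdir / f"bray_curtis_{gname.lower()}.tsv")
        tissue = sub.set_index("sample_id")["tissue"].reindex(cols)
        tissue = tissue.astype(str).str.upper().str[0].to_numpy()
        perm = permanova(dist, tissue, n_perm=config.n_permutations,
                         seed=config.seed)
        coords, eig, prop = pcoa(dist, n_axes=2)
        coords.to_csv(outdir / f"pcoa_{gname.lower()}.tsv", sep="\t")
        if config.make_plots:
            _plot_pcoa(coords, sub, outdir, gname)
        genus_tests = paired_genus_tests(rel_g, sub)
        genus_tests.to_csv(outdir / f"genus_wilcoxon_{gname.lower()}.tsv", sep="\t")
        alpha_res = paired_alpha_test(alpha["berger_parker"], sub)
        alpha_res.to_csv(outdir / f"alpha_wilcoxon_{gname.lower()}.tsv", sep="\t")
        results[gname] = {
            "permanova_f": perm.pseudo_f,
            "permanova_p": perm.p_value,
            "alpha_wilcoxon_p": float(alpha_res["p_value"].iloc[0]),
            "n_pairs": int(sub["patient_id"].nunique()),
        }
    return results


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": _version,
        "config": config.to_dict(),
        "stages": {},
    }

    tumor, nbt, clinical, genus, pairing, truth = _load_inputs(config)
    if config.simulation is not None:
        nio.write_counts(tumor, outdir / "tumor_counts.tsv")
        nio.write_counts(nbt, outdir / "nbt_counts.tsv")
        nio.write_clinical(clinical, outdir / "clinical.tsv")
        nio.write_genus(genus, outdir / "genus_counts.tsv")
        nio.write_pairing(pairing, outdir / "pairing.tsv")
        truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)
    manifest["stages"]["input"] = {
        "n_genes": int(tumor.shape[0]),
        "n_patients": int(tumor.shape[1]),
    }

    # normalization on the pooled tumor+NBT libraries
    pooled = pd.concat([tumor, nbt], axis=1)
    factors = tmm_factors(pooled)
    factors.factors.rename_axis("sample_id").to_csv(
        outdir / "tmm_factors.tsv", sep="\t")
    logcpm = cpm(pooled, factors, log=True)
    avg = average_log2cpm(pooled, factors)
    logcpm_t = logcpm[tumor.columns]
    logcpm_n = logcpm[nbt.columns]
    manifest["stages"]["normalize"] = {
        "reference_sample": factors.reference_sample,
        "n_samples": int(pooled.shape[1]),
    }
    log.info("normalize: %d samples, reference %s",
             pooled.shape[1], factors.reference_sample)

    # paired differential expression + filters
    deg = paired_moderated_test(logcpm_t, logcpm_n)
    ranked, deg_table = filter_and_rank(
        deg, avg, config.lfc_min, config.fdr_max, config.alogcpm_min)
    deg_out = deg_table.rename_axis("gene_id").rename(
        columns={"p_value": "p", "passes_filter": "pass"})
    deg_out[["log2fc", "avg_log2cpm", "p", "fdr", "pass", "fc_rank"]].to_csv(
        outdir / "deg.tsv", sep="\t")
    manifest["stages"]["deg"] = {
        "n_tested": int(deg.shape[0]),
        "n_passing": int(deg_table["passes_filter"].sum()),
        "d0": float(deg.attrs["d0"]) if np.isfinite(deg.attrs["d0"]) else "inf",
    }
    log.info("deg: %d genes pass the filters", len(ranked))

    # signature-size sweep + classification
    params = SsgseaParams(config.ssgsea_alpha, config.ssgsea_normalize)
    sweep = sweep_signature_size(
        ranked, logcpm_n, clinical,
        k_range=range(config.k_min, config.k_max + 1),
        endpoint=config.endpoint, objective=config.sweep_objective, params=params,
    )
    sweep.table.to_csv(outdir / "sweep.tsv", sep="\t", index=False)
    nio.write_gmt({"tumor_supportive_signature": sweep.selected_genes},
                  outdir / "signature.gmt")
    cls = sweep.classification
    scores_out = cls.to_frame().rename_axis("sample_id")
    scores_out.to_csv(outdir / "scores.tsv", sep="\t")
    if config.make_plots:
        _plot_sweep(sweep.table, outdir)
    n_tsm = int((cls.labels == "TSM").sum())
    n_hm = int((cls.labels == "HM").sum())
    manifest["stages"]["sweep"] = {
        "selected_k": sweep.selected_k,
        "cutoff": cls.cutoff,
        "hr": sweep.cox.hazard_ratio("tsm"),
        "n_tsm": n_tsm,
        "n_hm": n_hm,
    }
    log.info("sweep: selected k=%d, HR=%.3f, %d TSM / %d HM",
             sweep.selected_k, sweep.cox.hazard_ratio("tsm"), n_tsm, n_hm)

    # survival analysis on the classified groups
    labels = cls.labels.copy()
    labels.index = [p for p in labels.index]
    surv_summaries = {}
    for endpoint in ("rfs", "os"):
        surv_summaries[endpoint] = _km_tables(
            clinical, labels, endpoint, outdir, config.make_plots)
    cov = _encode_covariates(clinical, labels)
    fits_rows = []
    if cov.shape[1] >= 2:
        uni, multi = screen_then_multivariate(
            pd.concat([cov, clinical[[f"time_{config.endpoint}",
                                      f"event_{config.endpoint}"]]], axis=1),
            f"time_{config.endpoint}", f"event_{config.endpoint}",
            list(cov.columns),
        )
        for name, fit in uni.items():
            row = fit.summary.loc[name].to_dict()
            fits_rows.append(dict(model="univariate", covariate=name, **row))
        if multi is not None:
            for name, row in multi.summary.iterrows():
                fits_rows.append(dict(model="multivariate", covariate=name,
                                      **row.to_dict()))
    pd.DataFrame(fits_rows).to_csv(outdir / "cox_fits.tsv", sep="\t", index=False)
    manifest["stages"]["survival"] = surv_summaries

    # recovery metrics against planted truth (simulation runs only)
    if truth is not None:
        planted = set(truth.planted_genes)
        selected = set(sweep.selected_genes)
        agree = (labels.reindex(truth.labels.index) == truth.labels).mean()
        manifest["stages"]["truth_recovery"] = {
            "planted_recovered_frac": len(planted & selected) / len(planted),
            "label_agreement": float(agree),
            "beta_true": truth.beta_true,
        }

    # microbiome resemblance
    if genus is not None:
        manifest["stages"]["microbiome"] = {}
        manifest["stages"]["microbiome"] = dict(
            manifest["stages"]["microbiome"],
            **{"groups": _microbiome_stage(genus, pairing, labels, config,
                                           outdir, manifest)},
        )
    else:
        manifest["stages"]["microbiome"] = {"skipped": "no genus table provided"}
        log.info("microbiome stage skipped: no genus table")

    checksums = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest["checksums"] = checksums
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return manifest
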