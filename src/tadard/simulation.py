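"""Null (error-control) and power simulations for the Random Draw pipeline.

The score model is Gaussian: de novo scores ~ N(0.6, 0.1) and inherited
scores ~ N(0.2, 0.1) (variances, not standard deviations).  Because these
distributions are taken as known, the sensitivity and specificity at a
threshold c are available analytically:

    w1(c) = 1 - Phi((c - 0.6) / sqrt(0.1)),
    w2(c) = Phi((c - 0.2) / sqrt(0.1)).

The *power* simulation plants risk genes: per gene the number of de novo
case variants is the de novo fraction (0.603 risk / 0.026 non-risk) times
its case variant count, rounded to the nearest integer; scores are drawn
per hidden label, thresholded, and the Random Draw Bayes factors are
combined with fixed family-based Bayes factors (flooring at 1) before
q-value selection.  The mean number of discoveries per threshold is
reported alongside the family-only baseline.

The *null* simulation draws fully signal-free replicates (background de
novo rate everywhere, family counts from the null Poisson model) and
reports the per-family error rate (PFER): the mean number of selected
genes, all of which are false by construction, under both the Bonferroni
and the q-value rule.

Scores are not clipped to [0, 1]; thresholding operates on the real line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .classdn import score_variants
from .exceptions import ConfigurationError
from .random_draw import RDParameters, RDPriors, rd_bayes_factor_table
from .synthetic_data import generate_null_case_table, round_half_away
from .tada_integration import (FDRConfig, bayesian_fdr, combine_bfs,
                               denovo_bayes_factor, select_genes,
                               DeNovoBFParams)


@dataclass(frozen=True)
class PowerSimConfig:
    """Score model, de novo fractions, thresholds and replication depth."""

    thresholds: tuple = (0.3, 0.5, 0.7, 0.9)
    n_replicates: int = 100
    score_mean_denovo: float = 0.6
    score_mean_inherited: float = 0.2
    score_variance: float = 0.1
    denovo_fraction_risk: float = 0.603
    denovo_fraction_nonrisk: float = 0.026
    q_cutoff: float = 0.05
    pi_risk: float = 0.06
    rng_seed: int = 0

    def __post_init__(self):
        if any(not 0.0 <= c <= 1.0 for c in self.thresholds):
            raise ConfigurationError("thresholds must lie in [0, 1]")
        if self.score_variance <= 0:
            raise ConfigurationError("score variance must be positive")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be at least 1")
        if self.denovo_fraction_risk < self.denovo_fraction_nonrisk:
            raise ConfigurationError(
                "denovo_fraction_risk must be >= denovo_fraction_nonrisk")

    @property
    def fdr_config(self) -> FDRConfig:
        return FDRConfig(pi_risk=self.pi_risk, q_cutoff=self.q_cutoff,
                         bonferroni_alpha=self.q_cutoff)


def gaussian_threshold_performance(c: float,
                                   config: PowerSimConfig = PowerSimConfig()
                                   ) -> tuple[float, float]:
    """Analytic (w1, w2) at threshold c under the Gaussian score model."""
    sd = math.sqrt(config.score_variance)
    w1 = float(norm.sf((c - config.score_mean_denovo) / sd))
    w2 = float(norm.cdf((c - config.score_mean_inherited) / sd))
    return w1, w2


def generation_matched_priors(config: PowerSimConfig) -> RDPriors:
    """Point priors at the exact fractions the simulation generates from."""
    return RDPriors.point(config.denovo_fraction_risk,
                          config.denovo_fraction_nonrisk)


def _threshold_counts(n_dn, n_inh, scores_dn, scores_inh, c):
    """Per-gene (xd, xh) from label-wise score vectors at threshold c."""
    n_genes = len(n_dn)
    gidx_dn = np.repeat(np.arange(n_genes), n_dn)
    gidx_inh = np.repeat(np.arange(n_genes), n_inh)
    hits_dn = np.bincount(gidx_dn[scores_dn > c], minlength=n_genes)
    hits_inh = np.bincount(gidx_inh[scores_inh > c], minlength=n_genes)
    xd = hits_dn + hits_inh
    xh = (n_dn + n_inh) - xd
    return xd, xh


def _count_discoveries(genes, bf_rd, config, rule="qvalue"):
    table = pd.DataFrame({
        "gene_id": genes["gene_id"],
        "bf_final": combine_bfs(genes["bf_family"].to_numpy(), bf_rd),
    })
    ranked = select_genes(bayesian_fdr(table, config.fdr_config),
                          config.fdr_config)
    col = "selected_fdr" if rule == "qvalue" else "selected_bonferroni"
    return ranked.loc[ranked[col], "gene_id"]


def family_only_discoveries(genes: pd.DataFrame,
                            config: PowerSimConfig = PowerSimConfig()) -> int:
    """Discoveries from family-based Bayes factors alone (RD disabled)."""
    return int(len(_count_discoveries(genes, np.ones(len(genes)), config)))


def run_power_simulation(genes: pd.DataFrame,
                         config: PowerSimConfig = PowerSimConfig(),
                         priors: RDPriors | None = None) -> pd.DataFrame:
    """Mean discoveries per threshold on a cohort with planted risk genes.

    ``genes`` needs columns gene_id, n_case_variants, is_risk and
    bf_family.  Per replicate, hidden labels follow the rounding rule,
    scores are drawn once and swept over all thresholds (paired
    comparisons), and discoveries are genes with q-value below the cutoff.

    Returns one row per threshold with the analytic (w1, w2), the mean and
    standard deviation of the discovery count, and the constant
    family-only baseline.
    """
    required = {"gene_id", "n_case_variants", "is_risk", "bf_family"}
    if not required <= set(genes.columns):
        raise ConfigurationError(f"gene table needs columns {sorted(required)}")
    if len(genes) == 0:
        raise ConfigurationError("gene table is empty")
    if priors is None:
        priors = RDPriors.default()
    genes = genes.reset_index(drop=True)
    n = genes["n_case_variants"].to_numpy(dtype=int)
    frac = np.where(genes["is_risk"].to_numpy(),
                    config.denovo_fraction_risk, config.denovo_fraction_nonrisk)
    n_dn = np.minimum(np.maximum(round_half_away(frac * n), 0).astype(int), n)
    n_inh = n - n_dn
    sd = math.sqrt(config.score_variance)
    baseline = family_only_discoveries(genes, config)

    rngs = [np.random.Generator(np.random.PCG64(s))
            for s in np.random.SeedSequence(config.rng_seed).spawn(config.n_replicates)]
    disc = {c: [] for c in config.thresholds}
    for rng in rngs:
        scores_dn = rng.normal(config.score_mean_denovo, sd, int(n_dn.sum()))
        scores_inh = rng.normal(config.score_mean_inherited, sd, int(n_inh.sum()))
        for c in config.thresholds:
            w1, w2 = gaussian_threshold_performance(c, config)
            xd, xh = _threshold_counts(n_dn, n_inh, scores_dn, scores_inh, c)
            counts = pd.DataFrame({"gene_id": genes["gene_id"],
                                   "xd": xd, "xh": xh})
            bf = rd_bayes_factor_table(counts, RDParameters(w1, w2, c),
                                       priors)
            selected = _count_discoveries(genes, bf["bf_rd"].to_numpy(), config)
            disc[c].append(len(selected))
    rows = []
    for c in config.thresholds:
        w1, w2 = gaussian_threshold_performance(c, config)
        rows.append({
            "threshold": c, "w1": w1, "w2": w2,
            "mean_discoveries": float(np.mean(disc[c])),
            "sd_discoveries": float(np.std(disc[c])),
            "family_only_discoveries": baseline,
        })
    return pd.DataFrame(rows)


def run_null_simulation(genes: pd.DataFrame,
                        config: PowerSimConfig = PowerSimConfig(),
                        denovo_params: DeNovoBFParams | None = None,
                        background_denovo_fraction: float = 0.026,
                        priors: RDPriors | None = None) -> pd.DataFrame:
    """PFER per threshold on replicates whose case data carry no signal.

    ``genes`` needs gene_id, n_case_variants and mu.  Two designs are
    supported.  In the fully null design (default), each replicate draws a
    signal-free family dataset (de novo counts Poisson at 2*N*mu, gamma=1);
    no gene is a risk gene, so every selection is an error.  If ``genes``
    carries a ``bf_family`` column, those family Bayes factors are held
    fixed across replicates — the analogue of combining one real family
    cohort with resampled null case data — and an ``is_risk`` column (if
    present) designates the true genes excluded from the error count.
    In both designs the case data are null: hidden labels are Bernoulli at
    the background de novo fraction for every gene.
    """
    required = {"gene_id", "n_case_variants", "mu"}
    if not required <= set(genes.columns):
        raise ConfigurationError(f"gene table needs columns {sorted(required)}")
    if len(genes) == 0:
        raise ConfigurationError("gene table is empty")
    if denovo_params is None:
        denovo_params = DeNovoBFParams(n_trios=10_000)
    if priors is None:
        priors = RDPriors.default()
    genes = genes.reset_index(drop=True)
    n = genes["n_case_variants"].to_numpy(dtype=int)
    mu = genes["mu"].to_numpy(dtype=float)
    sd = math.sqrt(config.score_variance)
    lam0 = 2.0 * denovo_params.n_trios * mu
    fixed_family = "bf_family" in genes.columns
    true_genes = (set(genes.loc[genes["is_risk"], "gene_id"])
                  if "is_risk" in genes.columns else set())

    rngs = [np.random.Generator(np.random.PCG64(s))
            for s in np.random.SeedSequence(config.rng_seed).spawn(config.n_replicates)]
    pfer = {c: {"bonferroni": [], "qvalue": []} for c in config.thresholds}
    for rng in rngs:
        if fixed_family:
            fam = genes[["gene_id", "bf_family"]]
        else:
            x_family = rng.poisson(lam0)
            bf_family = denovo_bayes_factor(x_family, mu, denovo_params)
            fam = pd.DataFrame({"gene_id": genes["gene_id"],
                                "bf_family": bf_family})
        labels_dn = rng.binomial(n, background_denovo_fraction)
        n_inh = n - labels_dn
        scores_dn = rng.normal(config.score_mean_denovo, sd, int(labels_dn.sum()))
        scores_inh = rng.normal(config.score_mean_inherited, sd, int(n_inh.sum()))
        for c in config.thresholds:
            w1, w2 = gaussian_threshold_performance(c, config)
            xd, xh = _threshold_counts(labels_dn, n_inh, scores_dn, scores_inh, c)
            counts = pd.DataFrame({"gene_id": genes["gene_id"],
                                   "xd": xd, "xh": xh})
            bf = rd_bayes_factor_table(counts, RDParameters(w1, w2, c),
                                       priors)
            for rule in ("bonferroni", "qvalue"):
                sel = _count_discoveries(fam, bf["bf_rd"].to_numpy(), config,
                                         rule=rule)
                pfer[c][rule].append(len(set(sel) - true_genes))
    rows = []
    for c in config.thresholds:
        w1, w2 = gaussian_threshold_performance(c, config)
        rows.append({
            "threshold": c, "w1": w1, "w2": w2,
            "pfer_bonferroni": float(np.mean(pfer[c]["bonferroni"])),
            "pfer_qvalue": float(np.mean(pfer[c]["qvalue"])),
        })
    return pd.DataFrame(rows)


def run_classifier_null_simulation(genes: pd.DataFrame,
                                   model,
                                   performance: dict[float, tuple[float, float]],
                                   config: PowerSimConfig = PowerSimConfig(),
                                   denovo_params: DeNovoBFParams | None = None,
                                   cohort_config=None,
                                   profiles=None,
                                   n_variants: int | None = None,
                                   background_denovo_fraction: float = 0.026,
                                   priors: RDPriors | None = None
                                   ) -> pd.DataFrame:
    """PFER per threshold with de novo scores from a fitted ClassDn model.

    The closest synthetic analogue of the sibling-resampling null: each
    replicate draws a fresh signal-free case table of *covariates* (hidden
    labels at the background de novo rate), scores it with the trained
    classifier, and thresholds the scores.  ``performance`` maps each
    threshold to the (w1, w2) estimated on labeled test data — exactly what
    a real analysis would feed the Random Draw model.  Family evidence is a
    signal-free Poisson draw per replicate, as in the Gaussian-score null.
    """
    required = {"gene_id", "mu"}
    if not required <= set(genes.columns):
        raise ConfigurationError(f"gene table needs columns {sorted(required)}")
    missing = [c for c in config.thresholds if c not in performance]
    if missing:
        raise ConfigurationError(f"performance missing thresholds {missing}")
    if denovo_params is None:
        denovo_params = DeNovoBFParams(n_trios=10_000)
    if priors is None:
        priors = RDPriors.default()
    genes = genes.reset_index(drop=True)
    mu = genes["mu"].to_numpy(dtype=float)
    lam0 = 2.0 * denovo_params.n_trios * mu
    if n_variants is None:
        if "n_case_variants" not in genes.columns:
            raise ConfigurationError("give n_variants or an n_case_variants column")
        n_variants = int(genes["n_case_variants"].sum())
    gene_pos = {g: i for i, g in enumerate(genes["gene_id"])}

    seeds = np.random.SeedSequence(config.rng_seed).spawn(config.n_replicates)
    pfer = {c: {"bonferroni": [], "qvalue": []} for c in config.thresholds}
    for seq in seeds:
        rep_seed = int(seq.generate_state(1)[0] % (2**31 - 1))
        rng = np.random.Generator(np.random.PCG64(seq))
        case, _ = generate_null_case_table(
            n_variants, profiles=profiles, rng_seed=rep_seed,
            config=cohort_config,
            background_denovo_fraction=background_denovo_fraction,
            genes=genes[["gene_id", "mu"]])
        scores = score_variants(model, case)
        gidx = case["gene_id"].map(gene_pos).to_numpy()
        x_family = rng.poisson(lam0)
        bf_family = denovo_bayes_factor(x_family, mu, denovo_params)
        fam = pd.DataFrame({"gene_id": genes["gene_id"], "bf_family": bf_family})
        n_per_gene = np.bincount(gidx, minlength=len(genes))
        for c in config.thresholds:
            w1, w2 = performance[c]
            xd = np.bincount(gidx[scores > c], minlength=len(genes))
            counts = pd.DataFrame({"gene_id": genes["gene_id"],
                                   "xd": xd, "xh": n_per_gene - xd})
            bf = rd_bayes_factor_table(counts, RDParameters(w1, w2, c),
                                       priors)
            for rule in ("bonferroni", "qvalue"):
                sel = _count_discoveries(fam, bf["bf_rd"].to_numpy(), config,
                                         rule=rule)
                pfer[c][rule].append(len(sel))
    rows = []
    for c in config.thresholds:
        w1, w2 = performance[c]
        rows.append({
            "threshold": c, "w1": w1, "w2": w2,
            "pfer_bonferroni": float(np.mean(pfer[c]["bonferroni"])),
            "pfer_qvalue": float(np.mean(pfer[c]["qvalue"])),
        })
    return pd.DataFrame(rows)
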