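"""Family-based de novo Bayes factors, BF combination and Bayesian FDR.

The family-based (trio) evidence per gene follows the classical transmitted
and de novo association model: the observed de novo count x in a gene with
per-chromosome mutation rate mu across N trios is

    H0:  x ~ Poisson(2 N mu)
    H1:  x ~ Poisson(2 N mu gamma),  gamma ~ Gamma(gamma_mean * beta, rate beta)

so the H1 marginal is negative-binomial and the Bayes factor has a closed
form.  Gene-level evidence streams are combined by flooring each BF at 1 and
multiplying; the products are converted to Bayesian FDR q-values (cumulative
mean posterior null probability down the BF ranking) and genes are selected
either at a q-value cutoff or by a Bonferroni rule on a q-to-p inversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import poisson

from .exceptions import SchemaError


@dataclass(frozen=True)
class DeNovoBFParams:
    """Trio count model: cohort size and the relative-risk prior.

    ``gamma_mean`` is the prior mean relative risk of a risk gene and
    ``beta`` the rate hyperparameter of its Gamma prior (shape is
    ``gamma_mean * beta``); these must be chosen by the analyst for real
    data — the defaults are conventional values for haploinsufficient
    developmental-disorder genes.
    """

    n_trios: int
    gamma_mean: float = 20.0
    beta: float = 1.0

    def __post_init__(self):
        if self.n_trios < 1:
            raise ValueError("n_trios must be at least 1")
        if self.gamma_mean <= 1.0:
            raise ValueError("gamma_mean must exceed 1 for a risk-conferring "
                             "alternative")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


@dataclass(frozen=True)
class FDRConfig:
    """Risk-gene prior proportion and selection cutoffs."""

    pi_risk: float = 0.06
    q_cutoff: float = 0.05
    bonferroni_alpha: float = 0.05

    def __post_init__(self):
        for name in ("pi_risk", "q_cutoff", "bonferroni_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} outside (0, 1)")


def denovo_bayes_factor(x, mu, params: DeNovoBFParams):
    """Closed-form de novo BF for count x at mutation rate mu.

    Vectorised over x and mu.  The H1 marginal is the Poisson-Gamma
    (negative binomial) mixture; H0 is Poisson with gamma = 1.
    """
    x = np.asarray(x)
    if np.any(x < 0) or np.any(np.asarray(x, dtype=float) != np.floor(x)):
        raise ValueError("de novo counts must be non-negative integers")
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mutation rates must be positive")
    lam0 = 2.0 * params.n_trios * mu
    a = params.gamma_mean * params.beta
    b = params.beta
    log_m1 = (gammaln(x + a) - gammaln(a) - gammaln(x + 1)
              + a * (np.log(b) - np.log(b + lam0))
              + x * (np.log(lam0) - np.log(b + lam0)))
    log_m0 = poisson.logpmf(x, lam0)
    bf = np.exp(log_m1 - log_m0)
    return float(bf) if bf.ndim == 0 else bf


def combine_bfs(bf_family, bf_rd):
    """Floor each evidence stream at 1, then multiply.

    Flooring prevents one stream's absence of signal from down-weighting
    the other's; the combined BF is therefore always >= 1.
    """
    bf_family = np.asarray(bf_family, dtype=float)
    bf_rd = np.asarray(bf_rd, dtype=float)
    if np.any(bf_family <= 0) or np.any(bf_rd <= 0):
        raise ValueError("Bayes factors must be positive")
    out = np.maximum(bf_family, 1.0) * np.maximum(bf_rd, 1.0)
    return float(out) if out.ndim == 0 else out


def bayesian_fdr(table: pd.DataFrame, config: FDRConfig = FDRConfig(),
                 bf_column: str = "bf_final") -> pd.DataFrame:
    """Posterior probabilities and Bayesian FDR q-values from gene BFs.

    With prior risk proportion pi, the posterior of being a risk gene is
    ``pi*BF / (pi*BF + 1 - pi)``.  Genes are ranked by BF (descending, ties
    broken by gene_id) and the q-value of rank i is the mean posterior null
    probability (1 - posterior) of the top i genes, made monotone
    non-decreasing down the ranking.
    """
    for col in ("gene_id", bf_column):
        if col not in table.columns:
            raise SchemaError(f"table is missing column {col!r}")
    out = table.copy()
    if len(out) == 0:
        for col in ("posterior_p1", "qvalue", "rank"):
            out[col] = np.empty(0)
        return out
    bf = out[bf_column].to_numpy(dtype=float)
    if np.any(bf <= 0):
        raise ValueError("Bayes factors must be positive")
    pi = config.pi_risk
    out["posterior_p1"] = pi * bf / (pi * bf + 1.0 - pi)
    out = out.sort_values([bf_column, "gene_id"],
                          ascending=[False, True], kind="mergesort")
    q = np.cumsum(1.0 - out["posterior_p1"].to_numpy()) / np.arange(1, len(out) + 1)
    out["qvalue"] = np.maximum.accumulate(q)
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def select_genes(results: pd.DataFrame,
                 config: FDRConfig = FDRConfig()) -> pd.DataFrame:
    """Flag genes under the FDR cutoff and the Bonferroni rule.

    The Bonferroni rule converts q-values back to per-gene p-values by
    inverting the Benjamini-Hochberg relation, ``p_i = q_i * rank_i / m``
    on the monotone q sequence — a documented convention, since a q-to-p
    inversion is not unique — and selects p_i < alpha / m.
    """
    for col in ("qvalue", "rank"):
        if col not in results.columns:
            raise SchemaError(f"results table is missing column {col!r}; "
                              "run bayesian_fdr first")
    out = results.copy()
    m = len(out)
    if m == 0:
        out["selected_fdr"] = np.empty(0, dtype=bool)
        out["selected_bonferroni"] = np.empty(0, dtype=bool)
        return out
    out["selected_fdr"] = out["qvalue"].to_numpy() < config.q_cutoff
    p = out["qvalue"].to_numpy() * out["rank"].to_numpy() / m
    out["selected_bonferroni"] = p < config.bonferroni_alpha / m
    return out


def integrate_evidence(family: pd.DataFrame, rd: pd.DataFrame,
                       config: FDRConfig = FDRConfig(),
                       denovo_params: DeNovoBFParams | None = None
                       ) -> pd.DataFrame:
    """Full gene-result table from family and Random Draw evidence.

    ``family`` must carry gene_id and either a precomputed ``bf_family``
    column or de novo counts ``x`` plus mutation rates ``mu`` (then
    ``denovo_params`` is required).  ``rd`` carries gene_id and ``bf_rd``.
    Genes present in only one table contribute a neutral BF of 1 for the
    missing stream.
    """
    if "gene_id" not in family.columns or "gene_id" not in rd.columns:
        raise SchemaError("both tables need a gene_id column")
    fam = family.copy()
    if "bf_family" not in fam.columns:
        if denovo_params is None or not {"x", "mu"} <= set(fam.columns):
            raise SchemaError("family table needs bf_family, or x and mu "
                              "plus denovo_params")
        fam["bf_family"] = denovo_bayes_factor(fam["x"].to_numpy(),
                                               fam["mu"].to_numpy(),
                                               denovo_params)
    merged = fam[["gene_id", "bf_family"]].merge(
        rd[["gene_id", "bf_rd"]], on="gene_id", how="outer")
    merged["bf_family"] = merged["bf_family"].fillna(1.0)
    merged["bf_rd"] = merged["bf_rd"].fillna(1.0)
    merged["bf_final"] = combine_bfs(merged["bf_family"].to_numpy(),
                                     merged["bf_rd"].to_numpy())
    ranked = bayesian_fdr(merged, config)
    return select_genes(ranked, config)
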