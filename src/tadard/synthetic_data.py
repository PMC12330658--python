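"""Synthetic cohorts of rare protein-truncating variants.

Generates the three kinds of tables the pipeline consumes, without any
external data:

* *labeled* family-style tables, where each variant carries its true
  inheritance class (1 = de novo, 0 = inherited) — the analogue of
  trio-sequenced offspring variants used to train and test the classifier;
* *case-only* tables, where the inheritance class is hidden and only a
  de novo score (drawn from a label-conditional Gaussian) is observed;
* fully *null* case tables with no gene-level enrichment, used for
  error-rate calibration.

Covariates are drawn from label-conditional distributions chosen so that de
novo variants have lower allele frequency, lower LOEUF, higher CCR, lower
developmental-delay FDR, lower observed and higher expected LoF counts than
inherited variants — the directions seen in real family data.  The exact
distribution families are a modelling choice (documented in
``docs/methods.md``); only the class separation and the legal ranges matter
downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError

COVARIATES = ("AF", "LOEUF", "CCR", "FDR_TADA_DD", "obs_lof", "exp_lof")

#: Directions in which the de novo class mean differs from the inherited
#: class mean (-1: lower for de novo, +1: higher for de novo).
CLASS_DIRECTIONS = {
    "AF": -1,
    "LOEUF": -1,
    "CCR": +1,
    "FDR_TADA_DD": -1,
    "obs_lof": -1,
    "exp_lof": +1,
}


@dataclass(frozen=True)
class DistSpec:
    """One univariate sampling distribution.

    ``family`` is one of ``lognormal`` (params: mean of log, sd of log),
    ``scaled_beta`` (a, b, scale), ``truncnorm`` (mean, sd, low, high),
    ``poisson`` (rate) and ``gamma`` (shape, scale).  ``clip`` optionally
    clamps draws into a closed interval (used to enforce the rare-variant
    allele-frequency bound).
    """

    family: str
    params: tuple
    clip: tuple | None = None

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "lognormal":
            mean_log, sd_log = self.params
            x = rng.lognormal(mean=mean_log, sigma=sd_log, size=n)
        elif self.family == "scaled_beta":
            a, b, scale = self.params
            x = rng.beta(a, b, size=n) * scale
        elif self.family == "truncnorm":
            mean, sd, low, high = self.params
            a, b = (low - mean) / sd, (high - mean) / sd
            x = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n,
                                    random_state=rng)
        elif self.family == "poisson":
            (lam,) = self.params
            x = rng.poisson(lam, size=n).astype(float)
        elif self.family == "gamma":
            shape, scale = self.params
            x = rng.gamma(shape, scale, size=n)
        else:  # pragma: no cover - guarded by profile construction
            raise ConfigurationError(f"unknown distribution family {self.family!r}")
        if self.clip is not None:
            x = np.clip(x, self.clip[0], self.clip[1])
        return x

    def mean(self) -> float:
        """Analytic mean, used to validate class-separation directions."""
        if self.family == "lognormal":
            m, s = self.params
            return math.exp(m + s**2 / 2)
        if self.family == "scaled_beta":
            a, b, scale = self.params
            return scale * a / (a + b)
        if self.family == "truncnorm":
            mean, sd, low, high = self.params
            a, b = (low - mean) / sd, (high - mean) / sd
            return float(stats.truncnorm.mean(a, b, loc=mean, scale=sd))
        if self.family == "poisson":
            return float(self.params[0])
        if self.family == "gamma":
            return float(self.params[0] * self.params[1])
        raise ConfigurationError(f"unknown distribution family {self.family!r}")


@dataclass(frozen=True)
class CovariateProfile:
    """Label-conditional distributions of one covariate."""

    name: str
    denovo_dist: DistSpec
    inherited_dist: DistSpec

    def __post_init__(self):
        if self.name not in COVARIATES:
            raise ConfigurationError(f"unknown covariate {self.name!r}")
        direction = CLASS_DIRECTIONS[self.name]
        diff = self.denovo_dist.mean() - self.inherited_dist.mean()
        if diff * direction <= 0:
            raise ConfigurationError(
                f"covariate {self.name}: de novo mean must be "
                f"{'higher' if direction > 0 else 'lower'} than inherited mean"
            )


def default_profiles() -> list[CovariateProfile]:
    """Covariate profiles with roughly unit standardized mean differences.

    AF is clamped to the ultra-rare range [0, 0.001]; CCR to its percentile
    range [0, 100]; FDR to [0, 1]; obs_lof is a non-negative count and
    exp_lof a positive expectation.
    """
    return [
        CovariateProfile(
            "AF",
            # clip strictly below the 0.1% bound so every generated variant
            # survives the rarity filter (AF < 0.001 is strict)
            DistSpec("lognormal", (math.log(1e-5), 1.0),
                     clip=(0.0, 0.000999)),
            DistSpec("lognormal", (math.log(1.2e-4), 1.0),
                     clip=(0.0, 0.000999)),
        ),
        CovariateProfile(
            "LOEUF",
            DistSpec("scaled_beta", (2.0, 6.0, 2.0)),
            DistSpec("scaled_beta", (6.0, 4.0, 2.0)),
        ),
        CovariateProfile(
            "CCR",
            DistSpec("truncnorm", (75.0, 20.0, 0.0, 100.0)),
            DistSpec("truncnorm", (40.0, 25.0, 0.0, 100.0)),
        ),
        CovariateProfile(
            "FDR_TADA_DD",
            DistSpec("scaled_beta", (1.2, 3.0, 1.0)),
            DistSpec("scaled_beta", (4.0, 1.5, 1.0)),
        ),
        CovariateProfile(
            "obs_lof",
            DistSpec("poisson", (5.0,)),
            DistSpec("poisson", (15.0,)),
        ),
        CovariateProfile(
            "exp_lof",
            DistSpec("gamma", (8.0, 2.5)),
            DistSpec("gamma", (4.0, 2.5)),
        ),
    ]


@dataclass(frozen=True)
class SimulatedCohortConfig:
    """Study conditions for a synthetic cohort.

    The de novo fractions default to the proportions of de novo variants
    observed among case variants in risk genes (0.603) and non-risk genes
    (0.026) in large family-based autism data, and the score model to
    Gaussians N(0.6, 0.1) / N(0.2, 0.1) for de novo / inherited variants.
    Per-gene variant counts are negative-binomial with mean proportional to
    the gene's mutation rate ``mu`` (lognormal across genes).
    """

    n_genes: int = 800
    n_variants_total: int = 2400
    denovo_fraction_risk: float = 0.603
    denovo_fraction_nonrisk: float = 0.026
    risk_gene_fraction: float = 0.05
    score_model: tuple[float, float, float] = (0.6, 0.2, 0.1)
    rng_seed: int = 0
    mean_mutation_rate: float = 2e-6
    mutation_rate_sigma: float = 1.2
    count_dispersion: float = 4.0

    def __post_init__(self):
        if self.n_genes <= 0 or self.n_variants_total < 0:
            raise ConfigurationError("n_genes must be positive, n_variants_total >= 0")
        for name in ("denovo_fraction_risk", "denovo_fraction_nonrisk",
                     "risk_gene_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.denovo_fraction_risk < self.denovo_fraction_nonrisk:
            raise ConfigurationError(
                "denovo_fraction_risk must be >= denovo_fraction_nonrisk"
            )
        if self.score_model[2] <= 0:
            raise ConfigurationError("score variance must be positive")

    def with_seed(self, seed: int) -> "SimulatedCohortConfig":
        return replace(self, rng_seed=seed)


def round_half_away(x):
    """Round to nearest integer, halves away from zero (fixed convention)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s))
            for s in np.random.SeedSequence(seed).spawn(n)]


def generate_genes(config: SimulatedCohortConfig) -> pd.DataFrame:
    """Gene table: identifier, mutation rate mu, risk flag.

    Deterministic given ``config.rng_seed``; the same gene table underlies
    the labeled, case and null tables produced from one config.
    """
    rng = _child_rngs(config.rng_seed, 1)[0]
    width = max(4, len(str(config.n_genes)))
    gene_id = [f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)]
    mu = rng.lognormal(math.log(config.mean_mutation_rate),
                       config.mutation_rate_sigma, size=config.n_genes)
    is_risk = rng.random(config.n_genes) < config.risk_gene_fraction
    return pd.DataFrame({"gene_id": gene_id, "mu": mu, "is_risk": is_risk})


def _draw_gene_counts(genes: pd.DataFrame, n_total: int, dispersion: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Per-gene variant counts ~ NB(mean proportional to mu)."""
    weights = genes["mu"].to_numpy()
    mean = weights / weights.sum() * n_total
    r = dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _check_profiles(profiles) -> dict[str, CovariateProfile]:
    if not profiles:
        raise ConfigurationError("profile list is empty")
    by_name = {p.name: p for p in profiles}
    missing = set(COVARIATES) - set(by_name)
    if missing:
        raise ConfigurationError(f"profiles missing covariates: {sorted(missing)}")
    return by_name


def _draw_covariates(labels: np.ndarray, profiles, rng) -> pd.DataFrame:
    by_name = _check_profiles(profiles)
    n = labels.size
    is_dn = labels.astype(bool)
    out = {}
    for name in COVARIATES:
        prof = by_name[name]
        x = np.empty(n)
        x[is_dn] = prof.denovo_dist.draw(rng, int(is_dn.sum()))
        x[~is_dn] = prof.inherited_dist.draw(rng, int((~is_dn).sum()))
        out[name] = x
    return pd.DataFrame(out)


def generate_labeled_table(config: SimulatedCohortConfig,
                           profiles: list[CovariateProfile] | None = None
                           ) -> pd.DataFrame:
    """Family-style variant table with known inheritance labels.

    Each variant's label is a Bernoulli draw with the gene's de novo
    fraction (risk vs non-risk); covariates follow the label-conditional
    profiles.  Columns: gene_id, the six covariates, ``label``.
    """
    profiles = default_profiles() if profiles is None else profiles
    _check_profiles(profiles)
    genes = generate_genes(config)
    _, counts_rng, label_rng, cov_rng = _child_rngs(config.rng_seed, 4)
    counts = _draw_gene_counts(genes, config.n_variants_total,
                               config.count_dispersion, counts_rng)
    gene_idx = np.repeat(np.arange(len(genes)), counts)
    frac = np.where(genes["is_risk"].to_numpy()[gene_idx],
                    config.denovo_fraction_risk, config.denovo_fraction_nonrisk)
    labels = (label_rng.random(gene_idx.size) < frac).astype(int)
    table = _draw_covariates(labels, profiles, cov_rng)
    table.insert(0, "gene_id", genes["gene_id"].to_numpy()[gene_idx])
    table["label"] = labels
    return table


def generate_case_table(config: SimulatedCohortConfig,
                        profiles: list[CovariateProfile] | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Case-only table (labels hidden) plus the hidden truth table.

    Per gene the number of de novo variants is the de novo fraction times
    the gene's variant count, rounded half-away-from-zero and floored at
    zero; the rest are inherited.  Each variant receives a de novo score
    drawn from the Gaussian score model conditional on its hidden label.

    Returns ``(case, truth)``: ``case`` has gene_id, the six covariates and
    ``score``; ``truth`` has gene_id, hidden ``label`` and ``gene_is_risk``,
    row-aligned with ``case`` (for evaluation only).
    """
    profiles = default_profiles() if profiles is None else profiles
    _check_profiles(profiles)
    if config.n_variants_total == 0:
        raise ConfigurationError("n_variants_total must be positive for a case table")
    genes = generate_genes(config)
    _, counts_rng, score_rng, cov_rng = _child_rngs(config.rng_seed, 4)
    counts = _draw_gene_counts(genes, config.n_variants_total,
                               config.count_dispersion, counts_rng)
    frac = np.where(genes["is_risk"].to_numpy(),
                    config.denovo_fraction_risk, config.denovo_fraction_nonrisk)
    n_dn = np.maximum(round_half_away(frac * counts), 0).astype(int)
    n_dn = np.minimum(n_dn, counts)
    labels = np.concatenate([
        np.repeat([1, 0], [d, c - d]) for c, d in zip(counts, n_dn)
    ]) if counts.sum() else np.empty(0, dtype=int)
    gene_idx = np.repeat(np.arange(len(genes)), counts)
    mean_dn, mean_inh, var = config.score_model
    means = np.where(labels == 1, mean_dn, mean_inh)
    scores = score_rng.normal(means, math.sqrt(var))
    case = _draw_covariates(labels, profiles, cov_rng)
    case.insert(0, "gene_id", genes["gene_id"].to_numpy()[gene_idx])
    case["score"] = scores
    truth = pd.DataFrame({
        "gene_id": case["gene_id"],
        "label": labels,
        "gene_is_risk": genes["is_risk"].to_numpy()[gene_idx],
    })
    return case, truth


def generate_null_case_table(n_variants: int,
                             profiles: list[CovariateProfile] | None = None,
                             rng_seed: int = 0,
                             config: SimulatedCohortConfig | None = None,
                             background_denovo_fraction: float = 0.026,
                             genes: pd.DataFrame | None = None,
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fully null case table: background de novo rate, no enriched gene.

    Variants are assigned to genes proportionally to mutation-opportunity
    weights (the gene's mu); hidden labels are Bernoulli draws at the
    background de novo fraction with no dependence on any risk flag, and
    covariates/scores follow the label-conditional models.  The truth table
    flags zero risk genes by construction.  Pass ``genes`` (gene_id, mu) to
    reuse a fixed gene table across replicate draws.
    """
    if n_variants <= 0:
        raise ConfigurationError("n_variants must be positive")
    base = config if config is not None else SimulatedCohortConfig()
    null_config = replace(
        base,
        n_variants_total=n_variants,
        risk_gene_fraction=0.0,
        denovo_fraction_risk=background_denovo_fraction,
        denovo_fraction_nonrisk=background_denovo_fraction,
        rng_seed=rng_seed,
    )
    profiles = default_profiles() if profiles is None else profiles
    _check_profiles(profiles)
    if genes is None:
        genes = generate_genes(null_config)
    _, counts_rng, label_rng, cov_rng, score_rng = _child_rngs(rng_seed, 5)
    counts = _draw_gene_counts(genes, n_variants, null_config.count_dispersion,
                               counts_rng)
    gene_idx = np.repeat(np.arange(len(genes)), counts)
    labels = (label_rng.random(gene_idx.size) < background_denovo_fraction).astype(int)
    mean_dn, mean_inh, var = null_config.score_model
    scores = score_rng.normal(np.where(labels == 1, mean_dn, mean_inh),
                              math.sqrt(var))
    case = _draw_covariates(labels, profiles, cov_rng)
    case.insert(0, "gene_id", genes["gene_id"].to_numpy()[gene_idx])
    case["score"] = scores
    truth = pd.DataFrame({
        "gene_id": case["gene_id"],
        "label": labels,
        "gene_is_risk": np.zeros(gene_idx.size, dtype=bool),
    })
    return case, truth
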