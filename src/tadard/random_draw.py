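"""The Random Draw (RD) gene-level Bayes factor.

Each rare case-only variant in a gene is treated as an independent Bernoulli
draw of de novo status.  The draw probability depends on the gene's hidden
risk status D: ``p1 = P(I=1 | D=1)`` for risk genes and ``p0 = P(I=1 | D=0)``
for non-risk genes, with ``p1 > p0`` — risk genes carry a much larger
fraction of de novo variants.  De novo status itself is unobserved; what we
see is the classifier's thresholded call X, whose accuracy is summarised by
sensitivity ``w1 = P(X=1 | I=1)`` and specificity ``w2 = P(X=0 | I=0)``.
Marginalising over the true status gives the misclassification-adjusted call
rate

    P(X=1 | D) = w1 * p + (1 - w2) * (1 - p),   p in {p0, p1},

so the observed counts ``(xd, xh)`` of likely-de-novo and likely-inherited
variants are binomial under either scenario, and the evidence for D=1 is the
Bayes factor of the two binomial marginals, integrating (p0, p1) over prior
distributions P0, P1 (point masses or Beta).

Numerics: Beta-prior marginals use self-normalised Gauss–Jacobi quadrature
whose weight function *is* the Beta kernel, so the polynomial binomial
integrand is integrated exactly for xd + xh < 2 * ``_N_QUAD`` nodes, and
Beta shapes below 1 (endpoint-singular densities) cost no accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp, roots_jacobi

from .exceptions import SchemaError

logger = logging.getLogger(__name__)

_N_QUAD = 128
#: Bayes factors are clamped into this range to avoid overflow on extreme
#: counts; hitting a bound is logged.
BF_FLOOR, BF_CAP = 1e-12, 1e12


@dataclass(frozen=True)
class RDParameters:
    """Classifier accuracy (w1 sensitivity, w2 specificity) and threshold."""

    w1: float
    w2: float
    threshold_c: float | None = None

    def __post_init__(self):
        for name in ("w1", "w2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.threshold_c is not None and not 0.0 <= self.threshold_c <= 1.0:
            raise ValueError(f"threshold_c={self.threshold_c} outside [0, 1]")
        if self.is_degenerate:
            logger.warning(
                "RDParameters w1=%.4g equals 1-w2: predictions are "
                "independent of true de novo status; all Bayes factors "
                "will be 1", self.w1)

    @property
    def is_degenerate(self) -> bool:
        """True when w1 == 1 - w2, i.e. X carries no information about I."""
        return abs(self.w1 - (1.0 - self.w2)) < 1e-12


@dataclass(frozen=True)
class PriorSpec:
    """Prior on a de novo fraction: a point mass or a Beta(a, b)."""

    kind: str  # "point" | "beta"
    value: float | None = None
    a: float | None = None
    b: float | None = None

    def __post_init__(self):
        if self.kind == "point":
            if self.value is None or not 0.0 <= self.value <= 1.0:
                raise ValueError("point prior needs a value in [0, 1]")
        elif self.kind == "beta":
            if self.a is None or self.b is None or self.a <= 0 or self.b <= 0:
                raise ValueError("beta prior needs shape parameters a, b > 0")
        else:
            raise ValueError(f"unknown prior kind {self.kind!r}")

    @property
    def mean(self) -> float:
        if self.kind == "point":
            return float(self.value)
        return self.a / (self.a + self.b)

    @classmethod
    def point(cls, value: float) -> "PriorSpec":
        return cls(kind="point", value=value)

    @classmethod
    def beta(cls, a: float, b: float) -> "PriorSpec":
        return cls(kind="beta", a=a, b=b)

    @classmethod
    def beta_from_mean(cls, mean: float, concentration: float = 10.0) -> "PriorSpec":
        """Beta prior with the given mean and total concentration a + b."""
        return cls.beta(mean * concentration, (1.0 - mean) * concentration)


@dataclass(frozen=True)
class RDPriors:
    """Priors P1 (risk genes) and P0 (non-risk genes) on the de novo fraction."""

    p1: PriorSpec
    p0: PriorSpec

    def __post_init__(self):
        if self.p1.mean <= self.p0.mean:
            raise ValueError(
                f"mean of the risk-gene prior ({self.p1.mean:.4g}) must exceed "
                f"the non-risk mean ({self.p0.mean:.4g})")

    @classmethod
    def point(cls, p1: float, p0: float) -> "RDPriors":
        return cls(p1=PriorSpec.point(p1), p0=PriorSpec.point(p0))

    @classmethod
    def default(cls) -> "RDPriors":
        """Beta priors with means 0.603 / 0.026 and total concentration 10.

        The means anchor at the observed de novo fractions among case
        variants in risk and non-risk genes from large family-based data;
        the concentration encodes moderate uncertainty around them.
        """
        return cls(p1=PriorSpec.beta_from_mean(0.603),
                   p0=PriorSpec.beta_from_mean(0.026))


def misclassification_adjusted_rate(p, params: RDParameters):
    """P(X=1 | D) = w1*p + (1-w2)*(1-p) for a true de novo fraction p."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("de novo fraction outside [0, 1]")
    out = params.w1 * p + (1.0 - params.w2) * (1.0 - p)
    return float(out) if out.ndim == 0 else out


def rd_log_likelihood(xd, xh, q):
    """log Binomial(xd; xd+xh, q) — likelihood of the thresholded counts."""
    xd = np.asarray(xd, dtype=float)
    xh = np.asarray(xh, dtype=float)
    q = np.asarray(q, dtype=float)
    n = xd + xh
    with np.errstate(divide="ignore", invalid="ignore"):
        log_q = np.where(q > 0, np.log(np.where(q > 0, q, 1.0)), -np.inf)
        log_1mq = np.where(q < 1, np.log1p(-np.where(q < 1, q, 0.0)), -np.inf)
        ll = (gammaln(n + 1) - gammaln(xd + 1) - gammaln(xh + 1)
              + np.where(xd > 0, xd * log_q, 0.0)
              + np.where(xh > 0, xh * log_1mq, 0.0))
    return ll


def rd_likelihood(xd, xh, q):
    """Binomial probability of observing (xd, xh) calls at call rate q."""
    return np.exp(rd_log_likelihood(xd, xh, q))


def _beta_nodes(prior: PriorSpec):
    """Quadrature nodes/log-weights matching a Beta(a, b) density on [0, 1].

    ``roots_jacobi(n, alpha, beta)`` integrates with weight
    (1-t)^alpha (1+t)^beta on [-1, 1]; mapping t -> p = (1+t)/2 turns that
    into the Beta(a, b) kernel with alpha = b-1, beta = a-1.  Weights are
    self-normalised, so the Beta normalising constant cancels.
    """
    nodes, weights = roots_jacobi(_N_QUAD, prior.b - 1.0, prior.a - 1.0)
    p = (nodes + 1.0) / 2.0
    logw = np.log(weights) - logsumexp(np.log(weights))
    return p, logw


def _log_marginal(xd, xh, prior: PriorSpec, params: RDParameters):
    """log ∫ Binom(xd; xd+xh, q(p)) dPrior(p), vectorised over counts."""
    xd = np.atleast_1d(np.asarray(xd, dtype=float))
    xh = np.atleast_1d(np.asarray(xh, dtype=float))
    if prior.kind == "point":
        q = misclassification_adjusted_rate(prior.value, params)
        return rd_log_likelihood(xd, xh, q)
    p, logw = _beta_nodes(prior)
    q = misclassification_adjusted_rate(p, params)  # (K,)
    ll = rd_log_likelihood(xd[:, None], xh[:, None], q[None, :])  # (G, K)
    return logsumexp(ll + logw[None, :], axis=1)


def _validate_counts(xd, xh):
    xd = np.atleast_1d(np.asarray(xd))
    xh = np.atleast_1d(np.asarray(xh))
    if np.any(xd < 0) or np.any(xh < 0):
        raise ValueError("variant counts must be non-negative")
    if np.any(xd != np.floor(xd)) or np.any(xh != np.floor(xh)):
        raise ValueError("variant counts must be integers")
    return xd.astype(int), xh.astype(int)


def rd_bayes_factor(xd: int, xh: int, params: RDParameters,
                    priors: RDPriors) -> float:
    """Bayes factor for D=1 vs D=0 from thresholded counts (xd, xh)."""
    xd, xh = _validate_counts(xd, xh)
    log_num = _log_marginal(xd, xh, priors.p1, params)
    log_den = _log_marginal(xd, xh, priors.p0, params)
    return float(_clamp_bf(np.exp(log_num - log_den))[0])


def rd_bayes_factor_table(counts: pd.DataFrame, params: RDParameters,
                          priors: RDPriors) -> pd.DataFrame:
    """Vectorised per-gene Bayes factors.

    ``counts`` needs columns gene_id, xd, xh with unique gene identifiers;
    returns a copy with a ``bf_rd`` column appended.
    """
    for col in ("gene_id", "xd", "xh"):
        if col not in counts.columns:
            raise SchemaError(f"gene-count table is missing column {col!r}")
    if counts["gene_id"].duplicated().any():
        dupes = counts.loc[counts["gene_id"].duplicated(), "gene_id"].tolist()
        raise SchemaError(f"duplicate gene_id(s): {dupes[:5]}")
    out = counts.copy()
    if len(out) == 0:
        out["bf_rd"] = np.empty(0)
        return out
    xd, xh = _validate_counts(out["xd"].to_numpy(), out["xh"].to_numpy())
    log_num = _log_marginal(xd, xh, priors.p1, params)
    log_den = _log_marginal(xd, xh, priors.p0, params)
    out["bf_rd"] = _clamp_bf(np.exp(log_num - log_den))
    return out


def _clamp_bf(bf: np.ndarray) -> np.ndarray:
    bf = np.atleast_1d(np.asarray(bf, dtype=float))
    bad = ~np.isfinite(bf) | (bf < BF_FLOOR) | (bf > BF_CAP)
    if bad.any():
        logger.warning("clamping %d Bayes factor(s) into [%g, %g]",
                       int(bad.sum()), BF_FLOOR, BF_CAP)
    bf = np.where(np.isnan(bf), 1.0, bf)
    return np.clip(bf, BF_FLOOR, BF_CAP)
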