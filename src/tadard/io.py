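"""Table readers/writers, run configuration and the end-to-end pipeline.

All interchange is tab-separated text with documented headers.  Variant
tables carry gene_id plus the six covariates (AF, LOEUF, CCR, FDR_TADA_DD,
obs_lof, exp_lof), optionally a true inheritance ``label`` and a de novo
``score``.  Readers validate schema and ranges before returning, and the
rare-variant filter (allele frequency below 0.001 by default) is applied on
read with a logged count of excluded rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classdn import (estimate_performance, classify_at_threshold,
                      score_variants, train_classdn)
from .exceptions import ConfigurationError, SchemaError
from .random_draw import PriorSpec, RDParameters, RDPriors, rd_bayes_factor_table
from .synthetic_data import COVARIATES
from .tada_integration import DeNovoBFParams, FDRConfig, integrate_evidence

logger = logging.getLogger(__name__)

_RANGES = {
    "AF": (0.0, 1.0),
    "LOEUF": (0.0, np.inf),
    "CCR": (0.0, 100.0),
    "FDR_TADA_DD": (0.0, 1.0),
    "obs_lof": (0.0, np.inf),
    "exp_lof": (0.0, np.inf),
}


def read_variant_table(path, require_label: bool = False,
                       require_score: bool = False,
                       maf_max: float = 0.001) -> pd.DataFrame:
    """Read and validate a variant TSV; apply the rare-variant AF filter.

    Columns are keyed by name, so header order is irrelevant.  Rows with
    AF >= ``maf_max`` are excluded (logged); pass ``maf_max=None`` to skip
    the filter.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, sep="\t")
    if table.empty and table.columns.size == 0:
        raise SchemaError(f"{path}: file is empty")
    required = ["gene_id", *COVARIATES]
    if require_label:
        required.append("label")
    if require_score:
        required.append("score")
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    for col, (lo, hi) in _RANGES.items():
        vals = pd.to_numeric(table[col], errors="coerce")
        if vals.isna().any() and table[col].notna().any():
            bad = table.loc[vals.isna() & table[col].notna(), col]
            raise SchemaError(f"{path}: unparseable value(s) in {col}: "
                              f"{bad.head(3).tolist()}")
        table[col] = vals
        out_of_range = vals.dropna().lt(lo) | vals.dropna().gt(hi)
        if out_of_range.any():
            raise SchemaError(f"{path}: {int(out_of_range.sum())} value(s) in "
                              f"{col} outside [{lo}, {hi}]")
    if require_label and not table["label"].isin([0, 1]).all():
        raise SchemaError(f"{path}: label column must be binary 0/1")
    if maf_max is not None:
        keep = table["AF"] < maf_max
        n_filtered = int((~keep).sum())
        if n_filtered:
            logger.info("%s: excluded %d variant(s) with AF >= %g "
                        "(rare-variant filter)", path, n_filtered, maf_max)
        table = table.loc[keep].reset_index(drop=True)
    return table


def write_table(table: pd.DataFrame, path) -> None:
    """Write any result table as TSV (stable float formatting)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_gene_counts(path) -> pd.DataFrame:
    """Read a per-gene count TSV with columns gene_id, xd, xh."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in ("gene_id", "xd", "xh") if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    for col in ("xd", "xh"):
        vals = pd.to_numeric(table[col], errors="raise")
        if (vals < 0).any() or (vals != vals.astype(int)).any():
            raise SchemaError(f"{path}: {col} must be non-negative integers")
        table[col] = vals.astype(int)
    return table


def read_family_table(path) -> pd.DataFrame:
    """Read per-gene family evidence: gene_id plus bf_family or (x, mu)."""
    table = pd.read_csv(path, sep="\t")
    if "gene_id" not in table.columns:
        raise SchemaError(f"{path}: missing gene_id column")
    if "bf_family" not in table.columns and not {"x", "mu"} <= set(table.columns):
        raise SchemaError(f"{path}: needs bf_family, or x and mu columns")
    return table


def aggregate_counts(scored: pd.DataFrame, c: float) -> pd.DataFrame:
    """Per-gene likely-de-novo / likely-inherited counts at threshold c.

    xd counts scores strictly above c; xh the rest, so xd + xh equals the
    gene's variant count for any threshold.
    """
    if "score" not in scored.columns:
        raise SchemaError("scored table has no 'score' column")
    if scored["score"].isna().any():
        raise SchemaError("scored table contains missing scores")
    pred = classify_at_threshold(scored["score"].to_numpy(), c)
    table = pd.DataFrame({"gene_id": scored["gene_id"], "pred": pred})
    grouped = table.groupby("gene_id", sort=True)["pred"].agg(["sum", "count"])
    return pd.DataFrame({
        "gene_id": grouped.index,
        "xd": grouped["sum"].astype(int).to_numpy(),
        "xh": (grouped["count"] - grouped["sum"]).astype(int).to_numpy(),
    }).reset_index(drop=True)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (see ``run_pipeline``)."""

    train_path: str
    test_path: str
    case_path: str
    family_path: str
    out_dir: str
    algorithm: str = "rusboost"
    threshold_c: float = 0.7
    maf_max: float = 0.001
    pi_risk: float = 0.06
    q_cutoff: float = 0.05
    rng_seed: int = 0
    prior_p1_mean: float = 0.603
    prior_p0_mean: float = 0.026
    prior_concentration: float = 10.0  # 0 means point-mass priors
    n_trios: int | None = None
    gamma_mean: float = 20.0
    gamma_beta: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.threshold_c <= 1.0:
            raise ConfigurationError("threshold_c must lie in [0, 1]")
        if not 0.0 < self.maf_max < 0.5:
            raise ConfigurationError("maf_max must lie in (0, 0.5)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def priors(self) -> RDPriors:
        if self.prior_concentration <= 0:
            return RDPriors.point(self.prior_p1_mean, self.prior_p0_mean)
        return RDPriors(
            p1=PriorSpec.beta_from_mean(self.prior_p1_mean,
                                        self.prior_concentration),
            p0=PriorSpec.beta_from_mean(self.prior_p0_mean,
                                        self.prior_concentration))


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Train, learn performance, score cases, and select risk genes.

    Stages: train ClassDn on the labeled training table; estimate (w1, w2)
    on the labeled test table at the configured threshold; score the
    case-only table; aggregate per-gene counts; Random Draw Bayes factors;
    combine with family-based evidence; Bayesian FDR and gene selection.
    Writes ``scored_case.tsv``, ``gene_counts.tsv`` and ``results.tsv``
    into ``out_dir`` and returns the results table.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("[%s] starting", name)

    stage("train")
    train = read_variant_table(config.train_path, require_label=True,
                               maf_max=config.maf_max)
    model = train_classdn(train, algorithm=config.algorithm,
                          rng_seed=config.rng_seed)
    logger.info("[train] fitted %s on %d variants (%d dropped)",
                config.algorithm, len(train), model.n_dropped_rows)

    stage("test-performance")
    test = read_variant_table(config.test_path, require_label=True,
                              maf_max=config.maf_max)
    test_scores = score_variants(model, test)
    w1, w2 = estimate_performance(test["label"],
                                  classify_at_threshold(test_scores,
                                                        config.threshold_c))
    logger.info("[test-performance] c=%.3g -> w1=%.4f w2=%.4f",
                config.threshold_c, w1, w2)

    stage("score-case")
    case = read_variant_table(config.case_path, maf_max=config.maf_max)
    case = case.copy()
    case["score"] = score_variants(model, case)
    pct_dn = 100.0 * (case["score"] > config.threshold_c).mean()
    logger.info("[score-case] %d case variants; %.1f%% classified de novo",
                len(case), pct_dn)
    write_table(case, out_dir / "scored_case.tsv")

    stage("aggregate")
    counts = aggregate_counts(case, config.threshold_c)
    write_table(counts, out_dir / "gene_counts.tsv")

    stage("rd-bf")
    params = RDParameters(w1=w1, w2=w2, threshold_c=config.threshold_c)
    rd = rd_bayes_factor_table(counts, params, config.priors())

    stage("integrate")
    family = read_family_table(config.family_path)
    denovo_params = (DeNovoBFParams(n_trios=config.n_trios,
                                    gamma_mean=config.gamma_mean,
                                    beta=config.gamma_beta)
                     if config.n_trios else None)
    fdr = FDRConfig(pi_risk=config.pi_risk, q_cutoff=config.q_cutoff,
                    bonferroni_alpha=config.q_cutoff)
    results = integrate_evidence(family, rd, fdr, denovo_params)
    logger.info("[integrate] %d genes; %d selected at q<%.3g, %d by Bonferroni",
                len(results), int(results["selected_fdr"].sum()),
                config.q_cutoff, int(results["selected_bonferroni"].sum()))
    write_table(results, out_dir / "results.tsv")
    return results
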