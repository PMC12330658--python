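"""Gene-level cohorts for the null and power simulations.

The cohort-level simulations operate on a per-gene table (case variant
counts, risk flags, family-based Bayes factors) rather than on individual
variants.  This module builds that table from the synthetic-cohort
machinery: mutation rates are lognormal across genes, case variant counts
are negative-binomial with mean proportional to the mutation rate, and the
family dataset is a single draw of de novo counts across ``n_trios`` trios
(relative risk ``gamma_mean`` in risk genes, 1 elsewhere) held fixed across
simulation replicates — mirroring a real family cohort reused for every
simulated case dataset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic_data import SimulatedCohortConfig, generate_genes, _child_rngs, \
    _draw_gene_counts
from .tada_integration import DeNovoBFParams, denovo_bayes_factor


def build_simulation_cohort(n_genes: int = 800, n_variants: int = 2400,
                            n_trios: int = 10_000, seed: int = 0,
                            null: bool = False,
                            risk_gene_fraction: float = 0.05,
                            gamma_mean: float = 20.0,
                            denovo_params: DeNovoBFParams | None = None
                            ) -> pd.DataFrame:
    """Per-gene table for ``run_power_simulation`` / ``run_null_simulation``.

    Columns: gene_id, mu, is_risk, n_case_variants and (unless ``null``)
    bf_family from one fixed draw of trio de novo counts.  Under ``null``
    every risk flag is False and no family draw is made — the null
    simulation redraws signal-free family data per replicate.
    """
    config = SimulatedCohortConfig(
        n_genes=n_genes, n_variants_total=n_variants,
        risk_gene_fraction=0.0 if null else risk_gene_fraction,
        rng_seed=seed)
    genes = generate_genes(config)
    _, counts_rng, family_rng = _child_rngs(seed, 3)
    counts = _draw_gene_counts(genes, n_variants, config.count_dispersion,
                               counts_rng)
    genes = genes.assign(n_case_variants=counts)
    if null:
        return genes
    if denovo_params is None:
        denovo_params = DeNovoBFParams(n_trios=n_trios, gamma_mean=gamma_mean)
    gamma = np.where(genes["is_risk"], gamma_mean, 1.0)
    lam = 2.0 * n_trios * genes["mu"].to_numpy() * gamma
    x = family_rng.poisson(lam)
    genes["x_family"] = x
    genes["bf_family"] = denovo_bayes_factor(x, genes["mu"].to_numpy(),
                                             denovo_params)
    return genes
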