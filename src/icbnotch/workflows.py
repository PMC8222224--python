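"""End-to-end convenience pipelines used by the CLI, tests and demos."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classification import assign_subtype, cluster_ne_groups, quantile_high_classifier
from .cohort_stats import MultivariableResult, multivariable_benefit_model
from .io_formats import ExpressionMatrix, GeneSetCollection
from .normalization import compute_cpm, tmm_factors
from .signature_scoring import NEScoreConfig, ne_score, ssgsea_score
from .synthetic import SyntheticCohort

__all__ = ["benefit_covariates", "fit_benefit_model_on_cohort", "label_cohort"]


def benefit_covariates(
    expr_counts: ExpressionMatrix,
    gene_sets: GeneSetCollection,
    notch_set: str = "NOTCH_SIGNALING",
    immune_set: str = "IMMUNE_SIGNATURE",
    myc_gene: str = "MYC",
    ezh2_gene: str = "EZH2",
) -> pd.DataFrame:
    """TMM-normalize counts and build the five benefit-model covariates:
    Notch and immune ssGSEA scores, the NE score, and log2 CPM of MYC
    and EZH2."""
    factors = tmm_factors(expr_counts)
    cpm = compute_cpm(expr_counts, factors)
    notch = ssgsea_score(cpm, gene_sets[notch_set])
    immune = ssgsea_score(cpm, gene_sets[immune_set])
    ne = ne_score(cpm, gene_sets, NEScoreConfig())
    myc = np.log2(cpm.values.loc[myc_gene] + 1.0)
    ezh2 = np.log2(cpm.values.loc[ezh2_gene] + 1.0)
    return pd.DataFrame(
        {"Notch": notch, "Immune": immune, "NE": ne, "MYC": myc, "EZH2": ezh2}
    )


def fit_benefit_model_on_cohort(
    cohort: SyntheticCohort, family: str = "logit"
) -> MultivariableResult:
    """Simulated counts -> TMM/CPM -> signature scores -> benefit model."""
    covariates = benefit_covariates(cohort.expression, cohort.gene_sets)
    return multivariable_benefit_model(
        covariates, cohort.clinical.benefit_series(), family=family
    )


def label_cohort(
    expr_counts: ExpressionMatrix, gene_sets: GeneSetCollection, q: float = 0.75
) -> pd.DataFrame:
    """Produce the categorical labels for a cohort: Notch-high flag,
    transcriptional subtype and NE group."""
    factors = tmm_factors(expr_counts)
    cpm = compute_cpm(expr_counts, factors)
    notch = ssgsea_score(cpm, gene_sets["NOTCH_SIGNALING"])
    ne = ne_score(cpm, gene_sets, NEScoreConfig())
    return pd.DataFrame(
        {
            "notch_high": quantile_high_classifier(notch, q=q),
            "subtype": assign_subtype(cpm),
            "ne_group": cluster_ne_groups(ne),
        }
    )
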