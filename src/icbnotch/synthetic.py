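"""Seeded generators for every input the pipeline consumes.

The expression-cohort generator plants the correlation structure the
analysis assumes: a latent neuroendocrine (NE) axis per sample, a Notch
latent negatively correlated with it, an immune latent likewise
negatively correlated with NE, and a clinical-benefit label whose
log-odds are proportional to the Notch latent. Signature genes load on
their latent with a log2 fold change per latent SD; counts are negative
binomial so the TMM/CPM stages are exercised on realistically
overdispersed libraries. Lineage transcription factors (ASCL1, NEUROD1,
POU2F3, YAP1) follow a planted near-exclusive subtype per sample.

The repertoire generator draws a Zipf-shaped baseline clone
distribution, multinomial sequencing samples at a fixed depth, a
responder-specific multiplicative expansion of chosen clones in
on-treatment draws, and a tumor repertoire sharing a configured
fraction of the expanded clones.

Every generator is a pure function of its config, seed included, and
returns a truth record alongside the observables so recovery tests
never re-derive ground truth from simulated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import warnings

import numpy as np
import pandas as pd

from .io_formats import (
    ClinicalTable,
    ClonotypeTable,
    ExpressionMatrix,
    GeneSetCollection,
    ValidationError,
)

__all__ = [
    "SyntheticCohortConfig",
    "SyntheticCohort",
    "SyntheticRepertoireConfig",
    "SyntheticRepertoireSeries",
    "simulate_expression_cohort",
    "simulate_repertoire_series",
    "simulate_dsp",
    "simulate_ihc",
]

SUBTYPES = ("ASCL1", "NEUROD1", "POU2F3", "YAP1")


@dataclass
class SyntheticCohortConfig:
    """Study conditions for the simulated expression cohort.

    ``ne_notch_corr`` and ``ne_immune_corr`` are the target latent
    correlations of the Notch and immune axes with the NE axis (both
    negative, mirroring the inverse relationship between neuroendocrine
    differentiation and Notch/immune activity). ``benefit_logit_beta``
    is the log-odds of clinical benefit per SD of the Notch latent.
    ``loading`` is the log2 fold change of a signature gene per latent
    SD; ``count_dispersion`` is the negative-binomial dispersion phi in
    var = mu + phi*mu^2. ``subtype_separation`` is the planted
    transcription-factor shift in units of the within-gene log2 noise
    SD; the default 4 reflects the near-exclusive expression of the
    four lineage factors in real tumors.
    """

    n_samples: int = 60
    n_genes: int = 1000
    genes_per_signature: int = 12
    ne_notch_corr: float = -0.6
    ne_immune_corr: float = -0.6
    benefit_logit_beta: float = 1.5
    count_dispersion: float = 0.3
    loading: float = 1.0
    subtype_separation: float = 4.0
    baseline_mean: float = 50.0
    cohort: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.ne_notch_corr <= 0.0:
            raise ValidationError("ne_notch_corr must lie in [-1, 0]")
        if not -1.0 <= self.ne_immune_corr <= 0.0:
            raise ValidationError("ne_immune_corr must lie in [-1, 0]")
        if self.count_dispersion < 0:
            raise ValidationError("count_dispersion must be non-negative")
        needed = 4 * self.genes_per_signature + len(SUBTYPES) + 2
        if needed > self.n_genes:
            raise ValidationError(
                f"{self.n_genes} genes cannot host {needed} signature/marker genes"
            )


@dataclass
class SyntheticCohort:
    """Simulated observables plus the generating truth."""

    expression: ExpressionMatrix  # raw counts
    clinical: ClinicalTable
    gene_sets: GeneSetCollection
    truth: pd.DataFrame  # per-sample latents, subtype, benefit
    config: SyntheticCohortConfig


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _log2_noise_sd(mean: float, dispersion: float) -> float:
    # SD of log2(count) under the lognormal approximation to NB
    cv2 = 1.0 / mean + dispersion
    return float(np.sqrt(np.log1p(cv2)) / np.log(2.0))


def simulate_expression_cohort(cfg: SyntheticCohortConfig) -> SyntheticCohort:
    """Simulate a count matrix, clinical table and truth record."""
    rng = np.random.default_rng(cfg.seed)
    n, g = cfg.n_samples, cfg.n_genes

    # latents
    u_ne = rng.standard_normal(n)
    rho_t = cfg.ne_notch_corr
    u_notch = rho_t * u_ne + np.sqrt(1.0 - rho_t**2) * rng.standard_normal(n)
    rho_i = cfg.ne_immune_corr
    u_immune = rho_i * u_ne + np.sqrt(1.0 - rho_i**2) * rng.standard_normal(n)
    u_myc = rng.standard_normal(n)
    u_ezh2 = rng.standard_normal(n)

    # gene layout: four signatures, four subtype TFs, MYC, EZH2, background
    k = cfg.genes_per_signature
    sets = {
        "NE_HIGH": [f"NEHI_{i:03d}" for i in range(k)],
        "NE_LOW": [f"NELO_{i:03d}" for i in range(k)],
        "NOTCH_SIGNALING": [f"NOTCH_{i:03d}" for i in range(k)],
        "IMMUNE_SIGNATURE": [f"IMM_{i:03d}" for i in range(k)],
    }
    marker_genes = list(SUBTYPES) + ["MYC", "EZH2"]
    named = [gid for genes in sets.values() for gid in genes] + marker_genes
    background = [f"GENE_{i:04d}" for i in range(g - len(named))]
    gene_ids = named + background

    baselines = np.exp(rng.normal(np.log(cfg.baseline_mean), 0.8, size=g))
    loadings = np.zeros((g, n))
    idx = {gid: i for i, gid in enumerate(gene_ids)}
    for gid in sets["NE_HIGH"]:
        loadings[idx[gid]] = cfg.loading * u_ne
    for gid in sets["NE_LOW"]:
        loadings[idx[gid]] = -cfg.loading * u_ne
    for gid in sets["NOTCH_SIGNALING"]:
        loadings[idx[gid]] = cfg.loading * u_notch
    for gid in sets["IMMUNE_SIGNATURE"]:
        loadings[idx[gid]] = cfg.loading * u_immune
    loadings[idx["MYC"]] = cfg.loading * u_myc
    loadings[idx["EZH2"]] = cfg.loading * u_ezh2

    subtype = rng.choice(SUBTYPES, size=n)
    sigma = _log2_noise_sd(cfg.baseline_mean, cfg.count_dispersion)
    for tf in SUBTYPES:
        loadings[idx[tf]] += np.where(subtype == tf, cfg.subtype_separation * sigma, 0.0)

    mean = baselines[:, None] * np.exp2(loadings)
    counts = _nb_draw(rng, mean, cfg.count_dispersion)

    logits = cfg.benefit_logit_beta * u_notch
    benefit = np.where(rng.random(n) < 1.0 / (1.0 + np.exp(-logits)), "CB", "NCB")

    sample_ids = [f"S{i:03d}" for i in range(n)]
    expr = ExpressionMatrix(
        values=pd.DataFrame(counts.astype(float), index=gene_ids, columns=sample_ids),
        unit="counts",
        dataset_id=cfg.cohort,
    )
    clinical = ClinicalTable(
        table=pd.DataFrame(
            {
                "sample_id": sample_ids,
                "patient_id": [f"P{i:03d}" for i in range(n)],
                "cohort": cfg.cohort,
                "benefit": benefit,
                "response": np.where(benefit == "CB", "PR", "PD"),
            }
        )
    )
    truth = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "ne_latent": u_ne,
            "notch_latent": u_notch,
            "immune_latent": u_immune,
            "myc_latent": u_myc,
            "ezh2_latent": u_ezh2,
            "subtype": subtype,
            "benefit": benefit,
            "seed": cfg.seed,
        }
    )
    return SyntheticCohort(
        expression=expr,
        clinical=clinical,
        gene_sets=GeneSetCollection(sets=sets, provenance=f"simulated (seed {cfg.seed})"),
        truth=truth,
        config=cfg,
    )


@dataclass
class SyntheticRepertoireConfig:
    """Study conditions for the longitudinal repertoire series.

    Baseline clone frequencies follow a Zipf law over ``n_clones``
    ranks; each draw is multinomial at ``depth`` templates. Responders
    have ``n_expanded`` randomly chosen clones multiplied by
    ``expansion_factor`` (then renormalized) in every on-treatment
    sample; the tumor repertoire contains ``tumor_overlap_fraction`` of
    the expanded clones plus unrelated background clones.
    """

    n_clones: int = 2000
    zipf_exponent: float = 1.0
    depth: int = 100_000
    n_on_samples: int = 3
    responder: bool = True
    n_expanded: int = 50
    expansion_factor: float = 10.0
    tumor_overlap_fraction: float = 0.11
    n_tumor_background: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_expanded > self.n_clones:
            raise ValidationError("n_expanded cannot exceed n_clones")
        if not 0.0 <= self.tumor_overlap_fraction <= 1.0:
            raise ValidationError("tumor_overlap_fraction must lie in [0, 1]")
        if self.depth < self.n_clones / 100:
            warnings.warn(
                f"depth {self.depth} is sparse for {self.n_clones} clones; "
                "richness will be heavily undersampled",
                stacklevel=2,
            )


@dataclass
class SyntheticRepertoireSeries:
    pre: ClonotypeTable
    on: list[ClonotypeTable]
    tumor: ClonotypeTable
    truth: dict
    config: SyntheticRepertoireConfig


def simulate_repertoire_series(cfg: SyntheticRepertoireConfig) -> SyntheticRepertoireSeries:
    rng = np.random.default_rng(cfg.seed)
    keys = np.array([f"TCRB{i:05d}" for i in range(cfg.n_clones)])
    base = np.arange(1, cfg.n_clones + 1, dtype=float) ** (-cfg.zipf_exponent)
    base /= base.sum()
    # shuffle so clone identity is independent of abundance rank
    perm = rng.permutation(cfg.n_clones)
    base = base[perm]

    expanded_keys: np.ndarray = np.array([], dtype=keys.dtype)
    on_freq = base.copy()
    if cfg.responder and cfg.n_expanded > 0:
        chosen = rng.choice(cfg.n_clones, size=cfg.n_expanded, replace=False)
        expanded_keys = keys[chosen]
        on_freq = base.copy()
        on_freq[chosen] *= cfg.expansion_factor
        on_freq /= on_freq.sum()

    def draw(freq: np.ndarray, sample_id: str, timepoint: str, compartment: str) -> ClonotypeTable:
        counts = rng.multinomial(cfg.depth, freq)
        keep = counts > 0
        return ClonotypeTable(
            sample_id=sample_id,
            counts=pd.Series(counts[keep], index=keys[keep]).sort_index(),
            timepoint=timepoint,
            compartment=compartment,
        )

    pre = draw(base, "blood_pre", "pre", "blood")
    on = [
        draw(on_freq, f"blood_on{j + 1}", f"on-cycle-{j + 1}", "blood")
        for j in range(cfg.n_on_samples)
    ]

    # tumor: configured fraction of expanded clones + unrelated background
    n_shared = int(round(cfg.tumor_overlap_fraction * len(expanded_keys)))
    shared = rng.choice(expanded_keys, size=n_shared, replace=False) if n_shared else np.array([])
    non_expanded = np.setdiff1d(keys, expanded_keys)
    bg = rng.choice(non_expanded, size=min(cfg.n_tumor_background, len(non_expanded)), replace=False)
    tumor_keys = np.concatenate([shared, bg])
    tumor_freq_full = np.zeros(cfg.n_clones)
    key_pos = {k: i for i, k in enumerate(keys)}
    for k in tumor_keys:
        tumor_freq_full[key_pos[k]] = rng.gamma(2.0, 1.0)
    tumor_freq_full /= tumor_freq_full.sum()
    tumor = draw(tumor_freq_full, "tumor_pre", "pre", "tumor")

    truth = {
        "expanded_clones": frozenset(expanded_keys.tolist()),
        "tumor_shared_clones": frozenset(np.asarray(shared).tolist()),
        "seed": cfg.seed,
    }
    return SyntheticRepertoireSeries(pre=pre, on=on, tumor=tumor, truth=truth, config=cfg)


def simulate_dsp(
    n_patients: int = 6,
    n_rois: int = 4,
    proteins: tuple[str, ...] = ("CD3", "CD45", "PD-L1", "B2M"),
    seed: int = 0,
) -> pd.DataFrame:
    """Log-normal ROI protein values with patient random effects; each
    patient also gets one negative-control ROI and one non-tumor ROI."""
    if n_patients <= 0 or n_rois <= 0 or not proteins:
        raise ValidationError("n_patients, n_rois and proteins must be positive/non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_patients):
        pid = f"PT{p:02d}"
        for prot in proteins:
            patient_eff = rng.normal(0.0, 0.5)
            for r in range(n_rois):
                rows.append(
                    {
                        "patient_id": pid,
                        "roi_id": f"ROI{r:02d}",
                        "protein": prot,
                        "value": float(np.exp(np.log(100.0) + patient_eff + rng.normal(0, 0.3))),
                        "tumor_annotated": True,
                        "is_negative_control": False,
                    }
                )
            rows.append(
                {
                    "patient_id": pid,
                    "roi_id": "ROI_NEG",
                    "protein": prot,
                    "value": float(np.exp(rng.normal(0, 0.3))),
                    "tumor_annotated": True,
                    "is_negative_control": True,
                }
            )
            rows.append(
                {
                    "patient_id": pid,
                    "roi_id": "ROI_STROMA",
                    "protein": prot,
                    "value": float(np.exp(np.log(50.0) + rng.normal(0, 0.3))),
                    "tumor_annotated": False,
                    "is_negative_control": False,
                }
            )
    return pd.DataFrame(rows)


def simulate_ihc(n_samples: int = 20, marker: str = "cleaved_NOTCH1", seed: int = 0) -> list:
    """IHC records with Dirichlet intensity-bin percentages scaled to
    sum below 100; % positive cells = sum of the stained bins."""
    from .dsp_ihc import IHCRecord

    if n_samples <= 0:
        raise ValidationError("n_samples must be positive")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_samples):
        # first component = unstained cells
        parts = rng.dirichlet((6.0, 2.0, 1.5, 1.0)) * 100.0
        records.append(
            IHCRecord(
                sample_id=f"S{i:03d}",
                marker=marker,
                pct_1plus=float(parts[1]),
                pct_2plus=float(parts[2]),
                pct_3plus=float(parts[3]),
                pct_positive_cells=float(parts[1] + parts[2] + parts[3]),
            )
        )
    return records
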