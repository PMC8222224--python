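"""Count normalization and cross-cohort harmonization.

Counts are corrected for library composition with trimmed-mean-of-M-values
(TMM) factors, scaled to counts-per-million (CPM) or, when gene lengths
are available, reads-per-kilobase-per-million (RPKM). Cohorts quantified
on different platforms are harmonized by per-gene z-scoring of
log2-transformed values within each dataset before concatenation, which
removes per-dataset location and scale so rank-based downstream scores
are comparable across cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import ExpressionMatrix, ValidationError

__all__ = [
    "NormalizationFactors",
    "tmm_factors",
    "compute_cpm",
    "compute_rpkm",
    "log2_cpm",
    "zscore_genes",
    "combine_datasets_zscore",
]


@dataclass
class NormalizationFactors:
    """Per-sample library sizes and TMM scaling factors.

    Factors multiply the library size to give the effective library
    size; they are rescaled so their geometric mean is exactly 1.
    """

    sample_ids: list[str]
    library_sizes: np.ndarray
    tmm_factors: np.ndarray

    def __post_init__(self) -> None:
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        self.tmm_factors = np.asarray(self.tmm_factors, dtype=float)
        if len(self.sample_ids) != len(self.library_sizes) or len(self.sample_ids) != len(
            self.tmm_factors
        ):
            raise ValidationError("factor vectors must align with sample_ids")
        if (self.library_sizes <= 0).any():
            raise ValidationError("library sizes must be positive")
        if (self.tmm_factors <= 0).any():
            raise ValidationError("TMM factors must be positive")
        gm = float(np.exp(np.mean(np.log(self.tmm_factors))))
        if abs(gm - 1.0) > 1e-9:
            raise ValidationError(f"TMM factors must have geometric mean 1 (got {gm})")

    @property
    def effective_library_sizes(self) -> np.ndarray:
        return self.library_sizes * self.tmm_factors


def _quantile_factor(counts: np.ndarray, lib_sizes: np.ndarray, p: float = 0.75) -> np.ndarray:
    # per-sample p-quantile of counts, scaled by library size
    return np.quantile(counts, p, axis=0) / lib_sizes


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
    weighted: bool = True,
) -> float:
    """TMM factor of one sample against the reference sample.

    M (log ratio) and A (mean log abundance) are computed on genes with
    positive counts in both samples; genes are doubly trimmed — the most
    extreme ``trim_m`` fraction by M on each side and ``trim_a`` by A —
    and the factor is 2 to the inverse-asymptotic-variance weighted mean
    of the surviving M values.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / lib_obs) / (ref / lib_ref))
        abs_e = (np.log2(obs / lib_obs) + np.log2(ref / lib_ref)) / 2.0
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    finite = np.isfinite(log_r) & np.isfinite(abs_e)
    log_r, abs_e, v = log_r[finite], abs_e[finite], v[finite]
    if log_r.size == 0:
        return np.nan
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * trim_m) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * trim_a) + 1
    hi_s = n + 1 - lo_s
    rank_m = rankdata(log_r)
    rank_a = rankdata(abs_e)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep.any():
        return 1.0
    if weighted:
        f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    else:
        f = np.mean(log_r[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0**f)


def tmm_factors(
    m: ExpressionMatrix, trim_m: float = 0.30, trim_a: float = 0.05, weighted: bool = True
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values composition factors for a count matrix.

    The reference sample is the one whose library-size-scaled upper
    quartile is closest to the mean upper quartile across samples. The
    resulting factors are rescaled to geometric mean 1, so CPM values of
    a composition-unbiased dataset are unchanged.
    """
    if m.unit != "counts":
        raise ValidationError(f"TMM needs raw counts, got unit {m.unit!r}")
    if m.n_samples < 2:
        raise ValidationError("TMM needs at least 2 samples")
    X = m.values.to_numpy(dtype=float)
    lib = X.sum(axis=0)
    if (lib <= 0).any():
        bad = m.sample_ids[int(np.argmax(lib <= 0))]
        raise ValidationError(f"sample {bad!r} has an empty library")
    f75 = _quantile_factor(X, lib)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.ones(m.n_samples)
    for s in range(m.n_samples):
        if s == ref:
            factors[s] = 1.0
            continue
        f = _tmm_pair(X[:, s], X[:, ref], lib[s], lib[ref], trim_m, trim_a, weighted)
        if not np.isfinite(f):
            raise ValidationError(
                f"sample {m.sample_ids[s]!r} shares no expressed genes with the "
                f"reference sample {m.sample_ids[ref]!r}"
            )
        factors[s] = f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(
        sample_ids=m.sample_ids, library_sizes=lib, tmm_factors=factors
    )


def compute_cpm(
    m: ExpressionMatrix, factors: NormalizationFactors | None = None, log2: bool = False
) -> ExpressionMatrix:
    """Counts per million over the (optionally TMM-adjusted) library size.

    With ``log2`` the values are log2(CPM + 1) and the unit is logCPM.
    """
    if m.unit != "counts":
        raise ValidationError(f"CPM needs raw counts, got unit {m.unit!r}")
    X = m.values.to_numpy(dtype=float)
    if factors is None:
        lib = X.sum(axis=0)
        if (lib <= 0).any():
            bad = m.sample_ids[int(np.argmax(lib <= 0))]
            raise ValidationError(f"sample {bad!r} has zero library size")
        eff = lib
    else:
        if factors.sample_ids != m.sample_ids:
            raise ValidationError("normalization factors do not match matrix samples")
        eff = factors.effective_library_sizes
    cpm = X / eff * 1e6
    unit = "CPM"
    if log2:
        cpm = np.log2(cpm + 1.0)
        unit = "logCPM"
    return ExpressionMatrix(
        values=pd.DataFrame(cpm, index=m.values.index, columns=m.values.columns),
        unit=unit,
        dataset_id=m.dataset_id,
        sample_datasets=m.sample_datasets,
    )


def compute_rpkm(
    m: ExpressionMatrix,
    gene_lengths: pd.Series,
    factors: NormalizationFactors | None = None,
) -> ExpressionMatrix:
    """Reads per kilobase per million; needs a per-gene length in bp."""
    lengths = gene_lengths.reindex(m.values.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][0]
        raise ValidationError(f"no gene length for {missing!r}")
    if (lengths <= 0).any():
        raise ValidationError("gene lengths must be positive")
    cpm = compute_cpm(m, factors)
    rpkm = cpm.values.div(lengths / 1e3, axis=0)
    return ExpressionMatrix(
        values=rpkm, unit="RPKM", dataset_id=m.dataset_id, sample_datasets=m.sample_datasets
    )


def log2_cpm(m: ExpressionMatrix, factors: NormalizationFactors | None = None) -> ExpressionMatrix:
    return compute_cpm(m, factors, log2=True)


def zscore_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-scores across samples (sample SD, n-1 denominator).

    Genes with zero variance map to all-zero rows with a warning rather
    than NaNs, so constant housekeeping rows do not poison heatmaps or
    downstream classifiers.
    """
    if m.n_samples < 2:
        raise ValidationError("z-scoring needs at least 2 samples")
    X = m.values.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant gene row(s) mapped to zeros in z-scoring",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (X - mu) / sd
    Z[flat, :] = 0.0
    return ExpressionMatrix(
        values=pd.DataFrame(Z, index=m.values.index, columns=m.values.columns),
        unit="zscore",
        dataset_id=m.dataset_id,
        sample_datasets=m.sample_datasets,
    )


def combine_datasets_zscore(ms: Sequence[ExpressionMatrix]) -> ExpressionMatrix:
    """Combine cohorts by per-dataset, per-gene z-scores of log2 values.

    Each dataset is log2(x+1)-transformed and z-scored gene-wise within
    itself; the results are column-concatenated over the intersection of
    gene ids. The output records the source dataset of every sample in
    ``sample_datasets``.
    """
    if not ms:
        raise ValidationError("no datasets to combine")
    units = {m.unit for m in ms}
    if len(units) > 1:
        raise ValidationError(f"datasets must share a unit, got {sorted(units)}")
    common = ms[0].values.index
    for m in ms[1:]:
        common = common.intersection(m.values.index)
    if len(common) == 0:
        raise ValidationError("empty gene intersection between datasets")
    blocks: list[pd.DataFrame] = []
    origins: list[pd.Series] = []
    seen_samples: set[str] = set()
    for k, m in enumerate(ms):
        sub = m.values.loc[common]
        logged = ExpressionMatrix(
            values=np.log2(sub + 1.0) if m.unit != "zscore" else sub,
            unit="logCPM" if m.unit != "zscore" else "zscore",
            dataset_id=m.dataset_id,
        )
        z = zscore_genes(logged)
        cols = list(z.values.columns)
        # disambiguate colliding sample ids across cohorts
        renames = {c: f"{m.dataset_id}:{c}" for c in cols if c in seen_samples}
        block = z.values.rename(columns=renames)
        seen_samples.update(block.columns)
        blocks.append(block)
        origins.append(pd.Series(m.dataset_id or f"dataset{k}", index=block.columns))
    combined = pd.concat(blocks, axis=1)
    return ExpressionMatrix(
        values=combined,
        unit="zscore",
        dataset_id="combined",
        sample_datasets=pd.concat(origins),
    )
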