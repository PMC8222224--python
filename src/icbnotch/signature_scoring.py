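"""Single-sample gene-set enrichment (ssGSEA) and composite scores.

The enrichment score of a gene set in one sample is the sum over the
ranked gene list of the difference between two empirical distribution
functions: the in-set ECDF weighted by rank^alpha, and the uniform
out-of-set ECDF. A set concentrated at the top of the expression
ranking scores positive, one at the bottom negative; because only ranks
enter, the score is invariant to any strictly monotone transform of a
sample's values.

The neuroendocrine (NE) score contrasts two opposing signatures: genes
high in classic NE small cell lung cancer minus genes high in the
low-NE / non-neuroendocrine state, so higher means more neuroendocrine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, GeneSetCollection, ValidationError

__all__ = [
    "SignatureScoreTable",
    "NEScoreConfig",
    "ssgsea_score",
    "score_collection",
    "ne_score",
    "load_bundled_signatures",
    "BUNDLED_SIGNATURES",
]

#: names of the signatures shipped with the package (small synthetic
#: test-scale lists of real SCLC marker genes; user GMTs override them)
BUNDLED_SIGNATURES = (
    "NE_HIGH",
    "NE_LOW",
    "NOTCH_SIGNALING",
    "IMMUNE_SIGNATURE",
    "ANTIGEN_PRESENTATION",
)


@dataclass
class SignatureScoreTable:
    """Sample x signature real-valued score matrix."""

    scores: pd.DataFrame  # samples x signatures
    alpha: float = 0.25
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValidationError(f"alpha must be positive, got {self.alpha}")
        if self.scores.size and not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise ValidationError("signature scores must be finite")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def signature_names(self) -> list[str]:
        return list(self.scores.columns)


@dataclass
class NEScoreConfig:
    ne_set_name: str = "NE_HIGH"
    low_ne_set_name: str = "NE_LOW"
    rescale: bool = False


def _order_by_expression(values: np.ndarray, lex_rank: np.ndarray) -> np.ndarray:
    """Positions of genes sorted by expression descending, ties broken
    by gene-id lexicographic order (ascending)."""
    return np.lexsort((lex_rank, -values))


def ssgsea_score(
    m: ExpressionMatrix,
    gene_set: Sequence[str],
    alpha: float = 0.25,
    min_genes: int = 3,
) -> pd.Series:
    """Per-sample ssGSEA enrichment of one gene set.

    Per sample, genes are ordered by expression descending (ties broken
    lexicographically by gene id) and given rank values N..1 down the
    ordering. With w_g = rank_g^alpha for in-set genes, the running
    in-set weight P_in(i) = sum of w over in-set genes at positions <= i
    divided by the total in-set weight, the out-of-set ECDF
    P_out(i) = (# out-of-set genes at positions <= i) / (N - |G|), and
    the score is sum_i (P_in(i) - P_out(i)).

    Set genes missing from the matrix are dropped with a warning; fewer
    than ``min_genes`` surviving genes is an error, as is a set covering
    the whole matrix (the out-of-set ECDF would be undefined).
    """
    if alpha <= 0:
        raise ValidationError(f"alpha must be positive, got {alpha}")
    genes = list(dict.fromkeys(gene_set))
    present = [g for g in genes if g in m.values.index]
    if not present:
        raise ValidationError("gene set shares no genes with the expression matrix")
    if len(present) < len(genes):
        warnings.warn(
            f"{len(genes) - len(present)} gene-set gene(s) absent from the matrix; dropped",
            stacklevel=2,
        )
    if len(present) < min_genes:
        raise ValidationError(
            f"only {len(present)} gene-set gene(s) overlap the matrix "
            f"(minimum {min_genes})"
        )
    N = m.n_genes
    if len(present) == N:
        raise ValidationError("gene set covers the entire matrix; no out-of-set genes")

    gene_index = pd.Index(m.values.index)
    lex_rank = np.argsort(np.argsort(gene_index.to_numpy().astype(str)))
    in_set = np.zeros(N, dtype=bool)
    in_set[gene_index.get_indexer(present)] = True
    X = m.values.to_numpy(dtype=float)
    rank_values = np.arange(N, 0, -1, dtype=float)  # N..1 down the ordering
    n_out = N - int(in_set.sum())

    out = np.empty(m.n_samples)
    for s in range(m.n_samples):
        order = _order_by_expression(X[:, s], lex_rank)
        in_ordered = in_set[order]
        w = np.where(in_ordered, rank_values**alpha, 0.0)
        p_in = np.cumsum(w) / w.sum()
        p_out = np.cumsum(~in_ordered) / n_out
        out[s] = float(np.sum(p_in - p_out))
    return pd.Series(out, index=m.values.columns, name="ssgsea")


def score_collection(
    m: ExpressionMatrix,
    c: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = False,
    min_genes: int = 3,
) -> SignatureScoreTable:
    """Score every set in a collection; optionally range-normalize.

    With ``normalize``, every score is divided by the global
    (max - min) across the whole table, the same rescaling the
    GenePattern tool applies.
    """
    if not c.sets:
        raise ValidationError("empty gene-set collection")
    cols = {
        name: ssgsea_score(m, genes, alpha=alpha, min_genes=min_genes)
        for name, genes in c.sets.items()
    }
    scores = pd.DataFrame(cols, index=m.values.columns)
    if normalize:
        rng = float(scores.to_numpy().max() - scores.to_numpy().min())
        if rng > 0:
            scores = scores / rng
    return SignatureScoreTable(scores=scores, alpha=alpha, normalized=normalize)


def ne_score(
    m: ExpressionMatrix,
    gene_sets: GeneSetCollection,
    cfg: NEScoreConfig | None = None,
    alpha: float = 0.25,
    min_genes: int = 3,
) -> pd.Series:
    """Neuroendocrine differentiation score: ssGSEA(NE) - ssGSEA(low-NE)."""
    cfg = cfg or NEScoreConfig()
    for name in (cfg.ne_set_name, cfg.low_ne_set_name):
        if name not in gene_sets:
            raise ValidationError(f"gene-set collection lacks {name!r}")
    ne_genes = gene_sets[cfg.ne_set_name]
    low_genes = gene_sets[cfg.low_ne_set_name]
    overlap = set(ne_genes) & set(low_genes)
    if overlap:
        raise ValidationError(
            f"NE and low-NE sets overlap ({sorted(overlap)}); remove shared genes first"
        )
    hi = ssgsea_score(m, ne_genes, alpha=alpha, min_genes=min_genes)
    lo = ssgsea_score(m, low_genes, alpha=alpha, min_genes=min_genes)
    score = hi - lo
    if cfg.rescale:
        rng = float(score.max() - score.min())
        if rng > 0:
            score = score / rng
    return score.rename("ne_score")


def load_bundled_signatures() -> GeneSetCollection:
    """Small bundled NE / low-NE / Notch / immune / antigen-presentation
    gene lists for tests and demos; supply your own GMT for real data."""
    from . import io_formats

    ref = resources.files("icbnotch").joinpath("data/sclc_signatures.gmt")
    with resources.as_file(ref) as path:
        return io_formats.read_gmt(path)
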