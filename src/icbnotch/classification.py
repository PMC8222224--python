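"""Categorical sample labels derived from scores and expression.

Three labelings are produced: Notch-high status (signature score above
the within-dataset 75th percentile), transcriptional subtype (arg-max of
the four lineage transcription factors ASCL1 / NEUROD1 / POU2F3 / YAP1
on within-dataset z-scores), and the NE vs low-NE dichotomy (two-group
cut of a complete-linkage Euclidean dendrogram over NE scores).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.cluster.vq import kmeans2

from .io_formats import ExpressionMatrix, ValidationError
from .normalization import zscore_genes

__all__ = [
    "SUBTYPE_TFS",
    "quantile_high_classifier",
    "assign_subtype",
    "cluster_ne_groups",
]

#: lineage transcription factors defining SCLC subtypes, in tie-break
#: priority order
SUBTYPE_TFS = ("ASCL1", "NEUROD1", "POU2F3", "YAP1")


def quantile_high_classifier(
    scores: pd.Series,
    q: float = 0.75,
    group_by: pd.Series | None = None,
    min_group_size: int = 4,
) -> pd.Series:
    """Flag samples strictly above the within-dataset q-quantile.

    The quantile is the linear-interpolation order statistic; "high"
    means strictly greater, so when all scores of a dataset are equal no
    sample is flagged. ``group_by`` maps sample -> dataset; without it
    all samples form one dataset.
    """
    if not 0.0 < q < 1.0:
        raise ValidationError(f"quantile must be in (0, 1), got {q}")
    if group_by is None:
        group_by = pd.Series("all", index=scores.index)
    group_by = group_by.reindex(scores.index)
    if group_by.isna().any():
        missing = scores.index[group_by.isna()][0]
        raise ValidationError(f"sample {missing!r} has no dataset label")
    flags = pd.Series(False, index=scores.index)
    for _, idx in scores.groupby(group_by.to_numpy()).groups.items():
        vals = scores.loc[idx]
        if len(vals) < min_group_size:
            raise ValidationError(
                f"dataset with {len(vals)} sample(s); need >= {min_group_size} "
                "for a quantile threshold"
            )
        threshold = float(np.quantile(vals.to_numpy(dtype=float), q))
        flags.loc[idx] = vals > threshold
    return flags.rename("high")


def assign_subtype(
    m: ExpressionMatrix,
    tf_genes: tuple[str, ...] = SUBTYPE_TFS,
    group_by: pd.Series | None = None,
) -> pd.Series:
    """Transcriptional subtype = arg-max within-dataset TF z-score.

    Exact ties go to the earlier transcription factor in ``tf_genes``
    order (ASCL1 > NEUROD1 > POU2F3 > YAP1).
    """
    for g in tf_genes:
        if g not in m.values.index:
            raise ValidationError(f"subtype transcription factor {g!r} absent from matrix")
    if group_by is None:
        group_by = m.sample_datasets
    if group_by is None:
        group_by = pd.Series("all", index=m.values.columns)
    group_by = group_by.reindex(m.values.columns)
    sub = m.values.loc[list(tf_genes)]
    calls = pd.Series(index=m.values.columns, dtype=object)
    for _, cols in sub.T.groupby(group_by.to_numpy()).groups.items():
        block = ExpressionMatrix(values=sub[cols], unit=m.unit if m.unit != "counts" else "CPM")
        z = zscore_genes(block).values if len(cols) >= 2 else sub[cols] * 0.0
        # first index wins on ties -> tf_genes priority order
        calls.loc[cols] = [tf_genes[int(np.argmax(z[c].to_numpy()))] for c in cols]
    return calls.rename("subtype")


def cluster_ne_groups(ne_scores: pd.Series, method: str = "hclust", seed: int = 0) -> pd.Series:
    """Split samples into NE and lowNE by clustering their NE scores.

    Default is a complete-linkage Euclidean dendrogram cut at two
    clusters; ``method='kmeans'`` uses seeded 1-D k-means instead. The
    cluster with the lower mean score is labeled lowNE.
    """
    if len(ne_scores) < 4:
        raise ValidationError("NE grouping needs at least 4 samples")
    x = ne_scores.to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValidationError("all NE scores identical; no two-group structure")
    if method == "hclust":
        # sort first so assignments cannot depend on input sample order
        order = np.argsort(x, kind="stable")
        Z = linkage(x[order, None], method="complete", metric="euclidean")
        labels_sorted = fcluster(Z, t=2, criterion="maxclust")
        labels = np.empty(len(x), dtype=int)
        labels[order] = labels_sorted
    elif method == "kmeans":
        rng = np.random.default_rng(seed)
        _, labels = kmeans2(x[:, None], 2, minit="++", seed=rng)
        labels = labels + 1
    else:
        raise ValidationError(f"unknown clustering method {method!r}")
    means = {lab: x[labels == lab].mean() for lab in np.unique(labels)}
    low = min(means, key=means.get)
    out = np.where(labels == low, "lowNE", "NE")
    return pd.Series(out, index=ne_scores.index, name="ne_group")
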