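"""Longitudinal T-cell repertoire analysis.

Diversity of a clonotype frequency distribution is summarized by
richness (distinct clonotypes observed), Shannon entropy (natural log)
and clonality = 1 - H / ln(richness), which is 0 for a perfectly even
repertoire and 1 for a monoclonal one. Repertoire turnover between two
samples is the Jensen-Shannon divergence over the union of clonotype
keys, in bits, so it lies in [0, 1] with 1 for fully disjoint
repertoires.

Clone expansion between a pre-treatment and an on-treatment blood draw
uses a frequency fold-change rule with a read floor: a clone is called
expanded when its on-treatment count reaches the floor and its
frequency grew more than fold_change-fold (clones absent pre-treatment
count as infinitely expanded). Clones expanded in a large enough
fraction of on-treatment draws are "persistently expanded", and their
presence in a tumor repertoire quantifies blood-tumor overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ClonotypeTable, ValidationError

__all__ = [
    "RepertoireMetrics",
    "ExpansionCallSet",
    "repertoire_metrics",
    "jsd_divergence",
    "detect_expanded_clones",
    "persistent_expanded_clones",
    "repertoire_overlap",
    "rarefy",
]


@dataclass
class RepertoireMetrics:
    sample_id: str
    richness: int
    shannon_entropy: float  # natural log
    clonality: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.clonality <= 1.0 + 1e-12:
            raise ValidationError(f"clonality out of [0,1]: {self.clonality}")


@dataclass
class ExpansionCallSet:
    """Expanded-clone calls for one (pre, on) sample pair, with the
    thresholds that produced them."""

    pre_sample_id: str
    on_sample_id: str
    expanded: frozenset[str]
    fold_change: float = 3.0
    min_reads: int = 10
    min_reads_mode: str = "on"
    fold_change_on: str = "frequency"


def repertoire_metrics(t: ClonotypeTable) -> RepertoireMetrics:
    """Richness, Shannon entropy (nats) and clonality of one sample.

    A single-clone repertoire has clonality 1 by the continuity limit
    (it is maximally clonal even though ln(richness) vanishes).
    """
    counts = t.counts[t.counts > 0]
    if counts.empty:
        raise ValidationError(f"sample {t.sample_id!r} has an empty repertoire")
    f = counts.to_numpy(dtype=float)
    f = f / f.sum()
    entropy = float(-(f * np.log(f)).sum())
    richness = int(len(f))
    clonality = 1.0 if richness == 1 else 1.0 - entropy / np.log(richness)
    # clamp tiny negative float error on perfectly even repertoires
    clonality = min(max(clonality, 0.0), 1.0)
    return RepertoireMetrics(
        sample_id=t.sample_id,
        richness=richness,
        shannon_entropy=entropy,
        clonality=clonality,
    )


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def jsd_divergence(p_table: ClonotypeTable, q_table: ClonotypeTable) -> float:
    """Jensen-Shannon divergence (base 2) between two repertoires.

    Frequencies are taken over the union of clonotype keys, with 0 for
    clones absent from one sample; JSD = H(m) - [H(p) + H(q)] / 2 with
    m the equal-weight mixture. 0 iff identical, 1 iff disjoint.
    """
    p = p_table.frequencies
    q = q_table.frequencies
    union = p.index.union(q.index)
    pv = p.reindex(union, fill_value=0.0).to_numpy(dtype=float)
    qv = q.reindex(union, fill_value=0.0).to_numpy(dtype=float)
    m = (pv + qv) / 2.0
    jsd = _entropy_bits(m) - 0.5 * (_entropy_bits(pv) + _entropy_bits(qv))
    return min(max(float(jsd), 0.0), 1.0)


def detect_expanded_clones(
    pre: ClonotypeTable,
    on: ClonotypeTable,
    fold_change: float = 3.0,
    min_reads: int = 10,
    min_reads_mode: str = "on",
) -> ExpansionCallSet:
    """Call clones expanded between a pre- and an on-treatment sample.

    A clone is expanded when (a) its read count reaches ``min_reads``
    (in the on-treatment sample by default; ``min_reads_mode='either'``
    accepts the floor in either sample) and (b) its frequency grew more
    than ``fold_change``-fold. Fold change is computed on frequencies,
    not raw counts, so sequencing-depth differences between the two
    draws do not masquerade as expansion; clones absent pre-treatment
    are treated as expanded (infinite fold change) once they pass the
    read floor.
    """
    if fold_change < 0 or min_reads < 0:
        raise ValidationError("thresholds must be non-negative")
    if min_reads_mode not in ("on", "either"):
        raise ValidationError(f"min_reads_mode must be 'on' or 'either', got {min_reads_mode!r}")
    union = pre.counts.index.union(on.counts.index)
    pre_counts = pre.counts.reindex(union, fill_value=0)
    on_counts = on.counts.reindex(union, fill_value=0)
    pre_freq = pre_counts / max(pre.total, 1)
    on_freq = on_counts / max(on.total, 1)
    if min_reads_mode == "on":
        floor_ok = on_counts >= min_reads
    else:
        floor_ok = (on_counts >= min_reads) | (pre_counts >= min_reads)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = on_freq.to_numpy() / pre_freq.to_numpy()
    grew = np.where(pre_freq.to_numpy() == 0, on_counts.to_numpy() > 0, ratio > fold_change)
    expanded = frozenset(union[floor_ok.to_numpy() & grew])
    return ExpansionCallSet(
        pre_sample_id=pre.sample_id,
        on_sample_id=on.sample_id,
        expanded=expanded,
        fold_change=fold_change,
        min_reads=min_reads,
        min_reads_mode=min_reads_mode,
    )


def persistent_expanded_clones(
    calls: list[ExpansionCallSet], min_fraction: float = 0.8
) -> frozenset[str]:
    """Clones expanded in at least ``min_fraction`` of on-treatment
    samples (compared with >=, so 4 of 5 passes the default 0.8)."""
    if len(calls) < 2:
        raise ValidationError("persistence needs >= 2 on-treatment call sets")
    if not 0.0 < min_fraction <= 1.0:
        raise ValidationError(f"min_fraction must be in (0, 1], got {min_fraction}")
    n = len(calls)
    tally: dict[str, int] = {}
    for cs in calls:
        for clone in cs.expanded:
            tally[clone] = tally.get(clone, 0) + 1
    return frozenset(c for c, k in tally.items() if k / n >= min_fraction)


def repertoire_overlap(clones: frozenset[str] | set[str], tumor: ClonotypeTable) -> float:
    """Fraction of a clone set observed (count > 0) in a tumor sample."""
    if not clones:
        raise ValidationError("empty clone set")
    present = tumor.counts[tumor.counts > 0].index
    return len(set(clones) & set(present)) / len(clones)


def rarefy(t: ClonotypeTable, depth: int, seed: int = 0) -> ClonotypeTable:
    """Seeded multinomial down-sampling to a common depth, for
    depth-fair richness comparisons."""
    if depth <= 0:
        raise ValidationError("rarefaction depth must be positive")
    if depth > t.total:
        raise ValidationError(
            f"depth {depth} exceeds sample {t.sample_id!r} total {t.total}"
        )
    rng = np.random.default_rng(seed)
    drawn = rng.multinomial(depth, t.frequencies.to_numpy(dtype=float))
    return ClonotypeTable(
        sample_id=t.sample_id,
        counts=pd.Series(drawn, index=t.counts.index),
        timepoint=t.timepoint,
        compartment=t.compartment,
    )
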