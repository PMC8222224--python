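"""Tabular containers and readers/writers for the pipeline's artifacts.

Everything on disk is tab-separated UTF-8 with a header row and "."
decimals, so round-trips are bit-stable and locale-independent. Gene
identifiers are case-sensitive symbols matched by exact string equality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ParseError",
    "EXPRESSION_UNITS",
    "BENEFIT_LABELS",
    "RESPONSE_LABELS",
    "ExpressionMatrix",
    "GeneSetCollection",
    "ClinicalTable",
    "ClonotypeTable",
    "read_expression_table",
    "write_expression_table",
    "read_gmt",
    "write_gmt",
    "read_clinical_table",
    "write_clinical_table",
    "read_clonotype_table",
    "write_clonotype_table",
    "write_score_table",
    "read_score_table",
]


class ValidationError(ValueError):
    """An in-memory table violates one of its invariants."""


class ParseError(ValueError):
    """A file could not be interpreted; the message locates the offence."""


EXPRESSION_UNITS = ("counts", "CPM", "RPKM", "logCPM", "zscore")
BENEFIT_LABELS = ("CB", "NCB")
RESPONSE_LABELS = ("CR", "PR", "SD", "PD", "NE")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """A genes x samples quantitative table with a declared unit.

    ``values`` is a pandas DataFrame indexed by gene symbol with one
    column per sample. ``unit`` declares what the numbers mean (raw
    ``counts``, ``CPM``, ``RPKM``, ``logCPM`` or per-gene ``zscore``).
    ``sample_datasets`` optionally records, per sample, which source
    dataset it came from -- populated by cross-cohort combination and
    consumed by within-dataset operations (quantile thresholds,
    subtype z-scores).
    """

    values: pd.DataFrame
    unit: str
    dataset_id: str = "dataset"
    sample_datasets: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.unit not in EXPRESSION_UNITS:
            raise ValidationError(
                f"unknown expression unit {self.unit!r}; expected one of {EXPRESSION_UNITS}"
            )
        _check_unique(list(self.values.index), "gene")
        _check_unique(list(self.values.columns), "sample")
        vals = self.values.to_numpy(dtype=float)
        if vals.size and not np.isfinite(vals).all():
            raise ValidationError("expression values must be finite")
        if self.unit == "counts" and vals.size and (vals < 0).any():
            gene, sample = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.values.index[gene]!r}, "
                f"sample {self.values.columns[sample]!r}"
            )
        if self.sample_datasets is not None:
            self.sample_datasets = self.sample_datasets.reindex(self.values.columns)
            if self.sample_datasets.isna().any():
                raise ValidationError("sample_datasets must cover every sample")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class GeneSetCollection:
    """Named gene lists (GMT-derived) driving the signature scores."""

    sets: dict[str, list[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            _check_unique(genes, f"gene (set {name!r})")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class ClinicalTable:
    """Per-sample clinical annotation: patient, cohort, benefit label.

    ``benefit`` is the dichotomy used throughout the association tests:
    CB (clinical benefit: complete / partial / mixed response) versus
    NCB (progression or not-evaluable disease).
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "patient_id", "cohort", "benefit")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValidationError(f"clinical table missing required column {col!r}")
        _check_unique(list(self.table["sample_id"]), "sample")
        benefit = self.table["benefit"].astype(str).str.upper()
        bad = sorted(set(benefit) - set(BENEFIT_LABELS))
        if bad:
            raise ValidationError(
                f"unknown benefit label(s) {bad}; allowed values: {list(BENEFIT_LABELS)}"
            )
        self.table = self.table.assign(benefit=benefit.to_numpy())
        if "response" in self.table.columns:
            resp = self.table["response"].dropna().astype(str).str.upper()
            bad = sorted(set(resp) - set(RESPONSE_LABELS))
            if bad:
                raise ValidationError(
                    f"unknown response label(s) {bad}; allowed values: {list(RESPONSE_LABELS)}"
                )
        if "weeks_on_therapy" in self.table.columns:
            weeks = pd.to_numeric(self.table["weeks_on_therapy"], errors="coerce")
            if (weeks.dropna() < 0).any():
                raise ValidationError("weeks_on_therapy must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def benefit_series(self) -> pd.Series:
        return pd.Series(
            self.table["benefit"].to_numpy(), index=self.table["sample_id"].to_numpy()
        )


@dataclass
class ClonotypeTable:
    """One sample's clonotype repertoire: counts per clonotype key.

    ``counts`` is indexed by the clonotype key (nucleotide rearrangement
    by default, or CDR3aa|V|J). Frequencies are derived from counts and
    must sum to 1 whenever any count is positive.
    """

    sample_id: str
    counts: pd.Series
    timepoint: str = "pre"
    compartment: str = "blood"

    def __post_init__(self) -> None:
        if self.compartment not in ("blood", "tumor"):
            raise ValidationError(
                f"compartment must be 'blood' or 'tumor', got {self.compartment!r}"
            )
        _check_unique(list(self.counts.index), f"clonotype (sample {self.sample_id!r})")
        arr = self.counts.to_numpy()
        if arr.size and (arr < 0).any():
            raise ValidationError(f"negative clonotype count in sample {self.sample_id!r}")
        if arr.size and not np.allclose(arr, np.round(arr)):
            raise ValidationError(f"non-integer clonotype count in sample {self.sample_id!r}")
        self.counts = self.counts.astype(np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> pd.Series:
        total = self.total
        if total == 0:
            raise ValidationError(f"sample {self.sample_id!r} has no reads")
        return self.counts / total


# ---------------------------------------------------------------------------
# expression tables


def read_expression_table(path: str | Path, unit: str) -> ExpressionMatrix:
    """Read a TSV with a sample-id header row and gene ids in column 1."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, encoding="utf-8")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    df.index = df.index.astype(str)
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise ParseError(
                f"{path}: non-numeric value {df[col].iloc[i]!r} at "
                f"gene {df.index[i]!r} (row {i + 2}), sample {col!r} (column {j + 2})"
            )
        numeric[col] = converted
    return ExpressionMatrix(values=numeric, unit=unit, dataset_id=path.stem)


def write_expression_table(m: ExpressionMatrix, path: str | Path) -> None:
    df = m.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.12g", encoding="utf-8", lineterminator="\n")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a Broad-dialect GMT file: name, description, genes, tab-separated."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene "
                    f"(got {len(fields)} field(s))"
                )
            name = fields[0]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            genes: list[str] = []
            seen: set[str] = set()
            dupes: list[str] = []
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    dupes.append(g)
                    continue
                seen.add(g)
                genes.append(g)
            if dupes:
                warnings.warn(
                    f"{path}:{lineno}: set {name!r} repeats gene(s) {sorted(set(dupes))}; "
                    "duplicates removed",
                    stacklevel=2,
                )
            if not genes:
                raise ParseError(f"{path}:{lineno}: set {name!r} has no genes")
            sets[name] = genes
    return GeneSetCollection(sets=sets, provenance=str(path))


def write_gmt(c: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, genes in c.sets.items():
            fh.write("\t".join([name, c.provenance or "na", *genes]) + "\n")


# ---------------------------------------------------------------------------
# clinical tables


def read_clinical_table(path: str | Path) -> ClinicalTable:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, encoding="utf-8")
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"{path}: {exc}") from exc
    if "weeks_on_therapy" in df.columns:
        df["weeks_on_therapy"] = pd.to_numeric(df["weeks_on_therapy"], errors="coerce")
    return ClinicalTable(table=df)


def write_clinical_table(t: ClinicalTable, path: str | Path) -> None:
    t.table.to_csv(path, sep="\t", index=False, encoding="utf-8", lineterminator="\n")


# ---------------------------------------------------------------------------
# clonotype tables

#: default column names, following the Adaptive immunoSEQ export dialect;
#: override any entry via the ``column_map`` argument.
DEFAULT_CLONOTYPE_COLUMNS: Mapping[str, str] = {
    "rearrangement": "rearrangement",
    "cdr3_aa": "amino_acid",
    "v_gene": "v_gene",
    "j_gene": "j_gene",
    "count": "templates",
    "frequency": "frequency",
}


def read_clonotype_table(
    path: str | Path,
    key_mode: str = "nucleotide",
    column_map: Mapping[str, str] | None = None,
    sample_id: str | None = None,
    timepoint: str = "pre",
    compartment: str = "blood",
) -> ClonotypeTable:
    """Read one sample's immunoSEQ-style clonotype TSV.

    ``key_mode`` selects the clonotype identity: ``nucleotide`` keys on
    the nucleotide rearrangement (the immunoSEQ convention);
    ``aminoacid_vj`` keys on CDR3 amino-acid sequence plus V and J gene,
    summing counts over rows that collapse to the same key. Frequencies
    are recomputed from counts (the on-disk frequency column, if any, is
    ignored so collapsed keys stay consistent).
    """
    if key_mode not in ("nucleotide", "aminoacid_vj"):
        raise ValueError(f"key_mode must be 'nucleotide' or 'aminoacid_vj', got {key_mode!r}")
    cols = dict(DEFAULT_CLONOTYPE_COLUMNS)
    if column_map:
        cols.update(column_map)
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, encoding="utf-8")
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"{path}: {exc}") from exc
    count_col = cols["count"]
    if count_col not in df.columns:
        raise ParseError(f"{path}: missing count column {count_col!r}")
    counts = pd.to_numeric(df[count_col], errors="coerce")
    if counts.isna().any():
        i = int(np.argmax(counts.isna().to_numpy()))
        raise ParseError(f"{path}: non-numeric count {df[count_col].iloc[i]!r} at row {i + 2}")
    if (counts < 0).any():
        raise ParseError(f"{path}: negative count at row {int(np.argmax((counts < 0).to_numpy())) + 2}")
    if key_mode == "nucleotide":
        key_col = cols["rearrangement"]
        if key_col not in df.columns:
            raise ParseError(f"{path}: missing clonotype column {key_col!r}")
        keys = df[key_col].astype(str)
    else:
        for part in ("cdr3_aa", "v_gene", "j_gene"):
            if cols[part] not in df.columns:
                raise ParseError(f"{path}: missing clonotype column {cols[part]!r}")
        keys = (
            df[cols["cdr3_aa"]].astype(str)
            + "|"
            + df[cols["v_gene"]].astype(str)
            + "|"
            + df[cols["j_gene"]].astype(str)
        )
    collapsed = counts.groupby(keys.to_numpy()).sum().sort_index()
    if sample_id is None:
        sample_id = (
            df["sample_id"].iloc[0] if "sample_id" in df.columns and len(df) else path.stem
        )
    if "timepoint" in df.columns and len(df):
        timepoint = df["timepoint"].iloc[0]
    if "compartment" in df.columns and len(df):
        compartment = df["compartment"].iloc[0]
    return ClonotypeTable(
        sample_id=str(sample_id),
        counts=collapsed,
        timepoint=str(timepoint),
        compartment=str(compartment),
    )


def write_clonotype_table(t: ClonotypeTable, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "rearrangement": t.counts.index,
            "templates": t.counts.to_numpy(),
            "sample_id": t.sample_id,
            "timepoint": t.timepoint,
            "compartment": t.compartment,
        }
    )
    df.to_csv(path, sep="\t", index=False, encoding="utf-8", lineterminator="\n")


# ---------------------------------------------------------------------------
# score tables


def write_score_table(scores: pd.DataFrame, path: str | Path) -> None:
    """Write a sample x signature score table, deterministically sorted."""
    out = scores.sort_index(axis=0).sort_index(axis=1)
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.12g", encoding="utf-8", lineterminator="\n")


def read_score_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, encoding="utf-8")
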