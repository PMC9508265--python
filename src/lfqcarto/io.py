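"""Readers and writers for the external formats the pipeline touches.

Three inputs exist: a protein-by-sample LFQ intensity table (MaxQuant
``proteinGroups``-style TSV with one ``LFQ intensity <sample>`` column per
sample), a sample sheet mapping sample names to their experimental
annotations, and optional gene-set collections in GMT format.  All outputs
are TSV with a documented header.

Parsing is strict: empty strings, ``NaN`` and missing cells inside LFQ
columns are format errors, never silent zeros — only a literal numeric 0
carries the "not detected" (dropout) meaning.  Sample names are matched
between LFQ columns and the sample sheet exactly after stripping the LFQ
prefix; no fuzzy matching.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "SampleAnnotation",
    "IntensityMatrix",
    "GeneSet",
    "GeneSetCollection",
    "read_lfq_table",
    "write_lfq_table",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gmt",
    "write_gmt",
    "write_table",
    "TISSUES",
    "ZONES",
    "METHODS",
]

TISSUES = ("tumor", "healthy_breast")
ZONES = ("center", "middle", "periphery", "none")
METHODS = ("ebiopsy", "lysis")

#: default column conventions of a MaxQuant proteinGroups export
DEFAULT_ID_COLUMN = "Protein IDs"
DEFAULT_GENE_COLUMN = "Gene names"
DEFAULT_LFQ_PREFIX = "LFQ intensity "

#: significant digits used when rendering reals to TSV
TABLE_SIG_DIGITS = 6


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


@dataclass(frozen=True)
class SampleAnnotation:
    """Experimental annotation of one sample column.

    ``zone`` is ``"none"`` exactly for healthy-breast samples; tumor
    samples carry one of the three spatial zones.
    """

    sample_name: str
    mouse_id: str
    tissue: str
    zone: str
    replica: int
    method: str

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValidationError(
                f"sample {self.sample_name!r}: unknown tissue {self.tissue!r}"
            )
        if self.zone not in ZONES:
            raise ValidationError(
                f"sample {self.sample_name!r}: unknown zone {self.zone!r}"
            )
        if self.method not in METHODS:
            raise ValidationError(
                f"sample {self.sample_name!r}: unknown method {self.method!r}"
            )
        if (self.zone == "none") != (self.tissue == "healthy_breast"):
            raise ValidationError(
                f"sample {self.sample_name!r}: zone must be 'none' iff tissue "
                f"is 'healthy_breast' (got tissue={self.tissue!r}, zone={self.zone!r})"
            )
        if int(self.replica) < 1:
            raise ValidationError(
                f"sample {self.sample_name!r}: replica must be >= 1"
            )

    @property
    def group_key(self) -> tuple:
        return (self.mouse_id, self.tissue, self.zone, self.replica, self.method)


def _validate_sheet(annotations: Sequence[SampleAnnotation]) -> None:
    seen_keys: dict[tuple, str] = {}
    seen_names: set[str] = set()
    for ann in annotations:
        if ann.sample_name in seen_names:
            raise ValidationError(f"duplicate sample name {ann.sample_name!r}")
        seen_names.add(ann.sample_name)
        key = ann.group_key
        if key in seen_keys:
            raise ValidationError(
                f"samples {seen_keys[key]!r} and {ann.sample_name!r} share "
                f"(mouse, tissue, zone, replica, method) = {key}"
            )
        seen_keys[key] = ann.sample_name


@dataclass
class IntensityMatrix:
    """Protein-by-sample table of non-negative LFQ intensities.

    ``values`` is indexed by gene symbol (one gene per protein group, the
    first listed symbol), with one column per sample.  ``protein_ids``
    maps gene -> protein-group identifier; ``extra_genes`` keeps the
    remaining semicolon-separated symbols of multi-gene groups.
    ``annotations`` is attached lazily (the LFQ table alone carries none).
    """

    values: pd.DataFrame
    protein_ids: pd.Series
    extra_genes: pd.Series
    annotations: pd.DataFrame | None = None
    parse_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (np.asarray(self.values, dtype=float) < 0).any():
            raise ValidationError("LFQ intensities must be non-negative")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene identifiers: {list(dups)[:5]}")
        if not self.values.index.equals(self.protein_ids.index):
            raise ValidationError("protein_ids misaligned with value rows")

    # -- basic shape ------------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def sample_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    # -- annotations ------------------------------------------------------
    def attach_annotations(
        self, annotations: Sequence[SampleAnnotation]
    ) -> "IntensityMatrix":
        """Return a copy with sample annotations joined on sample name.

        Every matrix column must be annotated; annotations for absent
        samples are an error (silent mis-joins are the worst failure mode).
        """
        _validate_sheet(annotations)
        by_name = {a.sample_name: a for a in annotations}
        missing = [s for s in self.sample_names if s not in by_name]
        if missing:
            raise ValidationError(f"samples without annotation: {missing}")
        extra = [n for n in by_name if n not in set(self.sample_names)]
        if extra:
            raise ValidationError(f"annotations for unknown samples: {extra}")
        ann = pd.DataFrame(
            [dataclasses.asdict(by_name[s]) for s in self.sample_names]
        ).set_index("sample_name")
        return IntensityMatrix(
            values=self.values.copy(),
            protein_ids=self.protein_ids.copy(),
            extra_genes=self.extra_genes.copy(),
            annotations=ann,
            parse_report=dict(self.parse_report),
        )

    def require_annotations(self) -> pd.DataFrame:
        if self.annotations is None:
            raise ValidationError("matrix has no sample annotations attached")
        return self.annotations

    def annotation_list(self) -> list[SampleAnnotation]:
        ann = self.require_annotations()
        return [
            SampleAnnotation(sample_name=str(name), **row)
            for name, row in ann.iterrows()
        ]

    def select_samples(self, mask: Iterable[bool]) -> "IntensityMatrix":
        mask = np.asarray(list(mask), dtype=bool)
        cols = [s for s, m in zip(self.sample_names, mask) if m]
        ann = self.annotations.loc[cols] if self.annotations is not None else None
        return IntensityMatrix(
            values=self.values[cols],
            protein_ids=self.protein_ids,
            extra_genes=self.extra_genes,
            annotations=ann,
            parse_report=dict(self.parse_report),
        )


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet]

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if not gs.members:
                raise ValidationError(f"gene set {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())


# ---------------------------------------------------------------------------
# LFQ table
# ---------------------------------------------------------------------------

def read_lfq_table(
    path: str | Path,
    id_column: str = DEFAULT_ID_COLUMN,
    gene_column: str = DEFAULT_GENE_COLUMN,
    lfq_prefix: str = DEFAULT_LFQ_PREFIX,
) -> IntensityMatrix:
    """Read a MaxQuant-style LFQ intensity TSV.

    Rows must carry both a protein-group identifier and a gene symbol to
    be retained (the valid-ID rule); dropped rows are counted in
    ``matrix.parse_report``.  Multi-gene groups (semicolon-separated) keep
    the first symbol; the rest go to ``extra_genes``.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty LFQ table") from exc
    if id_column not in raw.columns:
        raise FormatError(f"{path}: missing id column {id_column!r}")
    if gene_column not in raw.columns:
        raise FormatError(f"{path}: missing gene column {gene_column!r}")
    lfq_cols = [c for c in raw.columns if c.startswith(lfq_prefix)]
    if not lfq_cols:
        raise FormatError(f"{path}: no column starts with {lfq_prefix!r}")

    n_input = len(raw)
    valid = (raw[id_column].str.strip() != "") & (raw[gene_column].str.strip() != "")
    kept = raw.loc[valid].copy()
    n_dropped = n_input - len(kept)

    gene_parts = kept[gene_column].str.strip().str.split(";")
    genes = gene_parts.str[0]
    extra = gene_parts.apply(lambda p: ";".join(p[1:]))

    values = pd.DataFrame(index=pd.Index(genes.to_numpy(), name="gene"))
    for col in lfq_cols:
        cell = kept[col].str.strip()
        bad = cell == ""
        parsed = pd.to_numeric(cell.where(~bad, other="x"), errors="coerce")
        if parsed.isna().any():
            row = parsed.index[parsed.isna()][0]
            raise FormatError(
                f"{path}: non-numeric LFQ cell at input row {row + 2} "
                f"(1-based, incl. header), column {col!r}: {kept.loc[row, col]!r}"
            )
        if (parsed < 0).any():
            row = parsed.index[parsed < 0][0]
            raise FormatError(
                f"{path}: negative LFQ intensity at input row {row + 2}, "
                f"column {col!r}"
            )
        values[col[len(lfq_prefix):]] = parsed.to_numpy(dtype=float)

    matrix = IntensityMatrix(
        values=values,
        protein_ids=pd.Series(
            kept[id_column].to_numpy(), index=values.index, name="protein_id"
        ),
        extra_genes=pd.Series(
            extra.to_numpy(), index=values.index, name="extra_genes"
        ),
        parse_report={
            "input_rows": n_input,
            "kept_rows": len(kept),
            "dropped_invalid_id": n_dropped,
        },
    )
    return matrix


def write_lfq_table(
    matrix: IntensityMatrix,
    path: str | Path,
    id_column: str = DEFAULT_ID_COLUMN,
    gene_column: str = DEFAULT_GENE_COLUMN,
    lfq_prefix: str = DEFAULT_LFQ_PREFIX,
) -> None:
    """Write the matrix back in the same MaxQuant-style TSV layout."""
    out = pd.DataFrame(
        {
            id_column: matrix.protein_ids.to_numpy(),
            gene_column: [
                g if not e else f"{g};{e}"
                for g, e in zip(matrix.genes, matrix.extra_genes)
            ],
        }
    )
    for sample in matrix.sample_names:
        out[f"{lfq_prefix}{sample}"] = matrix.values[sample].to_numpy()
    write_table(out, path)


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

_SHEET_COLUMNS = ["sample_name", "mouse_id", "tissue", "zone", "replica", "method"]


def read_sample_sheet(path: str | Path) -> list[SampleAnnotation]:
    """Read the TSV sample sheet and validate all annotation invariants."""
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty sample sheet") from exc
    missing = [c for c in _SHEET_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: sample sheet missing columns {missing}")
    if len(raw) == 0:
        raise FormatError(f"{path}: sample sheet has a header but no samples")
    annotations = []
    for _, row in raw.iterrows():
        try:
            replica = int(row["replica"])
        except ValueError as exc:
            raise FormatError(
                f"{path}: non-integer replica {row['replica']!r} "
                f"for sample {row['sample_name']!r}"
            ) from exc
        annotations.append(
            SampleAnnotation(
                sample_name=row["sample_name"],
                mouse_id=row["mouse_id"],
                tissue=row["tissue"],
                zone=row["zone"],
                replica=replica,
                method=row["method"],
            )
        )
    _validate_sheet(annotations)
    return annotations


def write_sample_sheet(
    annotations: Sequence[SampleAnnotation], path: str | Path
) -> None:
    df = pd.DataFrame([dataclasses.asdict(a) for a in annotations])
    write_table(df[_SHEET_COLUMNS], path)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name TAB description TAB member...).

    Duplicate members within a set are deduplicated; member case is
    preserved.  Duplicate set names are an error.
    """
    path = Path(path)
    sets: dict[str, GeneSet] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated "
                    f"fields (name, description, members), got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = frozenset(m for m in fields[2:] if m != "")
            if not members:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = GeneSet(name=name, description=description, members=members)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in collection:
            members = "\t".join(sorted(gs.members))
            fh.write(f"{gs.name}\t{gs.description}\t{members}\n")


# ---------------------------------------------------------------------------
# Generic result tables
# ---------------------------------------------------------------------------

def write_table(
    rows: pd.DataFrame, path: str | Path, sig_digits: int = TABLE_SIG_DIGITS
) -> None:
    """Write a rectangular result table as TSV with a header row.

    Reals are rendered in scientific notation with ``sig_digits``
    significant digits (default 6: ``3.476e-4`` -> ``3.47600e-04``), so a
    read-back reproduces values to rendering precision.  Integers and
    strings are written verbatim.
    """
    path = Path(path)
    rows.to_csv(
        path, sep="\t", index=False, float_format=f"%.{sig_digits - 1}e"
    )
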