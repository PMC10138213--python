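"""Readers and writers for the external formats the pipeline touches.

Conventions
-----------
* Genomic coordinates are 0-based half-open everywhere (BED semantics);
  any 1-based source must be converted at the boundary.
* BED columns beyond the sixth are ignored, not rejected: peak callers
  routinely export extra columns.
* Gene identity is the symbol string, case-sensitive; no alias
  resolution is attempted.
* Readers emit canonically sorted collections (independent of input
  line order) except expression matrices, which preserve declared
  row/column order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

_VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval [start, end)."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)
    strand: str = field(default=".", compare=False)

    def __post_init__(self):
        if not self.chrom:
            raise ValidationError("interval chromosome must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def overlaps(self, other: "GenomicInterval") -> bool:
        """At least 1 bp of overlap under half-open semantics."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene symbols (GMT record)."""

    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self):
        if not self.name:
            raise ValidationError("gene set name must be nonempty")
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} has no members")
        seen = set()
        deduped = []
        for m in self.members:
            if m not in seen:
                seen.add(m)
                deduped.append(m)
        object.__setattr__(self, "members", tuple(deduped))

    def __contains__(self, symbol: str) -> bool:
        return symbol in set(self.members)

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# BED

def read_bed(path) -> list[GenomicInterval]:
    """Read a BED3+/BED6 file into a sorted interval list.

    Track, browser, and ``#`` comment lines are skipped.  Lines with
    fewer than 3 tab-separated columns, non-integer coordinates, or
    start >= end raise :class:`ParseError` naming the line.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"expected >=3 tab-separated columns, got {len(fields)}",
                    path=path,
                    line=lineno,
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(
                    f"non-integer coordinates {fields[1]!r}/{fields[2]!r}",
                    path=path,
                    line=lineno,
                ) from None
            if start >= end:
                raise ParseError(
                    f"start >= end ({start} >= {end})", path=path, line=lineno
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError:
                    raise ParseError(
                        f"non-numeric score {fields[4]!r}", path=path, line=lineno
                    ) from None
            strand = fields[5] if len(fields) > 5 else "."
            intervals.append(
                GenomicInterval(chrom, start, end, name=name, score=score, strand=strand)
            )
    return sorted(intervals)


def _fmt_score(score: float | None) -> str:
    if score is None:
        return "."
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    """Write intervals as BED6, canonically sorted (deterministic)."""
    with open(path, "w") as fh:
        for iv in sorted(intervals):
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        iv.name if iv.name is not None else ".",
                        _fmt_score(iv.score),
                        iv.strand,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GMT

def read_gmt(path) -> list[GeneSet]:
    """Read a Broad-dialect GMT file: name, description, members.

    Duplicate members within a set are collapsed (first occurrence
    wins); duplicate set names are a conflict error.
    """
    sets: list[GeneSet] = []
    names: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"GMT line needs name, description, >=1 member; got "
                    f"{len(fields)} fields",
                    path=path,
                    line=lineno,
                )
            name = fields[0]
            if name in names:
                raise ValidationError(f"duplicate gene set name {name!r} in {path}")
            names.add(name)
            members = tuple(m for m in fields[2:] if m)
            if not members:
                raise ParseError(
                    f"gene set {name!r} has no members", path=path, line=lineno
                )
            sets.append(GeneSet(name=name, description=fields[1], members=members))
    return sets


def write_gmt(gene_sets: Iterable[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


# ---------------------------------------------------------------------------
# Expression matrix + sample map

def read_expression(matrix_path, sample_map_path, allowed_conditions: Sequence[str] | None = None):
    """Read a genes x samples log2 matrix plus its sample->condition map.

    The matrix is a TSV with a header row of sample ids and the first
    column holding gene ids.  The sample map is a TSV with columns
    ``sample`` and ``condition`` (extra columns ignored).  Every matrix
    column must appear in the map.
    """
    from .diffexpr import ExpressionMatrix  # local import: io <- diffexpr only here

    mat = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#")
    if mat.index.duplicated().any():
        dupes = sorted(mat.index[mat.index.duplicated()].unique())
        raise ValidationError(f"duplicated gene id(s) in {matrix_path}: {dupes[:5]}")
    try:
        values = mat.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric cell in {matrix_path}: {exc}") from None
    if not np.isfinite(values.to_numpy()).all():
        raise ValidationError(f"non-finite value in {matrix_path}")

    smap = pd.read_csv(sample_map_path, sep="\t", comment="#", dtype=str)
    for col in ("sample", "condition"):
        if col not in smap.columns:
            raise ValidationError(f"sample map {sample_map_path} lacks column {col!r}")
    if smap["sample"].duplicated().any():
        raise ValidationError(f"duplicate sample row in {sample_map_path}")
    conditions = smap.set_index("sample")["condition"]
    missing = [s for s in values.columns if s not in conditions.index]
    if missing:
        raise ValidationError(
            f"sample(s) in matrix but not in sample map: {missing}"
        )
    conditions = conditions.loc[list(values.columns)]
    if allowed_conditions is not None:
        bad = sorted(set(conditions) - set(allowed_conditions))
        if bad:
            raise ValidationError(f"undeclared condition(s): {bad}")
    return ExpressionMatrix(values=values, conditions=conditions)


def write_expression(expr, matrix_path, sample_map_path) -> None:
    expr.values.to_csv(matrix_path, sep="\t", index_label="gene")
    smap = pd.DataFrame(
        {"sample": expr.conditions.index, "condition": expr.conditions.values}
    )
    smap["replicate"] = smap.groupby("condition").cumcount() + 1
    smap.to_csv(sample_map_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Transcript annotation TSV

ANNOTATION_COLUMNS = ("transcript_id", "gene_id", "gene_name", "chrom", "strand", "tss", "biotype")


def read_annotation(path):
    """Read the transcript annotation TSV defined by the simulator."""
    from .peakloss import TranscriptAnnotation

    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"annotation {path} lacks column(s) {missing}")
    return TranscriptAnnotation(df[list(ANNOTATION_COLUMNS)].copy())


def write_annotation(ann, path) -> None:
    ann.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Dose-response CSV (first row = doses of drug B, first column = doses of drug A)

def read_dose_csv(path):
    from .synergy import DoseResponseMatrix

    df = pd.read_csv(path, index_col=0, comment="#")
    try:
        doses_a = np.asarray([float(x) for x in df.index])
        doses_b = np.asarray([float(x) for x in df.columns])
    except ValueError as exc:
        raise ValidationError(f"non-numeric dose label in {path}: {exc}") from None
    return DoseResponseMatrix(
        doses_a=doses_a, doses_b=doses_b, response=df.to_numpy(dtype=float)
    )


def write_dose_csv(matrix, path) -> None:
    df = pd.DataFrame(
        matrix.response,
        index=[_fmt_num(d) for d in matrix.doses_a],
        columns=[_fmt_num(d) for d in matrix.doses_b],
    )
    df.to_csv(path, index_label="dose_a\\dose_b")


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


# ---------------------------------------------------------------------------
# Cohort TSV

COHORT_META_COLUMNS = ("sample", "tissue", "time", "event")


def read_cohort(path):
    from .cohort import CohortTable

    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in ("sample", "tissue") if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort table {path} lacks column(s) {missing}")
    return CohortTable(df)


def write_cohort(cohort, path) -> None:
    cohort.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Plain gene lists (one symbol per line)

def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")
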