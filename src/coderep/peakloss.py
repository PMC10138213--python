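"""Differential peak analysis at transcript start sites.

The procedure annotates each protein-coding transcript with a
symmetric window around its TSS (default +/- 10 kb), assigns peaks to
windows by any >=1 bp overlap (half-open semantics, strand-blind, as
``bedtools intersect`` with default parameters would), and then calls
a control-condition peak "lost" when no treated-condition peak
overlaps it.  A transcript is lost when at least one of its window
peaks is lost; a gene is lost when at least one of its transcripts is.
Genes losing repressive H3K27me3 peaks under EZH2 inhibition are the
putative PRC2 targets fed into candidate intersection.

Peak matching across conditions is by overlap only — no peak ids, no
reciprocal-fraction requirement, no score thresholds.  Adding peaks to
the treated set can therefore only flip lost -> retained, never the
reverse (monotonicity), and comparing a peak set against itself flags
nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .errors import ValidationError
from .io import GenomicInterval

logger = logging.getLogger(__name__)

PROTEIN_CODING = "protein_coding"


@dataclass
class TranscriptAnnotation:
    """Transcript records: id, gene, chrom, strand, TSS, biotype."""

    df: pd.DataFrame

    def __post_init__(self):
        required = {"transcript_id", "gene_id", "chrom", "strand", "tss", "biotype"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValidationError(f"annotation lacks column(s) {sorted(missing)}")
        if self.df["transcript_id"].duplicated().any():
            dupes = self.df.loc[
                self.df["transcript_id"].duplicated(), "transcript_id"
            ].tolist()
            raise ValidationError(f"duplicate transcript id(s): {dupes[:5]}")
        if (self.df["tss"] < 0).any():
            raise ValidationError("TSS positions must be >= 0")
        bad = set(self.df["strand"]) - {"+", "-"}
        if bad:
            raise ValidationError(f"invalid strand value(s): {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def gene_ids(self) -> set[str]:
        return set(self.df["gene_id"])

    def gene_of(self) -> dict[str, str]:
        return dict(zip(self.df["transcript_id"], self.df["gene_id"]))


@dataclass(frozen=True)
class PromoterWindow:
    """TSS-centered window [tss - W, tss + W) clipped at coordinate 0."""

    transcript_id: str
    gene_id: str
    chrom: str
    start: int
    end: int


class PeakSet:
    """A condition's peak collection with an interval index per chromosome."""

    def __init__(self, intervals):
        self.intervals: tuple[GenomicInterval, ...] = tuple(sorted(intervals))
        self._trees: dict[str, IntervalTree] = {}
        for iv in self.intervals:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __eq__(self, other) -> bool:
        return isinstance(other, PeakSet) and self.intervals == other.intervals

    @property
    def chroms(self) -> set[str]:
        return set(self._trees)

    def overlapping(self, chrom: str, start: int, end: int) -> list[GenomicInterval]:
        """Peaks with >=1 bp overlap with [start, end), sorted."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(hit.data for hit in tree.overlap(start, end))


def build_windows(
    ann: TranscriptAnnotation,
    halfwidth: int = 10_000,
    protein_coding_only: bool = True,
) -> list[PromoterWindow]:
    """One TSS-centered window per retained transcript.

    Windows are symmetric and strand-blind; strand matters upstream
    only when the TSS itself is chosen.  Noncoding transcripts are
    dropped when ``protein_coding_only`` is set.  Windows are clipped
    at coordinate 0.
    """
    if halfwidth <= 0:
        raise ValidationError("halfwidth must be positive")
    df = ann.df
    if protein_coding_only:
        df = df[df["biotype"] == PROTEIN_CODING]
    if df.empty:
        logger.warning("annotation yielded no windows")
        return []
    return [
        PromoterWindow(
            transcript_id=row.transcript_id,
            gene_id=row.gene_id,
            chrom=row.chrom,
            start=max(0, int(row.tss) - halfwidth),
            end=int(row.tss) + halfwidth,
        )
        for row in df.itertuples(index=False)
    ]


def assign_peaks(
    windows: list[PromoterWindow], peaks: PeakSet
) -> dict[str, list[GenomicInterval]]:
    """Map transcript -> peaks overlapping its window by >=1 bp.

    A peak may be assigned to several transcripts.  Peaks on
    chromosomes absent from the annotation are ignored (count logged).
    """
    window_chroms = {w.chrom for w in windows}
    orphan_chroms = peaks.chroms - window_chroms
    if orphan_chroms:
        n = sum(1 for iv in peaks if iv.chrom in orphan_chroms)
        logger.info(
            "%d peak(s) on %d chromosome(s) absent from annotation ignored",
            n,
            len(orphan_chroms),
        )
    return {
        w.transcript_id: peaks.overlapping(w.chrom, w.start, w.end) for w in windows
    }


@dataclass
class PeakLossReport:
    """Lost/retained status per control peak, transcript, and gene."""

    transcripts: pd.DataFrame  # transcript_id, gene_id, n_control_peaks, n_lost, lost
    peak_status: list[tuple[str, GenomicInterval, bool]] = field(repr=False, default_factory=list)

    @property
    def gene_lost(self) -> pd.Series:
        """Gene lost flag = OR over the gene's transcripts."""
        return self.transcripts.groupby("gene_id")["lost"].any()

    def lost_genes(self) -> set[str]:
        flags = self.gene_lost
        return set(flags.index[flags])

    def to_tsv(self, path) -> None:
        out = self.transcripts.sort_values("transcript_id")
        out.to_csv(path, sep="\t", index=False)


def call_lost(
    control: PeakSet, treated: PeakSet, windows: list[PromoterWindow]
) -> PeakLossReport:
    """Flag transcripts/genes whose window lost >=1 control peak.

    For every control peak assigned to a window, the peak is retained
    iff some treated peak overlaps it by >=1 bp; otherwise it is lost.
    """
    rows = []
    peak_status: list[tuple[str, GenomicInterval, bool]] = []
    for w in windows:
        in_window = control.overlapping(w.chrom, w.start, w.end)
        n_lost = 0
        for peak in in_window:
            retained = bool(treated.overlapping(peak.chrom, peak.start, peak.end))
            peak_status.append((w.transcript_id, peak, retained))
            if not retained:
                n_lost += 1
        rows.append(
            {
                "transcript_id": w.transcript_id,
                "gene_id": w.gene_id,
                "n_control_peaks": len(in_window),
                "n_lost": n_lost,
                "lost": n_lost > 0,
            }
        )
    transcripts = pd.DataFrame(
        rows,
        columns=["transcript_id", "gene_id", "n_control_peaks", "n_lost", "lost"],
    )
    return PeakLossReport(transcripts=transcripts, peak_status=peak_status)


def prc2_target_genes(report: PeakLossReport) -> set[str]:
    """Genes flagged as having lost >=1 promoter peak (putative PRC2 targets)."""
    return report.lost_genes()
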