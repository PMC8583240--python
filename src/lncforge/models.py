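"""Core genomic data types and coordinate conventions.

All coordinates are 0-based, half-open internally.  GTF I/O (see
:mod:`lncforge.gtf`) converts to and from the 1-based closed convention of
that dialect.  A :class:`TranscriptModel` is a stranded, multi-exon gene
structure on one chromosome; its exons are sorted and disjoint, as emitted
by transcript assemblers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded interval on a chromosome, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"require start < end, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share at least one base (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        """True if *other* lies entirely within this interval (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        """True if the 0-based position *pos* lies within the interval."""
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class IntronChain:
    """The ordered introns of a transcript; empty for single-exon models.

    Intron-chain identity (terminal exon ends free to differ) is the
    structural definition of a transcript match used throughout the
    discovery pipeline.
    """

    chrom: str
    strand: str
    introns: tuple

    def __len__(self) -> int:
        return len(self.introns)

    @property
    def coordinates(self) -> tuple:
        """Hashable (start, end) pairs, for set-based chain matching."""
        return tuple((i.start, i.end) for i in self.introns)


@dataclass
class TranscriptModel:
    """A stranded multi- (or single-) exon transcript model.

    Exons must be sorted by start, pairwise disjoint, and share one
    chromosome and strand.  Overlapping exons are rejected rather than
    merged: assemblers emit disjoint exons, so overlap signals corrupt
    input.
    """

    transcript_id: str
    gene_id: str
    exons: List[GenomicInterval]
    biotype: Optional[str] = None
    attributes: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >=1 exon")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(
                f"{self.transcript_id}: exons must share one chromosome and strand"
            )
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            # adjacency is rejected too: it would imply a zero-length intron
            if b.start <= a.end:
                raise ValueError(
                    f"{self.transcript_id}: overlapping or adjacent exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        """The genomic span from first exon start to last exon end."""
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def is_multi_exonic(self) -> bool:
        return len(self.exons) > 1


def transcript_length(t: TranscriptModel) -> int:
    """Spliced transcript length: the sum of exon lengths, not the genomic span.

    This is the quantity the "> 200 nucleotides" lncRNA length criterion is
    applied to.
    """
    return sum(len(e) for e in t.exons)


def intron_chain(t: TranscriptModel) -> IntronChain:
    """Introns as the gaps between consecutive exons; empty for single-exon."""
    introns = tuple(
        GenomicInterval(t.chrom, a.end, b.start, t.strand)
        for a, b in zip(t.exons, t.exons[1:])
    )
    return IntronChain(chrom=t.chrom, strand=t.strand, introns=introns)


class AnnotationCatalog:
    """A collection of transcript models grouped by gene.

    Transcript ids are unique; ``genes`` maps gene_id to the ids of its
    transcripts.  Iteration yields transcripts in insertion order, which
    for GTF input is file order.
    """

    def __init__(self, transcripts: Iterable[TranscriptModel] = ()) -> None:
        self._transcripts: Dict[str, TranscriptModel] = {}
        self.genes: Dict[str, List[str]] = {}
        for t in transcripts:
            self.add(t)

    def add(self, t: TranscriptModel) -> None:
        if t.transcript_id in self._transcripts:
            raise ValueError(f"duplicate transcript_id {t.transcript_id!r}")
        self._transcripts[t.transcript_id] = t
        self.genes.setdefault(t.gene_id, []).append(t.transcript_id)

    def __len__(self) -> int:
        return len(self._transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self._transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._transcripts

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self._transcripts[transcript_id]

    def get(self, transcript_id: str) -> Optional[TranscriptModel]:
        return self._transcripts.get(transcript_id)

    @property
    def transcript_ids(self) -> List[str]:
        return list(self._transcripts)

    def subset(self, transcript_ids: Iterable[str]) -> "AnnotationCatalog":
        """A new catalog restricted to the given transcript ids."""
        return AnnotationCatalog(self._transcripts[i] for i in transcript_ids)

    def chromosomes(self) -> List[str]:
        return sorted({t.chrom for t in self})
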