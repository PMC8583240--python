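"""Structural classification of candidate transcripts against a reference.

Each candidate receives exactly one class code describing its relation to
the reference annotation, in the style of transcript-comparison tools:

``=``
    some reference transcript has an identical intron chain (same strand;
    terminal exon ends are free to differ);
``y``
    a whole reference transcript span lies entirely inside one intron of
    the candidate;
``x``
    the candidate shares exonic sequence with a reference exon on the
    opposite strand and none on the same strand (novel antisense);
``i``
    the candidate lies entirely within one intron of a reference
    transcript (either strand) with no reference-exon overlap;
``u``
    no overlap with any reference exon, intron, or span (intergenic);
``o``
    any remaining overlap pattern, e.g. same-strand partial exon overlap.

Codes are assigned with precedence ``=`` > ``y`` > ``x`` > ``i`` > ``o``
> ``u``, so every candidate gets exactly one code.  Candidates on strand
``.`` cannot receive the strand-dependent codes ``=`` and ``x`` and are
flagged.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Optional, Set, Tuple

import pandas as pd
from intervaltree import IntervalTree

from .models import AnnotationCatalog, GenomicInterval, TranscriptModel, intron_chain

logger = logging.getLogger(__name__)

EQUAL = "="
INTERGENIC = "u"
INTRONIC = "i"
ANTISENSE = "x"
CONTAINS_REF = "y"
OTHER = "o"

CLASS_CODES = (EQUAL, INTERGENIC, INTRONIC, ANTISENSE, CONTAINS_REF, OTHER)

#: Novelty-compatible codes: intergenic, intronic, antisense, gene-in-intron.
NOVEL_CODES = frozenset({INTERGENIC, INTRONIC, ANTISENSE, CONTAINS_REF})


@dataclass
class ClassifiedTranscript:
    """A candidate transcript with its class code and best reference match."""

    candidate: TranscriptModel
    code: str
    best_ref: Optional[str] = None
    evidence: str = ""
    strand_warning: bool = False

    def __post_init__(self) -> None:
        if self.code == EQUAL and self.best_ref is None:
            raise ValueError("'=' classification requires best_ref")
        if self.code == INTERGENIC and self.best_ref is not None:
            raise ValueError("'u' classification forbids best_ref")


class ReferenceIndex:
    """Per-chromosome interval indexes over reference exons, introns and spans.

    Queries return exactly the reference features overlapping a query
    interval, as a linear scan would.
    """

    def __init__(self, ref: AnnotationCatalog) -> None:
        self.catalog = ref
        self._exons: Dict[str, IntervalTree] = {}
        self._introns: Dict[str, IntervalTree] = {}
        self._spans: Dict[str, IntervalTree] = {}
        # chain key -> reference transcript ids with that intron chain
        self._chains: Dict[Tuple, List[str]] = {}
        for t in ref:
            for exon in t.exons:
                self._exons.setdefault(t.chrom, IntervalTree()).addi(
                    exon.start, exon.end, (t.transcript_id, t.strand)
                )
            chain = intron_chain(t)
            for iv in chain.introns:
                self._introns.setdefault(t.chrom, IntervalTree()).addi(
                    iv.start, iv.end, (t.transcript_id, t.strand)
                )
            self._spans.setdefault(t.chrom, IntervalTree()).addi(
                t.start, t.end, (t.transcript_id, t.strand)
            )
            if chain.introns:
                key = (t.chrom, t.strand, chain.coordinates)
                self._chains.setdefault(key, []).append(t.transcript_id)

    @staticmethod
    def _query(
        trees: Dict[str, IntervalTree], iv: GenomicInterval
    ) -> Set[Tuple[str, str, int, int]]:
        tree = trees.get(iv.chrom)
        if tree is None:
            return set()
        return {
            (hit.data[0], hit.data[1], hit.begin, hit.end)
            for hit in tree.overlap(iv.start, iv.end)
        }

    def overlapping_exons(self, iv: GenomicInterval):
        """(transcript_id, strand, start, end) of reference exons hitting *iv*."""
        return self._query(self._exons, iv)

    def overlapping_introns(self, iv: GenomicInterval):
        return self._query(self._introns, iv)

    def overlapping_spans(self, iv: GenomicInterval):
        return self._query(self._spans, iv)

    def transcripts_with_chain(self, t: TranscriptModel) -> List[str]:
        """Reference transcripts sharing t's exact intron chain and strand."""
        chain = intron_chain(t)
        if not chain.introns:
            return []
        return list(self._chains.get((t.chrom, t.strand, chain.coordinates), []))


def build_reference_index(ref: AnnotationCatalog) -> ReferenceIndex:
    """Index a reference catalog for overlap and intron-chain queries."""
    return ReferenceIndex(ref)


def match_intron_chains(a: TranscriptModel, b: TranscriptModel) -> bool:
    """True iff the two transcripts share a complete intron chain.

    Same chromosome, same strand, and identical intron coordinates; the
    terminal exon boundaries may differ.  For two single-exon transcripts
    the chain is vacuous, so the match degenerates to same-strand exon
    overlap; a single-exon transcript never matches a multi-exon one.
    """
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    ca, cb = intron_chain(a), intron_chain(b)
    if len(ca) != len(cb):
        return False
    if len(ca) == 0:
        return a.exons[0].overlaps(b.exons[0])
    return ca.coordinates == cb.coordinates


def _exonic_overlap_bases(cand: TranscriptModel, ref: TranscriptModel) -> int:
    total = 0
    for e in cand.exons:
        for r in ref.exons:
            if e.overlaps(r):
                total += min(e.end, r.end) - max(e.start, r.start)
    return total


def classify_transcript(
    cand: TranscriptModel,
    index: ReferenceIndex,
    same_strand_intronic: bool = False,
    antisense_exclusive: bool = True,
) -> ClassifiedTranscript:
    """Assign one class code to a candidate against an indexed reference.

    ``same_strand_intronic`` restricts 'i' to same-strand host introns;
    ``antisense_exclusive`` requires 'x' candidates to have *no* same-strand
    reference exon overlap (the default), otherwise any opposite-strand
    exon overlap qualifies.
    """
    stranded = cand.strand in ("+", "-")
    strand_warning = not stranded

    exon_hits_same: Set[str] = set()
    exon_hits_opposite: Set[str] = set()
    overlap_any = False
    for exon in cand.exons:
        for tid, strand, _s, _e in index.overlapping_exons(exon):
            overlap_any = True
            if stranded and strand == cand.strand:
                exon_hits_same.add(tid)
            elif stranded and strand in ("+", "-") and strand != cand.strand:
                exon_hits_opposite.add(tid)
            else:
                exon_hits_same.add(tid)  # unstranded comparisons count as same

    # '=': identical intron chain on the same strand.
    if stranded:
        equal_ids = index.transcripts_with_chain(cand)
        if equal_ids:
            best = _best_by_overlap(cand, equal_ids, index.catalog)
            return ClassifiedTranscript(
                cand, EQUAL, best_ref=best,
                evidence=f"intron chain identical to {best}",
            )

    # 'y': a whole reference span inside one intron of the candidate.
    for iv in intron_chain(cand).introns:
        for tid, _strand, s, e in index.overlapping_spans(iv):
            if iv.start <= s and e <= iv.end:
                return ClassifiedTranscript(
                    cand, CONTAINS_REF, best_ref=tid,
                    evidence=f"reference {tid} contained in candidate intron "
                             f"[{iv.start},{iv.end})",
                    strand_warning=strand_warning,
                )

    # 'x': opposite-strand exonic overlap (exclusive of same-strand by default).
    if stranded and exon_hits_opposite and (
        not antisense_exclusive or not exon_hits_same
    ):
        best = _best_by_overlap(cand, sorted(exon_hits_opposite), index.catalog)
        return ClassifiedTranscript(
            cand, ANTISENSE, best_ref=best,
            evidence=f"antisense exonic overlap with {best}",
        )

    # 'i': candidate wholly inside one reference intron, no ref-exon overlap.
    if not overlap_any:
        span = cand.span
        for tid, strand, s, e in index.overlapping_introns(span):
            if same_strand_intronic and stranded and strand != cand.strand:
                continue
            if s <= span.start and span.end <= e:
                return ClassifiedTranscript(
                    cand, INTRONIC, best_ref=tid,
                    evidence=f"contained in intron [{s},{e}) of {tid}",
                    strand_warning=strand_warning,
                )

    # 'u': no overlap with any reference feature at all.
    span = cand.span
    if (
        not index.overlapping_exons(span)
        and not index.overlapping_introns(span)
        and not index.overlapping_spans(span)
    ):
        return ClassifiedTranscript(
            cand, INTERGENIC, evidence="no reference overlap",
            strand_warning=strand_warning,
        )

    hits = exon_hits_same | exon_hits_opposite
    best = _best_by_overlap(cand, sorted(hits), index.catalog) if hits else None
    return ClassifiedTranscript(
        cand, OTHER, best_ref=best, evidence="residual overlap pattern",
        strand_warning=strand_warning,
    )


def _best_by_overlap(
    cand: TranscriptModel, tids: List[str], ref: AnnotationCatalog
) -> str:
    """Tie-break among reference candidates by longest shared exonic overlap."""
    if len(tids) == 1:
        return tids[0]
    scored = sorted(
        tids, key=lambda tid: (-_exonic_overlap_bases(cand, ref[tid]), tid)
    )
    return scored[0]


def classify_catalog(
    cands: AnnotationCatalog,
    ref: AnnotationCatalog,
    **kwargs,
) -> pd.DataFrame:
    """Classify every candidate; returns one row per candidate transcript.

    Candidates on chromosomes absent from the reference are necessarily
    intergenic and logged as such.  Per-code summary counts go to the log.
    """
    index = build_reference_index(ref)
    ref_chroms = set(ref.chromosomes())
    rows = []
    for cand in cands:
        if cand.chrom not in ref_chroms:
            logger.warning(
                "candidate %s on chromosome %s absent from reference; "
                "classified 'u'", cand.transcript_id, cand.chrom,
            )
        ct = classify_transcript(cand, index, **kwargs)
        rows.append(
            {
                "transcript_id": cand.transcript_id,
                "gene_id": cand.gene_id,
                "code": ct.code,
                "best_ref": ct.best_ref,
                "evidence": ct.evidence,
                "strand_warning": ct.strand_warning,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "gene_id", "code", "best_ref", "evidence",
            "strand_warning",
        ],
    )
    counts = Counter(table["code"]) if len(table) else {}
    logger.info("classification summary: %s", dict(counts))
    return table
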