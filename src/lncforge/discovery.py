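"""The novel-lncRNA discovery pipeline.

Candidate transcripts survive discovery when they
(i)   have read counts > 0 in at least half of the samples (prevalence),
(ii)  have spliced length > 200 nt,
(iii) are multi-exonic,
(iv)  carry a novelty-compatible class code (u, i, x or y) against the
      reference annotation,
(v)   lack coding potential, and
      map to an allowed chromosome (autosomes 1-22 plus X by default).

Survivors from two sequencing platforms are cross-validated by complete
intron-chain identity, and the validated set is partitioned into
previously-annotated vs novel by re-annotation against updated database
catalogs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from . import classify as _classify
from .coding import CodingModel, HexamerTable, coding_probability
from .models import AnnotationCatalog, TranscriptModel, transcript_length

logger = logging.getLogger(__name__)

DEFAULT_ALLOWED_CHROMS = frozenset(
    [f"chr{i}" for i in range(1, 23)] + ["chrX"]
    + [str(i) for i in range(1, 23)] + ["X"]
)

CRITERIA = ("length", "multi_exonic", "class_code", "noncoding", "chromosome")


@dataclass
class DiscoveryConfig:
    """Thresholds of the novelty filter.

    ``min_length_nt`` uses "length > 200" semantics: a transcript passes
    when its spliced length is at least ``min_length_nt`` (default 201).
    """

    min_sample_fraction: float = 0.5
    min_length_nt: int = 201
    allowed_codes: frozenset = _classify.NOVEL_CODES
    allowed_chroms: frozenset = DEFAULT_ALLOWED_CHROMS
    coding_cutoff: float = 0.364
    db_match_mode: str = "chain_or_overlap"  # or "chain_only"

    def __post_init__(self) -> None:
        if not 0.0 < self.min_sample_fraction <= 1.0:
            raise ValueError("min_sample_fraction must lie in (0, 1]")
        if self.min_length_nt <= 0:
            raise ValueError("min_length_nt must be positive")
        if not 0.0 < self.coding_cutoff < 1.0:
            raise ValueError("coding_cutoff must lie in (0, 1)")
        self.allowed_codes = frozenset(self.allowed_codes)
        self.allowed_chroms = frozenset(self.allowed_chroms)


@dataclass
class NoveltyReport:
    """Accumulated results of the discovery stages."""

    criteria: pd.DataFrame = None  # per-candidate per-criterion booleans
    surviving: List[str] = field(default_factory=list)
    validated_pairs: List[Tuple[str, str]] = field(default_factory=list)
    validated: List[str] = field(default_factory=list)
    previously_annotated: Dict[str, str] = field(default_factory=dict)
    novel: List[str] = field(default_factory=list)

    def stage_counts(self) -> Dict[str, int]:
        return {
            "candidates": 0 if self.criteria is None else len(self.criteria),
            "surviving": len(self.surviving),
            "validated": len(self.validated),
            "previously_annotated": len(self.previously_annotated),
            "novel": len(self.novel),
        }


def prevalence_filter(
    counts: pd.DataFrame, min_fraction: float = 0.5
) -> List[str]:
    """Ids detected (count > 0) in at least ceil(min_fraction * n) samples."""
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValueError("empty count matrix")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    needed = math.ceil(min_fraction * counts.shape[1])
    detected = (counts > 0).sum(axis=1)
    return list(counts.index[detected >= needed])


def apply_novelty_criteria(
    cands: AnnotationCatalog,
    codes: pd.DataFrame,
    sequences: Mapping[str, str],
    model: CodingModel,
    table: HexamerTable,
    cfg: DiscoveryConfig = None,
) -> NoveltyReport:
    """Evaluate criteria ii-v plus the chromosome filter per candidate.

    ``codes`` is the classification table from
    :func:`lncforge.classify.classify_catalog`.  A candidate missing from
    ``sequences`` fails the coding criterion with a logged reason rather
    than crashing.  Criteria are independent booleans, so their
    application order cannot change the surviving set.
    """
    cfg = cfg or DiscoveryConfig()
    code_of = dict(zip(codes["transcript_id"], codes["code"]))
    rows = []
    for t in cands:
        if t.transcript_id not in code_of:
            raise ValueError(f"candidate {t.transcript_id} has no class code")
        length_ok = transcript_length(t) >= cfg.min_length_nt
        multi_ok = t.is_multi_exonic()
        code_ok = code_of[t.transcript_id] in cfg.allowed_codes
        chrom_ok = t.chrom in cfg.allowed_chroms
        seq = sequences.get(t.transcript_id)
        if seq is None:
            logger.warning(
                "candidate %s has no sequence; fails coding-potential criterion",
                t.transcript_id,
            )
            prob = float("nan")
            noncoding_ok = False
        else:
            prob = coding_probability(seq, model, table)
            noncoding_ok = prob < cfg.coding_cutoff
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "length": length_ok,
                "multi_exonic": multi_ok,
                "class_code": code_ok,
                "noncoding": noncoding_ok,
                "chromosome": chrom_ok,
                "coding_probability": prob,
                "pass": length_ok and multi_ok and code_ok and noncoding_ok
                and chrom_ok,
            }
        )
    criteria = pd.DataFrame(rows).set_index("transcript_id")
    report = NoveltyReport(criteria=criteria)
    report.surviving = list(criteria.index[criteria["pass"]])
    return report


def cross_platform_validate(
    set_a: AnnotationCatalog, set_b: AnnotationCatalog
) -> Tuple[List[Tuple[str, str]], List[str]]:
    """Pairs of transcripts from two platforms with identical intron chains.

    Returns (validated pairs as (a_id, b_id), unmatched a-side ids).  The
    a-side model is the retained representative of each validated pair.
    A multi-exon transcript validates iff some b-side transcript shares
    its complete intron chain on the same strand.
    """
    index = _classify.build_reference_index(set_b)
    pairs: List[Tuple[str, str]] = []
    unmatched: List[str] = []
    for t in set_a:
        hits = index.transcripts_with_chain(t)
        if not hits and not t.is_multi_exonic():
            # single-exon chains are vacuous; degenerate overlap rule
            hits = [
                b.transcript_id for b in set_b
                if _classify.match_intron_chains(t, b)
            ]
        if hits:
            best = _classify._best_by_overlap(t, sorted(hits), set_b)
            pairs.append((t.transcript_id, best))
        else:
            unmatched.append(t.transcript_id)
    return pairs, unmatched


def _db_match(
    cand: TranscriptModel,
    db: AnnotationCatalog,
    index: _classify.ReferenceIndex,
    mode: str,
) -> Optional[str]:
    hits = index.transcripts_with_chain(cand)
    if hits:
        return sorted(hits)[0]
    if mode == "chain_only":
        return None
    # same-strand exonic overlap >= 50% of the shorter transcript
    for exon in cand.exons:
        for tid, strand, _s, _e in index.overlapping_exons(exon):
            if strand != cand.strand:
                continue
            other = db[tid]
            shared = _classify._exonic_overlap_bases(cand, other)
            shorter = min(transcript_length(cand), transcript_length(other))
            if shorter and shared / shorter >= 0.5:
                return tid
    return None


def annotate_against_databases(
    validated: AnnotationCatalog,
    dbs: Sequence[Tuple[str, AnnotationCatalog]],
    mode: str = "chain_or_overlap",
) -> NoveltyReport:
    """Partition validated transcripts into previously annotated vs novel.

    A transcript is previously annotated when any database transcript
    matches it by intron-chain identity or (in ``chain_or_overlap`` mode)
    by same-strand exonic overlap covering at least 50% of the shorter
    transcript; the first matching database (in the given order) is
    recorded as provenance.
    """
    if not dbs:
        logger.warning("no databases given; all validated transcripts novel")
    indexes = [(name, db, _classify.build_reference_index(db)) for name, db in dbs]
    report = NoveltyReport()
    report.validated = list(validated.transcript_ids)
    for t in validated:
        source = None
        for name, db, index in indexes:
            if _db_match(t, db, index, mode) is not None:
                source = name
                break
        if source is None:
            report.novel.append(t.transcript_id)
        else:
            report.previously_annotated[t.transcript_id] = source
    return report
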