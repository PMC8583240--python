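"""GTF2.2 reading and writing for annotation catalogs.

Only ``exon`` features are modelled; ``gene_id`` and ``transcript_id``
attributes are mandatory and any further attributes are preserved as
opaque text so that ``read_gtf(write_gtf(c))`` reproduces ``c`` exactly.
GTF coordinates are 1-based closed; internally everything is 0-based
half-open, so an exon printed as ``100 200`` becomes ``[99, 200)``.
"""

from __future__ import annotations

import os
from typing import Dict, List, Optional, Tuple

from gffutils.feature import feature_from_line

from .models import AnnotationCatalog, GenomicInterval, TranscriptModel


class GtfParseError(ValueError):
    """A malformed GTF line, reported with its line number."""


_RESERVED = ("gene_id", "transcript_id", "biotype")


def read_gtf(path: str) -> AnnotationCatalog:
    """Read a GTF2.2 file into an :class:`AnnotationCatalog`.

    Exon features are grouped by ``transcript_id`` and sorted by start;
    non-exon features and comment lines are skipped.  A ``biotype``
    attribute, when present, is carried onto the transcript.
    """
    exons: Dict[str, List[GenomicInterval]] = {}
    gene_of: Dict[str, str] = {}
    biotype_of: Dict[str, Optional[str]] = {}
    extra_of: Dict[str, Dict[str, str]] = {}
    order: List[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception as exc:  # gffutils raises assorted types
                raise GtfParseError(f"{path}:{lineno}: malformed GTF line: {exc}")
            if feat.featuretype != "exon":
                continue
            attrs = feat.attributes
            if "transcript_id" not in attrs or not attrs["transcript_id"]:
                raise GtfParseError(
                    f"{path}:{lineno}: exon record lacks transcript_id"
                )
            if "gene_id" not in attrs or not attrs["gene_id"]:
                raise GtfParseError(f"{path}:{lineno}: exon record lacks gene_id")
            tid = attrs["transcript_id"][0]
            gid = attrs["gene_id"][0]
            if tid not in exons:
                exons[tid] = []
                order.append(tid)
                gene_of[tid] = gid
                biotype_of[tid] = (
                    attrs["biotype"][0] if "biotype" in attrs else None
                )
                extra_of[tid] = {
                    k: v[0] for k, v in attrs.items() if k not in _RESERVED
                }
            try:
                iv = GenomicInterval(
                    feat.seqid, feat.start - 1, feat.end, feat.strand
                )
            except ValueError as exc:
                raise GtfParseError(f"{path}:{lineno}: {exc}")
            exons[tid].append(iv)

    catalog = AnnotationCatalog()
    for tid in order:
        catalog.add(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_of[tid],
                exons=exons[tid],
                biotype=biotype_of[tid],
                attributes=extra_of[tid],
            )
        )
    return catalog


def _format_attributes(t: TranscriptModel) -> str:
    parts = [f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";']
    if t.biotype is not None:
        parts.append(f'biotype "{t.biotype}";')
    for key, value in t.attributes.items():
        parts.append(f'{key} "{value}";')
    return " ".join(parts)


def write_gtf(catalog: AnnotationCatalog, path: str, source: str = "lncforge") -> None:
    """Write a catalog as GTF2.2 (1-based closed coordinates)."""
    with open(path, "w") as fh:
        fh.write("#gtf-version 2.2\n")
        for t in catalog:
            attrs = _format_attributes(t)
            for exon in t.exons:
                fh.write(
                    "\t".join(
                        (
                            exon.chrom,
                            source,
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            exon.strand,
                            ".",
                            attrs,
                        )
                    )
                    + "\n"
                )
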