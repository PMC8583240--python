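"""Overlap of lncRNA exons with cis-eQTL SNPs and eGene correlation.

A cis-eQTL table associates an eSNP (a single genomic base) with the
expression of a nearby gene (its eGene).  Exon/eSNP containment overlap
identifies lncRNAs positioned over regulatory variants; correlating the
lncRNA's expression with its eGene's across samples probes a shared
regulatory mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .models import AnnotationCatalog, GenomicInterval

DEFAULT_P_THRESHOLD = 1e-8

SNP_COLUMNS = ("snp_id", "chrom", "pos", "egene_id", "pvalue")


@dataclass(frozen=True)
class SnpAssociation:
    """One eSNP-eGene association; the SNP occupies a single base."""

    snp_id: str
    position: GenomicInterval
    egene_id: str
    pvalue: float

    def __post_init__(self) -> None:
        if len(self.position) != 1:
            raise ValueError("SNP position must have width exactly 1")
        if not 0.0 < self.pvalue <= 1.0:
            raise ValueError("association p must lie in (0, 1]")


def read_snp_table(
    path: str, p_threshold: float = DEFAULT_P_THRESHOLD
) -> List[SnpAssociation]:
    """Read a SNP association TSV and keep rows with p < ``p_threshold``.

    Expected columns: snp_id, chrom, pos (1-based), egene_id, pvalue.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(SNP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if not pd.api.types.is_numeric_dtype(df["pos"]):
        raise ValueError(f"{path}: non-numeric SNP positions")
    records = []
    for row in df.itertuples(index=False):
        if row.pvalue >= p_threshold:
            continue
        pos0 = int(row.pos) - 1  # 1-based input
        records.append(
            SnpAssociation(
                snp_id=str(row.snp_id),
                position=GenomicInterval(str(row.chrom), pos0, pos0 + 1),
                egene_id=str(row.egene_id),
                pvalue=float(row.pvalue),
            )
        )
    return records


def overlap_exons_with_snps(
    catalog: AnnotationCatalog, snps: Sequence[SnpAssociation]
) -> pd.DataFrame:
    """All (exon, SNP) containment pairs; strand is ignored for points.

    Returns one row per containment: transcript_id, exon_index, snp_id,
    egene_id.  Output is sorted, so it is invariant to input ordering.
    """
    by_chrom: dict = {}
    for snp in snps:
        by_chrom.setdefault(snp.position.chrom, []).append(snp)
    for chrom_snps in by_chrom.values():
        chrom_snps.sort(key=lambda s: s.position.start)
    rows = []
    for t in catalog:
        chrom_snps = by_chrom.get(t.chrom)
        if not chrom_snps:
            continue
        positions = np.array([s.position.start for s in chrom_snps])
        for idx, exon in enumerate(t.exons):
            lo = np.searchsorted(positions, exon.start, side="left")
            hi = np.searchsorted(positions, exon.end, side="left")
            for snp in chrom_snps[lo:hi]:
                rows.append(
                    {
                        "transcript_id": t.transcript_id,
                        "exon_index": idx,
                        "snp_id": snp.snp_id,
                        "egene_id": snp.egene_id,
                    }
                )
    out = pd.DataFrame(
        rows, columns=["transcript_id", "exon_index", "snp_id", "egene_id"]
    )
    return out.sort_values(
        ["transcript_id", "exon_index", "snp_id"], ignore_index=True
    )


def lncrna_egene_correlation(
    expr: pd.DataFrame,
    pairs: Iterable[Tuple[str, str]],
    modules: pd.Series = None,
) -> pd.DataFrame:
    """Pearson correlation of each (lncRNA, eGene) pair across samples.

    ``modules``, when given, maps feature id -> module label and the
    output reports whether both members share a module.  A pair with a
    member missing from the matrix yields an error record, not a crash.
    """
    rows = []
    for lnc, egene in pairs:
        row = {"lncrna_id": lnc, "egene_id": egene, "pcc": np.nan,
               "pvalue": np.nan, "same_module": pd.NA, "error": ""}
        if lnc not in expr.index or egene not in expr.index:
            row["error"] = "feature missing from expression matrix"
        else:
            x = expr.loc[lnc].to_numpy(dtype=float)
            y = expr.loc[egene].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                row["error"] = "zero-variance feature"
            else:
                pcc, p = stats.pearsonr(x, y)
                row["pcc"], row["pvalue"] = float(pcc), float(p)
        if modules is not None and lnc in modules.index and egene in modules.index:
            row["same_module"] = bool(modules[lnc] == modules[egene])
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["lncrna_id", "egene_id", "pcc", "pvalue", "same_module", "error"],
    )


def export_overlaps_bed(
    overlaps: pd.DataFrame, catalog: AnnotationCatalog, path: str
) -> None:
    """BED export of overlapped SNP positions, named transcript:snp."""
    with open(path, "w") as fh:
        for _, r in overlaps.iterrows():
            t = catalog[r["transcript_id"]]
            exon = t.exons[int(r["exon_index"])]
            fh.write(
                f"{exon.chrom}\t{exon.start}\t{exon.end}\t"
                f"{r['transcript_id']}:{r['snp_id']}\t0\t{t.strand}\n"
            )
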