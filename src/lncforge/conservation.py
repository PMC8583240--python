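"""Per-exon conservation from a base-wise score track.

The track is a phastCons-like bedGraph: each base carries a score in
[0, 1], higher meaning more conserved.  For every exon the mean score over
track-covered bases is extracted; bases the track does not cover are
excluded from both numerator and denominator (the ``uncovered_as_zero``
flag switches to imputing them as 0).  Class-wise summaries (novel lncRNA
vs annotated lncRNA vs mRNA) support density-style profile comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from .models import AnnotationCatalog, GenomicInterval

logger = logging.getLogger(__name__)


@dataclass
class ScoreTrack:
    """Sorted, disjoint scored intervals per chromosome, values in [0, 1]."""

    starts: Dict[str, np.ndarray]
    ends: Dict[str, np.ndarray]
    values: Dict[str, np.ndarray]

    def chromosomes(self):
        return sorted(self.starts)

    def point_value(self, chrom: str, pos: int) -> Optional[float]:
        """Score at one base, or None when uncovered."""
        if chrom not in self.starts:
            return None
        idx = np.searchsorted(self.starts[chrom], pos, side="right") - 1
        if idx >= 0 and pos < self.ends[chrom][idx]:
            return float(self.values[chrom][idx])
        return None


def read_score_track(path: str) -> ScoreTrack:
    """Read a 4-column bedGraph (0-based half-open) into a validated track.

    Input intervals may arrive unsorted and are sorted per chromosome;
    overlapping intervals or values outside [0, 1] are errors, because the
    track is a per-base conservation probability by contract.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64,
               "value": np.float64},
    )
    if ((df["value"] < 0) | (df["value"] > 1)).any():
        raise ValueError(f"{path}: track values must lie in [0, 1]")
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"{path}: intervals must satisfy start < end")
    starts, ends, values = {}, {}, {}
    for chrom, grp in df.groupby("chrom", sort=True):
        grp = grp.sort_values("start", kind="mergesort")
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        if np.any(s[1:] < e[:-1]):
            raise ValueError(f"{path}: overlapping intervals on {chrom}")
        starts[chrom] = s
        ends[chrom] = e
        values[chrom] = grp["value"].to_numpy()
    return ScoreTrack(starts=starts, ends=ends, values=values)


def _exon_mean(
    track: ScoreTrack, exon: GenomicInterval, uncovered_as_zero: bool
) -> tuple:
    """(mean, covered_bases) for one exon; mean is NaN when fully uncovered."""
    chrom = exon.chrom
    if chrom not in track.starts:
        covered = 0
    else:
        s, e, v = track.starts[chrom], track.ends[chrom], track.values[chrom]
        lo = np.searchsorted(e, exon.start, side="right")
        hi = np.searchsorted(s, exon.end, side="left")
        ov = np.minimum(e[lo:hi], exon.end) - np.maximum(s[lo:hi], exon.start)
        ov = np.clip(ov, 0, None)
        covered = int(ov.sum())
        total = float(np.dot(ov, v[lo:hi]))
    if covered == 0:
        return (0.0, 0) if uncovered_as_zero else (np.nan, 0)
    if uncovered_as_zero:
        return total / len(exon), covered
    return total / covered, covered


def exon_mean_scores(
    catalog: AnnotationCatalog,
    track: ScoreTrack,
    uncovered_as_zero: bool = False,
) -> pd.DataFrame:
    """Mean conservation per exon of every transcript in the catalog.

    Returns a table with one row per exon: transcript_id, exon_index
    (0-based, in start order), mean_score, covered_bases, and the
    transcript's biotype as the class label.
    """
    rows = []
    for t in catalog:
        for idx, exon in enumerate(t.exons):
            mean, covered = _exon_mean(track, exon, uncovered_as_zero)
            rows.append(
                {
                    "transcript_id": t.transcript_id,
                    "exon_index": idx,
                    "chrom": exon.chrom,
                    "start": exon.start,
                    "end": exon.end,
                    "mean_score": mean,
                    "covered_bases": covered,
                    "class": t.biotype,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "exon_index", "chrom", "start", "end",
                 "mean_score", "covered_bases", "class"],
    )


def class_profiles(table: pd.DataFrame) -> pd.DataFrame:
    """Per-class summaries of exon conservation means.

    One row per class: exon count, mean, median, and the nine deciles of
    the per-exon means — the ingredients of a density-plot comparison of
    conservation profiles.  Exons with no covered bases are excluded;
    classes left with no exons are omitted with a warning.
    """
    rows = []
    for cls, grp in table.groupby("class", dropna=False):
        scores = grp["mean_score"].dropna().to_numpy()
        if scores.size == 0:
            logger.warning("class %r has no scored exons; omitted", cls)
            continue
        deciles = np.quantile(scores, np.arange(0.1, 1.0, 0.1))
        row = {
            "class": cls,
            "n_exons": scores.size,
            "mean": float(scores.mean()),
            "median": float(np.median(scores)),
        }
        row.update({f"q{10 * (i + 1)}": float(d) for i, d in enumerate(deciles)})
        rows.append(row)
    return pd.DataFrame(rows)


def export_bed(table: pd.DataFrame, path: str) -> None:
    """BED6 export of exons, score column scaled to [0, 1000]."""
    with open(path, "w") as fh:
        for _, r in table.iterrows():
            score = 0 if np.isnan(r["mean_score"]) else int(round(r["mean_score"] * 1000))
            fh.write(
                f"{r['chrom']}\t{r['start']}\t{r['end']}\t"
                f"{r['transcript_id']}.exon{r['exon_index']}\t{score}\t.\n"
            )
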