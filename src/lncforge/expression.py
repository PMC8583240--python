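"""Abundance normalization and paired differential expression.

Expression matrices are pandas DataFrames with features (genes or
transcripts) as rows and samples as columns.  The paired design compares
one pre and one post sample per subject.  The differential engine shipped
here is a paired t-test on log2(TPM + 1) differences with Benjamini-
Hochberg adjustment; external per-feature (log2FC, p) tables from other
engines can be injected through :func:`de_from_external`, so the
selection rule is decoupled from the fitting engine.

The high-confidence selection rule: BH-adjusted p < 0.001, absolute
signed fold change > 1.2 (post/pre), and — for annotated features only —
at least 90% of samples in each of the pre and post groups at >= 0.5 TPM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: pseudocount used in the fold-change ratio of group mean TPMs
FC_PSEUDOCOUNT = 0.01
#: pseudocount inside the log2 transform for the paired test
LOG_PSEUDOCOUNT = 1.0

DEFAULT_ADJ_P = 0.001
DEFAULT_MIN_ABS_FC = 1.2
DEFAULT_MIN_TPM = 0.5
DEFAULT_MIN_TPM_FRACTION = 0.9


@dataclass
class PairedDesign:
    """Sample-to-subject mapping for a pre/post paired comparison."""

    subject: Mapping[str, str]  # sample id -> subject id
    condition: Mapping[str, str]  # sample id -> "pre" | "post"

    def __post_init__(self) -> None:
        if set(self.subject) != set(self.condition):
            raise ValueError("subject and condition must cover the same samples")
        bad = {v for v in self.condition.values()} - {"pre", "post"}
        if bad:
            raise ValueError(f"conditions must be pre/post, got {bad}")
        pairs = {}
        for sample, subj in self.subject.items():
            pairs.setdefault(subj, []).append(self.condition[sample])
        for subj, conds in pairs.items():
            if sorted(conds) != ["post", "pre"]:
                raise ValueError(
                    f"subject {subj!r} must have exactly one pre and one post sample"
                )

    @property
    def n_pairs(self) -> int:
        return len(set(self.subject.values()))

    def paired_columns(self):
        """(pre_samples, post_samples) ordered by subject id."""
        pre, post = {}, {}
        for sample, subj in self.subject.items():
            (pre if self.condition[sample] == "pre" else post)[subj] = sample
        subjects = sorted(pre)
        return [pre[s] for s in subjects], [post[s] for s in subjects]

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "PairedDesign":
        """Build from a design table with columns sample, subject, condition."""
        return cls(
            subject=dict(zip(table["sample"], table["subject"])),
            condition=dict(zip(table["sample"], table["condition"])),
        )

    def to_table(self) -> pd.DataFrame:
        samples = sorted(self.subject)
        return pd.DataFrame(
            {
                "sample": samples,
                "subject": [self.subject[s] for s in samples],
                "condition": [self.condition[s] for s in samples],
            }
        )


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from counts and effective lengths.

    tpm_ij = (c_ij / len_i) / sum_k (c_kj / len_k) * 1e6; every column of
    the result sums to 1e6.  Invariant under per-column scaling of counts.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()[:5]
        raise ValueError(f"missing effective lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    zero_cols = denom.index[denom == 0].tolist()
    if zero_cols:
        raise ValueError(f"all-zero count column(s): {zero_cols}")
    return rate.div(denom, axis=1) * 1e6


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed; filter them first")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def signed_fold_change(
    mean_pre: np.ndarray, mean_post: np.ndarray,
    pseudocount: float = FC_PSEUDOCOUNT,
) -> np.ndarray:
    """Signed fold change: r = post/pre; reported as r if r >= 1 else -1/r.

    A halving (r = 0.5) is thus reported as -2, matching the reporting
    convention in which |FC| thresholds apply symmetrically to up- and
    down-regulation.
    """
    r = (np.asarray(mean_post) + pseudocount) / (np.asarray(mean_pre) + pseudocount)
    return np.where(r >= 1.0, r, -1.0 / r)


def paired_de_test(
    tpm: pd.DataFrame,
    design: PairedDesign,
    fc_pseudocount: float = FC_PSEUDOCOUNT,
    log_pseudocount: float = LOG_PSEUDOCOUNT,
    min_tpm: float = DEFAULT_MIN_TPM,
) -> pd.DataFrame:
    """Per-feature paired t-test on log2(TPM + 1) post - pre differences.

    Returns a table indexed by feature with: fold_change (signed),
    log2fc (mean paired log difference), pvalue, padj, mean TPM and
    fraction of samples >= ``min_tpm`` per group, and a zero_variance
    flag.  Features whose paired differences are all exactly zero get
    p = 1; features with zero-variance nonzero differences have an
    undefined t statistic, get p = NaN, and are excluded from the BH
    denominator.
    """
    if design.n_pairs < 3:
        raise ValueError("need at least 3 subject pairs")
    missing = set(design.subject) - set(tpm.columns)
    if missing:
        raise ValueError(f"samples missing from matrix: {sorted(missing)[:5]}")
    pre_cols, post_cols = design.paired_columns()
    pre = tpm[pre_cols].to_numpy(dtype=float)
    post = tpm[post_cols].to_numpy(dtype=float)

    log_pre = np.log2(pre + log_pseudocount)
    log_post = np.log2(post + log_pseudocount)
    diffs = log_post - log_pre
    mean_diff = diffs.mean(axis=1)
    sd_diff = diffs.std(axis=1, ddof=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, pvals = stats.ttest_rel(log_post, log_pre, axis=1)
    pvals = np.asarray(pvals, dtype=float)

    zero_var = sd_diff == 0
    all_zero = zero_var & (mean_diff == 0)
    pvals[all_zero] = 1.0  # identical pre/post: no evidence, not undefined
    pvals[zero_var & ~all_zero] = np.nan

    padj = np.full_like(pvals, np.nan)
    ok = ~np.isnan(pvals)
    if ok.any():
        padj[ok] = bh_adjust(pvals[ok])

    mean_pre = pre.mean(axis=1)
    mean_post = post.mean(axis=1)
    return pd.DataFrame(
        {
            "fold_change": signed_fold_change(mean_pre, mean_post, fc_pseudocount),
            "log2fc": mean_diff,
            "pvalue": pvals,
            "padj": padj,
            "mean_tpm_pre": mean_pre,
            "mean_tpm_post": mean_post,
            "frac_expressed_pre": (pre >= min_tpm).mean(axis=1),
            "frac_expressed_post": (post >= min_tpm).mean(axis=1),
            "zero_variance": zero_var,
        },
        index=tpm.index,
    )


def de_from_external(
    table: pd.DataFrame,
    tpm: pd.DataFrame,
    design: PairedDesign,
    min_tpm: float = DEFAULT_MIN_TPM,
) -> pd.DataFrame:
    """Adapt an external engine's per-feature (log2fc, pvalue) output.

    ``table`` must carry columns ``log2fc`` and ``pvalue`` indexed by
    feature; BH adjustment and the TPM-prevalence columns are recomputed
    here so :func:`de_select` applies unchanged.
    """
    for col in ("log2fc", "pvalue"):
        if col not in table.columns:
            raise ValueError(f"external DE table lacks column {col!r}")
    pre_cols, post_cols = design.paired_columns()
    pre = tpm[pre_cols].reindex(table.index).to_numpy(dtype=float)
    post = tpm[post_cols].reindex(table.index).to_numpy(dtype=float)
    pvals = table["pvalue"].to_numpy(dtype=float)
    padj = np.full_like(pvals, np.nan)
    ok = ~np.isnan(pvals)
    padj[ok] = bh_adjust(pvals[ok])
    ratio = np.power(2.0, table["log2fc"].to_numpy(dtype=float))
    return pd.DataFrame(
        {
            "fold_change": np.where(ratio >= 1, ratio, -1.0 / ratio),
            "log2fc": table["log2fc"].to_numpy(dtype=float),
            "pvalue": pvals,
            "padj": padj,
            "mean_tpm_pre": pre.mean(axis=1),
            "mean_tpm_post": post.mean(axis=1),
            "frac_expressed_pre": (pre >= min_tpm).mean(axis=1),
            "frac_expressed_post": (post >= min_tpm).mean(axis=1),
            "zero_variance": np.isnan(pvals),
        },
        index=table.index,
    )


def de_select(
    result: pd.DataFrame,
    annotated: Optional[Iterable[str]] = None,
    max_adj_p: float = DEFAULT_ADJ_P,
    min_abs_fc: float = DEFAULT_MIN_ABS_FC,
    min_tpm_fraction: float = DEFAULT_MIN_TPM_FRACTION,
    exempt_novel: bool = True,
) -> pd.DataFrame:
    """Apply the high-confidence differential-expression selection rule.

    Keeps features with adjusted p strictly below ``max_adj_p`` and
    |fold change| strictly above ``min_abs_fc``; features in ``annotated``
    must additionally be expressed (>= 0.5 TPM) in at least
    ``min_tpm_fraction`` of samples in *each* group.  Novel features are
    exempt from the prevalence clause unless ``exempt_novel`` is False,
    in which case it applies to every feature.  Returns the input table
    with a boolean ``high_confidence`` column added.
    """
    annotated_set = set(annotated) if annotated is not None else set(result.index)
    out = result.copy()
    sig = (out["padj"] < max_adj_p) & (out["fold_change"].abs() > min_abs_fc)
    prevalent = (out["frac_expressed_pre"] >= min_tpm_fraction) & (
        out["frac_expressed_post"] >= min_tpm_fraction
    )
    if exempt_novel:
        needs_prevalence = out.index.to_series().isin(annotated_set)
    else:
        needs_prevalence = pd.Series(True, index=out.index)
    out["high_confidence"] = sig & (prevalent | ~needs_prevalence)
    out["high_confidence"] = out["high_confidence"].fillna(False)
    return out
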