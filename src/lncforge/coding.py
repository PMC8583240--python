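"""Protein-coding potential scoring for transcripts.

A transcript is scored by a logistic combiner over four sequence features:
longest-ORF length, ORF coverage (ORF length / transcript length), the
Fickett TESTCODE statistic, and a hexamer-usage log-odds score trained on
coding vs noncoding corpora.  This is the classical coding/noncoding
discriminator design; the default decision cutoff is 0.364 (the published
human default for this feature set) and a transcript is called noncoding
when its coding probability falls below the cutoff.

No pretrained weights are shipped: models are trained on synthetic corpora
(see :mod:`lncforge.simulate`) or on user-supplied FASTA, and can be
serialized to JSON.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import statsmodels.api as sm

DEFAULT_CUTOFF = 0.364

FEATURE_NAMES = ("orf_length", "orf_coverage", "fickett", "hexamer")

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")

# Fickett TESTCODE lookup tables (Fickett 1982): probability that a
# sequence with the given position-asymmetry / composition value is coding,
# and the weight of each parameter (its discriminative value in the
# original training data).  Buckets run from the highest parameter value
# (first entry) downward; the last entry covers everything below the final
# threshold.
_POSITION_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_PARAM = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]

_CONTENT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.58, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.61, 0.42, 0.66, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.26, 0.33, 0.29, 0.24, 0.18, 0.26, 0.24, 0.70],
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_PARAM = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17]

ALL_HEXAMERS = ["".join(p) for p in product(_BASES, repeat=6)]


@dataclass(frozen=True)
class OrfCall:
    """A called open reading frame within a transcript sequence."""

    start: int
    end: int
    frame: int
    length_nt: int

    def __post_init__(self) -> None:
        if self.length_nt != self.end - self.start:
            raise ValueError("length_nt must equal end - start")
        if self.length_nt % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")


_SENTINEL_ORF = OrfCall(start=0, end=0, frame=0, length_nt=0)


def find_longest_orf(seq: str) -> OrfCall:
    """Longest ATG-initiated ORF across the three forward frames.

    The ORF runs from an ATG to the first in-frame stop codon (stop
    included) or, if no stop follows, to the last complete codon of the
    sequence.  Ties are broken by smallest start.  With no ATG at all a
    zero-length sentinel is returned.
    """
    s = seq.upper()
    if len(s) < 3:
        raise ValueError("sequence must be at least 3 nt")
    best = _SENTINEL_ORF
    for frame in range(3):
        i = frame
        open_start = None
        while i + 3 <= len(s):
            codon = s[i : i + 3]
            if open_start is None and codon == "ATG":
                open_start = i
            if open_start is not None and codon in _STOPS:
                length = i + 3 - open_start
                if length > best.length_nt or (
                    length == best.length_nt and open_start < best.start
                ):
                    best = OrfCall(open_start, i + 3, frame, length)
                open_start = None
            i += 3
        if open_start is not None:
            end = open_start + ((len(s) - open_start) // 3) * 3
            length = end - open_start
            if length > best.length_nt or (
                length == best.length_nt and open_start < best.start
            ):
                best = OrfCall(open_start, end, frame, length)
    return best


def _lookup(value: float, params: Sequence[float], probs: Sequence[float]) -> float:
    for i, threshold in enumerate(params):
        if value >= threshold:
            return probs[i]
    return probs[len(params)]  # below every threshold: last bucket


def fickett_score(seq: str) -> float:
    """Fickett TESTCODE statistic over position asymmetry and composition.

    For each base, the position parameter is max/(min+1) over its counts in
    the three codon positions and the content parameter is its overall
    fraction; both are converted to coding probabilities through the
    published lookup tables and combined with the published weights.
    Deterministic and case-insensitive; N bases are excluded from content
    fractions.
    """
    s = seq.upper()
    if len(s) < 200:
        warnings.warn("Fickett score is calibrated for sequences >= 200 nt")
    acgt = sum(s.count(b) for b in _BASES)
    if len(s) and (len(s) - acgt) / len(s) > 0.10:
        raise ValueError("more than 10% non-ACGT bases")
    if acgt == 0:
        raise ValueError("sequence contains no ACGT bases")
    score = 0.0
    for base in _BASES:
        counts = [s[offset::3].count(base) for offset in range(3)]
        asymmetry = max(counts) / (min(counts) + 1)
        fraction = s.count(base) / acgt
        score += _lookup(asymmetry, _POSITION_PARAM, _POSITION_PROB[base]) * \
            _POSITION_WEIGHT[base]
        score += _lookup(fraction, _CONTENT_PARAM, _CONTENT_PROB[base]) * \
            _CONTENT_WEIGHT[base]
    return score


@dataclass
class HexamerTable:
    """Per-hexamer log-odds log(f_coding / f_noncoding) over all 4096 hexamers."""

    log_odds: Dict[str, float]
    pseudocount: float

    def __post_init__(self) -> None:
        if len(self.log_odds) != 4096:
            raise ValueError("hexamer table must cover all 4096 hexamers")
        if not all(np.isfinite(list(self.log_odds.values()))):
            raise ValueError("hexamer log-odds must be finite")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"format": "lncforge.hexamer/1", "pseudocount": self.pseudocount,
                 "log_odds": self.log_odds},
                fh,
            )

    @classmethod
    def from_json(cls, path: str) -> "HexamerTable":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(log_odds=payload["log_odds"], pseudocount=payload["pseudocount"])


def _hexamer_counts(seqs: Iterable[str], step: int, in_orf: bool) -> Dict[str, float]:
    counts = dict.fromkeys(ALL_HEXAMERS, 0.0)
    for seq in seqs:
        s = seq.upper()
        if in_orf:
            orf = find_longest_orf(s)
            if orf.length_nt >= 6:
                s = s[orf.start : orf.end]
        for i in range(0, len(s) - 5, step):
            h = s[i : i + 6]
            if "N" not in h and set(h) <= set(_BASES):
                counts[h] += 1.0
    return counts


def train_hexamer_table(
    coding: Sequence[str],
    noncoding: Sequence[str],
    pseudocount: float = 1.0,
) -> HexamerTable:
    """Hexamer log-odds from in-frame coding ORF usage vs noncoding background.

    Coding frequencies come from in-frame (step 3) hexamers of each
    sequence's longest ORF; noncoding from every-frame (step 1) hexamers of
    the whole sequence.  A shared pseudocount keeps the log-odds finite and
    symmetric: a hexamer absent from both corpora scores 0.
    """
    if len(coding) < 10 or len(noncoding) < 10:
        raise ValueError("need at least 10 sequences per class")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    cod = _hexamer_counts(coding, step=3, in_orf=True)
    non = _hexamer_counts(noncoding, step=1, in_orf=False)
    # symmetric pseudo-frequency: counts are normalized to frequencies
    # first and the pseudocount is added as the frequency it would have in
    # a uniform table, so a hexamer absent from both corpora scores 0
    cod_total = max(sum(cod.values()), 1.0)
    non_total = max(sum(non.values()), 1.0)
    p_frac = pseudocount / 4096.0
    log_odds = {
        h: float(
            np.log(cod[h] / cod_total + p_frac)
            - np.log(non[h] / non_total + p_frac)
        )
        for h in ALL_HEXAMERS
    }
    return HexamerTable(log_odds=log_odds, pseudocount=pseudocount)


def hexamer_score(seq: str, table: HexamerTable) -> float:
    """Mean log-odds over in-frame hexamers of the longest ORF.

    Falls back to frame-0 hexamers of the whole sequence when the
    transcript has no ORF.  Hexamers containing non-ACGT characters are
    skipped; with no scorable hexamer the score is 0.
    """
    s = seq.upper()
    if len(s) < 6:
        raise ValueError("sequence must be at least 6 nt")
    orf = find_longest_orf(s) if len(s) >= 3 else _SENTINEL_ORF
    window = s[orf.start : orf.end] if orf.length_nt >= 6 else s
    values = [
        table.log_odds[window[i : i + 6]]
        for i in range(0, len(window) - 5, 3)
        if set(window[i : i + 6]) <= set(_BASES)
    ]
    return float(np.mean(values)) if values else 0.0


@dataclass
class CodingModel:
    """Logistic model over (orf_length, orf_coverage, fickett, hexamer)."""

    coefficients: np.ndarray
    intercept: float
    cutoff: float = DEFAULT_CUTOFF
    feature_names: Tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (4,):
            raise ValueError("coefficient vector must have length 4")
        if not 0.0 < self.cutoff < 1.0:
            raise ValueError("cutoff must lie in (0, 1)")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "format": "lncforge.coding_model/1",
                    "feature_names": list(self.feature_names),
                    "coefficients": self.coefficients.tolist(),
                    "intercept": self.intercept,
                    "cutoff": self.cutoff,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path: str) -> "CodingModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            coefficients=np.asarray(payload["coefficients"]),
            intercept=payload["intercept"],
            cutoff=payload["cutoff"],
            feature_names=tuple(payload["feature_names"]),
        )


def sequence_features(seq: str, table: HexamerTable) -> np.ndarray:
    """The four-feature vector for one transcript sequence."""
    orf = find_longest_orf(seq)
    length = len(seq)
    return np.array(
        [
            float(orf.length_nt),
            orf.length_nt / length if length else 0.0,
            fickett_score(seq),
            hexamer_score(seq, table),
        ]
    )


def train_logistic(features: np.ndarray, labels: Sequence[int]) -> CodingModel:
    """Maximum-likelihood logistic fit of coding (1) vs noncoding (0).

    Fit by iteratively reweighted least squares; on (quasi-)perfect
    separation the fit falls back to a ridge-stabilized solution with a
    warning, since the unpenalized MLE then diverges.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if X.ndim != 2 or X.shape[1] != 4:
        raise ValueError("features must be an (n, 4) array")
    if len(y) != X.shape[0] or len(y) < 40:
        raise ValueError("need n >= 40 labelled sequences")
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("both classes must be present")
    # standardize for numerical stability; coefficients mapped back below
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    design = sm.add_constant(Z, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            fit = sm.Logit(y, design).fit(disp=False, maxiter=100, tol=1e-8)
        params = fit.params
    except Exception:
        warnings.warn(
            "perfect or quasi-perfect separation; using ridge-stabilized fit"
        )
        params = _ridge_logistic_irls(design, y, alpha=1e-2)
    beta_std = params[1:]
    beta = beta_std / sd
    intercept = float(params[0] - np.sum(beta_std * mu / sd))
    return CodingModel(coefficients=beta, intercept=intercept)


def _ridge_logistic_irls(
    design: np.ndarray, y: np.ndarray, alpha: float, max_iter: int = 100,
    tol: float = 1e-8,
) -> np.ndarray:
    """L2-penalized logistic IRLS (intercept unpenalized); always converges."""
    n, p = design.shape
    penalty = alpha * np.eye(p)
    penalty[0, 0] = 0.0
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = np.clip(design @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        grad = design.T @ (y - mu) - penalty @ beta
        hess = (design * w[:, None]).T @ design + penalty
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def coding_probability(
    seq: str, model: CodingModel, table: HexamerTable
) -> float:
    """Coding probability of one sequence; noncoding iff below the cutoff."""
    x = sequence_features(seq, table)
    z = np.clip(model.intercept + float(np.dot(model.coefficients, x)), -500, 500)
    return float(1.0 / (1.0 + np.exp(-z)))


def is_noncoding(seq: str, model: CodingModel, table: HexamerTable) -> bool:
    return coding_probability(seq, model, table) < model.cutoff
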