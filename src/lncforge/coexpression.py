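"""Unsigned weighted co-expression network analysis.

Genes are connected by the adjacency a_ij = |cor(x_i, x_j)|^beta with the
soft power beta chosen for approximate scale-free topology.  The
topological overlap matrix (TOM) combines direct adjacency with shared
neighbourhoods; average-linkage clustering of 1 - TOM with a static cut
yields modules.  Each module is summarized by its eigengene (first
principal component of member expression), eigengenes are correlated with
a sample trait, and a gene's module membership (kME) — its correlation
with a module eigengene — flags intramodular hub genes.

Module labels: 0 is the unassigned pool; labels 1, 2, ... are assigned by
decreasing module size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

DEFAULT_CUT_HEIGHT = 0.99
DEFAULT_MIN_MODULE_SIZE = 30
DEFAULT_KME_THRESHOLD = 0.7
DEFAULT_SOFT_POWERS = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20)
FALLBACK_POWER = 6


def _drop_constant(expr: pd.DataFrame) -> pd.DataFrame:
    sd = expr.std(axis=1, ddof=0)
    constant = sd[sd == 0].index
    if len(constant):
        logger.warning("removing %d constant-expression genes", len(constant))
        expr = expr.drop(index=constant)
    return expr


def correlation_matrix(expr: pd.DataFrame) -> np.ndarray:
    """Pearson correlation between gene rows (samples are observations)."""
    return np.corrcoef(expr.to_numpy(dtype=float))


def adjacency(expr: pd.DataFrame, beta: int) -> np.ndarray:
    """Unsigned adjacency |cor|^beta with unit diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    expr = _drop_constant(expr)
    a = np.abs(correlation_matrix(expr)) ** beta
    np.fill_diagonal(a, 1.0)
    return np.clip(a, 0.0, 1.0)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10 p(k) vs log10 mean-k over connectivity bins.

    The signature of scale-free topology is an approximately linear
    log-log degree distribution; R^2 of that line measures the fit.
    """
    k = np.asarray(connectivity, dtype=float)
    if k.size < 2 or np.allclose(k.max(), k.min()):
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        mean_k = k[mask].mean()
        freq = mask.mean()
        if mean_k > 0 and freq > 0:
            xs.append(np.log10(mean_k))
            ys.append(np.log10(freq))
    if len(xs) < 3:
        return 0.0
    fit = stats.linregress(xs, ys)
    return float(fit.rvalue ** 2)


def pick_soft_threshold(
    expr: pd.DataFrame,
    powers: Sequence[int] = DEFAULT_SOFT_POWERS,
    r2_target: float = 0.8,
) -> Tuple[int, pd.DataFrame]:
    """Smallest power whose network is approximately scale-free.

    Returns (beta, diagnostics table with per-power R^2 and mean
    connectivity).  With a single candidate power it is returned as-is;
    if no power reaches ``r2_target`` the fallback beta = 6 is used with
    a warning.
    """
    expr = _drop_constant(expr)
    if expr.shape[1] < 8:
        raise ValueError("need at least 8 samples")
    if len(powers) == 1:
        only = int(powers[0])
        return only, pd.DataFrame({"power": [only], "r_squared": [np.nan],
                                   "mean_connectivity": [np.nan]})
    cor = np.abs(correlation_matrix(expr))
    np.fill_diagonal(cor, 0.0)
    rows = []
    chosen: Optional[int] = None
    for power in powers:
        a = cor ** power
        k = a.sum(axis=1)
        r2 = scale_free_fit(k)
        rows.append({"power": power, "r_squared": r2,
                     "mean_connectivity": float(k.mean())})
        if chosen is None and r2 >= r2_target:
            chosen = int(power)
    if chosen is None:
        logger.warning(
            "no candidate power reached scale-free R^2 >= %.2f; "
            "falling back to beta = %d", r2_target, FALLBACK_POWER,
        )
        chosen = FALLBACK_POWER
    return chosen, pd.DataFrame(rows)


def topological_overlap(a: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    the shared-neighbour sum excluding u in {i, j} and
    k_i = sum_{u != i} a_iu; the diagonal is set to 1.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    off = a.copy()
    np.fill_diagonal(off, 0.0)
    k = off.sum(axis=1)
    shared = off @ off  # (shared)_ij = sum_u a_iu a_uj over u != i, j on off-diag
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (shared + off) / (kmin + 1.0 - off)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def detect_modules(
    tom: np.ndarray,
    gene_ids: Sequence[str],
    min_size: int = DEFAULT_MIN_MODULE_SIZE,
    cut_height: float = DEFAULT_CUT_HEIGHT,
) -> pd.Series:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    Clusters smaller than ``min_size`` fall into module 0 (unassigned);
    surviving modules are labelled 1, 2, ... by decreasing size (ties by
    first gene appearance, so the labelling is deterministic).
    """
    n = tom.shape[0]
    if n != len(gene_ids):
        raise ValueError("gene_ids length must match TOM size")
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # enforce exact symmetry
    tree = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(tree, t=cut_height, criterion="distance")
    assignment = np.zeros(n, dtype=int)
    sizes = []
    for label in np.unique(raw):
        members = np.flatnonzero(raw == label)
        if len(members) >= min_size:
            sizes.append((len(members), members[0], members))
    if not sizes:
        logger.warning("no cluster reached min_size=%d; all genes unassigned",
                       min_size)
    sizes.sort(key=lambda item: (-item[0], item[1]))
    for new_label, (_, _, members) in enumerate(sizes, start=1):
        assignment[members] = new_label
    return pd.Series(assignment, index=list(gene_ids), name="module")


def module_eigengene(
    expr: pd.DataFrame, members: Sequence[str]
) -> Tuple[pd.Series, float]:
    """First principal component of the member x sample matrix.

    Genes are standardized first; the eigengene is scaled to unit
    variance and its sign oriented so it correlates positively with the
    mean member expression profile.  Returns (eigengene over samples,
    fraction of variance explained).
    """
    members = list(members)
    if len(members) < 2:
        raise ValueError("a module needs at least 2 members")
    x = expr.loc[members].to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    pc1 = vt[0]
    explained = float(s[0] ** 2 / np.sum(s ** 2))
    mean_profile = z.mean(axis=0)
    if np.dot(pc1, mean_profile) < 0:
        pc1 = -pc1
    pc1 = pc1 / pc1.std(ddof=0)
    return pd.Series(pc1, index=expr.columns, name="eigengene"), explained


def eigengene_matrix(
    expr: pd.DataFrame, assignment: pd.Series
) -> pd.DataFrame:
    """Eigengenes for every non-zero module, one column per module label."""
    cols = {}
    for label in sorted(set(assignment) - {0}):
        members = assignment.index[assignment == label]
        eg, _ = module_eigengene(expr, members)
        cols[label] = eg
    return pd.DataFrame(cols, index=expr.columns)


def module_trait_correlation(
    eigengenes: pd.DataFrame, trait: Sequence[float]
) -> pd.DataFrame:
    """Pearson correlation of each eigengene with a sample trait.

    Two-sided p from the t distribution with n - 2 degrees of freedom.
    """
    trait = np.asarray(trait, dtype=float)
    if len(trait) != eigengenes.shape[0]:
        raise ValueError("trait length must match number of samples")
    if np.std(trait) == 0:
        raise ValueError("trait has zero variance")
    rows = []
    for label in eigengenes.columns:
        pcc, p = stats.pearsonr(eigengenes[label].to_numpy(), trait)
        rows.append({"module": label, "pcc": float(pcc), "pvalue": float(p)})
    return pd.DataFrame(rows)


def module_membership(
    expr: pd.DataFrame, eigengenes: pd.DataFrame
) -> pd.DataFrame:
    """kME: correlation of every gene with every module eigengene."""
    x = expr.to_numpy(dtype=float)
    xz = (x - x.mean(axis=1, keepdims=True))
    xsd = x.std(axis=1, ddof=0, keepdims=True)
    xsd[xsd == 0] = np.inf  # constant gene: kME 0
    xz = xz / xsd
    e = eigengenes.to_numpy(dtype=float).T
    ez = (e - e.mean(axis=1, keepdims=True)) / e.std(axis=1, ddof=0, keepdims=True)
    kme = (xz @ ez.T) / x.shape[1]
    return pd.DataFrame(kme, index=expr.index, columns=eigengenes.columns)


def hub_genes(
    kme: pd.DataFrame,
    assignment: pd.Series,
    threshold: float = DEFAULT_KME_THRESHOLD,
    restrict_to: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Genes whose kME in their own module strictly exceeds ``threshold``.

    ``restrict_to`` (typically the differentially expressed set) limits
    hub calling to those genes, mirroring module filtering before hub
    reporting.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    allowed = set(restrict_to) if restrict_to is not None else None
    rows = []
    for gene, label in assignment.items():
        if label == 0 or gene not in kme.index or label not in kme.columns:
            continue
        if allowed is not None and gene not in allowed:
            continue
        value = kme.at[gene, label]
        if value > threshold:
            rows.append({"gene_id": gene, "module": label, "kme": float(value)})
    return pd.DataFrame(rows, columns=["gene_id", "module", "kme"])


def export_edge_list(
    tom: np.ndarray, gene_ids: Sequence[str], path: str,
    min_weight: float = 0.0,
) -> None:
    """TSV edge list (gene_i, gene_j, tom) for external graph viewers."""
    ids = list(gene_ids)
    with open(path, "w") as fh:
        fh.write("gene_i\tgene_j\ttom\n")
        n = len(ids)
        for i in range(n):
            for j in range(i + 1, n):
                if tom[i, j] >= min_weight:
                    fh.write(f"{ids[i]}\t{ids[j]}\t{tom[i, j]:.6g}\n")
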