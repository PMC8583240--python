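"""Deterministic synthetic-data generators with planted ground truth.

Every input the discovery pipeline consumes can be generated here:
reference and candidate annotations with planted class codes, coding and
noncoding transcript sequences, per-base conservation tracks, paired
pre/post expression with planted differential features, co-expression
modules and hubs, and cis-eQTL SNP tables.  Generators are
bit-reproducible given a seed; each generator draws from its own RNG
stream derived from the master seed by a stable label, so adding one
generator never perturbs another.

:func:`simulate_study` assembles a full coherent study on disk, emulating
a paired-ischemia cohort profiled with a short-read platform (platform A,
with per-sample counts) and an independent long-read platform (platform
B) used for structural validation.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .expression import PairedDesign
from .models import AnnotationCatalog, GenomicInterval, TranscriptModel

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = ["".join((a, b, c)) for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_SENSE_CODONS = [c for c in _CODONS if c not in _STOPS]

# Codon usage for synthetic coding ORFs, built as a product of per-codon-
# position base profiles.  The profiles are solved so that after stop-codon
# removal the within-codon position asymmetry (max/min base frequency across
# the three codon positions) is A 1.45, C 1.35, G 1.75, T 1.75 — values that
# sit mid-bucket in coding-favourable regions of the published TESTCODE
# position lookup tables, whereas a dinucleotide shuffle of the same
# sequence has asymmetry near 1.  The non-uniform codon distribution also
# carries the in-frame hexamer signal that real ORFs show.
_POSITION_PROFILE = {
    "A": (1.2000, 1.5397, 0.9418),
    "C": (1.1000, 1.4345, 0.9411),
    "G": (1.6756, 1.0444, 1.3200),
    "T": (1.1474, 1.3200, 1.5252),
}


def _coding_codon_p() -> np.ndarray:
    m = np.array([_POSITION_PROFILE[b] for b in "ACGT"])
    m = m / m.sum(axis=0, keepdims=True)
    pos = {b: i for i, b in enumerate("ACGT")}
    w = np.array([
        m[pos[c[0]], 0] * m[pos[c[1]], 1] * m[pos[c[2]], 2]
        for c in _SENSE_CODONS
    ])
    return w / w.sum()


_CODING_CODON_P = _coding_codon_p()

DEFAULT_CLASS_PARAMS = {
    "mRNA": (8.0, 2.0),
    "lncRNA": (2.0, 8.0),
    "novel": (2.0, 8.0),
    None: (2.0, 8.0),
}


def rng_stream(seed: int, label: str) -> np.random.Generator:
    """An RNG stream derived from (seed, label); stable across runs."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode())])
    )


# ---------------------------------------------------------------------------
# annotations


def generate_reference(
    n_genes: int = 50,
    chrom_sizes: Optional[Mapping[str, int]] = None,
    seed: int = 0,
    p_single_exon: float = 0.2,
    p_lncrna: float = 0.3,
) -> AnnotationCatalog:
    """Non-overlapping multi- and single-exon genes on both strands.

    Genes are laid left to right with generous intergenic gaps; introns
    are wide enough to host intronic candidates.  Raises when the
    chromosomes cannot hold the requested gene count.
    """
    chrom_sizes = dict(chrom_sizes or {"chr1": 2_000_000, "chr2": 2_000_000})
    rng = rng_stream(seed, "reference")
    catalog = AnnotationCatalog()
    chroms = sorted(chrom_sizes)
    cursors = {c: 10_000 for c in chroms}
    placed = 0
    chrom_cycle = 0
    attempts = 0
    while placed < n_genes:
        attempts += 1
        if attempts > n_genes * 10:
            raise ValueError("chromosomes too small for requested gene count")
        chrom = chroms[chrom_cycle % len(chroms)]
        chrom_cycle += 1
        strand = "+" if rng.random() < 0.5 else "-"
        single = rng.random() < p_single_exon
        start = cursors[chrom]
        exons = []
        if single:
            length = int(rng.integers(200, 401))
            exons.append(GenomicInterval(chrom, start, start + length, strand))
        else:
            n_exons = int(rng.integers(2, 6))
            pos = start
            for k in range(n_exons):
                exon_len = int(rng.integers(120, 301))
                exons.append(GenomicInterval(chrom, pos, pos + exon_len, strand))
                if k < n_exons - 1:
                    pos += exon_len + int(rng.integers(1500, 2501))
                else:
                    pos += exon_len
        end = exons[-1].end
        if end + 12_000 > chrom_sizes[chrom]:
            continue  # try another chromosome slot
        cursors[chrom] = end + int(rng.integers(6000, 12_001))
        biotype = "lncRNA" if (single or rng.random() < p_lncrna) else "mRNA"
        catalog.add(
            TranscriptModel(
                transcript_id=f"REF.T{placed + 1}",
                gene_id=f"REF.G{placed + 1}",
                exons=exons,
                biotype=biotype,
            )
        )
        placed += 1
    return catalog


def _gene_spans(ref: AnnotationCatalog) -> Dict[str, List[TranscriptModel]]:
    by_chrom: Dict[str, List[TranscriptModel]] = {}
    for t in ref:
        by_chrom.setdefault(t.chrom, []).append(t)
    for ts in by_chrom.values():
        ts.sort(key=lambda t: t.start)
    return by_chrom


def _gaps(ref: AnnotationCatalog, margin: int = 800) -> List[Tuple[str, int, int]]:
    """Intergenic windows (chrom, start, end) clear of every gene span."""
    gaps = []
    for chrom, ts in _gene_spans(ref).items():
        prev = 1000
        for t in ts:
            if t.start - margin > prev + margin:
                gaps.append((chrom, prev + margin, t.start - margin))
            prev = max(prev, t.end)
        gaps.append((chrom, prev + margin, prev + margin + 200_000))
    gaps.sort()
    return gaps


class _GapAllocator:
    """Hands out disjoint windows from the intergenic gaps of a reference."""

    def __init__(self, ref: AnnotationCatalog) -> None:
        self.gaps = _gaps(ref)

    def take(self, width: int, chrom: Optional[str] = None) -> Tuple[str, int]:
        for i, (c, s, e) in enumerate(self.gaps):
            if chrom is not None and c != chrom:
                continue
            if e - s >= width + 200:
                self.gaps[i] = (c, s + width + 200, e)
                return c, s
        raise ValueError("reference has no intergenic gap wide enough")


def _two_exon(
    chrom: str, start: int, strand: str, exon_len: int = 250, intron_len: int = 500
) -> List[GenomicInterval]:
    return [
        GenomicInterval(chrom, start, start + exon_len, strand),
        GenomicInterval(
            chrom, start + exon_len + intron_len,
            start + 2 * exon_len + intron_len, strand,
        ),
    ]


def generate_candidates(
    ref: AnnotationCatalog,
    plan: Mapping[str, int],
    seed: int = 0,
    jitter: int = 50,
    id_prefix: str = "CAND",
) -> Tuple[AnnotationCatalog, Dict[str, str]]:
    """Candidates constructed geometrically to satisfy planted class codes.

    Supported plan keys: ``=`` (intron-chain copies of reference
    transcripts with jittered terminal exons), ``u`` (intergenic), ``i``
    (inside a reference intron), ``x`` (antisense exonic overlap), ``y``
    (a small reference gene inside the candidate's intron).  Returns the
    candidate catalog and the planted truth (transcript id -> code).
    """
    rng = rng_stream(seed, "candidates")
    alloc = _GapAllocator(ref)
    ref_list = list(ref)
    multi = [t for t in ref_list if t.is_multi_exonic()]
    with_wide_intron = [
        t for t in multi
        if any(b.start - a.end >= 1600 for a, b in zip(t.exons, t.exons[1:]))
    ]
    small = [t for t in ref_list if t.end - t.start <= 600]

    catalog = AnnotationCatalog()
    truth: Dict[str, str] = {}
    counter = 0

    def _add(exons, code):
        nonlocal counter
        counter += 1
        tid = f"{id_prefix}.{counter}"
        catalog.add(
            TranscriptModel(
                transcript_id=tid, gene_id=f"{id_prefix}.G{counter}", exons=exons
            )
        )
        truth[tid] = code

    for _ in range(int(plan.get("=", 0))):
        if not multi:
            raise ValueError("'=' requested but reference has no multi-exon gene")
        t = multi[int(rng.integers(len(multi)))]
        exons = [GenomicInterval(e.chrom, e.start, e.end, e.strand) for e in t.exons]
        if jitter:
            d0 = int(rng.integers(-jitter, jitter + 1))
            d1 = int(rng.integers(-jitter, jitter + 1))
            first, last = exons[0], exons[-1]
            new_start = min(max(1, first.start + d0), first.end - 20)
            new_end = max(last.end + d1, last.start + 20)
            exons[0] = GenomicInterval(first.chrom, new_start, first.end, first.strand)
            exons[-1] = GenomicInterval(last.chrom, last.start, new_end, last.strand)
        _add(exons, "=")

    for _ in range(int(plan.get("u", 0))):
        exon_len = int(rng.integers(200, 301))
        intron_len = int(rng.integers(400, 801))
        chrom, start = alloc.take(2 * exon_len + intron_len)
        strand = "+" if rng.random() < 0.5 else "-"
        _add(_two_exon(chrom, start, strand, exon_len, intron_len), "u")

    for k in range(int(plan.get("i", 0))):
        if not with_wide_intron:
            raise ValueError("'i' requested but reference has no wide intron")
        host = with_wide_intron[k % len(with_wide_intron)]
        wide = [
            (a.end, b.start) for a, b in zip(host.exons, host.exons[1:])
            if b.start - a.end >= 1600
        ]
        lo, hi = wide[int(rng.integers(len(wide)))]
        exon_len, intron_len = 150, 300
        width = 2 * exon_len + intron_len
        start = int(rng.integers(lo + 100, hi - width - 100))
        strand = "+" if rng.random() < 0.5 else "-"
        _add(_two_exon(host.chrom, start, strand, exon_len, intron_len), "i")

    for k in range(int(plan.get("x", 0))):
        targets = [t for t in multi if len(t.exons[0]) >= 150]
        if not targets:
            raise ValueError("'x' requested but no reference exon is wide enough")
        host = targets[k % len(targets)]
        anti = "-" if host.strand == "+" else "+"
        ref_exon = host.exons[0]
        # first exon straddles the reference exon's start; second sits in
        # the first intron of the same gene, so the candidate stays inside
        # the host span and cannot swallow another reference gene.
        e1 = GenomicInterval(host.chrom, max(1, ref_exon.start - 120),
                             ref_exon.start + 100, anti)
        intron_lo, intron_hi = ref_exon.end, host.exons[1].start
        e2_start = intron_lo + 200
        e2 = GenomicInterval(host.chrom, e2_start, e2_start + 180, anti)
        _add([e1, e2], "x")

    for _ in range(int(plan.get("y", 0))):
        if not small:
            raise ValueError("'y' requested but reference has no small gene")
        # find a small gene flanked by wide gaps
        target = None
        for t in small:
            left = [g for g in alloc.gaps if g[0] == t.chrom
                    and g[2] <= t.start and g[2] - g[1] >= 600]
            right = [g for g in alloc.gaps if g[0] == t.chrom
                     and g[1] >= t.end and g[2] - g[1] >= 600]
            if left and right:
                target = (t, left[-1], right[0])
                break
        if target is None:
            raise ValueError("'y' requested but no small gene has flanking room")
        t, left, right = target
        e1 = GenomicInterval(t.chrom, left[2] - 500, left[2] - 200, "+")
        e2 = GenomicInterval(t.chrom, right[1] + 200, right[1] + 500, "+")
        alloc.gaps.remove(left)
        alloc.gaps.remove(right)
        small.remove(t)
        _add([e1, e2], "y")

    return catalog, truth


# ---------------------------------------------------------------------------
# sequences


def generate_coding_sequence(length: int, rng: np.random.Generator) -> str:
    """A transcript dominated by one codon-biased ORF (~90% coverage)."""
    n_codons = max(10, int(length * 0.9) // 3)
    codons = rng.choice(_SENSE_CODONS, size=n_codons, p=_CODING_CODON_P)
    orf = "ATG" + "".join(codons) + "TAA"
    utr5 = "".join(rng.choice(_BASES, size=max(0, (length - len(orf)) // 2)))
    utr3 = "".join(rng.choice(_BASES, size=max(0, length - len(orf) - len(utr5))))
    return utr5 + orf + utr3


def generate_noncoding_sequence(
    length: int,
    rng: np.random.Generator,
    max_orf_coverage: float = 0.5,
) -> str:
    """A noncoding sequence: dinucleotide-preserving shuffle of a fresh
    coding draw, composition-matched to the coding class.

    Short shuffles occasionally carry a long chance ORF, which is a coding
    signal a noncoding transcript should not plant, so the shuffle is
    redrawn (up to 100 times) until no ORF covers more than
    ``max_orf_coverage`` of the sequence.  Every draw is still an exact
    dinucleotide-preserving shuffle.
    """
    from .coding import find_longest_orf

    src = generate_coding_sequence(max(60, length), rng)
    out = src
    for _ in range(100):
        out = dinucleotide_shuffle(src, rng)
        if find_longest_orf(out).length_nt <= max_orf_coverage * len(out):
            break
    return out


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Exact dinucleotide-preserving shuffle (Eulerian-walk construction).

    Base and dinucleotide counts of the output equal the input's exactly,
    so GC content is preserved while ORF and hexamer structure dissolve.
    """
    s = seq.upper()
    if len(s) < 3:
        return s
    edges: Dict[str, List[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    last = s[-1]
    vertices = sorted(edges)
    for _ in range(1000):
        # pick a candidate final edge per vertex; they must form a tree into
        # the terminal vertex for an Eulerian walk to exist
        final = {
            v: edges[v][int(rng.integers(len(edges[v])))]
            for v in vertices if v != last
        }
        ok = True
        for v in final:
            seen, cur = set(), v
            while cur != last and cur in final and cur not in seen:
                seen.add(cur)
                cur = final[cur]
            if cur != last:
                ok = False
                break
        if ok:
            break
    else:  # pragma: no cover - tiny alphabet, never reached in practice
        return s
    shuffled: Dict[str, List[str]] = {}
    for v in vertices:
        pool = list(edges[v])
        if v != last:
            pool.remove(final[v])
        rng.shuffle(pool)
        if v != last:
            pool.append(final[v])
        shuffled[v] = pool
    out = [s[0]]
    cursors = {v: 0 for v in vertices}
    cur = s[0]
    for _ in range(len(s) - 1):
        nxt = shuffled[cur][cursors[cur]]
        cursors[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def generate_sequences(
    catalog: AnnotationCatalog,
    coding_fraction: float,
    seed: int = 0,
    min_length: int = 300,
) -> Tuple[Dict[str, str], Dict[str, str]]:
    """One sequence per transcript with planted coding/noncoding labels.

    Coding sequences carry a long codon-biased ORF; noncoding sequences
    are dinucleotide-preserving shuffles of freshly generated coding
    sequence, so base composition matches between the classes.
    """
    rng = rng_stream(seed, "sequences")
    seqs: Dict[str, str] = {}
    labels: Dict[str, str] = {}
    for t in catalog:
        length = max(min_length, sum(len(e) for e in t.exons))
        if rng.random() < coding_fraction:
            seqs[t.transcript_id] = generate_coding_sequence(length, rng)
            labels[t.transcript_id] = "coding"
        else:
            seqs[t.transcript_id] = generate_noncoding_sequence(length, rng)
            labels[t.transcript_id] = "noncoding"
    return seqs, labels


def generate_training_corpus(
    n_coding: int,
    n_noncoding: int,
    seed: int = 0,
    length_range: Tuple[int, int] = (400, 1500),
) -> Tuple[List[str], List[str]]:
    """Coding / noncoding sequence corpora for model training."""
    rng = rng_stream(seed, "training-corpus")
    lo, hi = length_range
    coding = [
        generate_coding_sequence(int(rng.integers(lo, hi + 1)), rng)
        for _ in range(n_coding)
    ]
    noncoding = [
        generate_noncoding_sequence(int(rng.integers(lo, hi + 1)), rng)
        for _ in range(n_noncoding)
    ]
    return coding, noncoding


def write_fasta(seqs: Mapping[str, str], path: str) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    seqio_write(records, path, "fasta")


def read_fasta(path: str) -> Dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


# ---------------------------------------------------------------------------
# conservation


def generate_conservation_track(
    catalog: AnnotationCatalog,
    class_params: Optional[Mapping[Optional[str], Tuple[float, float]]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-base Beta-distributed conservation over every exon of the catalog.

    Scores are drawn Beta(alpha, beta) with parameters chosen by the
    transcript's biotype (coding exons conserved, noncoding not), and
    adjacent equal-valued bases merged into bedGraph intervals.
    """
    params = dict(DEFAULT_CLASS_PARAMS)
    if class_params:
        params.update(class_params)
    rng = rng_stream(seed, "conservation")
    rows = []
    covered: Dict[str, List[Tuple[int, int]]] = {}
    for t in catalog:
        a, b = params.get(t.biotype, params[None])
        for exon in t.exons:
            # emit only bases not already covered by an earlier exon, so
            # overlapping exons never yield overlapping bedGraph rows
            segments = [(exon.start, exon.end)]
            for cs, ce in covered.get(exon.chrom, []):
                segments = [
                    part
                    for s, e in segments
                    for part in ((s, min(e, cs)), (max(s, ce), e))
                    if part[0] < part[1]
                ]
            covered.setdefault(exon.chrom, []).append((exon.start, exon.end))
            for seg_start, seg_end in segments:
                values = np.round(rng.beta(a, b, size=seg_end - seg_start), 3)
                # run-length encode equal neighbours
                change = np.flatnonzero(np.diff(values)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [len(values)]))
                for s, e in zip(starts, ends):
                    rows.append(
                        (exon.chrom, seg_start + int(s), seg_start + int(e),
                         float(values[s]))
                    )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    return df.sort_values(["chrom", "start"], ignore_index=True)


def write_bedgraph(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# expression


@dataclass
class ModulePlan:
    """A planted co-expression module.

    ``loading`` is the latent-factor loading of ordinary members,
    ``hub_loading`` that of the first ``n_hubs`` members; ``trait_corr``
    correlates the module's latent factor with the pre/post trait.
    ``members`` may name the member features explicitly (otherwise the
    next ``size`` features are taken in order); ``loadings`` may give a
    per-member loading overriding the loading/hub_loading scheme.
    """

    size: int
    loading: float = 0.85
    trait_corr: float = 0.0
    n_hubs: int = 0
    hub_loading: float = 0.95
    members: Optional[Sequence[str]] = None
    loadings: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        if self.members is not None and len(self.members) != self.size:
            raise ValueError("members must have length == size")
        if self.loadings is not None and len(self.loadings) != self.size:
            raise ValueError("loadings must have length == size")


@dataclass
class ExpressionFixture:
    counts: pd.DataFrame
    tpm: pd.DataFrame
    log_expr: pd.DataFrame  # planted log2-scale expression (pre-normalization)
    design: PairedDesign
    truth: Dict


def generate_expression(
    n_features: int = 500,
    n_pairs: int = 40,
    seed: int = 0,
    de_plan: Optional[Mapping[str, float]] = None,
    module_plan: Sequence[ModulePlan] = (),
    sigma: float = 0.25,
    depth: float = 2e6,
    feature_ids: Optional[Sequence[str]] = None,
    base_log2_mean: float = 8.0,
    base_log2_sd: float = 1.0,
    counts_model: str = "poisson",
    nb_dispersion: float = 0.1,
    pair_plan: Optional[Sequence[Tuple[str, str, float]]] = None,
    baseline_log2: Optional[Mapping[str, float]] = None,
    de_noise_sd: Optional[float] = None,
) -> ExpressionFixture:
    """Paired pre/post expression with planted effects and modules.

    Per feature g and sample s, log2 x_gs = baseline_g + structure + noise:
    module members follow loading * latent + sqrt(1 - loading^2) * noise
    (unit variance on the log2 scale); other features get N(0, sigma^2)
    noise; features in ``de_plan`` have log2(effect) added to their post
    samples.  TPM is the column-normalized linear expression; counts are
    Poisson (or negative binomial) draws at the given depth.

    ``baseline_log2`` pins the log2 baseline of named features.  Because
    TPM is compositional, features whose mean shifts with the condition
    (module members with a trait correlation, de_plan features) should be
    kept a small fraction of total library mass, or the per-sample
    normalization factor itself tracks the condition and leaks a common
    trait-correlated component into every feature.

    ``de_noise_sd`` sets the noise level of non-module de_plan features.
    They model genes responding through pathways other than the planted
    modules, so they need inter-individual variability of their own:
    with only the small background ``sigma`` they would form a tight
    trait-driven cluster that bridges the planted modules in a
    co-expression network.
    """
    if n_pairs < 3:
        raise ValueError("need n_pairs >= 3")
    rng = rng_stream(seed, "expression")
    if feature_ids is None:
        feature_ids = [f"G{i + 1:04d}" for i in range(n_features)]
    feature_ids = list(feature_ids)
    n_features = len(feature_ids)
    if sum(m.size for m in module_plan) > n_features:
        raise ValueError("module sizes exceed feature count")
    de_plan = dict(de_plan or {})
    unknown = set(de_plan) - set(feature_ids)
    if unknown:
        raise ValueError(f"de_plan names unknown features: {sorted(unknown)[:5]}")

    subjects = [f"P{i + 1:03d}" for i in range(n_pairs)]
    samples = [f"{s}_pre" for s in subjects] + [f"{s}_post" for s in subjects]
    trait = np.array([0.0] * n_pairs + [1.0] * n_pairs)
    trait_z = (trait - trait.mean()) / trait.std()

    baseline = rng.normal(base_log2_mean, base_log2_sd, size=n_features)
    index_of = {g: i for i, g in enumerate(feature_ids)}
    for gene, value in (baseline_log2 or {}).items():
        if gene not in index_of:
            raise ValueError(f"baseline_log2 names unknown feature: {gene}")
        baseline[index_of[gene]] = float(value)
    log_expr = np.tile(baseline[:, None], (1, 2 * n_pairs))

    module_of = {}
    loading_of = {}
    hubs: List[str] = []
    in_module = np.zeros(n_features, dtype=bool)
    cursor = 0
    planted_resids: List[np.ndarray] = []
    for m_idx, plan in enumerate(module_plan, start=1):
        # orthogonalize the residual against the trait and every earlier
        # latent so the planted correlations hold exactly in-sample:
        # cor(latent, trait) = trait_corr and cor(latent_a, latent_b) =
        # trait_corr_a * trait_corr_b, with no sampling drift on top
        resid = rng.normal(size=2 * n_pairs)
        for basis in [trait_z] + planted_resids:
            bz = (basis - basis.mean()) / basis.std()
            resid = resid - np.dot(resid, bz) / np.dot(bz, bz) * bz
        resid = (resid - resid.mean()) / resid.std()
        rho = plan.trait_corr
        latent = rho * trait_z + np.sqrt(1 - rho ** 2) * resid
        latent = (latent - latent.mean()) / latent.std()
        planted_resids.append(resid)
        if plan.members is not None:
            member_ids = list(plan.members)
        else:
            member_ids = []
            while len(member_ids) < plan.size:
                gene = feature_ids[cursor]
                cursor += 1
                if gene not in module_of:
                    member_ids.append(gene)
        for k, gene in enumerate(member_ids):
            idx = index_of[gene]
            if plan.loadings is not None:
                loading = plan.loadings[k]
            else:
                loading = plan.hub_loading if k < plan.n_hubs else plan.loading
            noise = rng.normal(size=2 * n_pairs)
            log_expr[idx] = (
                baseline[idx]
                + loading * latent
                + np.sqrt(1 - loading ** 2) * noise
            )
            in_module[idx] = True
            module_of[gene] = m_idx
            loading_of[gene] = loading
            if k < plan.n_hubs:
                hubs.append(gene)
    free = ~in_module
    de_free = np.zeros(n_features, dtype=bool)
    if de_noise_sd is not None:
        for gene in de_plan:
            if free[index_of[gene]]:
                de_free[index_of[gene]] = True
    plain = free & ~de_free
    log_expr[plain] += rng.normal(0.0, sigma,
                                  size=(int(plain.sum()), 2 * n_pairs))
    if de_free.any():
        log_expr[de_free] += rng.normal(
            0.0, de_noise_sd, size=(int(de_free.sum()), 2 * n_pairs)
        )

    for gene, effect in de_plan.items():
        log_expr[index_of[gene], n_pairs:] += np.log2(effect)

    for gene_a, gene_b, rho in pair_plan or ():
        ia, ib = index_of[gene_a], index_of[gene_b]
        xa = log_expr[ia]
        za = (xa - xa.mean()) / xa.std()
        noise = rng.normal(size=2 * n_pairs)
        log_expr[ib] = baseline[ib] + rho * za + np.sqrt(1 - rho ** 2) * noise

    linear = np.power(2.0, log_expr)
    tpm = linear / linear.sum(axis=0, keepdims=True) * 1e6
    lam = tpm * depth / 1e6
    if counts_model == "poisson":
        counts = rng.poisson(lam)
    elif counts_model == "nb":
        shape = 1.0 / nb_dispersion
        counts = rng.poisson(rng.gamma(shape, lam / shape))
    else:
        raise ValueError("counts_model must be 'poisson' or 'nb'")

    design = PairedDesign(
        subject={s: s.rsplit("_", 1)[0] for s in samples},
        condition={s: s.rsplit("_", 1)[1] for s in samples},
    )
    truth = {
        "de_effects": de_plan,
        "module_of": module_of,
        "loading_of": loading_of,
        "hubs": hubs,
        "pairs": [list(p) for p in (pair_plan or ())],
        "trait": trait.tolist(),
    }
    frame = lambda a: pd.DataFrame(a, index=feature_ids, columns=samples)
    return ExpressionFixture(
        counts=frame(counts), tpm=frame(tpm), log_expr=frame(log_expr),
        design=design, truth=truth,
    )


# ---------------------------------------------------------------------------
# SNPs


def generate_snps(
    catalog: AnnotationCatalog,
    target: str,
    plan: Optional[Mapping[str, int]] = None,
    seed: int = 0,
    egene_id: str = "EGENE1",
    p_threshold: float = 1e-8,
) -> Tuple[pd.DataFrame, Dict]:
    """A SNP association table with planted in-exon hits and decoys.

    ``plan`` keys: ``in_exon`` (SNPs inside exons of ``target`` with
    association p below ``p_threshold``), ``decoy_intronic`` and
    ``decoy_intergenic`` (strong associations that do not touch the
    target's exons), ``in_exon_weak`` (in-exon but with p above the
    threshold, dropped on read).
    """
    plan = dict(plan or {"in_exon": 5, "decoy_intronic": 10,
                         "decoy_intergenic": 10})
    rng = rng_stream(seed, "snps")
    t = catalog[target]
    rows = []
    truth_in = []

    def strong_p():
        return float(10.0 ** rng.uniform(-14, np.log10(p_threshold) - 0.5))

    def weak_p():
        return float(10.0 ** rng.uniform(np.log10(p_threshold) + 0.5, -2))

    n_in = int(plan.get("in_exon", 0))
    for k in range(n_in):
        exon = t.exons[k % len(t.exons)]
        pos0 = int(rng.integers(exon.start, exon.end))
        snp = f"rs{900000 + k}"
        rows.append((snp, exon.chrom, pos0 + 1, egene_id, strong_p()))
        truth_in.append(snp)
    introns = [
        GenomicInterval(t.chrom, a.end, b.start)
        for a, b in zip(t.exons, t.exons[1:])
    ]
    for k in range(int(plan.get("decoy_intronic", 0))):
        if not introns:
            raise ValueError("target has no intron for intronic decoys")
        iv = introns[k % len(introns)]
        pos0 = int(rng.integers(iv.start, iv.end))
        rows.append((f"rs{910000 + k}", t.chrom, pos0 + 1, egene_id, strong_p()))
    for k in range(int(plan.get("decoy_intergenic", 0))):
        pos0 = int(t.end + 50_000 + rng.integers(0, 100_000))
        rows.append((f"rs{920000 + k}", t.chrom, pos0 + 1, egene_id, strong_p()))
    for k in range(int(plan.get("in_exon_weak", 0))):
        exon = t.exons[k % len(t.exons)]
        pos0 = int(rng.integers(exon.start, exon.end))
        rows.append((f"rs{930000 + k}", t.chrom, pos0 + 1, egene_id, weak_p()))

    df = pd.DataFrame(
        rows, columns=["snp_id", "chrom", "pos", "egene_id", "pvalue"]
    ).sample(frac=1.0, random_state=int(rng.integers(2 ** 31))).reset_index(drop=True)
    return df, {"in_exon_snps": truth_in, "target": target, "egene": egene_id}


# ---------------------------------------------------------------------------
# full-study assembly


def _jitter_copy(
    t: TranscriptModel,
    rng: np.random.Generator,
    jitter: int,
    new_tid: str,
    new_gid: str,
) -> TranscriptModel:
    """Copy of a transcript with jittered terminal exon ends, chain intact."""
    exons = [GenomicInterval(e.chrom, e.start, e.end, e.strand) for e in t.exons]
    d0 = int(rng.integers(-jitter, jitter + 1))
    d1 = int(rng.integers(-jitter, jitter + 1))
    first, last = exons[0], exons[-1]
    exons[0] = GenomicInterval(
        first.chrom, min(max(1, first.start + d0), first.end - 20),
        first.end, first.strand,
    )
    exons[-1] = GenomicInterval(
        last.chrom, last.start, max(last.end + d1, last.start + 20), last.strand,
    )
    return TranscriptModel(transcript_id=new_tid, gene_id=new_gid, exons=exons)


def _noncoding_for(length: int, rng: np.random.Generator) -> str:
    return generate_noncoding_sequence(length, rng)


@dataclass
class StudyFixture:
    """Paths and planted truth of a fully assembled synthetic study."""

    outdir: str
    paths: Dict[str, str]
    truth: Dict


def simulate_study(
    outdir: str,
    seed: int = 100,
    n_ref_genes: int = 60,
    n_pairs: int = 40,
    n_features: int = 500,
) -> StudyFixture:
    """Assemble a complete synthetic paired-ischemia study on disk.

    Platform A carries 38 novelty-compatible candidates planted with the
    class-code partition 19 'u' / 13 'i' / 5 'x' / 1 'y', plus decoys
    failing exactly one criterion each (length, exon count, class code,
    coding potential, chromosome, prevalence).  Platform B carries
    intron-chain copies of the 38 plus extras, so cross-platform
    validation recovers exactly the planted pairs; 28 of the validated
    transcripts are planted into three mock databases, leaving 10 novel.
    Expression (paired pre/post) plants two trait-correlated modules with
    annotated-lncRNA hubs and one novel member, plus differential
    features; a conservation track separates coding from noncoding
    exons; a SNP table plants five eSNPs in the exons of one novel
    lncRNA.  Everything is written as plain-text pipeline inputs plus a
    ``truth.json`` with the per-stage expectations and a ready-to-run
    ``config.yaml``.
    """
    import os

    from .gtf import write_gtf

    os.makedirs(outdir, exist_ok=True)
    rng = rng_stream(seed, "study")

    ref = generate_reference(
        n_genes=n_ref_genes,
        chrom_sizes={"chr1": 2_500_000, "chr2": 2_500_000},
        seed=seed,
        p_single_exon=0.15,
        p_lncrna=0.35,
    )
    class_plan = {"u": 19, "i": 13, "x": 5, "y": 1}
    good, code_truth = generate_candidates(
        ref, class_plan, seed=seed, jitter=40, id_prefix="A"
    )

    # --- decoys, each failing exactly one criterion -----------------------
    combined = AnnotationCatalog(list(ref) + list(good))
    alloc = _GapAllocator(combined)
    decoys = AnnotationCatalog()
    decoy_truth: Dict[str, str] = {}
    coding_ids: List[str] = []
    prevalence_fail: List[str] = []

    def add_decoy(tid, exons, code, fails):
        decoys.add(TranscriptModel(transcript_id=tid, gene_id=tid + "g",
                                   exons=exons))
        decoy_truth[tid] = code

    for k in range(4):  # spliced length 160 < 201
        chrom, start = alloc.take(360)
        add_decoy(f"A.DLEN{k + 1}", _two_exon(chrom, start, "+", 80, 200),
                  "u", "length")
    for k in range(4):  # single exon
        chrom, start = alloc.take(400)
        add_decoy(f"A.DEXON{k + 1}",
                  [GenomicInterval(chrom, start, start + 400, "+")], "u",
                  "multi_exonic")
    multi = [t for t in ref if t.is_multi_exonic() and len(t.exons[0]) >= 150]
    for k in range(4):  # same-strand exon overlap -> class 'o'
        host = multi[-(k + 1)]
        e1 = GenomicInterval(host.chrom, max(1, host.exons[0].start - 120),
                             host.exons[0].start + 100, host.strand)
        e2s = host.exons[0].end + 250
        e2 = GenomicInterval(host.chrom, e2s, e2s + 180, host.strand)
        add_decoy(f"A.DCODE{k + 1}", [e1, e2], "o", "class_code")
    for k in range(4):  # coding sequence
        chrom, start = alloc.take(1000)
        tid = f"A.DCPC{k + 1}"
        add_decoy(tid, _two_exon(chrom, start, "+", 250, 500), "u", "noncoding")
        coding_ids.append(tid)
    for k in range(4):  # chrY
        start = 100_000 + k * 5_000
        add_decoy(f"A.DCHR{k + 1}", _two_exon("chrY", start, "+", 300, 500),
                  "u", "chromosome")
    for k in range(6):  # fails the read-count prevalence filter
        chrom, start = alloc.take(1000)
        tid = f"A.DPREV{k + 1}"
        add_decoy(tid, _two_exon(chrom, start, "+", 250, 500), "u", "prevalence")
        prevalence_fail.append(tid)

    platform_a = AnnotationCatalog(list(good) + list(decoys))

    # --- platform B: chain copies of the good set + extras ----------------
    platform_b = AnnotationCatalog()
    for i, t in enumerate(good, start=1):
        platform_b.add(_jitter_copy(t, rng, 40, f"B.{i}", f"B.G{i}"))
    for k in range(8):
        chrom, start = alloc.take(900)
        platform_b.add(TranscriptModel(
            transcript_id=f"B.X{k + 1}", gene_id=f"B.XG{k + 1}",
            exons=_two_exon(chrom, start, "-", 220, 400),
        ))

    # --- sequences --------------------------------------------------------
    seq_rng = rng_stream(seed, "study-sequences")
    seqs_a: Dict[str, str] = {}
    for t in platform_a:
        length = sum(len(e) for e in t.exons)
        if t.transcript_id in coding_ids:
            seqs_a[t.transcript_id] = generate_coding_sequence(length, seq_rng)
        else:
            seqs_a[t.transcript_id] = _noncoding_for(length, seq_rng)
    seqs_b = {
        t.transcript_id: _noncoding_for(sum(len(e) for e in t.exons), seq_rng)
        for t in platform_b
    }

    coding_corpus, noncoding_corpus = generate_training_corpus(
        n_coding=150, n_noncoding=150, seed=seed
    )

    # --- prevalence counts (platform A, transcript level) -----------------
    cnt_rng = rng_stream(seed, "study-counts")
    n_samples = 2 * n_pairs
    count_rows = {}
    for t in platform_a:
        tid = t.transcript_id
        if tid in prevalence_fail:
            row = np.zeros(n_samples, dtype=int)
            detected = cnt_rng.choice(n_samples, size=int(0.3 * n_samples),
                                      replace=False)
            row[detected] = cnt_rng.poisson(8, size=detected.size) + 1
        else:
            row = cnt_rng.poisson(20, size=n_samples) + 1
        count_rows[tid] = row

    # --- database catalogs with 28 of the 38 planted ----------------------
    good_ids = sorted(code_truth)
    two_exon_u = [
        t.transcript_id for t in good
        if code_truth[t.transcript_id] == "u" and t.n_exons == 2
    ]
    eqtl_novel = two_exon_u[0]       # stays novel; carries the planted eSNPs
    module_novel = two_exon_u[1]     # stays novel; joins module 1
    eligible = [i for i in good_ids if i not in (eqtl_novel, module_novel)]
    known_ids = sorted(rng.choice(eligible, size=28, replace=False).tolist())
    novel_ids = sorted(set(good_ids) - set(known_ids))
    db_members = {
        "GENCODEv32": known_ids[:12],
        "FANTOM_CAT": known_ids[7:],
        "NONCODEv5": known_ids[13:],
    }
    dbs = {}
    for name, members in db_members.items():
        db = AnnotationCatalog()
        for j, tid in enumerate(members, start=1):
            db.add(_jitter_copy(good[tid], rng, 30, f"{name}.{j}",
                                f"{name}.G{j}"))
        dbs[name] = db

    # --- expression with modules, DE features, and the eQTL pair ----------
    biotype_of: Dict[str, str] = {}
    ref_gene_ids = []
    for t in ref:
        ref_gene_ids.append(t.gene_id)
        biotype_of[t.gene_id] = t.biotype
    lnc_genes = [g for g in ref_gene_ids if biotype_of[g] == "lncRNA"]
    mrna_genes = [g for g in ref_gene_ids if biotype_of[g] == "mRNA"]
    egene = "EGENE.RWDD3"
    n_fill = n_features - len(ref_gene_ids) - len(good_ids) - 1
    filler = [f"FILL.G{i + 1:03d}" for i in range(n_fill)]
    feature_ids = ref_gene_ids + good_ids + [egene] + filler
    for tid in good_ids:
        biotype_of[tid] = "novel"
    biotype_of[egene] = "mRNA"
    for g in filler:
        biotype_of[g] = "mRNA"

    hub_lnc = lnc_genes[:5]
    low_lnc = lnc_genes[5:7]
    mod2_lnc = lnc_genes[7:10]
    de_down_lnc = lnc_genes[10:14]
    m1_members = (hub_lnc[:3] + filler[:55] + low_lnc + [module_novel])
    m1_loadings = [0.95] * 3 + [0.85] * 55 + [0.30] * 2 + [0.85]
    m2_members = hub_lnc[3:5] + mod2_lnc + filler[55:90]
    m2_loadings = [0.95] * 2 + [0.30] * 3 + [0.85] * 35
    module_plan = [
        ModulePlan(size=len(m1_members), trait_corr=-0.69, n_hubs=3,
                   members=m1_members, loadings=m1_loadings),
        ModulePlan(size=len(m2_members), trait_corr=0.67, n_hubs=2,
                   members=m2_members, loadings=m2_loadings),
    ]
    de_plan = {g: 2.5 for g in filler[90:102]}
    de_plan.update({g: 0.4 for g in de_down_lnc})
    # keep condition-shifting features a small share of library mass
    # (lncRNAs and novel transcripts lowly expressed, regulated mRNAs
    # moderate, background mRNAs high) so TPM normalization stays stable
    baseline_log2 = {}
    for g in feature_ids:
        if biotype_of.get(g) in ("lncRNA", "novel") or g == egene:
            baseline_log2[g] = float(rng.normal(5.0, 0.5))
    for g in filler[:102]:
        baseline_log2[g] = float(rng.normal(6.0, 0.5))
    expr = generate_expression(
        n_pairs=n_pairs,
        seed=seed,
        de_plan=de_plan,
        module_plan=module_plan,
        sigma=0.25,
        feature_ids=feature_ids,
        pair_plan=[(eqtl_novel, egene, -0.2)],
        base_log2_mean=9.0,
        base_log2_sd=0.5,
        baseline_log2=baseline_log2,
        de_noise_sd=1.0,
    )
    hub_ids = expr.truth["hubs"]
    de_expected = sorted(
        [g for g, l in expr.truth["loading_of"].items() if l >= 0.85]
        + list(de_plan)
    )

    # --- conservation track over reference + novel exons ------------------
    scored = AnnotationCatalog(list(ref))
    for tid in novel_ids:
        t = good[tid]
        scored.add(TranscriptModel(
            transcript_id=f"NOVEL.{tid}", gene_id=f"NOVEL.{tid}",
            exons=list(t.exons), biotype="novel",
        ))
    track = generate_conservation_track(scored, seed=seed)

    # --- SNP table --------------------------------------------------------
    snp_plan = {"in_exon": 5, "decoy_intronic": 10, "decoy_intergenic": 10,
                "in_exon_weak": 5}
    snps, snp_truth = generate_snps(
        good, target=eqtl_novel, plan=snp_plan, seed=seed, egene_id=egene
    )

    # --- write everything -------------------------------------------------
    paths = {k: os.path.join(outdir, v) for k, v in {
        "reference": "reference.gtf",
        "platform_a": "platform_a.gtf",
        "platform_b": "platform_b.gtf",
        "sequences_a": "sequences_a.fa",
        "sequences_b": "sequences_b.fa",
        "train_coding": "train_coding.fa",
        "train_noncoding": "train_noncoding.fa",
        "counts": "counts.tsv",
        "tpm": "tpm.tsv",
        "design": "design.tsv",
        "biotypes": "biotypes.tsv",
        "conservation": "conservation.bedgraph",
        "snps": "snps.tsv",
        "db_GENCODEv32": "db_GENCODEv32.gtf",
        "db_FANTOM_CAT": "db_FANTOM_CAT.gtf",
        "db_NONCODEv5": "db_NONCODEv5.gtf",
        "truth": "truth.json",
        "config": "config.yaml",
    }.items()}

    write_gtf(ref, paths["reference"])
    write_gtf(platform_a, paths["platform_a"])
    write_gtf(platform_b, paths["platform_b"])
    for name, db in dbs.items():
        write_gtf(db, paths[f"db_{name}"])
    write_fasta(seqs_a, paths["sequences_a"])
    write_fasta(seqs_b, paths["sequences_b"])
    write_fasta({f"COD{i + 1}": s for i, s in enumerate(coding_corpus)},
                paths["train_coding"])
    write_fasta({f"NON{i + 1}": s for i, s in enumerate(noncoding_corpus)},
                paths["train_noncoding"])
    sample_names = list(expr.tpm.columns)
    pd.DataFrame(count_rows, index=sample_names).T.to_csv(
        paths["counts"], sep="\t", index_label="transcript_id"
    )
    expr.tpm.round(4).to_csv(paths["tpm"], sep="\t", index_label="feature_id")
    expr.design.to_table().to_csv(paths["design"], sep="\t", index=False)
    pd.DataFrame(
        {"feature_id": feature_ids,
         "biotype": [biotype_of[f] for f in feature_ids]}
    ).to_csv(paths["biotypes"], sep="\t", index=False)
    write_bedgraph(track, paths["conservation"])
    snps.to_csv(paths["snps"], sep="\t", index=False)

    exon_counts = {}
    for t in scored:
        exon_counts[t.biotype] = exon_counts.get(t.biotype, 0) + t.n_exons

    truth = {
        "seed": seed,
        "class_codes": {**code_truth, **decoy_truth},
        "class_plan": class_plan,
        "stage_counts": {
            "candidates_a": len(platform_a),
            "prevalence_pass": len(platform_a) - len(prevalence_fail),
            "criteria_pass": len(good_ids),
            "validated": len(good_ids),
            "previously_annotated": len(known_ids),
            "novel": len(novel_ids),
            "de_high_confidence": len(de_expected),
            "n_modules": 2,
            "n_hubs": len(hub_ids),
            "eqtl_overlaps": snp_plan["in_exon"],
            "eqtl_pairs": 1,
        },
        "known_ids": known_ids,
        "novel_ids": novel_ids,
        "eqtl_novel": eqtl_novel,
        "module_novel": module_novel,
        "egene": egene,
        "de_expected": de_expected,
        "hubs": hub_ids,
        "module_of": expr.truth["module_of"],
        "snps_in_exon": snp_truth["in_exon_snps"],
        "conservation_exons": exon_counts,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)

    config = {
        "seed": seed,
        "inputs": {k: os.path.abspath(paths[k]) for k in (
            "reference", "platform_a", "platform_b", "sequences_a",
            "sequences_b", "train_coding", "train_noncoding", "counts",
            "tpm", "design", "biotypes", "conservation", "snps",
        )},
        "databases": {name: os.path.abspath(paths[f"db_{name}"])
                      for name in dbs},
        "discovery": {
            "min_sample_fraction": 0.5,
            "min_length_nt": 201,
            "allowed_codes": ["u", "i", "x", "y"],
            "coding_cutoff": 0.364,
        },
        "de": {"max_adj_p": 0.001, "min_abs_fc": 1.2, "min_tpm": 0.5,
               "min_tpm_fraction": 0.9},
        "network": {"beta": 6, "cut_height": 0.99, "min_module_size": 30,
                    "kme_threshold": 0.7},
        "eqtl": {"p_threshold": 1.0e-8},
    }
    import yaml

    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)

    return StudyFixture(outdir=outdir, paths=paths, truth=truth)


def generate_audit_fixture(seed: int = 0):
    """A 100-candidate fixture with planted per-criterion failures.

    50 candidates pass every novelty criterion; 10 fail only the length
    criterion, 10 only multi-exonicity, 10 only the class code, 10 only
    coding potential, and 10 only the chromosome filter.  Returns
    (reference, candidates, sequences, planted fail-category per id).
    """
    ref = generate_reference(
        n_genes=40, chrom_sizes={"chr1": 2_500_000, "chr2": 2_500_000},
        seed=seed,
    )
    rng = rng_stream(seed, "audit")
    seq_rng = rng_stream(seed, "audit-seq")
    alloc = _GapAllocator(ref)
    cands = AnnotationCatalog()
    seqs: Dict[str, str] = {}
    category: Dict[str, str] = {}

    def add(tid, exons, cat, coding=False):
        cands.add(TranscriptModel(transcript_id=tid, gene_id=tid + "g",
                                  exons=exons))
        length = sum(len(e) for e in exons)
        seqs[tid] = (generate_coding_sequence(length, seq_rng) if coding
                     else _noncoding_for(length, seq_rng))
        category[tid] = cat

    for k in range(50):
        chrom, start = alloc.take(900)
        add(f"AUD.PASS{k + 1}", _two_exon(chrom, start, "+", 220, 400), "pass")
    for k in range(10):
        chrom, start = alloc.take(360)
        add(f"AUD.LEN{k + 1}", _two_exon(chrom, start, "+", 80, 200), "length")
    for k in range(10):
        chrom, start = alloc.take(400)
        add(f"AUD.EXON{k + 1}",
            [GenomicInterval(chrom, start, start + 400, "+")], "multi_exonic")
    multi = [t for t in ref if t.is_multi_exonic() and len(t.exons[0]) >= 150]
    for k in range(10):
        host = multi[k % len(multi)]
        e1 = GenomicInterval(host.chrom, max(1, host.exons[0].start - 120),
                             host.exons[0].start + 100, host.strand)
        e2s = host.exons[0].end + 250
        e2 = GenomicInterval(host.chrom, e2s, e2s + 180, host.strand)
        add(f"AUD.CODE{k + 1}", [e1, e2], "class_code")
    for k in range(10):
        chrom, start = alloc.take(1000)
        add(f"AUD.CPC{k + 1}", _two_exon(chrom, start, "+", 250, 500),
            "noncoding", coding=True)
    for k in range(10):
        start = 50_000 + k * 5_000
        add(f"AUD.CHR{k + 1}", _two_exon("chrY", start, "+", 300, 500),
            "chromosome")
    return ref, cands, seqs, category
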