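# Methods

This document records the statistical model behind each pipeline stage,
the conventions of the synthetic-data generators, the numerical choices
that affect results, and known limitations.

## Transcript models and classification

Transcripts are ordered exon lists on a chromosome and strand with
half-open 0-based coordinates. The *intron chain* is the ordered list of
(donor, acceptor) coordinates between adjacent exons. Two transcripts
*match by intron chain* when they share chromosome, strand, and the
exact intron coordinates; terminal exon boundaries are free to differ.
For two single-exon transcripts the chain is vacuous and the match
degenerates to same-strand exon overlap; a single-exon transcript never
matches a multi-exon one.

Each candidate receives exactly one class code with precedence
`=` > `y` > `x` > `i` > `o` > `u`:

- `=` — some reference transcript matches the candidate's (non-empty)
  intron chain on the same strand;
- `y` — a whole reference transcript span lies inside one candidate
  intron;
- `x` — opposite-strand exonic overlap with no same-strand exonic
  overlap (novel antisense);
- `i` — the candidate span lies entirely within one reference intron
  and touches no reference exon;
- `u` — the candidate span overlaps no reference span at all
  (intergenic);
- `o` — any residual overlap pattern.

Unstranded (`.`) candidates cannot receive the strand-dependent codes
`=` and `x` and are flagged. When several references qualify, ties are
broken by the largest shared exonic base count, then lexicographically,
so classification is deterministic and independent of input order.

## Coding potential

Four features feed a logistic model:

- **ORF length** (nt) and **ORF coverage** (ORF length / transcript
  length) of the longest ATG→stop open reading frame over the three
  forward frames.
- **Fickett TESTCODE statistic**, computed with Fickett's published
  position and content lookup tables and weights. Position asymmetry
  for each base is `max/(min+1)` over the three codon-offset counts;
  content is the base fraction. Each value indexes a probability bucket
  and the statistic is the weighted sum of the eight probabilities. The
  statistic is calibrated for sequences of at least 200 nt; shorter
  inputs trigger a warning.
- **Hexamer score**: mean log-odds of the in-frame hexamers of the
  longest ORF under a table trained from coding vs noncoding corpora.
  Tables normalize counts to class frequencies and add a symmetric
  pseudocount (`pseudocount/4096` on both sides), so a hexamer absent
  from both corpora scores exactly 0 and identical corpora give an
  all-zero table.

The logistic model is fit by maximum likelihood on standardized
features, falling back to a ridge-stabilized fit under perfect
separation (synthetic corpora are usually separable). The default
decision cutoff on the coding probability is 0.364; it is a
configuration value (`discovery.coding_cutoff`), not a constant.

Because the longest-ORF search prefers stop-free windows, and stop-free
windows are enriched for hexamers depleted in random backgrounds, even
dinucleotide-preserved shuffles score a slightly *positive* mean hexamer
log-odds. The separation between classes remains large; only the zero
point of the score is shifted.

## Novelty discovery

The prevalence filter keeps transcripts with count > 0 in at least
`ceil(min_fraction * n_samples)` samples (inclusive "at least half" on
odd sample counts). The novelty criteria are independent booleans —
spliced length ≥ 201 nt ("length > 200" semantics), ≥ 2 exons, class
code in {u, i, x, y}, coding probability < cutoff, chromosome in
autosomes 1–22 plus X — so their application order cannot change the
surviving set, and raising any threshold can only shrink it. A
candidate with no sequence fails the coding criterion with a logged
reason instead of crashing.

Cross-platform validation pairs each surviving platform-A transcript
with a platform-B transcript sharing its complete intron chain; the
A-side model is retained as the representative.

Database re-annotation marks a validated transcript as previously
annotated when any database entry matches it by intron-chain identity
or (default `chain_or_overlap` mode) by same-strand exonic overlap
covering at least 50% of the shorter transcript; the first matching
database in the given order is recorded as provenance. `chain_only`
mode disables the overlap rule. The "known vs novel" partition is exact
and disjoint.

## Conservation

The score track is a bedGraph of per-chromosome sorted, non-overlapping
intervals with values in [0, 1]. Per-exon scores are the mean over
*covered* bases only; uncovered bases are excluded from the denominator
(an exon half covered at 1.0 scores 1.0, not 0.5). The alternative
`uncovered_as_zero=True` imputes 0 over the full exon length. Fully
uncovered exons score NaN (or 0 under imputation). Class profiles
summarize exon means per transcript class (mean, median, deciles);
empty classes are omitted with a warning.

## Differential expression

TPM is `(c_ij/len_i) / sum_k (c_kj/len_k) * 1e6`; every column sums to
1e6 and the transform is invariant to per-column count scaling.

Paired testing uses a two-sided paired t-test on per-subject
post − pre differences of `log2(TPM + 1)`. Degenerate cases: all-zero
differences give p = 1 (no evidence of change); constant non-zero
differences have zero variance and give p = NaN, which is excluded from
the Benjamini–Hochberg denominator. BH adjustment is the classic
step-up (`p_(i) * n / i` with a cumulative minimum from the largest
rank, clipped at 1).

The reported fold change is the signed linear ratio of mean TPMs with a
pseudocount: `r = (post+eps)/(pre+eps)`, reported as `r` if `r >= 1`
else `-1/r`, so 2-fold down is −2. Selection uses strict inequalities
(adjusted p < 0.001 and |FC| > 1.2 by default) plus, for annotated
features only, a prevalence requirement (≥ 0.5 TPM in ≥ 90% of samples
by default); novel transcripts are exempt unless `exempt_novel=False`.

Note that a constant TPM ratio between conditions is *not* a constant
difference of `log2(TPM + 1)` — the pseudocount breaks exact
proportionality. Zero-variance behaviour therefore only triggers on
literally constant values.

## Co-expression networks

Adjacency is `|cor|^beta` over genes (Pearson, samples as observations);
constant genes are dropped with a warning. The topological overlap
matrix is

```
TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
```

with connectivity `k_i = sum_{u != i} a_iu` and unit diagonal. Modules
come from average-linkage hierarchical clustering of `1 - TOM` with a
*static* height cut (default 0.99) and a minimum size (default 30);
clusters below the minimum fall into module 0 (unassigned). Labels are
assigned by decreasing size, so they are deterministic. This static cut
is simpler than dynamic tree cutting and can split or merge differently
on borderline topologies (see Limitations).

`pick_soft_threshold` selects the smallest power whose connectivity
distribution fits a scale-free log-log regression with R² ≥ 0.8,
falling back to β = 6 with a warning when no candidate power fits. The
fallback exists because the R² criterion is unreliable at high powers:
raising β concentrates connectivity onto the few largest correlations,
and even pure independent noise can *spuriously* pass R² ≥ 0.8 at high
powers. The candidate grid therefore matters; the default grid spans
1–20 and the selected power should be sanity-checked against the
diagnostic table the function returns.

The module eigengene is the first principal component of the
standardized member × sample matrix, scaled to unit variance and
sign-oriented to correlate positively with the mean member profile.
kME is the correlation of every gene with every eigengene; hub calling
uses a strict `kME > threshold` (default 0.7) in the gene's own module,
optionally restricted to a gene set (the pipeline restricts to
differentially expressed annotated lncRNAs). Module–trait association
is the Pearson correlation of each eigengene with the sample trait,
with a t-distribution p-value (n − 2 df).

## cis-eQTL overlap

SNP tables are TSV with columns `snp_id, chrom, pos (1-based), egene_id,
pvalue`; rows are kept only when p is strictly below the threshold
(default 1e-8; `p == threshold` is dropped). Positions convert to
0-based single-base intervals. Exon containment is `start <= pos < end`
on the same chromosome, strand-blind; the output table is sorted by
(transcript, exon index, SNP), so it is invariant to input order.
lncRNA–eGene expression correlations are Pearson on `log2(TPM + 1)`;
missing or constant features yield error records rather than crashes.

## Synthetic generators

All randomness flows through labelled streams:
`rng_stream(seed, label)` builds a `numpy` generator from
`SeedSequence([seed, crc32(label)])`, so adding a generator never
perturbs the draws of another, and everything is bit-reproducible per
(parameters, seed).

- **References**: non-overlapping single- and multi-exon genes laid
  left to right with wide intergenic gaps and introns big enough to
  host intronic candidates.
- **Candidates**: built geometrically to guarantee their planted class
  code — `=` by intron-chain copy with jittered termini, `u` in
  intergenic gaps, `i` inside wide introns, `x` straddling a reference
  exon on the antisense strand, `y` spanning a small reference gene.
- **Coding sequences** place one long ORF (~90% coverage) whose codons
  are drawn from a positional nucleotide profile. The profile was
  solved (by fixed-point iteration against the realized post-stop-codon
  frequencies) so the in-frame position asymmetries land in strongly
  coding-scoring regions of the Fickett tables (≈ A 1.45, C 1.35,
  G 1.75, T 1.75) while a composition-matched shuffle has asymmetry
  ≈ 1.
- **Noncoding sequences** are exact dinucleotide-preserving shuffles
  (Eulerian-walk construction) of fresh coding draws, so base and
  dinucleotide composition match the coding class exactly. Short
  shuffles occasionally contain a long chance ORF — a coding signal a
  noncoding transcript should not plant — so shuffles are redrawn (up
  to 100 times) until no ORF covers more than half the sequence; each
  redraw is still an exact shuffle.
- **Conservation** draws per-base scores Beta(α, β) by transcript class
  (defaults: coding 8,2; noncoding 2,8) and run-length encodes them
  into bedGraph intervals, skipping bases already covered by an earlier
  exon.
- **Expression** builds `log2` expression as baseline + structure +
  noise. Planted module members follow `loading * latent +
  sqrt(1 - loading^2) * noise` with latents orthogonalized exactly
  against the trait and earlier latents, so planted correlations hold
  in-sample without drift. Differential features add `log2(effect)` to
  post-condition samples. TPM is the column-normalized linear
  expression; counts are Poisson (negative binomial optional) at a
  target depth. Because TPM is compositional, features whose mean
  shifts with the condition are kept a small share of library mass;
  otherwise the per-sample normalization itself tracks the condition
  and leaks a trait-correlated component into every feature.
- **SNP tables** plant in-exon associations below the significance
  threshold plus intronic/intergenic/weak decoys, then shuffle row
  order deterministically.

## Numerical conventions

- Text round-trips: floats written to bedGraph/TSV and re-read through
  pandas can differ from the in-memory value by one ulp; comparisons
  against recomputed values use absolute tolerances of 1e-12.
- Reports round headline statistics (medians to 4 decimals, PCCs to 3)
  for stable text output; the underlying tables keep full precision.
- Reruns with the same seed and config are byte-identical, including
  `report.json`/`report.txt` and all stage tables.

## Limitations

- The static-height module cut can merge anticorrelated trait-driven
  modules at some seeds: two planted modules whose latents are coupled
  through the trait (`cor = rho_1 * rho_2`) are close in `1 - TOM`
  because adjacency is sign-blind, and whether they split at the 0.99
  cut depends on the noise realization. Dynamic tree cutting would be
  more robust; it is out of scope here.
- Scale-free fit selection is only meaningful on data with genuine
  modular structure; on unstructured data high powers can pass the R²
  criterion spuriously (see above), and the chosen β should be
  inspected.
- Planted differential effects leak small opposite fold changes into
  all other features through TPM normalization; with many strong
  planted effects some background features can cross loose fold-change
  thresholds.
- The Fickett statistic is unreliable below 200 nt, and the hexamer
  score's zero point is biased upward by longest-ORF selection; both
  are mitigated by the trained logistic combination rather than by
  per-feature thresholds.
- The discovery pipeline assumes assembled transcripts and
  transcript-level counts as inputs; read alignment, assembly, and
  quantification are out of scope.
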