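# Methods

## Data model

A dataset is a probes × samples matrix of diploid genotype calls with one
phenotype class label per sample. Calls are unordered allele pairs over
{−, A, C, G, T}, stored canonically sorted (`G/C` ≡ `C/G`): genotyping
arrays report genotypes, not phased haplotypes, so orientation carries no
information. The `−` symbol is a legitimate allele (deletion/absent
allele) and forms its own genotype categories; it is distinct from
`NoCall`, which means the platform could not determine the genotype at
all. `NoCall`, `---` and `./.` are accepted as missing-call spellings
(case-insensitive); real exports may use other tokens, which the parser
rejects loudly rather than guessing.

Class labels live in a second header row named `Class` or in a two-column
sidecar file. A file may contain more than two classes; an analysis always
selects exactly two.

## Association testing

Per probe, genotype symbols are tabulated by class into a 2×k table.
`NoCall` samples are excluded from the table by default — they are
non-measurements, and keeping them as a category (available via
`nocall_policy="as_category"`) is a sensitivity analysis, not the default
inference.

Two test granularities:

- **per_symbol** (default): each observed symbol versus the pooled rest,
  a 2×2 Fisher exact test per symbol. This mirrors how pharmacogenomic
  hits are reported (a specific genotype in a specific gene with its own
  p-value).
- **omnibus**: one exact 2×k conditional test per probe, by full
  enumeration of top rows under the multivariate hypergeometric null. The
  enumeration is capped (default 5·10⁶ tables) and raises a capacity error
  advising per-symbol mode beyond that.

The two-sided p-value uses the probability method: sum point probabilities
≤ that of the observed table. Point probabilities are computed in log
space (`gammaln`); ties are accepted within a relative tolerance of 1e-9.
For the table sizes involved the distinct rational point probabilities are
separated by far more than this, so the float path reproduces
exact-rational enumeration to ~1e-14 relative error (verified exhaustively
in the test suite for all 2×2 tables with n ≤ 30 and all 2×3 tables with
n ≤ 15).

Degenerate inputs: a probe where one class has no measured genotype is
untestable and is reported with a reason instead of a p-value; a k = 1
table has no variation and gets p = 1; tables with empty margins collapse
to the single compatible table and also give p = 1.

### Pre-filter

An optional optimization skips the exact test for probes whose maximal
between-class genotype frequency difference (max over symbols of
|count/classtotal difference|) does not exceed a threshold. The default is
*disabled* — every probe is tested — because the filter is an efficiency
device, not an inference step. Threshold 0 keeps any probe showing any
difference. Raising the threshold can only shrink the tested set
(monotonicity is property-tested).

### Multiple testing

Bonferroni (min(1, m·p)) and Benjamini–Hochberg step-up adjustments are
always computed alongside the raw values. The correction universe m is the
number of tests actually performed after pre-filtering, not the chip's
nominal 1936 probes and not probes × symbols before filtering: corrections
apply to conducted tests. This choice changes adjusted values when the
pre-filter is active, so it is stated here prominently. Result ordering is
deterministic: by raw p-value with ties broken by probe id then symbol, or
alphabetically; skipped probes sort last.

## Hardy–Weinberg equilibrium

Input is observed genotype *counts* (hom-ref, het, hom-var) — expected
counts require the sample size, so frequencies alone would be
ill-defined. The allele frequency is estimated by gene counting,
p̂ = (2·n_AA + n_Aa)/(2n); expected counts are (p̂²n, 2p̂q̂n, q̂²n); the
Pearson χ² uses df = 1 (three classes, one sum constraint, one estimated
parameter). No continuity correction by default (a Yates option exists).
Monomorphic inputs (p̂ ∈ {0,1}) have no testable deviation and return
χ² = 0 with a flag. An exact (permutation-style) HWE test is deliberately
out of scope; the chi-square approximation is anti-conservative at very
small n, which the calculator does not hide.

## Annotation

Fully offline: a TSV store maps probe ids to rsIDs and gene symbols, and
link construction is purely syntactic — `https://www.ncbi.nlm.nih.gov/snp/{rsid}`
and `https://www.pharmgkb.org/search?query={...}`. The PharmGKB link is a
search URL because stable entity accessions are not derivable offline.
Annotation never alters p-values, counts or ordering, and unannotated
probes pass through with empty fields.

## Synthetic data

The generator emulates a DMET-style export: 1936 probes by default, two
classes, bi-allelic probes (two alleles drawn per probe, genotypes on
{X/X, X/Y, Y/Y}), configurable NoCall rate (default 0). Null probes share
one genotype distribution between classes, taken as Hardy–Weinberg
proportions at an allele frequency uniform on [0.05, 0.95] — the typical
regime of common ADME markers. Associated probes use either an explicit
distribution pair or a scalar separation s ∈ (0, 1]: mass (1+s)/2 on X/X
and (1−s)/2 on Y/Y in one class, mirrored in the other, so s equals the
total-variation distance and s = 1 is complete separation (the classic
"all C/C cases vs all T/T controls" pattern). Associated probe positions
are drawn from a dedicated seeded stream.

Randomness is split per probe from the single global seed
(`SeedSequence(seed, spawn_key=(probe_index,))`), so a probe's draw does
not depend on generation order or on how many probes exist — identical
arguments give bit-identical files.

What the generator does *not* emulate: linkage disequilibrium between
markers (probes are independent), population structure, batch effects,
genotyping error beyond uniform NoCall, and multi-allelic probes. Passing
the recovery and type-I tests therefore demonstrates correctness of the
statistical machinery under idealized sampling, not robustness to the
correlation structure of real cohorts.

## Problem sizes and numerical choices

- Oracle sweeps: all 2×2 tables with n ≤ 30 and all 2×3 tables with
  n ≤ 15, against exact-rational enumeration, tolerance 1e-9 relative.
- Null calibration: 1936 probes at 10+10 samples; 20 seeded replicates for
  the BH zero-discovery check. Fisher at these sizes is strongly
  conservative (observed raw fraction below 0.05 is ≈ 0.01).
- Planted-signal recovery: 10 completely separated probes among 1926 nulls
  at 13 vs 13 — the scale of a twenty-six-patient toxicity cohort.
- Throughput: null chips from 100 to 1000 patients in steps of 100; each
  size completes in seconds on one CPU, and the per-test enumeration cost
  grows linearly in sample count, which the suite checks as a generous
  linear envelope rather than as absolute wall-clock targets.
- Heatmap coding: symbols sorted lexicographically over the whole dataset
  get codes 1..k, NoCall is always 0, samples are grouped by class
  (classes lexicographic, original order within class). Decoding through
  the legend is exact; colormap choice is left to the rendering layer and
  any image embeds the legend.

## Known limitations

Single-marker tests only — no haplotype or multi-marker models, no
covariates, no logistic regression, no LD statistics. The per-symbol mode
performs k correlated tests per probe (its columns share margins), which
the BH correction treats as independent; this is conventional but
conservative. Excel input is supported only through conversion via
openpyxl; the native formats are textual TSV/CSV.
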