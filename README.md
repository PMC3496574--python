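# dmetkit

Case-control association analysis for pharmacogenomic SNP genotype tables in
the DMET layout.

The Affymetrix DMET chip genotypes 1936 markers in 225 ADME genes
(absorption, distribution, metabolism, excretion). A typical pharmacogenomic
case-control study exports a probes × samples table of diploid calls
(`C/T`, `G/G`, `NoCall`, ...) and asks which markers distribute differently
between two phenotype classes — say, patients with and without a toxic
reaction to a drug. Cohorts in this field are small (often under 30
patients), so exact tests are the appropriate machinery. `dmetkit` is for
researchers who have such a table and want the whole workflow — parsing,
per-marker exact testing, multiple-testing correction, Hardy–Weinberg
checks, annotation links and heatmaps — scriptable in Python or from the
shell, with no GUI and no network access.

## The statistics

For each probe, genotype symbols are tabulated by class into a 2×k
contingency table. In the default *per-symbol* mode each observed genotype
g is tested against the pooled rest with a two-sided **Fisher exact test**:
with fixed margins, the p-value is the sum of hypergeometric point
probabilities P(T) ≤ P(T_obs),

p = Σ_{T: P(T) ≤ P(T_obs)} P(T),  P(T) = ∏_j C(c_j, a_j) / C(n, r₁),

which matches how findings are reported in this field ("the homozygous
genotype C/C in ABCC5, P = ..."). An *omnibus* mode runs one exact 2×k test
per probe by full enumeration. Raw p-values come with **Bonferroni**
(min(1, m·p)) and **Benjamini–Hochberg** step-up adjustments over the m
tests actually performed; an optional pre-filter skips probes whose largest
between-class genotype frequency difference does not exceed a threshold.

**Hardy–Weinberg equilibrium** for a bi-allelic marker is tested from the
observed genotype counts (n_AA, n_Aa, n_aa): p̂ = (2·n_AA + n_Aa)/(2n),
expected counts (p̂²n, 2p̂q̂n, q̂²n), Pearson χ² with df = 1.

A synthetic-data generator emits chip-scale datasets in the same file
format with known null/associated structure, so every claim above is
testable end to end without any download.

## Worked example

`python examples/analyze_case_control.py` builds a four-probe, four-subject
table (classes A = {Subject1, Subject2}, B = {Subject3, Subject4}) and
prints:

```
probe_id symbol counts_a counts_b    p_raw  p_bonferroni  p_fdr  prefiltered
  Probe1    C/C      2,0      0,2 0.333333           1.0    1.0        False
  Probe1    T/T      0,2      2,0 0.333333           1.0    1.0        False
  Probe2    -/T      0,2      1,1 1.000000           1.0    1.0        False
  ...
  Probe3    C/T      2,0      2,0 1.000000           1.0    1.0        False
```

Probe1 is `C/C` in every class-A subject and `T/T` in every class-B
subject; enumerating the three 2×2 tables with margins (2,2)/(2,2) gives
p = 1/3 — the smallest value four samples can achieve — so it ranks first.
Probe3 is identical in both classes and gets p = 1 (or is skipped when the
pre-filter is enabled). With only nine tests performed, both corrections
saturate at 1.

The same run from the shell:

```
dmetkit simulate --probes 1936 --assoc 10 --n 13 13 --seed 7 --out sim/
dmetkit analyze --input sim/dataset.tsv --classes A B --correction fdr --out results/
dmetkit hwe 50 20 30 --alpha 0.05
```

Other example scripts cover the Hardy–Weinberg calculator
(`hwe_calculator.py`), planted-signal recovery at cohort scale
(`simulate_and_recover.py`), and heatmap encoding plus offline
dbSNP/PharmGKB annotation (`heatmap_and_annotation.py`).

## File formats

- **Genotype table** (TSV/CSV): line 1 `ProbeID<TAB>sample1...`; line 2
  `Class<TAB>label1...` (or a two-column `sample<TAB>class` sidecar file);
  one probe per subsequent line, cells `X/Y` with X, Y ∈ {A,C,G,T,−} or
  `NoCall`.
- **Annotation TSV**: columns `probe_id`, `rsid`, `gene`, `note`.
- **Results TSV**: one row per test — probe, symbol, per-class counts, raw
  and adjusted p-values — plus `rsid`/`gene`/`dbsnp_url`/`pharmgkb_url`
  when an annotation store is supplied.

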