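# Methods

## The design and the classification model

The experiment is a 4 × 2 factorial: genotypes WT, *myc2*, *ein3 eil1*,
*myc2 ein3 eil1*; treatments JA and mock; `r` biological replicates per
cell (default 3). Per gene, six log2 ratios are estimated:

- within-genotype responses `fc_g = log2(g,JA / g,Mock)` for each genotype;
- cross-genotype amplitude ratios under JA, `x_myc2 = log2(myc2,JA / WT,JA)`
  and `x_ein = log2(ein3eil1,JA / WT,JA)`.

The five category rule-sets are strict-inequality predicates over these
ratios (threshold 1 log2 unit throughout):

| category | rule |
|---|---|
| EIN3_INDEP | \|fc_wt\|>1, \|fc_myc2\|>1, \|x_myc2\|<1, \|fc_ein\|<1, \|fc_triple\|<1, sign(fc_wt)=sign(fc_myc2) |
| MYC2_INDEP | \|fc_wt\|>1, \|fc_ein\|>1, \|x_ein\|<1, \|fc_myc2\|<1, \|fc_triple\|<1, sign(fc_wt)=sign(fc_ein) |
| SYNERGY | \|fc_wt\|>1, \|fc_myc2\|<1, \|fc_ein\|<1, \|fc_triple\|<1 |
| EIN3_UP_MYC2_REPRESSED | fc_wt>1, x_myc2>1, x_ein<−1, \|fc_ein\|<1, \|fc_triple\|<1 |
| MYC2_UP_EIN3_REPRESSED | fc_wt>1, x_ein>1, x_myc2<−1, \|fc_myc2\|<1, \|fc_triple\|<1 |

Decisions taken where the design was genuinely open:

- **Significance on "changed" legs.** A leg that requires a response
  (|fc|>1 within a genotype) additionally requires the BH-adjusted p of
  that genotype's JA-vs-mock contrast to be < .05 (`criteria=fc_and_padj`,
  default). "Not altered" legs and the cross-genotype ratios are
  fold-change-only — no p-value is defined for them in the source
  procedure. `criteria=fc_only` disables the significance legs.
- **Sign consistency** is enforced for categories 1–2: absolute-value
  notation alone would admit a gene induced in WT but repressed in the
  mutant as "regulated in both".
- **Overlapping rules.** The five sets are not mutually exclusive
  (provably exclusive pairs: 1–3, 1–4, 2–3, 2–5, via a shared ratio
  constrained to both sides of 1; the rest can co-fire — e.g. a
  rule-4 gene with |fc_myc2|<1 also satisfies rule 3, because rule 4
  constrains the *cross-genotype* myc2 ratio, not the within-genotype
  one). Default `rule_literal` mode reports every matching label and a
  multi-label flag; `priority` mode keeps one label in the order
  4, 5, 1, 2, 3 (most-constrained first) for partition-style summaries.
- **Boundary behavior**: a ratio exactly equal to ±1 satisfies neither
  the ">1" nor the "<1" side; all inequalities are strict.

## Differential expression

- **Normalization** is median-of-ratios: factor_j = median over genes
  (positive in all samples) of count_gj / geometric-mean_g. Counts divided
  by the factor are "normalized counts"; no gene-length term is needed
  because every contrast compares the same gene with itself.
- **Fold change**: log2((mean_A + 0.5) / (mean_B + 0.5)) of normalized
  group means. The 0.5 pseudocount keeps zero-count groups finite; both
  groups all-zero gives exactly 0.
- **Test**: a closed-form, moment-based NB Wald test. Per gene, the
  dispersion α (variance = μ + αμ²) is the average of the two within-group
  moment estimates (v − m)/m², floored at 1e-8 (Poisson-like genes produce
  negative moments); β = ln((m_A+pc)/(m_B+pc));
  se² = (1/n_A)(1/(m_A+pc)+α) + (1/n_B)(1/(m_B+pc)+α); p = 2(1 − Φ(|β/se|)).
  All-zero genes get p = 1 by convention. The test is deliberately simple —
  no shrinkage, no empirical Bayes — so it is deterministic and exactly
  checkable against simulation; on null simulations at r = 6 its raw-p
  rejection rate at α = .05 is ≈ 0.076 (mildly anticonservative, inside the
  accepted [0.03, 0.08] band; the normal approximation and the moment
  dispersion at small r are the cause).
- **Multiplicity**: Benjamini–Hochberg step-up per contrast
  (statsmodels' `fdr_bh`). The DE call (UP/DOWN/NONE) uses |log2FC| > 1 and
  adjusted p < .05, both strict; a `use_raw_p` switch thresholds the raw p
  instead, since the source procedure's wording leaves this ambiguous.
- **Robust size factors.** Plain median-of-ratios assumes most genes are
  unchanged. In the default simulation 80% of genes are planted DE, and the
  WT JA samples' factors absorb ~0.7 log2 of signal, destroying both
  sensitivity and the null false-assignment rate. The pipeline therefore
  defaults to DE-gene elimination (as in the TCC/DEGES strategy): estimate
  factors, call DE in the four within-genotype contrasts, re-estimate on
  the genes called DE in none of them, iterate (2 rounds; falls back if
  fewer than 100 genes survive). `estimate_size_factors` keeps the plain
  definition; `estimate_size_factors_deges` is the refinement;
  `build_fold_change_table(..., normalization="plain")` restores the naive
  behavior.

## Synthetic data

The generator states a world and is not tuned: equal mock baselines across
genotypes; per-gene baseline log2 mean uniform on [3, 12] (≈8–4,000 mean
counts per gene, ≈1.5 M reads per sample at 2,000 genes — sequencing depth
is unreported in the source, so this is a stated free choice); NB counts
via gamma-Poisson with per-gene dispersion α log-normal(ln 0.05, 0.5);
per-sample library factors 2^N(0, 0.25), recorded in the sample sheet for
oracle checks. Planted archetypes invert the rules into effect templates
over (WT, myc2, ein3eil1, triple), e.g. EIN3_INDEP_UP = (δ, δ, 0, 0),
EIN3_UP_MYC2_REPRESSED = (δ, δ_antag, 0, 0) with δ = 2, δ_antag = 3.5, so
expected ratios satisfy the category inequalities with margin ≥ 0.5 log2.
Defaults: 2,000 genes, 10% per archetype (eight archetypes → 20% nulls),
r = 3, seed-deterministic to the bit.

What a green recovery test establishes: the estimator + rules recover the
planted categories under NB noise, library-size jitter, and a majority-DE
transcriptome. What it does not: real data have unequal mutant baselines,
correlated genes, batch effects, length/GC biases, and a far smaller DE
fraction — none are emulated (mutant baseline shifts are a config
extension, default off).

## Enrichment

Fold enrichment = (a/n)/(K/N). P-values are one-sided hypergeometric upper
tails; default mode is EASE (overlap reduced by one before the tail;
a = 0 → p = 1), matching the "modified Fisher" of the DAVID tool family;
plain Fisher is selectable. The universe defaults to all genes surviving
the all-zero filter of the count matrix. BH is applied across terms within
one query list; a term is "enriched" iff fold enrichment > 1 and p < .05
(strict). `min_count` reproduces the NA behavior of tools that decline
p-values for overlaps below a minimum (default 1 = never blank; EASE at
a = 1 gives p = 1 analytically). The null rejection rate of the Fisher tail
is below nominal for small (N, K, n) because the statistic is discrete; the
calibration suite uses N = 10,000, n = 1,000, K = 500 where the tail is
near-continuous (exact rate 0.042).

## Numerical and reporting conventions

- Dispersion floor 1e-8; pseudocount 0.5 everywhere a mean enters a log.
- Percentages are shares of the universe (the WT DE count), rounded to one
  decimal, displayed without the decimal when integral ("25%").
- Venn regions are exclusive membership patterns; their counts sum to the
  union size.
- All outputs are TSV with stable column order; reruns with the same seed
  are byte-identical.

## Known limitations

- The Wald test is anticonservative at very small replicate numbers; padj
  thresholds partly absorb this, but r = 2 designs should be read
  cautiously.
- Priority mode imposes an ordering the underlying procedure never states;
  rule-literal mode with multi-label reporting is the honest default.
- The DEGES refinement assumes the non-DE set is large enough to anchor the
  median (≥ 100 genes by default); fully responsive transcriptomes would
  need spike-ins, which are out of scope.
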