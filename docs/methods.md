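# Methods

This note documents the statistical model behind `thermode`, the choices
made where the design was genuinely open, and what the synthetic-data
tests do and do not establish about real data.

## The inferential setting

The design has **no biological replication**: each
(species, stage, temperature) cell is observed through one sequencing
library made from a pool of embryos (10 per pool for the TSD species,
5 for the GSD species).  The only tractable null model is conditional on
the two libraries of a stage: given the focal gene's total and the two
library totals, the focal gene's count at 26 °C is hypergeometric under
the hypothesis that the gene occupies the same transcriptome share at
both temperatures.  This is Fisher's exact test on the focal-gene vs
remaining-genes 2×2 table.  It captures *technical* (counting) noise
only; variability between pools is unmodeled, which makes the test
anti-conservative against biological variation.  The package treats this
honestly in three ways: a stringent FDR tier (1e-10) far below the
nominal level, a subsampling consensus cross-check, and an explicit
overdispersion experiment in the acceptance suite showing the suggestive
tier inflating as between-pool dispersion grows.  Conclusions from the
suggestive tier alone should be treated as hypotheses, not findings.

## Exact tests and their conventions

**Two-sided convention.** For both the hypergeometric (per-gene) and the
conditional binomial (subsample-pair) tests, the two-sided p-value is the
total probability of outcomes whose probability does not exceed the
observed outcome's, with a `1 + 1e-7` relative guard so that outcomes
tied with the observed one up to floating-point error are included.
The probability-mass convention is a declared choice; the doubled
one-tail convention would differ slightly on asymmetric tables.

**Implementation.** P-values are computed from a shared log-factorial
table with the hypergeometric support enumerated exactly, so the cost per
gene is proportional to the focal-gene margin, not the library totals.
Rescaled probability masses can underflow for extremely significant
tables; p-values are clamped below at the smallest positive normal double
(the true p is always ≥ the observed table's probability > 0).  The test
suite validates the implementation against an independent exact-integer
enumeration oracle over every table with both row margins ≤ 60
(≈ 3.6 million tables) at relative error < 1e-9, and against
`scipy.stats.fisher_exact` on random tables.

**Untestable genes.** A gene with zero (rounded) counts at both
temperatures admits a single table; it is reported with p = q = 1, tier
`ns`, direction `none`, and excluded from the BH family so it does not
dilute the correction.

**FDR family.** Benjamini–Hochberg runs within each species × stage
family (tests are performed per stage per species), not pooled across
stages.  `bh_adjust` is a thin wrapper over
`statsmodels.stats.multitest.multipletests(method="fdr_bh")`, pinned by
hand-forced cases and monotonicity properties in the suite.

**Direction.** The focal gene's share per column, n₁₁/(n₁₁+n₂₁) vs
n₁₂/(n₁₂+n₂₂), compared by exact integer cross-multiplication; exact
ties are `none` rather than arbitrarily assigned.

**Test input.** Normalized values are rounded half-up to integers before
table construction (the exact test needs counts); raw-count input is
available via `DEConfig(input_values="raw")`.  Fold-changes are reported
as log2((high + 0.5)/(low + 0.5)) on unrounded normalized values —
reporting only, never used in testing.

## Normalization

Per-library factors, all centered to geometric mean 1:

- **Upper quartile**: the linearly interpolated 75th percentile of a
  library's *nonzero* counts among non-excluded genes.  Nonzero-only and
  the interpolation rule are stated because quantile conventions differ.
- **Housekeeping**: per library, the geometric mean over reference genes
  of (count ÷ that gene's cross-library geometric mean).  Symmetric in
  libraries and robust to a single outlying reference gene.  Reference
  genes must be present and nonzero everywhere.
- **Trimming** (the `*99` schemes): the `ceil(0.01 · n_genes)` genes with
  the largest mean raw count (global ranking, lexicographic tie-break at
  the boundary) are removed from factor estimation *and* from the tested
  universe; they still receive normalized values for inspection.

**Composition of the combined schemes.** Because the quantile is exactly
scale-equivariant (q(X/f) = q(X)/f) and factors are re-centered, a chain
of multiplicative factor steps telescopes to whichever step is applied
last: housekeeping-then-quartile reduces to quartile-only, and
quartile-then-housekeeping reduces to housekeeping anchoring.  The
combined `UQHK` schemes therefore apply the housekeeping anchor last —
this is what makes them distinct from `UQ100`, equalizes the reference
genes exactly (the property that permits validation against
housekeeping-normalized qPCR profiles), and yields the conservativeness
ordering |DE(UQHK100)| ≤ |DE(UQ100)| under library-composition skew.
Both step orders are computable (`apply_scheme(..., order=...)`); the
telescoping asymmetry is documented by a dedicated test rather than
hidden.  The upper-quartile component is retained in the factor table as
a diagnostic: the ratio of the two components measures how far
composition skews the quantile away from the housekeeping anchor.

## Subsampling pseudo-replication

Splitting a library's reads uniformly at random into k parts is, at
count level, an exact multinomial split of each gene's count with
probabilities 1/k; the package operates there directly (multi-mapping
effects of read-level splitting are out of scope).  Subsamples of one
library are technical replicates with purely multinomial noise, so the
matched-pair test is the exact conditional binomial test — valid without
any replicate-based variance estimation.  The consensus rule (significant
at 1 % BH FDR with a consistent direction in *all* pairs) is a declared
policy; it behaves as an intersection, so the consensus set's realized
FDR cannot practically exceed a single pair's, at the cost of power.
Note the subsamples inherit the *same* pool, so this cross-check guards
against counting noise and per-pair testing artifacts, not against
between-pool biological variation.

## Synthetic data generator

The generator reproduces the study design (2 species × 5 stages × 2
temperatures, one library per cell, pools of 10 and 5 embryos) with a
declared noise hierarchy:

1. per embryo and gene, expression ~ Gamma(1/d, μ·d) — NB-style
   dispersion d among embryos (variance μ²d); d = 0 means the embryo
   contributes μ exactly;
2. the pool sums its embryos' contributions (a Gamma sum, so pooling n
   embryos shrinks the effective between-library dispersion to d/n);
3. sequencing is one multinomial draw of the configured depth over the
   pooled proportions — column totals are exact.

Temperature effects are stage-specific log2 fold-changes on a
configurable fraction of genes, split symmetrically (2^(∓lfc/2) at
low/high temperature) with a per-gene sign shared across species so
cross-species concordance analyses are meaningful; the GSD species
defaults to zero effects (a negative control), with a "relic" mode
available by giving it a nonzero fraction.  Housekeeping genes (the
named *Tfr* and *Hprt1* plus unnamed companions) are constitutive: zero
fold-change, zero dispersion by default, abundance pinned at 3× the
upper-quartile so they sit where reference genes should.  An
"ncRNA-like" fraction (5 %) gets 0.05× abundance to exercise
low-count behavior.  Defaults follow the emulated design where it
specifies them (stages {9, 12, 15, 19, 22}; pool sizes 10 and 5;
effects confined to the thermosensitive period, stages 15–22); where it
does not, values are stated assumptions: base means log-normal with
σ = 1.2 (a typical bulk RNA-seq abundance spread), between-embryo
dispersion 0.05, thermosensitive fraction 5 % at |lfc| = 2.

**Depth.** Libraries default to 2 × 10⁶ reads — a desk-scale stand-in for
deep production sequencing, chosen so the full pipeline and its
evaluation run in minutes on one core; depth is a configuration knob and
every calibration statement in the tests names the depth it was measured
at.  20,000 genes approximates the annotated gene universe the emulated
design quantified against.

**What passing tests show.** Calibration and power results on this
generator validate the *procedure* (exactness, FDR mechanics, scheme
behavior, consensus logic) under its declared noise model.  Real
libraries add effects the generator deliberately omits — gene length and
GC bias, isoform ambiguity, multi-mapping, batch effects, and
between-pool variation of unknown magnitude — so realized FDR and power
on real data can be worse than the synthetic figures, which is precisely
why the stringent tier exists.

## Numerical and policy details

- Factors strictly positive and finite; geometric-mean centering to
  1 ± 1e-12.
- Normalization preserves zeros exactly (value 0 iff raw count 0).
- Rounding of normalized values: half-up (`floor(x + 0.5)`).
- Venn decompositions are exact set algebra, limited to 4 sets.
- Direction-concordance against a reference profile counts only stages
  where *both* sides call a direction (agreeing on "no signal" is not
  evidence of concordance); the ns-inclusive variant is available.
- Cross-species gene matching is caller-supplied (shared ids or an
  explicit two-column mapping); no orthology inference.
- All randomness flows from recorded seeds (simulation seed, subsample
  seeds derived per library via SHA-256); pipeline runs are byte-identical
  under identical configurations.

## Known limitations

- The exact test's validity is conditional; with one pool per condition
  its p-values understate uncertainty about the *population* of embryos.
  The stringent tier is a mitigation, not a cure.
- The subsampling consensus cannot detect pool-level confounding.
- The housekeeping anchor is only as good as the reference genes'
  constitutive expression; the factor table's component ratio is the
  diagnostic to inspect.
- Between-species normalization is intentionally absent (each species is
  normalized independently); cross-species statements are set-level only.
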