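# Methods

## Scope and model

`contamqc` operates on an ASV-by-sample table of non-negative integer
counts, sample metadata (batch, sequencing run, sample type, DNA
concentration), and optionally a 7-rank taxonomy.  It assumes a study
design with exactly two batches for between-batch operations (between-run
comparisons work within any batch with ≥ 2 runs), negative controls that
are template-free blanks, and — for the frequency score — a measured DNA
concentration per biological sample that predominantly reflects the
sample's own biomass.

The underlying contamination model: reagents inject a roughly constant
absolute amount of each contaminant's DNA per reaction.  In a sample with
true biomass *d*, a contaminant with load λ therefore has expected relative
frequency λ/(d + Λ) (Λ the summed load), which (i) decreases with *d*,
(ii) dominates template-free controls, and (iii) is consistent within a
batch but differs between batches that used different reagent lots.  The
three tiers of the framework each target one of these signatures.

## Tier 1: contaminant scores

**Frequency score.**  Both candidate models have one free parameter, fitted
by least squares in log10–log10 space over usable samples (relative
frequency > 0 and concentration known; minimum 5, else the score is
missing): contaminant log f = −log d + a, non-contaminant log f = b.  The
score is the upper tail of F(m−1, m−1) at S_n/S_c.  This is a model-
comparison ratio between two non-nested one-parameter models, not a nested
F test; under concentration-independent data it concentrates near 1, under
1/d data near 0, which is the behaviour the classification threshold needs.
Only `biological` samples enter the fit: control samples either lack a
meaningful concentration (blanks) or have compositions unrelated to the
community (mocks).

**Prevalence score.**  With the taxon present in p_s of n_s biological
samples and p_n of n_n pooled negative controls, the score is the
hypergeometric tail P[X ≥ p_n] for X drawn as n_n units from the p_s + p_n
presences among all n_s + n_n units — a one-sided Fisher exact test for
enrichment in the controls.  Negative controls from all batches are pooled.

**Classification.**  `either` takes the smaller defined score, `both` the
larger, `combined` Fisher's χ² combination (2 df per defined score); a
score below the threshold (default 0.5) flags the taxon.  Taxa with no
defined score are reported unscored rather than silently passed.

## Tier 2: prevalence structure

For prevalence P over N samples, SEP = √(P(1−P))/N.  This is the form the
framework fixes, dividing by N rather than √N; the conventional binomial
standard error √(P(1−P)/N) is available via `conventional=True` on `sep`
and `compare_groups`.  The default is deliberately the stricter/smaller
quantity; because the stringency factor k multiplies the whole bracket,
the choice moves thresholds only marginally.

The acceptance threshold for the other group is T = (P − (SEP_a + SEP_b))·k
with k ∈ [0,1], default 0.067.  A taxon is a contaminant of group a iff
p_b < T_a strictly; T ≤ 0 can never flag, and the two directions are
mutually exclusive for k ≤ 1 (asserted).  k is a user-set stringency; no
fitting procedure for it is provided.  Prevalence is computed on raw counts
(detection = ≥ 1 read by default, exposed as a parameter) over biological
samples only — negative controls, mocks and replicate biological controls
are excluded from group prevalences.  Between-run comparisons use all
unordered run pairs within a batch; between-batch uses the two batches.
All calls are unioned with per-analysis provenance.

## Stage 3: QC metrics

ICC variants follow the Shrout–Fleiss single-measurement forms computed
from the two-way ANOVA mean squares: absolute agreement ICC(2,1) =
(MSR−MSE)/(MSR+(k−1)MSE+k(MSC−MSE)/n) and consistency ICC(3,1) =
(MSR−MSE)/(MSR+(k−1)MSE).  Batch pairing aligns per-taxon batch means
(prevalence or mean relative abundance) over the union of taxa, entering
zeros for absent taxa; ICC is computed on raw values by default with a
log10(x + pseudocount) option.  A fully constant matrix returns ICC = 1 by
convention (logged).  Confidence intervals are out of scope.

Correlation structure is pairwise Spearman over samples, restricted to taxa
with mean relative abundance ≥ 0.1% (default); constant taxa give NaN.

## Community analysis

Processing order is fixed: tier-1 removals → taxonomy filter (unassigned
kingdom, Cyanobacteria, mitochondria, chloroplast) → tier-2 removals →
rarefaction (default depth 8000; samples below depth dropped; multivariate
hypergeometric draw with explicit seed) → removal of taxa with < 60 total
reads (strict) → relativization of every sample to 8000.  Bray–Curtis uses
the standard quantitative form; PCoA Gower-centers −d²/2 and reports
negative eigenvalues without using them for axes.  PERMANOVA partitions the
squared-distance sum with free label permutation; RDA projects the
column-centered response onto the centered design of a single variable
(dummy-coded if categorical; Hellinger transform optional) and permutes
design rows.  Both use p = (1 + exceedances)/(1 + permutations) and fixed
seeds, so reruns are bit-identical.

## Simulator

The generator emulates the structure above: a shared true composition drawn
once from a normalized log-normal (σ = 2, a realistic steep rank-abundance
curve), per-sample compositions Dirichlet(50·θ), DNA concentrations
LogNormal(0, 0.7) in arbitrary units, per-batch contaminant loads drawn
once from U(0.005, 0.03) per taxon (≈ 40% contaminant reads at median DNA
concentration — heavy but typical for genuinely low-biomass specimens),
depths NegBin(mean 20000, size 10) and multinomial counts.  Defaults: 200
biological samples per batch over 2 runs, 300 true taxa, 40 contaminants
per batch (disjoint sets), 12 negative controls and 8 mock samples per
batch, an 8-taxon mock at equal proportions (user-settable; vendor sheets
vary by kit), and 9 biological controls re-sequenced in both batches.
Run-confined contaminant subsets are available (off by default) to exercise
between-run detection.

What the simulator does *not* emulate: sequencing error and chimeras,
index hopping, taxon-taxon ecological correlations within the true
community, compositional coupling between contaminant load and measured
DNA concentration, and biological covariate structure.  Passing tests
therefore demonstrate that the algorithms behave as specified under the
contamination model they assume — not that any particular real dataset is
clean after processing.

## Numerical choices and degenerate inputs

Zero-total samples are dropped from relative abundance with a warning
(rarefaction removes them anyway); zero-total samples error in
`relativize`.  The frequency score returns missing on < 5 usable points or
a doubly-degenerate fit; scores are clipped at 1e-300 before Fisher
combination.  PCoA treats eigenvalues below 1e-12 of the leading one as
zero.  `compare_groups` reports only taxa detected in at least one group.
Pipeline problem sizes used in the shipped checks (400 biological samples,
~390 taxa, 999 permutations) were chosen so a complete run takes seconds
on a laptop while keeping binomial noise on prevalences far below the
tier-2 thresholds being tested.

## Known limitations

Exactly two batches for between-batch logic; single-variable (not
conditioned) RDA; no ICC confidence intervals; no abundance-based
between-batch flagging; k has no automatic selection — sensitivity to it
should be explored with `compare_groups` over a k grid.  The frequency
score cannot distinguish high true biomass from high contaminant load when
the measured concentration itself is contaminant-dominated; in that regime
only the structure tier and negative controls carry signal.
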