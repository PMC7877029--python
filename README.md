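# contamqc

Quality control for low-biomass microbiome count tables: two-tier reagent-
contaminant identification, batch-variability diagnosis, and repeatability /
reproducibility metrics.

## The problem

Low-biomass samples (human milk, skin, placenta, environmental swabs...)
carry so little microbial DNA that the "kitome" — bacterial DNA shipped
inside extraction and PCR reagents — makes up a large share of the reads in
a 16S rRNA amplicon sequence variant (ASV) table.  When a study is processed
in more than one batch with different reagent lots, each batch acquires its
own contaminant profile, which masquerades as a batch effect and can swamp
the real biology.  `contamqc` is for people running or merging multi-batch
amplicon studies who need to decide, taxon by taxon, what is signal and what
is kit.

## The method

**Tier 1 — statistical contaminant scores.**  Per taxon, two p-like scores
in [0, 1], small = contaminant-like:

* *frequency*: in log10–log10 space, compare a fixed-slope model of
  relative frequency *f* against DNA concentration *d*, log *f* = −log *d* + a
  (contaminant: constant absolute input), to a constant model log *f* = b
  (genuine community member).  With residual sums of squares S_c and S_n over
  m usable samples, score = P[F(m−1, m−1) ≥ S_n/S_c].
* *prevalence*: one-sided hypergeometric tail for over-representation in
  template-free negative controls.

Scores below a threshold (default 0.5) under a chosen combination rule
(`frequency`, `prevalence`, `either`, `both`, `combined`) flag the taxon.

**Tier 2 — prevalence data structure.**  Reagent contamination is consistent
within a batch but differs between batches, whereas a genuine taxon should be
detected at comparable rates in both.  For prevalence *P* over *N* samples
the standard error of prevalence is

    SEP = √(P·(1−P)) / N

and the minimum acceptable prevalence in the other group is

    T = (P − (SEP₁ + SEP₂)) · k,   k ∈ [0, 1]  (default 0.067).

A taxon whose prevalence in one group falls strictly below the other group's
threshold is flagged as a contaminant of the higher-prevalence group.  The
comparison runs pairwise between sequencing runs within each batch and
between batches; calls are unioned with provenance.

**Stage 3 — QC metrics.**  After cleaning (rarefaction to 8000 reads,
removal of taxa under 60 total reads, relativization to 8000), the package
quantifies what changed: intraclass correlation of per-taxon batch means
(absolute agreement ICC(2,1) and consistency ICC(3,1)), within-batch
Spearman correlation structure, Bray–Curtis dissimilarity with PCoA,
PERMANOVA of the batch factor, core-taxon detection, and univariable
redundancy analysis (RDA) against sample covariates.

A bundled simulator generates two-batch studies with planted ground truth —
shared true community, disjoint per-batch contaminant overlays whose
relative frequency falls with DNA concentration, negative controls, a mock
community and replicated biological controls — so every claim the package
makes can be tested against known labels.

## Worked example

```python
from contamqc import SimulationConfig, simulate_study, PipelineConfig, run_pipeline

study = simulate_study(SimulationConfig(seed=1))
report = run_pipeline(PipelineConfig(), study.table, study.metadata, study.annotations)
print(report.summary())
```

```
contamqc pipeline report
========================
input                        taxa=388    samples=458   removed_taxa=0
decontam                     taxa=285    samples=458   removed_taxa=103
taxonomy_filter              taxa=285    samples=458   removed_taxa=0
batch_structure              taxa=247    samples=458   removed_taxa=38
rarefaction                  taxa=247    samples=348   removed_taxa=0
low_count_filter             taxa=241    samples=348   removed_taxa=6
ICC(agreement) mean rel. abundance: 0.864 -> 0.999
ICC(consistency) mean rel. abundance: 0.863 -> 0.999
PERMANOVA batch R^2: 0.5598 (p=0.001) -> 0.0021 (p=0.938)
core taxa: 13
```

Reading this: the simulated study planted 80 batch-specific contaminants
among 388 taxa.  The decontam tier removed 103 taxa (contaminants plus some
rare noise), the structure tier caught 38 more, and rarefaction dropped the
348 deepest-enough samples (negative controls lose nearly all their reads
once contaminants are gone, so they fall out here — as intended).  Agreement
between the two batches' mean taxon abundances rose from 0.86 to ~1, and
the batch effect on community composition (PERMANOVA R² = 0.56, p = 0.001)
vanished after cleaning (R² = 0.002, p = 0.94).

The same pipeline is available from the shell:

```bash
contamqc simulate --seed 1 --out-dir study/
contamqc run-all --counts study/counts.tsv --metadata study/metadata.tsv \
    --taxonomy study/taxonomy.tsv --out-dir study/qc --seed 0
```

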