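# Methods

## Model and procedure

The package treats immune counterselection as a thinning process: a somatic
missense mutation that yields an MHC class I–displayed peptide in an
expressed gene marks the clone for possible T-cell elimination, so such
mutations are under-represented in sequenced tumors. The observable is a
density contrast, not a per-mutation label.

The pipeline stages are:

1. **Mapping.** Variants arrive annotated to a 1-based protein residue; the
   stated wild-type residue must match the protein sequence, otherwise the
   variant is kept but marked non-validated and excluded from all counts.
   Variants carrying only a gene id are resolved to the gene's longest
   isoform (deterministic; ties broken by protein id) and the fallback is
   counted in the run manifest.
2. **Display masks.** Strong binders are 9-mer windows with prediction
   score ≤ 50 (inclusive; lower = stronger). A protein's panel mask is the
   union of window coverage over the 12-allele prediction panel (5 HLA-A,
   7 HLA-B). In patient mode a copy-count track sums, per residue, the
   genotype copy count of each carried allele with a covering window.
   Masks are built on the wild-type sequence and are mutation-independent.
   Copy count 1 → D1, ≥ 2 → D2 (homozygous and two-distinct-allele display
   are pooled; the two sub-classes are not separated because copy number,
   not allele identity, is the modeled dose). Copy count 0 inside the panel
   mask (D0) is excluded from both numerator and denominator: such sites
   are not immunogenic for this patient, but they are also not clean
   background, since their composition matches displayed peptides.
   Out-of-panel alleles (including HLA-C) are treated as non-displaying —
   no predictions exist for them.
3. **Expression strata.** Per cancer type, genes with median RSEM 0 are
   UNDETECTED; detectably expressed genes are split at the 25/50/75th
   percentiles of their values in that cancer type. A value exactly on a
   boundary goes to the lower quartile; ties share a stratum. Genes absent
   from the expression table are excluded entirely (absence of evidence is
   not zero expression) and counted in the manifest.
4. **Opportunity counting.** For each cell (stratum × display class) a 2×2
   table is accumulated: mutations in/out of the class versus residue-site
   opportunities in/out. The opportunity set is, by default, every
   (patient, protein) pair with at least one validated mapped variant of
   that patient — of either variant class. Defining inclusion by both
   classes matters: if pairs entered only when they carry a variant of the
   analyzed class, pairs whose mutations were thinned hardest would enter
   less often, and the recovered survival would be biased upward (we
   measured ≈ +0.05 at moderate per-pair variant intensity). Synonymous
   variants are not thinned, so they keep inclusion nearly independent of
   selection. A `cohort_protein` option instead counts every
   (patient, mutated-protein) combination; pan-allele mode counts each
   (cancer type, protein) with a variant once.
5. **Statistics.** Density ratio `r = (m_in/s_in)/(m_out/s_out)`; Fisher's
   exact test (two-sided, scipy) on
   `[[m_in, s_in − m_in], [m_out, s_out − m_out]]` — this orientation makes
   the odds ratio approximate the density ratio since mutations are rare
   per site. The corrected ratio divides each expressed stratum's `r` (and
   the pooled-expressed `r`) by the UNDETECTED `r` of the same display
   class. Clearance is `100 × (1 − R)`, clamped to 0 and flagged when
   `R > 1`, an error for `R ≤ 0` (a corrected ratio of exactly 0 — empty
   numerator — is reported as 100% with the cell counts alongside).
   All arithmetic is at full precision; rounding (default 2 decimals)
   happens only in the TSV/report layer.
6. **Bootstrap.** Patients are the resampling unit, because mutations
   within a patient share one genotype. The pooled-expressed corrected
   ratio is recomputed on each of 500 (default) resamples of the
   per-patient count tensor; the 2.5/97.5 percentiles form the interval
   (plain percentile, no BCa — the replicate distribution is examined
   directly). Replicates with an empty cell are recorded as missing and
   excluded, with the count reported. The RNG stream derives from the run
   seed plus the display class, so classes are independent but the whole
   run is reproducible; identical config + seed gives byte-identical JSON.

### Degenerate inputs

A cell with a zero denominator (no sites, or no out-mutations) yields an
undefined, flagged ratio rather than a silent 0; correction and clearance
are skipped for it. A scope with no countable pairs at all is an error
naming the scope. Flagged proteins (non-standard residues) are excluded
from window building and counting, with counts in the manifest.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| strong_binder_threshold | 50 | prediction-score cutoff (score units, lower = stronger), inclusive |
| peptide_length | 9 | window length in residues |
| allele_panel | 12 HLA-A/B alleles | alleles with available predictions |
| bootstrap_reps | 500 | patient resamples per CI |
| opportunity | per_patient_protein | opportunity-set definition (see above) |
| gene_universe | all | `displayed` restricts to pairs with ≥ 1 patient-displayed site |
| rounding | 2 | reporting-layer decimals |

## Synthetic cohorts

The generator emulates the statistical structure the analysis relies on,
not real biology:

- **Sequences** are i.i.d. uniform over the 20 amino acids.
- **Binding** (`toy_pwm` default) scores each 9-mer from two anchors: a
  C-terminal anchor shared by all alleles (L/V/I, as for real class I
  C-termini) and an allele-specific position-2 anchor drawn from a common
  pool. Shared anchors make per-allele masks overlap (so D2-by-two-alleles
  occurs) and make displayed positions hydrophobic-enriched. A lognormal
  noise factor produces borderline scores on both sides of the threshold,
  and sub-threshold rows are emitted so the reader's filter is exercised.
  `random_windows` places windows without sequence bias.
- **Genotypes** are drawn per locus from rough European-ancestry panel
  frequencies; the remaining mass is a panel-external allele, which
  exercises the carried-but-unpredicted (D0) logic.
- **Expression** is 0 with probability 0.25, else lognormal (μ=2, σ=1 on
  the log scale), per gene per cancer type.
- **Mutations** arise per (patient, residue) as Bernoulli with rate
  `mutation_rate × multiplier(residue)`; hydrophobic residues mutate 1.5×
  faster, deliberately confounding display with mutation rate so that the
  uncorrected ratio sits away from 1 under the null and only the
  undetected-gene correction recovers it. A missense candidate at an
  expressed site survives with probability `survival[D1]`/`survival[D2]`
  (defaults 0.9 / 0.77, the study conditions); OUT, D0 and non-expressed
  sites always survive. Synonymous candidates always survive.
- Per-residue rates are per-cohort compressions (a few hundred proteins
  stand in for the exome), far above per-patient genomic rates; what
  matters for the estimator is counts per cell, not the absolute rate.

Not emulated: codon structure and mutational signatures, real binding
motifs, linked isoforms, per-sample expression, tumor purity/subclonality.
Passing tests therefore show the estimator recovers a known thinning under
the assumed sampling structure — not that any particular real cohort
satisfies those assumptions.

## Problem sizes used by tests and the acceptance script

Recovery runs use 400 proteins × 200 patients at per-residue rate 0.004
(~110k missense mutations), where the per-pair variant intensity is high
enough (inclusion probability ≈ 0.95) that the opportunity-set conditioning
described above is negligible and the configured survivals are recovered
within ±0.05. Null-calibration uses 50 cohorts of 120 proteins × 60
patients with survival 1.0; coverage of 1.0 by the 95% bootstrap interval
is required in ≥ 45/50. The exact-test implementation is checked against
an exhaustive hypergeometric enumeration on all 2×2 tables with row margins
≤ 30 (agreement to 1e-9).

## Limitations

- The corrected ratio is a cohort-level contrast; it does not score
  individual mutations.
- D2 pools homozygous and two-distinct-allele display; sub-class contrasts
  (e.g. monoallelic-expression hypotheses) need larger cohorts and are not
  separated here.
- Expression is matched by cancer type, not by sample; genes expressed in
  the cohort median but silenced in a particular tumor dilute the signal,
  biasing clearance estimates downward (conservative).
- The paper-scale analyses of public pan-cancer cohorts require those
  cohorts' variant, HLA and expression tables as inputs; the package ships
  only synthetic stand-ins with matching dialects.
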