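# neodepletion

Quantifies immune-based counterselection (immunoediting) of somatic
mutations in tumors: the depletion of missense mutations inside peptides
predicted to be displayed by MHC class I, stratified by gene expression and
by the number of HLA allele copies the patient carries that can display the
peptide.

It is aimed at cancer-genomics analysts who have, for a cohort of patients:
a somatic variant table annotated to protein space (MAF-like), protein
sequences (FASTA), 4-digit HLA class I genotypes, per-allele 9-mer binding
predictions (NetMHC-style long table), and median gene expression per
cancer type (RSEM scale). A synthetic-cohort generator with the same file
dialects makes every stage testable without access data.

## The statistic

For a set of proteins, residues covered by any strong-binder 9-mer
(prediction score ≤ 50; lower = stronger) form the *in* positions and the
rest the *out* positions. With mutation counts `m_in`, `m_out` over
residue-site opportunities `s_in`, `s_out`, the mutation density ratio is

```
r = (m_in / s_in) / (m_out / s_out)
```

Because MHC alleles prefer particular residue compositions, `r` can deviate
from 1 without any selection. Undetectably expressed genes cannot present
peptides, so their ratio `r_und` isolates that sequence bias, giving the
corrected mutational density ratio and the implied immune-clearance rate

```
R = r_expr / r_und            clearance % = 100 × (1 − R)
```

Significance per 2×2 opportunity table is assessed with Fisher's exact
test; uncertainty in `R` with a percentile bootstrap resampling patients.
In patient mode each variant site is classified by the number of carried
displaying-allele copies — D1 (one copy) vs D2 (two, via homozygosity or
two distinct displaying alleles) — so incomplete dominance of HLA alleles
appears as `R_D2 < R_D1`. Sites displayed only by panel alleles the patient
does not carry (D0) are excluded from both sides of the ratio.

## Worked example

Simulate a 60-patient cohort in which expressed, patient-displayed missense
mutations survive immune surveillance with probability 0.9 (D1) / 0.77
(D2), then analyze it:

```
neodepletion simulate --config examples/config.yaml --outdir demo/cohort
neodepletion run      --config examples/config.yaml --inputs demo/cohort --outdir demo/out
neodepletion report   --results demo/out/results.tsv
```

The report prints, per display class, the in/out opportunity tables and
ratios by expression stratum. For this seed the pooled expressed rows are:

```
display_class  ratio  corrected_ratio  ci_low  ci_high  clearance_percent  p_value
       ANY_IN   0.92             0.89    0.76     1.05              11.03 0.037050
           D1   0.97             0.97    0.82     1.13               3.06 0.530670
           D2   0.76             0.68    0.54     0.84              32.21 0.000034
```

Reading: among expressed genes, mutation density inside patient-displayed
peptides is 0.92× the outside density; correcting by the undetected-gene
control gives 0.89. Mutations displayable by two allele copies (D2) are
depleted more strongly (corrected 0.68, bootstrap 95% CI 0.54–0.84) than
D1 mutations — the incomplete-dominance signature. At this small cohort
size the intervals are wide; the configured survivals (0.9 / 0.77) are
recovered tightly at 200 patients and ~10⁵ mutations (see below). The
implied clearance rate for D2 here is 32%, i.e. roughly a third of such
mutant clones were eliminated before sampling.

`demo/out/` also contains `results.json` (full precision) and
`manifest.json` (config echo, input digests, stage counts), and reruns with
the same config and seed are byte-identical.

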