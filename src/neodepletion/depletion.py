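"""Opportunity-adjusted mutation counts, density ratios and exact tests.

For each (expression stratum, display class) cell the pipeline accumulates a
2x2 opportunity table: mutations falling inside vs outside displayed
positions, against residue-site totals inside vs outside. The in/out density
ratio among expressed genes is corrected by the same ratio among
undetectably expressed genes, cancelling sequence-composition bias of the
displayed peptides; 1 minus the corrected ratio is the implied fraction of
mutant clones cleared by immune surveillance.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from . import io as nio
from .display import (
    CODE_D0,
    CODE_D1,
    CODE_D2,
    CODE_IN,
    CODE_OUT,
    build_allele_masks,
    build_panel_mask,
    classify_positions,
)
from .io import ExpressionTable
from .strata import strata_by_cancer
from .types import (
    AnalysisConfig,
    BindingWindow,
    ConfigurationError,
    CountClass,
    DataError,
    ExpressionStratum,
    HlaGenotype,
    MappedVariant,
    Mode,
    ProteinRecord,
)

log = logging.getLogger(__name__)

_STRATUM_INDEX = {
    ExpressionStratum.UNDETECTED: 0,
    ExpressionStratum.Q1: 1,
    ExpressionStratum.Q2: 2,
    ExpressionStratum.Q3: 3,
    ExpressionStratum.Q4: 4,
}
_N_CODES = 5  # OUT, D0_IN_PANEL, D1, D2, IN
_KIND_SITE, _KIND_MUT = 0, 1

#: pooled-expressed pseudo-stratum label used in results
EXPRESSED = "EXPRESSED"

_CLASS_CODES = {
    CountClass.ANY_IN: (CODE_D1, CODE_D2, CODE_IN),
    CountClass.D1: (CODE_D1,),
    CountClass.D2: (CODE_D2,),
}


@dataclass(frozen=True)
class StratumCounts:
    """One 2x2 opportunity table for a (stratum, display class) cell."""

    stratum: str
    display_class: CountClass
    mut_in: int
    mut_out: int
    site_in: int
    site_out: int

    def __post_init__(self) -> None:
        if min(self.mut_in, self.mut_out, self.site_in, self.site_out) < 0:
            raise DataError("negative count in opportunity table")


@dataclass
class DepletionResult:
    cancer_scope: str
    variant_class: str
    mode: str
    counts: StratumCounts
    ratio: float | None
    p_value: float | None
    corrected_ratio: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    clearance_percent: float | None = None
    clearance_flagged: bool = False
    n_bootstrap: int = 0
    n_bootstrap_missing: int = 0
    seed: int = 0
    undefined_ratio: bool = False

    def as_row(self) -> dict:
        c = self.counts
        return {
            "cancer_scope": self.cancer_scope,
            "variant_class": self.variant_class,
            "mode": self.mode,
            "stratum": c.stratum,
            "display_class": c.display_class.value,
            "mut_in": c.mut_in,
            "site_in": c.site_in,
            "mut_out": c.mut_out,
            "site_out": c.site_out,
            "ratio": self.ratio,
            "p_value": self.p_value,
            "corrected_ratio": self.corrected_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "clearance_percent": self.clearance_percent,
            "n_bootstrap": self.n_bootstrap,
            "seed": self.seed,
        }


@dataclass
class CohortCounts:
    """Per-row (patient, or single pooled row in pan mode) count tensor.

    ``tensor[row, stratum, kind, code]`` with kind in {site, mutation} and
    code one of the five site codes. Patient-mode bootstrap resamples rows.
    """

    mode: Mode
    rows: list[str]  # patient ids, or ["cohort"] in pan mode
    tensor: np.ndarray  # (n_rows, 5, 2, 5) int64
    exclusions: dict[str, int] = field(default_factory=dict)
    n_variants_in_scope: int = 0

    def aggregate(self) -> np.ndarray:
        return self.tensor.sum(axis=0)


@dataclass
class CohortInputs:
    """All loaded inputs of one analysis run."""

    proteins: list[ProteinRecord]
    variants: list[MappedVariant]
    genotypes: list[HlaGenotype]
    windows: list[BindingWindow]
    expression: ExpressionTable
    load_stats: dict = field(default_factory=dict)

    @classmethod
    def load(cls, indir: str | Path, config: AnalysisConfig) -> "CohortInputs":
        """Load the five input files from a directory (fixed file names)."""
        indir = Path(indir)
        for name in ("proteins.fasta", "variants.tsv", "hla.tsv",
                     "predictions.tsv", "expression.tsv"):
            if not (indir / name).exists():
                raise ConfigurationError(f"missing input file: {indir / name}")
        proteins = nio.read_fasta(indir / "proteins.fasta")
        raw_variants, var_rejects = nio.read_variants(indir / "variants.tsv")
        mapped, map_rejects, map_stats = nio.map_variants(raw_variants, proteins)
        genotypes = nio.read_hla(indir / "hla.tsv")
        windows, win_rejects = nio.read_binding_predictions(
            indir / "predictions.tsv", config, proteins
        )
        expression = nio.read_expression(indir / "expression.tsv")
        return cls(
            proteins, mapped, genotypes, windows, expression,
            load_stats={
                "variant_rows": len(raw_variants) + len(var_rejects),
                "variant_rejects": len(var_rejects),
                "mapping_rejects": len(map_rejects),
                **map_stats,
                "windows_retained": len(windows),
                "window_rejects": len(win_rejects),
            },
        )


# ---------------------------------------------------------------------------
# count accumulation

def accumulate_counts(
    variants: list[MappedVariant],
    proteins: list[ProteinRecord],
    windows: list[BindingWindow],
    genotypes: list[HlaGenotype],
    strata: dict[str, dict[str, ExpressionStratum]],
    config: AnalysisConfig,
    scope: tuple[str, ...] | None = None,
) -> CohortCounts:
    """Accumulate the per-(stratum, code) site and mutation tensor.

    Opportunity sets: in pan mode each (cancer type, protein) with at least
    one in-scope variant contributes its residue sites once; in patient mode
    (default ``per_patient_protein``) each (patient, protein) pair with at
    least one mapped variant of that patient contributes the patient-specific
    sites once. Sites of class D0_IN_PANEL are tracked but excluded from both
    sides of every ratio.
    """
    by_id = {p.protein_id: p for p in proteins}
    geno = {g.sample_id: g for g in genotypes}
    excl: dict[str, int] = defaultdict(int)

    # opportunity pairs are defined by any validated mapped variant (either
    # class) so pair inclusion does not depend on the thinning acting on the
    # analyzed class; mutation counts use the configured class only
    scope_variants = [
        v
        for v in variants
        if v.validated and (scope is None or v.cancer_type in scope)
    ]
    in_scope = [v for v in scope_variants if v.variant_class is config.variant_class]
    if not in_scope:
        raise DataError(
            f"empty opportunity set: no validated {config.variant_class.value} "
            f"variants in scope {scope or 'ALL'}"
        )

    win_by_protein: dict[str, list[BindingWindow]] = defaultdict(list)
    win_by_protein_allele: dict[str, dict[str, list[BindingWindow]]] = defaultdict(
        lambda: defaultdict(list)
    )
    panel_set = set(config.allele_panel)
    for w in windows:
        if w.allele in panel_set:
            win_by_protein[w.protein_id].append(w)
            win_by_protein_allele[w.protein_id][w.allele].append(w)

    if config.mode is Mode.PAN_ALLELE:
        groups: dict[tuple, list[MappedVariant]] = defaultdict(list)
        for v in scope_variants:
            key = (v.cancer_type, v.protein_id)
            groups[key]
            if v.variant_class is config.variant_class:
                groups[key].append(v)
        rows = ["cohort"]
        row_of = {k: 0 for k in groups}
    else:
        groups = defaultdict(list)
        for v in scope_variants:
            key = (v.sample_id, v.cancer_type, v.protein_id)
            groups[key]
            if v.variant_class is config.variant_class:
                groups[key].append(v)
        if config.opportunity == "cohort_protein":
            # expand: every patient with any variant vs every mutated protein
            mutated = sorted({(k[1], k[2]) for k in groups})
            patients_ct = sorted({(v.sample_id, v.cancer_type) for v in scope_variants})
            expanded: dict[tuple, list[MappedVariant]] = defaultdict(list)
            for (s, ct) in patients_ct:
                for (ct2, pid) in mutated:
                    if ct2 == ct:
                        expanded[(s, ct, pid)] = []
            for k, vs in groups.items():
                expanded[k] = vs
            groups = expanded
        rows = sorted({k[0] for k in groups})
        row_of_patient = {p: i for i, p in enumerate(rows)}
        row_of = {k: row_of_patient[k[0]] for k in groups}

    tensor = np.zeros((len(rows), 5, 2, _N_CODES), dtype=np.int64)
    allele_order = list(config.allele_panel)
    # per-protein (n_panel_alleles x L) boolean coverage matrix, built once;
    # a patient's copy-count track is then a single matrix-vector product
    matrix_cache: dict[str, np.ndarray] = {}
    pan_cache: dict[str, np.ndarray] = {}
    copies_cache: dict[str, np.ndarray] = {}

    def _matrix(prot: ProteinRecord) -> np.ndarray:
        M = matrix_cache.get(prot.protein_id)
        if M is None:
            masks = build_allele_masks(
                prot, win_by_protein_allele.get(prot.protein_id, {}),
                config.peptide_length,
            )
            M = np.zeros((len(allele_order), prot.length), dtype=np.int16)
            for i, a in enumerate(allele_order):
                if a in masks:
                    M[i] = masks[a]
            matrix_cache[prot.protein_id] = M
        return M

    for key in sorted(groups):
        vs = groups[key]
        cancer_type, pid = key[-2], key[-1]
        prot = by_id.get(pid)
        if prot is None or prot.flagged:
            excl["protein_unavailable"] += len(vs)
            continue
        per_ct = strata.get(cancer_type)
        stratum = per_ct.get(prot.gene_id) if per_ct else None
        if stratum is None:
            excl["missing_expression"] += len(vs)
            continue
        if config.mode is Mode.PAN_ALLELE:
            codes = pan_cache.get(pid)
            if codes is None:
                codes = classify_positions(
                    build_panel_mask(prot, win_by_protein.get(pid, []),
                                     config.peptide_length),
                    Mode.PAN_ALLELE,
                )
                pan_cache[pid] = codes
        else:
            sample = key[0]
            g = geno.get(sample)
            if g is None:
                excl["missing_genotype"] += len(vs)
                continue
            copies = copies_cache.get(sample)
            if copies is None:
                copies = np.array([g.copies(a) for a in allele_order], dtype=np.int16)
                copies_cache[sample] = copies
            M = _matrix(prot)
            cc = copies @ M
            panel = M.any(axis=0)
            codes = np.zeros(prot.length, dtype=np.int8)
            codes[panel & (cc == 0)] = CODE_D0
            codes[panel & (cc == 1)] = CODE_D1
            codes[panel & (cc >= 2)] = CODE_D2
            if config.gene_universe == "displayed" and not (codes >= CODE_D1).any():
                excl["not_displayed_universe"] += len(vs)
                continue

        ridx = row_of[key]
        sidx = _STRATUM_INDEX[stratum]
        tensor[ridx, sidx, _KIND_SITE] += np.bincount(codes, minlength=_N_CODES)
        for v in vs:
            tensor[ridx, sidx, _KIND_MUT, codes[v.position - 1]] += 1

    if tensor[:, :, _KIND_SITE].sum() == 0:
        raise DataError("empty opportunity set: no countable (patient, protein) pairs")
    return CohortCounts(
        mode=config.mode,
        rows=rows,
        tensor=tensor,
        exclusions=dict(excl),
        n_variants_in_scope=len(in_scope),
    )


def cell_counts(
    cohort: CohortCounts,
    stratum: ExpressionStratum | str,
    display_class: CountClass,
    agg: np.ndarray | None = None,
) -> StratumCounts:
    """Extract the 2x2 opportunity table of one (stratum, class) cell."""
    a = cohort.aggregate() if agg is None else agg
    if stratum == EXPRESSED:
        sub = a[1:5].sum(axis=0)
        label = EXPRESSED
    else:
        sub = a[_STRATUM_INDEX[ExpressionStratum(stratum)]]
        label = ExpressionStratum(stratum).value
    codes = list(_CLASS_CODES[display_class])
    return StratumCounts(
        stratum=label,
        display_class=display_class,
        mut_in=int(sub[_KIND_MUT, codes].sum()),
        mut_out=int(sub[_KIND_MUT, CODE_OUT]),
        site_in=int(sub[_KIND_SITE, codes].sum()),
        site_out=int(sub[_KIND_SITE, CODE_OUT]),
    )


# ---------------------------------------------------------------------------
# statistics

def density_ratio(counts: StratumCounts) -> float:
    """(mut_in / site_in) / (mut_out / site_out); full precision."""
    if counts.site_in == 0 or counts.site_out == 0 or counts.mut_out == 0:
        raise DataError(
            f"undefined density ratio for cell ({counts.stratum}, "
            f"{counts.display_class.value}): zero denominator"
        )
    return (counts.mut_in / counts.site_in) / (counts.mut_out / counts.site_out)


def fisher_test(counts: StratumCounts) -> float:
    """Two-sided Fisher's exact p for the 2x2 mutated/non-mutated table."""
    table = [
        [counts.mut_in, counts.site_in - counts.mut_in],
        [counts.mut_out, counts.site_out - counts.mut_out],
    ]
    if min(table[0] + table[1]) < 0:
        raise DataError(f"negative cell in Fisher table {table}")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def corrected_ratio(expressed_ratio: float, nonexpressed_ratio: float) -> float:
    """Expressed-gene in/out ratio divided by the undetected-gene ratio."""
    if nonexpressed_ratio <= 0:
        raise DataError(
            f"non-positive control ratio {nonexpressed_ratio}; correction undefined"
        )
    return expressed_ratio / nonexpressed_ratio


def clearance_percent(corrected: float) -> float:
    """Implied immune-clearance rate, 100 * (1 - corrected ratio).

    Corrected ratios above 1 indicate no detectable depletion and return 0
    (callers flag this); non-positive inputs are an error.
    """
    if corrected <= 0:
        raise DataError(f"corrected ratio must be positive, got {corrected}")
    if corrected > 1:
        return 0.0
    return 100.0 * (1.0 - corrected)


# ---------------------------------------------------------------------------
# bootstrap

def _corrected_from_agg(agg: np.ndarray, display_class: CountClass) -> float:
    """Pooled-expressed corrected ratio from an aggregated tensor; nan if undefined."""
    codes = list(_CLASS_CODES[display_class])
    expr = agg[1:5].sum(axis=0)
    und = agg[0]
    vals = []
    for sub in (expr, und):
        mi = sub[_KIND_MUT, codes].sum()
        mo = sub[_KIND_MUT, CODE_OUT]
        si = sub[_KIND_SITE, codes].sum()
        so = sub[_KIND_SITE, CODE_OUT]
        if si == 0 or so == 0 or mo == 0:
            return float("nan")
        vals.append((mi / si) / (mo / so))
    if vals[1] <= 0:  # undetected control ratio must be positive to correct by
        return float("nan")
    return vals[0] / vals[1]


def bootstrap_ci(
    cohort: CohortCounts,
    display_class: CountClass,
    config: AnalysisConfig,
) -> tuple[float, float, int]:
    """Percentile bootstrap CI for the pooled-expressed corrected ratio.

    Patients are the resampling unit (mutations within a patient share a
    genotype and are not exchangeable). Resamples patients with replacement
    ``config.bootstrap_reps`` times; replicates with an empty cell are
    recorded as missing and excluded. Fully determined by ``config.rng_seed``
    and the display class.
    """
    if cohort.mode is not Mode.PATIENT:
        raise ConfigurationError("bootstrap requires patient mode")
    n = len(cohort.rows)
    if n < 2:
        raise DataError("bootstrap requires at least 2 patients")
    seq = np.random.SeedSequence(
        [config.rng_seed, list(CountClass).index(display_class)]
    )
    rng = np.random.default_rng(seq)
    reps = config.bootstrap_reps
    idx = rng.integers(0, n, size=(reps, n))
    vals = np.empty(reps)
    for r in range(reps):
        agg = cohort.tensor[idx[r]].sum(axis=0)
        vals[r] = _corrected_from_agg(agg, display_class)
    ok = vals[~np.isnan(vals)]
    n_missing = reps - ok.size
    if ok.size == 0:
        raise DataError("all bootstrap replicates had empty cells")
    lo, hi = np.percentile(ok, [2.5, 97.5])
    return float(lo), float(hi), int(n_missing)


# ---------------------------------------------------------------------------
# orchestration

def run_analysis(
    config: AnalysisConfig, inputs: CohortInputs
) -> tuple[list[DepletionResult], dict]:
    """Full depletion analysis; returns (results, manifest counts).

    Produces one result row per (cancer scope, stratum, display class), with
    corrected ratios pairing each expressed stratum (and the pooled-expressed
    stratum) against the UNDETECTED stratum of the same display class, a
    bootstrap CI on the pooled-expressed corrected ratio in patient mode, and
    the implied clearance rate wherever a corrected ratio exists.
    """
    variant_cts = sorted({v.cancer_type for v in inputs.variants})
    known_cts = [ct for ct in variant_cts if ct in inputs.expression.cancer_types]
    strata = strata_by_cancer(inputs.expression, known_cts)

    if config.cancer_types is None:
        scopes: list[tuple[str, tuple[str, ...] | None]] = [("ALL", None)]
    else:
        scopes = [(ct, (ct,)) for ct in config.cancer_types]

    classes = (
        [CountClass.ANY_IN]
        if config.mode is Mode.PAN_ALLELE
        else [c for c in (CountClass.ANY_IN, CountClass.D1, CountClass.D2)
              if c in config.display_classes]
    )

    results: list[DepletionResult] = []
    manifest: dict = {"load": dict(inputs.load_stats), "scopes": {}}
    for scope_name, scope in scopes:
        cohort = accumulate_counts(
            inputs.variants, inputs.proteins, inputs.windows, inputs.genotypes,
            strata, config, scope,
        )
        agg = cohort.aggregate()
        manifest["scopes"][scope_name] = {
            "n_rows": len(cohort.rows),
            "n_variants_in_scope": cohort.n_variants_in_scope,
            "n_variants_counted": int(agg[:, _KIND_MUT].sum()),
            "exclusions": cohort.exclusions,
        }
        for cls in classes:
            und = cell_counts(cohort, ExpressionStratum.UNDETECTED, cls, agg)
            try:
                und_ratio: float | None = density_ratio(und)
            except DataError:
                und_ratio = None
            strata_order: list = [
                ExpressionStratum.UNDETECTED,
                ExpressionStratum.Q1,
                ExpressionStratum.Q2,
                ExpressionStratum.Q3,
                ExpressionStratum.Q4,
                EXPRESSED,
            ]
            for stratum in strata_order:
                counts = (
                    und if stratum is ExpressionStratum.UNDETECTED
                    else cell_counts(cohort, stratum, cls, agg)
                )
                res = DepletionResult(
                    cancer_scope=scope_name,
                    variant_class=config.variant_class.value,
                    mode=config.mode.value,
                    counts=counts,
                    ratio=None,
                    p_value=None,
                    seed=config.rng_seed,
                )
                try:
                    res.ratio = density_ratio(counts)
                    res.p_value = fisher_test(counts)
                except DataError:
                    res.undefined_ratio = True
                is_expressed_row = stratum != ExpressionStratum.UNDETECTED
                if is_expressed_row and res.ratio is not None and und_ratio:
                    res.corrected_ratio = corrected_ratio(res.ratio, und_ratio)
                    if res.corrected_ratio > 0:
                        res.clearance_percent = clearance_percent(res.corrected_ratio)
                        res.clearance_flagged = res.corrected_ratio > 1
                    else:  # empty in-cell: complete depletion of the numerator
                        res.clearance_percent = 100.0
                if (
                    stratum == EXPRESSED
                    and config.mode is Mode.PATIENT
                    and config.bootstrap_reps > 1
                    and len(cohort.rows) >= 2
                ):
                    try:
                        lo, hi, miss = bootstrap_ci(cohort, cls, config)
                        res.ci_low, res.ci_high = lo, hi
                        res.n_bootstrap = config.bootstrap_reps
                        res.n_bootstrap_missing = miss
                    except DataError:
                        pass
                results.append(res)
    return results, manifest
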