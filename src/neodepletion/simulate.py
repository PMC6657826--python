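"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emits the five pipeline inputs — protein FASTA, long-format
binding predictions, HLA genotypes, expression medians and a somatic variant
table — plus a truth file recording the configured per-class survival. The
mechanism mirrors the causal model under study: candidate mutations arise at
residue-dependent baseline rates, and a candidate at an expressed,
patient-displayed site survives immune surveillance with a configurable
probability that depends on the number of displaying allele copies
(incomplete dominance). Synonymous candidates always survive, providing the
negative control by construction.

Two binder models are available. ``toy_pwm`` scores each 9-mer from anchor
residues at peptide positions 2 and 9 (a shared hydrophobic C-terminal
anchor plus allele-specific position-2 anchors drawn from a common pool, so
display masks overlap between alleles and correlate with sequence
composition — the confounder the non-expressed control corrects for).
``random_windows`` places windows uniformly at random, with no sequence
bias.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from .io import ExpressionTable
from .types import (
    AMINO_ACIDS,
    ConfigurationError,
    DEFAULT_ALLELE_PANEL,
    HlaGenotype,
    ProteinRecord,
    SomaticVariant,
    VariantClass,
)

#: roughly European-ancestry-like panel allele frequencies per locus; the
#: remainder of each locus is a panel-external allele with no predictions,
#: which exercises the carried-but-unpredicted (D0) logic.
DEFAULT_PANEL_FREQUENCIES: dict[str, dict[str, float]] = {
    "A": {
        "A*0101": 0.15, "A*0201": 0.25, "A*0301": 0.12,
        "A*2402": 0.10, "A*2601": 0.05,
    },
    "B": {
        "B*0702": 0.12, "B*0801": 0.10, "B*1501": 0.08,
        "B*2705": 0.04, "B*3901": 0.03, "B*4001": 0.06, "B*5801": 0.04,
    },
}

_HYDROPHOBIC = "AVLIMFWY"
#: anchor-2 residue pool shared across alleles (creates inter-allele overlap)
_ANCHOR2_POOL = "LMIVFYATSK"
#: shared hydrophobic C-terminal anchor residues
_ANCHOR9 = "LVI"


@dataclass
class SimulationConfig:
    """Cohort-generator parameters; defaults define the study conditions."""

    seed: int = 0
    n_proteins: int = 120
    protein_length: tuple[int, int] = (150, 450)  # uniform range, residues
    n_patients: int = 60
    n_cancer_types: int = 1
    panel_frequencies: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            locus: dict(d) for locus, d in DEFAULT_PANEL_FREQUENCIES.items()
        }
    )
    binder_model: str = "toy_pwm"  # or "random_windows"
    window_density: float = 0.02  # random_windows: per-start strong-binder prob
    strong_binder_threshold: float = 50.0
    emit_affinity_max: float = 500.0  # weaker rows still written (exercise filter)
    peptide_length: int = 9
    fraction_undetected: float = 0.25
    expression_lognorm: tuple[float, float] = (2.0, 1.0)  # (mu, sigma) of log RSEM
    mutation_rate: float = 0.0025  # missense candidates per residue per patient
    synonymous_rate: float = 0.0025
    #: residue-dependent rate multipliers; hydrophobic residues mutate faster,
    #: confounding display (which prefers hydrophobic anchors) with rate
    residue_rate_multipliers: dict[str, float] = field(
        default_factory=lambda: {aa: 1.5 for aa in _HYDROPHOBIC}
    )
    #: survival probability of an expressed, patient-displayed candidate
    #: mutation by displaying-allele copy-count class; OUT, D0 and
    #: non-expressed sites always survive
    survival: dict[str, float] = field(
        default_factory=lambda: {"D1": 0.9, "D2": 0.77}
    )

    def __post_init__(self) -> None:
        if self.protein_length[0] < self.peptide_length:
            raise ConfigurationError(
                f"minimum protein length {self.protein_length[0]} is shorter "
                f"than the peptide length {self.peptide_length}"
            )
        for k, v in self.survival.items():
            if not 0 <= v <= 1:
                raise ConfigurationError(f"survival[{k}]={v} outside [0, 1]")
        for locus, freqs in self.panel_frequencies.items():
            if sum(freqs.values()) > 1 + 1e-9:
                raise ConfigurationError(f"locus {locus} frequencies sum above 1")
        if self.binder_model not in ("toy_pwm", "random_windows"):
            raise ConfigurationError(f"unknown binder model {self.binder_model!r}")


@dataclass
class Cohort:
    """An in-memory synthetic cohort (files are a serialization of this)."""

    proteins: list[ProteinRecord]
    predictions: pd.DataFrame  # protein_id, allele, start, affinity
    genotypes: list[HlaGenotype]
    expression: ExpressionTable
    variants: list[SomaticVariant]
    truth: dict


def _allele_anchors(panel: tuple[str, ...]) -> dict[str, str]:
    """Deterministic allele-specific position-2 anchor residues."""
    out = {}
    for i, a in enumerate(sorted(panel)):
        out[a] = _ANCHOR2_POOL[i % len(_ANCHOR2_POOL)] + \
            _ANCHOR2_POOL[(i + 3) % len(_ANCHOR2_POOL)]
    return out


def _predict_windows(
    seq_idx: np.ndarray,
    panel: tuple[str, ...],
    sim: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(allele_idx, start_1based, affinity) arrays of emitted prediction rows."""
    L = seq_idx.size
    n_starts = L - sim.peptide_length + 1
    if sim.binder_model == "random_windows":
        strong = rng.random((len(panel), n_starts)) < sim.window_density
        affinity = np.where(
            strong,
            rng.uniform(1.0, sim.strong_binder_threshold, (len(panel), n_starts)),
            rng.uniform(
                sim.strong_binder_threshold + 1, sim.emit_affinity_max,
                (len(panel), n_starts),
            ),
        )
        # emit all strong rows plus a thin sample of weak decoys
        emit = strong | (rng.random((len(panel), n_starts)) < 0.01)
    else:
        anchors = _allele_anchors(panel)
        a2 = seq_idx[1 : n_starts + 1]  # residue at peptide position 2
        a9 = seq_idx[sim.peptide_length - 1 : n_starts + sim.peptide_length - 1]
        a9_match = np.isin(a9, [AMINO_ACIDS.index(c) for c in _ANCHOR9])
        affinity = np.empty((len(panel), n_starts))
        for i, allele in enumerate(panel):
            a2_match = np.isin(
                a2, [AMINO_ACIDS.index(c) for c in anchors[allele]]
            )
            base = np.full(n_starts, 2000.0)
            base[a2_match] *= 0.05
            base[a9_match] *= 0.05
            affinity[i] = base * rng.lognormal(0.0, 0.4, n_starts)
        emit = affinity <= sim.emit_affinity_max
    ai, si = np.nonzero(emit)
    return ai, si + 1, affinity[ai, si]


def _sample_genotypes(
    sim: SimulationConfig, rng: np.random.Generator, n: int
) -> list[HlaGenotype]:
    genotypes = []
    loci = sorted(sim.panel_frequencies)
    for k in range(n):
        copies: dict[str, int] = {}
        for locus in loci:
            freqs = sim.panel_frequencies[locus]
            names = sorted(freqs) + [f"{locus}*9901"]  # panel-external remainder
            p = np.array([freqs[a] for a in sorted(freqs)] + [0.0])
            p[-1] = max(0.0, 1.0 - p.sum())
            p = p / p.sum()
            for a in rng.choice(names, size=2, p=p):
                copies[a] = copies.get(a, 0) + 1
        genotypes.append(HlaGenotype(f"PT{k:04d}", copies, loci=tuple(loci)))
    return genotypes


def generate_cohort(sim: SimulationConfig) -> Cohort:
    """Generate a full synthetic cohort, deterministically from ``sim.seed``."""
    rng = np.random.default_rng(sim.seed)
    panel = DEFAULT_ALLELE_PANEL
    n_aa = len(AMINO_ACIDS)

    lengths = rng.integers(
        sim.protein_length[0], sim.protein_length[1] + 1, sim.n_proteins
    )
    seqs_idx = [rng.integers(0, n_aa, L) for L in lengths]
    proteins = [
        ProteinRecord.make(
            f"P{i:04d}", f"G{i:04d}", "".join(AMINO_ACIDS[j] for j in s)
        )
        for i, s in enumerate(seqs_idx)
    ]

    pred_frames = []
    strong_masks: list[np.ndarray] = []  # (n_panel, L) strong-binder coverage
    for prot, s in zip(proteins, seqs_idx):
        ai, starts, aff = _predict_windows(s, panel, sim, rng)
        pred_frames.append(
            pd.DataFrame(
                {
                    "protein_id": prot.protein_id,
                    "allele": np.array(panel)[ai],
                    "start": starts,
                    "affinity": np.round(aff, 3),
                }
            )
        )
        M = np.zeros((len(panel), prot.length), dtype=bool)
        strong = aff <= sim.strong_binder_threshold
        for a_i, st in zip(ai[strong], starts[strong]):
            M[a_i, st - 1 : st - 1 + sim.peptide_length] = True
        strong_masks.append(M)
    predictions = pd.concat(pred_frames, ignore_index=True)

    genotypes = _sample_genotypes(sim, rng, sim.n_patients)
    cancer_types = [f"C{1 + i % sim.n_cancer_types}" for i in range(sim.n_patients)]

    expr_values: dict[tuple[str, str], float] = {}
    for ct in sorted(set(cancer_types)):
        undetected = rng.random(sim.n_proteins) < sim.fraction_undetected
        vals = np.where(
            undetected,
            0.0,
            rng.lognormal(*sim.expression_lognorm, sim.n_proteins),
        )
        for prot, v in zip(proteins, vals):
            expr_values[(prot.gene_id, ct)] = float(np.round(v, 4))
    expression = ExpressionTable(expr_values)

    # per-patient panel copy vectors
    G = np.array(
        [[g.copies(a) for a in panel] for g in genotypes], dtype=np.int16
    )
    mult = np.array(
        [sim.residue_rate_multipliers.get(a, 1.0) for a in AMINO_ACIDS]
    )
    s_d1 = sim.survival.get("D1", 1.0)
    s_d2 = sim.survival.get("D2", 1.0)
    s_d0 = sim.survival.get("D0", 1.0)

    variants: list[SomaticVariant] = []
    truth_counts = {
        k: {"candidates": 0, "observed": 0}
        for k in ("expressed_D1", "expressed_D2", "expressed_D0",
                  "expressed_OUT", "unexpressed", "synonymous")
    }
    for prot, s_idx, M in zip(proteins, seqs_idx, strong_masks):
        L = prot.length
        rate = sim.mutation_rate * mult[s_idx]
        cc = G @ M.astype(np.int16)  # patients x L copy counts
        panel_mask = M.any(axis=0)
        expressed = np.array(
            [expression.median(prot.gene_id, ct) > 0 for ct in cancer_types]
        )
        surv = np.ones((sim.n_patients, L))
        e = expressed[:, None]
        surv[e & panel_mask & (cc == 0)] = s_d0
        surv[e & panel_mask & (cc == 1)] = s_d1
        surv[e & panel_mask & (cc >= 2)] = s_d2

        cand = rng.random((sim.n_patients, L)) < rate[None, :]
        kept = cand & (rng.random((sim.n_patients, L)) < surv)
        cand_syn = rng.random((sim.n_patients, L)) < sim.synonymous_rate * mult[s_idx]

        # truth bookkeeping
        classes = np.zeros((sim.n_patients, L), dtype=np.int8)  # 0 OUT,1 D0,2 D1,3 D2
        classes[panel_mask & (cc == 0)] = 1
        classes[panel_mask & (cc == 1)] = 2
        classes[panel_mask & (cc >= 2)] = 3
        for label, sel in (
            ("expressed_OUT", e & (classes == 0)),
            ("expressed_D0", e & (classes == 1)),
            ("expressed_D1", e & (classes == 2)),
            ("expressed_D2", e & (classes == 3)),
            ("unexpressed", ~e & np.ones_like(classes, dtype=bool)),
        ):
            truth_counts[label]["candidates"] += int(cand[sel].sum())
            truth_counts[label]["observed"] += int(kept[sel].sum())
        truth_counts["synonymous"]["candidates"] += int(cand_syn.sum())
        truth_counts["synonymous"]["observed"] += int(cand_syn.sum())

        for arr, vclass in ((kept, VariantClass.MISSENSE),
                            (cand_syn, VariantClass.SYNONYMOUS)):
            pi, pos = np.nonzero(arr)
            refs = s_idx[pos]
            if vclass is VariantClass.MISSENSE:
                alts = (refs + rng.integers(1, n_aa, refs.size)) % n_aa
            else:
                alts = refs
            for p_i, po, r_i, a_i in zip(pi, pos, refs, alts):
                variants.append(
                    SomaticVariant(
                        sample_id=genotypes[p_i].sample_id,
                        protein_id=prot.protein_id,
                        gene_id=prot.gene_id,
                        position=int(po) + 1,
                        ref_residue=AMINO_ACIDS[r_i],
                        alt_residue=AMINO_ACIDS[a_i],
                        variant_class=vclass,
                        cancer_type=cancer_types[p_i],
                    )
                )

    truth = {
        "seed": sim.seed,
        "survival": {"D0": s_d0, "D1": s_d1, "D2": s_d2},
        "expected_corrected_ratio": {"D1": s_d1, "D2": s_d2},
        "counts": truth_counts,
        "n_patients": sim.n_patients,
        "n_proteins": sim.n_proteins,
        "n_missense": sum(
            1 for v in variants if v.variant_class is VariantClass.MISSENSE
        ),
        "n_synonymous": sum(
            1 for v in variants if v.variant_class is VariantClass.SYNONYMOUS
        ),
    }
    return Cohort(proteins, predictions, genotypes, expression, variants, truth)


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Serialize a cohort to the five input files plus truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / fname for name, fname in [
        ("proteins", "proteins.fasta"), ("predictions", "predictions.tsv"),
        ("hla", "hla.tsv"), ("expression", "expression.tsv"),
        ("variants", "variants.tsv"), ("truth", "truth.json"),
    ]}
    nio.write_fasta(cohort.proteins, paths["proteins"])
    cohort.predictions.to_csv(paths["predictions"], sep="\t", index=False)

    loci = cohort.genotypes[0].loci if cohort.genotypes else ("A", "B")
    rows = []
    for g in cohort.genotypes:
        row = {"sample_id": g.sample_id}
        for locus in loci:
            alleles = []
            for a, n in sorted(g.allele_copies.items()):
                if a.startswith(locus):
                    alleles.extend([a] * n)
            row[f"{locus}1"], row[f"{locus}2"] = alleles[0], alleles[1]
        rows.append(row)
    pd.DataFrame(rows).to_csv(paths["hla"], sep="\t", index=False)

    nio.write_expression(cohort.expression, paths["expression"])

    pd.DataFrame(
        [
            {
                "sample_id": v.sample_id,
                "protein_id": v.protein_id,
                "gene_id": v.gene_id,
                "position": v.position,
                "ref_residue": v.ref_residue,
                "alt_residue": v.alt_residue,
                "variant_class": v.variant_class.value,
                "cancer_type": v.cancer_type,
            }
            for v in cohort.variants
        ]
    ).to_csv(paths["variants"], sep="\t", index=False)

    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def cohort_inputs(cohort: Cohort, config) -> "CohortInputs":
    """Build analysis inputs directly from an in-memory cohort (no files)."""
    from .depletion import CohortInputs
    from .types import BindingWindow

    mapped, rejects, stats = nio.map_variants(cohort.variants, cohort.proteins)
    strong = cohort.predictions[
        cohort.predictions["affinity"] <= config.strong_binder_threshold
    ]
    windows = [
        BindingWindow(str(r.protein_id), str(r.allele), int(r.start), float(r.affinity))
        for r in strong.itertuples(index=False)
    ]
    return CohortInputs(
        cohort.proteins, mapped, cohort.genotypes, windows, cohort.expression,
        load_stats={"mapping_rejects": len(rejects), **stats},
    )
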