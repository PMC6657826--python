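"""Domain types shared across the pipeline.

The analysis operates in protein space: somatic variants annotated to a
1-based residue position on a protein, per-residue display masks built from
strong-binding 9-mer predictions, per-patient HLA class I genotypes at
4-digit resolution, and per-(gene, cancer type) median expression values.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AMINO_ACID_SET = frozenset(AMINO_ACIDS)

#: The 12 common HLA class I alleles with display predictions, 4-digit form.
DEFAULT_ALLELE_PANEL = (
    "A*0101", "A*0201", "A*0301", "A*2402", "A*2601",
    "B*0702", "B*0801", "B*1501", "B*2705", "B*3901", "B*4001", "B*5801",
)


class ConfigurationError(ValueError):
    """A problem with run configuration or input file schema."""


class DataError(ValueError):
    """A problem with the content of an otherwise well-formed input."""


class VariantClass(str, enum.Enum):
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"


class Mode(str, enum.Enum):
    #: every panel allele treated as present in every patient
    PAN_ALLELE = "pan_allele"
    #: only alleles carried by the mutation's patient count as displaying
    PATIENT = "patient"


class ExpressionStratum(str, enum.Enum):
    UNDETECTED = "UNDETECTED"
    Q1 = "Q1"
    Q2 = "Q2"
    Q3 = "Q3"
    Q4 = "Q4"

    @property
    def expressed(self) -> bool:
        return self is not ExpressionStratum.UNDETECTED


#: Quantile strata ordered low to high expression.
EXPRESSED_STRATA = (
    ExpressionStratum.Q1,
    ExpressionStratum.Q2,
    ExpressionStratum.Q3,
    ExpressionStratum.Q4,
)


class DisplayClass(str, enum.Enum):
    """Residue-site classification with respect to predicted display.

    ``IN`` is the pan-allele in-mask class. In patient mode a site inside the
    panel mask is split by the number of displaying allele copies the patient
    carries: ``D0_IN_PANEL`` (zero copies; excluded from both sides of the
    ratio), ``D1`` (one copy) and ``D2`` (two or more copies).
    """

    OUT = "OUT"
    D0_IN_PANEL = "D0_IN_PANEL"
    D1 = "D1"
    D2 = "D2"
    IN = "IN"

    @property
    def excluded(self) -> bool:
        return self is DisplayClass.D0_IN_PANEL


class CountClass(str, enum.Enum):
    """Numerator classes for which 2x2 opportunity tables are accumulated."""

    ANY_IN = "ANY_IN"
    D1 = "D1"
    D2 = "D2"


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    gene_id: str
    sequence: str
    #: True when the sequence contains non-standard residue letters; flagged
    #: records are kept for reporting but excluded from window building.
    flagged: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)

    @staticmethod
    def make(protein_id: str, gene_id: str, sequence: str) -> "ProteinRecord":
        seq = sequence.upper()
        flagged = not set(seq) <= AMINO_ACID_SET
        return ProteinRecord(protein_id, gene_id, seq, flagged)


@dataclass(frozen=True)
class SomaticVariant:
    sample_id: str
    protein_id: str | None
    gene_id: str | None
    position: int  # 1-based residue index
    ref_residue: str
    alt_residue: str
    variant_class: VariantClass
    cancer_type: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise DataError(f"position must be >= 1, got {self.position}")
        if (
            self.variant_class is VariantClass.MISSENSE
            and self.ref_residue == self.alt_residue
        ):
            raise DataError(
                "missense variant with identical ref and alt residue "
                f"({self.sample_id} {self.protein_id or self.gene_id} "
                f"pos {self.position})"
            )


@dataclass(frozen=True)
class MappedVariant(SomaticVariant):
    """A variant resolved to a concrete protein and checked against it.

    Only variants with ``validated=True`` (wild-type residue matched the
    protein sequence at the stated position) enter any downstream count.
    """

    validated: bool = False


@dataclass(frozen=True)
class HlaGenotype:
    """4-digit HLA class I genotype of one patient.

    ``allele_copies`` maps normalized allele names to copy counts; per typed
    locus the copies sum to 2 (homozygous calls collapse to one entry with
    copy count 2).
    """

    sample_id: str
    allele_copies: dict[str, int] = field(hash=False)
    loci: tuple[str, ...] = ("A", "B")

    def __post_init__(self) -> None:
        per_locus: dict[str, int] = {}
        for allele, n in self.allele_copies.items():
            if n < 1:
                raise DataError(f"{self.sample_id}: copy count {n} for {allele}")
            per_locus[allele[0]] = per_locus.get(allele[0], 0) + n
        for locus in self.loci:
            if per_locus.get(locus, 0) != 2:
                raise DataError(
                    f"{self.sample_id}: locus {locus} has "
                    f"{per_locus.get(locus, 0)} allele copies, expected 2"
                )

    def copies(self, allele: str) -> int:
        return self.allele_copies.get(allele, 0)


@dataclass(frozen=True)
class BindingWindow:
    """One strong-binder 9-mer prediction for a (protein, allele) pair."""

    protein_id: str
    allele: str
    start: int  # 1-based; covers residues start..start+length-1
    affinity: float  # prediction score; lower = stronger binding

    def __post_init__(self) -> None:
        if self.start < 1:
            raise DataError(f"window start must be >= 1, got {self.start}")
        if self.affinity <= 0:
            raise DataError(f"affinity must be positive, got {self.affinity}")


@dataclass
class AnalysisConfig:
    """Parameters of one depletion analysis run."""

    mode: Mode = Mode.PATIENT
    variant_class: VariantClass = VariantClass.MISSENSE
    display_classes: tuple[CountClass, ...] = (
        CountClass.ANY_IN,
        CountClass.D1,
        CountClass.D2,
    )
    cancer_types: tuple[str, ...] | None = None  # None = ALL, pooled
    strong_binder_threshold: float = 50.0
    peptide_length: int = 9
    allele_panel: tuple[str, ...] = DEFAULT_ALLELE_PANEL
    bootstrap_reps: int = 500
    rng_seed: int = 0
    rounding: int = 2
    #: opportunity accounting: "per_patient_protein" counts each mutated
    #: (patient, protein) pair's sites once; "cohort_protein" counts each
    #: mutated protein's sites once per cancer-type scope.
    opportunity: str = "per_patient_protein"
    #: gene universe in patient mode: "all" mutated proteins, or "displayed"
    #: (only (patient, protein) pairs whose mask has >= 1 patient-displayed
    #: site, mirroring a universe of genes with >= 1 neo-antigenic variant).
    gene_universe: str = "all"

    def __post_init__(self) -> None:
        self.mode = Mode(self.mode)
        self.variant_class = VariantClass(self.variant_class)
        self.display_classes = tuple(CountClass(c) for c in self.display_classes)
        if self.cancer_types is not None:
            self.cancer_types = tuple(self.cancer_types)
        if self.strong_binder_threshold <= 0:
            raise ConfigurationError("strong_binder_threshold must be > 0")
        if self.peptide_length < 8:
            raise ConfigurationError("peptide_length must be >= 8")
        if self.bootstrap_reps < 1:
            raise ConfigurationError("bootstrap_reps must be >= 1")
        if self.opportunity not in ("per_patient_protein", "cohort_protein"):
            raise ConfigurationError(f"unknown opportunity mode {self.opportunity!r}")
        if self.gene_universe not in ("all", "displayed"):
            raise ConfigurationError(f"unknown gene_universe {self.gene_universe!r}")
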