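"""Readers and writers for the tabular and sequence formats the pipeline uses.

Every reader is total: each input row becomes either a parsed record or an
itemized reject (row number, reason); nothing is silently dropped. Allele
names and variant-class labels are normalized to a single dialect on the way
in.
"""
from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .types import (
    AMINO_ACID_SET,
    AnalysisConfig,
    BindingWindow,
    ConfigurationError,
    DataError,
    HlaGenotype,
    MappedVariant,
    ProteinRecord,
    SomaticVariant,
    VariantClass,
)

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# normalization

#: Accepted spellings of the two variant classes in MAF-like inputs.
VARIANT_CLASS_DIALECTS = {
    "missense": VariantClass.MISSENSE,
    "missense_mutation": VariantClass.MISSENSE,
    "missense_variant": VariantClass.MISSENSE,
    "nonsynonymous": VariantClass.MISSENSE,
    "synonymous": VariantClass.SYNONYMOUS,
    "synonymous_variant": VariantClass.SYNONYMOUS,
    "silent": VariantClass.SYNONYMOUS,
}

_ALLELE_RE = re.compile(r"^(?:HLA-)?([A-Z])\*?(\d{2}):?(\d{2})(?::\d+)*[A-Z]?$")


def normalize_allele(name: str) -> str:
    """Normalize an HLA class I allele name to 4-digit ``A*0201`` form.

    Accepts the common dialects ``HLA-A*02:01``, ``A*0201``, ``HLA-A02:01``,
    ``HLA-A0201`` and higher-resolution names (extra fields are truncated).
    """
    m = _ALLELE_RE.match(name.strip().upper())
    if not m:
        raise DataError(f"unrecognized HLA allele name: {name!r}")
    locus, f1, f2 = m.groups()
    return f"{locus}*{f1}{f2}"


def _resolve_columns(
    df: pd.DataFrame, aliases: dict[str, tuple[str, ...]], required: tuple[str, ...]
) -> dict[str, str]:
    """Map canonical column names to actual dataframe columns (case-insensitive)."""
    lower = {c.lower(): c for c in df.columns}
    found: dict[str, str] = {}
    for canon, names in aliases.items():
        for n in names:
            if n in lower:
                found[canon] = lower[n]
                break
    missing = [c for c in required if c not in found]
    if missing:
        raise ConfigurationError(
            f"missing required column(s): {', '.join(missing)} "
            f"(found columns: {list(df.columns)})"
        )
    return found


@dataclass
class Reject:
    row: int
    reason: str
    detail: str = ""


# ---------------------------------------------------------------------------
# variants

_VARIANT_ALIASES = {
    "sample_id": ("sample_id", "sample", "tumor_sample_barcode"),
    "protein_id": ("protein_id", "protein", "ensp"),
    "gene_id": ("gene_id", "gene", "hugo_symbol"),
    "position": ("position", "protein_position", "aa_position"),
    "ref_residue": ("ref_residue", "ref", "wt_residue", "reference_residue"),
    "alt_residue": ("alt_residue", "alt", "mut_residue", "variant_residue"),
    "variant_class": ("variant_class", "class", "variant_classification"),
    "cancer_type": ("cancer_type", "cancer", "project_code", "cohort"),
}


def read_variants(path: str | Path) -> tuple[list[SomaticVariant], list[Reject]]:
    """Read a MAF-like TSV of somatic variants annotated to protein space.

    Returns (variants, rejects); ``len(variants) + len(rejects)`` equals the
    number of data rows. Rows of variant classes other than
    missense/synonymous are rejected with reason ``unsupported_class``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = (
        "sample_id", "position", "ref_residue", "alt_residue",
        "variant_class", "cancer_type",
    )
    cols = _resolve_columns(df, _VARIANT_ALIASES, required)
    if "protein_id" not in cols and "gene_id" not in cols:
        raise ConfigurationError("missing required column(s): protein_id or gene_id")

    variants: list[SomaticVariant] = []
    rejects: list[Reject] = []
    for i, row in enumerate(df.itertuples(index=False)):
        r = dict(zip(df.columns, row))
        try:
            vclass = VARIANT_CLASS_DIALECTS.get(r[cols["variant_class"]].strip().lower())
            if vclass is None:
                raise DataError(f"unsupported_class:{r[cols['variant_class']]}")
            pos_raw = r[cols["position"]].strip()
            if not pos_raw.isdigit() or int(pos_raw) < 1:
                raise DataError(f"bad_position:{pos_raw!r}")
            ref = r[cols["ref_residue"]].strip().upper()
            alt = r[cols["alt_residue"]].strip().upper()
            for res in (ref, alt):
                if len(res) != 1 or res not in AMINO_ACID_SET:
                    raise DataError(f"bad_residue:{res!r}")
            variants.append(
                SomaticVariant(
                    sample_id=r[cols["sample_id"]].strip(),
                    protein_id=r[cols["protein_id"]].strip() or None
                    if "protein_id" in cols else None,
                    gene_id=r[cols["gene_id"]].strip() or None
                    if "gene_id" in cols else None,
                    position=int(pos_raw),
                    ref_residue=ref,
                    alt_residue=alt,
                    variant_class=vclass,
                    cancer_type=r[cols["cancer_type"]].strip(),
                )
            )
        except DataError as e:
            reason, _, detail = str(e).partition(":")
            rejects.append(Reject(row=i, reason=reason, detail=detail))
    log.info("read_variants: %d parsed, %d rejected", len(variants), len(rejects))
    return variants, rejects


# ---------------------------------------------------------------------------
# proteins

_GENE_KV_RE = re.compile(r"\bgene=(\S+)")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein sequences; header first token is the protein id and an
    optional ``gene=...`` key carries the gene id.

    Sequences are uppercased; records containing non-standard residues are
    flagged (kept, but excluded from window building). Duplicate protein ids
    raise an error listing them.
    """
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _GENE_KV_RE.search(rec.description)
        gene_id = m.group(1) if m else rec.id
        records.append(ProteinRecord.make(rec.id, gene_id, str(rec.seq)))
        seen[rec.id] = seen.get(rec.id, 0) + 1
    dups = sorted(p for p, n in seen.items() if n > 1)
    if dups:
        raise DataError(f"duplicate protein id(s): {', '.join(dups)}")
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id} gene={rec.gene_id}\n")
            for i in range(0, rec.length, 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# variant-to-protein mapping

def map_variants(
    variants: list[SomaticVariant], proteins: list[ProteinRecord]
) -> tuple[list[MappedVariant], list[Reject], dict[str, int]]:
    """Resolve each variant to a protein and validate its wild-type residue.

    Variants carrying a protein_id use it directly; variants with only a
    gene_id fall back to the gene's longest isoform (deterministic; ties
    broken by protein_id). Returns (mapped, rejects, stats); only
    ``validated`` mapped variants belong in downstream counts.
    """
    by_id = {p.protein_id: p for p in proteins}
    by_gene: dict[str, ProteinRecord] = {}
    for p in sorted(proteins, key=lambda p: (-p.length, p.protein_id)):
        by_gene.setdefault(p.gene_id, p)

    mapped: list[MappedVariant] = []
    rejects: list[Reject] = []
    stats = {"validated": 0, "mismatch": 0, "out_of_bounds": 0,
             "unknown_protein": 0, "isoform_fallback": 0}
    for i, v in enumerate(variants):
        if v.protein_id is not None:
            prot = by_id.get(v.protein_id)
        else:
            prot = by_gene.get(v.gene_id)
            if prot is not None:
                stats["isoform_fallback"] += 1
        if prot is None:
            stats["unknown_protein"] += 1
            rejects.append(Reject(i, "unknown_protein", v.protein_id or v.gene_id or ""))
            continue
        fields = {**v.__dict__, "protein_id": prot.protein_id,
                  "gene_id": prot.gene_id}
        if v.position > prot.length:
            stats["out_of_bounds"] += 1
            mapped.append(MappedVariant(**fields, validated=False))
        elif prot.sequence[v.position - 1] != v.ref_residue:
            stats["mismatch"] += 1
            mapped.append(MappedVariant(**fields, validated=False))
        else:
            stats["validated"] += 1
            mapped.append(MappedVariant(**fields, validated=True))
    return mapped, rejects, stats


# ---------------------------------------------------------------------------
# HLA genotypes

def read_hla(path: str | Path) -> list[HlaGenotype]:
    """Read per-sample 4-digit HLA class I genotypes.

    Expects one row per sample with two allele columns per locus (A1, A2,
    B1, B2, optionally C1, C2). Loci A and B are required; a locus present
    with only one of its two columns, or a blank allele cell, is an error —
    zygosity is meaningful downstream.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    lower = {c.lower(): c for c in df.columns}
    sample_col = lower.get("sample_id") or lower.get("sample")
    if sample_col is None:
        raise ConfigurationError("missing required column(s): sample_id")
    loci: list[str] = []
    locus_cols: dict[str, tuple[str, str]] = {}
    for locus in ("A", "B", "C"):
        names = [
            (lower.get(f"{locus.lower()}{k}") or lower.get(f"hla_{locus.lower()}{k}"))
            for k in (1, 2)
        ]
        present = [n for n in names if n]
        if len(present) == 2:
            loci.append(locus)
            locus_cols[locus] = (present[0], present[1])
        elif len(present) == 1:
            raise ConfigurationError(
                f"locus {locus} has only one allele column; two are required"
            )
    for locus in ("A", "B"):
        if locus not in loci:
            raise ConfigurationError(f"missing required HLA locus columns: {locus}1/{locus}2")

    genotypes: list[HlaGenotype] = []
    for _, row in df.iterrows():
        copies: dict[str, int] = {}
        for locus in loci:
            for col in locus_cols[locus]:
                raw = row[col].strip()
                if not raw:
                    raise DataError(
                        f"sample {row[sample_col]}: blank allele at locus {locus}"
                    )
                allele = normalize_allele(raw)
                if not allele.startswith(locus):
                    raise DataError(
                        f"sample {row[sample_col]}: allele {raw} in locus {locus} column"
                    )
                copies[allele] = copies.get(allele, 0) + 1
        genotypes.append(
            HlaGenotype(row[sample_col].strip(), copies, loci=tuple(loci))
        )
    return genotypes


# ---------------------------------------------------------------------------
# binding predictions

def read_binding_predictions(
    path: str | Path,
    config: AnalysisConfig,
    proteins: list[ProteinRecord] | None = None,
) -> tuple[list[BindingWindow], list[Reject]]:
    """Read a long-format 9-mer prediction table and keep strong binders.

    Only rows with affinity <= ``config.strong_binder_threshold`` are
    retained. When ``proteins`` is given, windows on unknown proteins or with
    starts outside [1, length - peptide_length + 1] are rejected with a
    report.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "allele": str})
    cols = _resolve_columns(
        df,
        {
            "protein_id": ("protein_id", "protein"),
            "allele": ("allele", "hla_allele"),
            "start": ("start", "peptide_start", "pos"),
            "affinity": ("affinity", "score", "ic50"),
        },
        ("protein_id", "allele", "start", "affinity"),
    )
    lengths = {p.protein_id: p.length for p in proteins} if proteins is not None else None
    flagged = {p.protein_id for p in (proteins or []) if p.flagged}
    windows: list[BindingWindow] = []
    rejects: list[Reject] = []
    n_weak = 0
    for i, row in enumerate(df.itertuples(index=False)):
        r = dict(zip(df.columns, row))
        pid = str(r[cols["protein_id"]])
        start = int(r[cols["start"]])
        affinity = float(r[cols["affinity"]])
        if affinity > config.strong_binder_threshold:
            n_weak += 1
            continue
        if lengths is not None:
            if pid not in lengths:
                rejects.append(Reject(i, "unknown_protein", pid))
                continue
            if pid in flagged:
                rejects.append(Reject(i, "flagged_protein", pid))
                continue
            if not 1 <= start <= lengths[pid] - config.peptide_length + 1:
                rejects.append(Reject(i, "start_out_of_bounds", f"{pid}:{start}"))
                continue
        windows.append(
            BindingWindow(pid, normalize_allele(str(r[cols["allele"]])), start, affinity)
        )
    log.info(
        "read_binding_predictions: %d strong binders retained, %d above threshold, "
        "%d rejected", len(windows), n_weak, len(rejects),
    )
    return windows, rejects


# ---------------------------------------------------------------------------
# expression

class ExpressionTable:
    """Median normalized expression per (gene, cancer type), RSEM scale."""

    def __init__(self, values: dict[tuple[str, str], float]):
        for (g, ct), v in values.items():
            if v < 0:
                raise DataError(f"negative expression for {g} in {ct}: {v}")
        self._values = dict(values)
        self._cancer_types = sorted({ct for _, ct in values})

    @property
    def cancer_types(self) -> list[str]:
        return list(self._cancer_types)

    def median(self, gene_id: str, cancer_type: str) -> float | None:
        """Median expression, or None when the pair is missing from the table."""
        return self._values.get((gene_id, cancer_type))

    def genes(self, cancer_type: str) -> list[str]:
        return sorted(g for g, ct in self._values if ct == cancer_type)

    def items(self):
        return self._values.items()

    def __len__(self) -> int:
        return len(self._values)


def read_expression(path: str | Path) -> ExpressionTable:
    """Read gene expression as a long table.

    Accepts either one row per (gene, cancer_type) with a value column, or
    per-sample rows (an extra sample column); per-sample values are reduced
    to the median within each (gene, cancer_type).
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    cols = _resolve_columns(
        df,
        {
            "gene_id": ("gene_id", "gene", "hugo_symbol"),
            "cancer_type": ("cancer_type", "cancer", "cohort"),
            "value": ("value", "median_expression", "expression", "rsem"),
            "sample_id": ("sample_id", "sample"),
        },
        ("gene_id", "cancer_type", "value"),
    )
    sub = df[[cols["gene_id"], cols["cancer_type"], cols["value"]]].copy()
    sub.columns = ["gene_id", "cancer_type", "value"]
    sub["value"] = sub["value"].astype(float)
    if (sub["value"] < 0).any():
        bad = sub[sub["value"] < 0].iloc[0]
        raise DataError(
            f"negative expression for {bad.gene_id} in {bad.cancer_type}: {bad.value}"
        )
    med = sub.groupby(["gene_id", "cancer_type"], sort=True)["value"].median()
    return ExpressionTable({(g, ct): float(v) for (g, ct), v in med.items()})


def write_expression(table: ExpressionTable, path: str | Path) -> None:
    rows = sorted(((g, ct, v) for (g, ct), v in table.items()))
    pd.DataFrame(rows, columns=["gene_id", "cancer_type", "value"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# results

RESULT_COLUMNS = [
    "cancer_scope", "variant_class", "mode", "stratum", "display_class",
    "mut_in", "site_in", "mut_out", "site_out", "ratio", "p_value",
    "corrected_ratio", "ci_low", "ci_high", "clearance_percent",
    "n_bootstrap", "seed",
]


def results_frame(results: list, rounding: int | None = None) -> pd.DataFrame:
    """Results as a DataFrame in the canonical column order.

    ``rounding`` rounds the reported ratios/CIs at the reporting layer only.
    """
    rows = []
    for res in results:
        d = res.as_row()
        if rounding is not None:
            for k in ("ratio", "corrected_ratio", "ci_low", "ci_high",
                      "clearance_percent"):
                if d[k] is not None:
                    d[k] = round(d[k], rounding)
        rows.append(d)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(
    results: list,
    tsv_path: str | Path,
    json_path: str | Path,
    config: AnalysisConfig,
    manifest: dict | None = None,
) -> None:
    """Write results as a rounded TSV plus a full-precision JSON report."""
    results_frame(results, rounding=config.rounding).to_csv(
        tsv_path, sep="\t", index=False
    )
    payload = {
        "config": _config_echo(config),
        "results": [r.as_row() for r in results],
        "manifest": manifest or {},
        "seed": config.rng_seed,
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _config_echo(config: AnalysisConfig) -> dict:
    echo = {}
    for k, v in config.__dict__.items():
        if isinstance(v, tuple):
            v = list(v)
        if hasattr(v, "value"):
            v = v.value
        elif isinstance(v, list):
            v = [x.value if hasattr(x, "value") else x for x in v]
        echo[k] = v
    return echo


# ---------------------------------------------------------------------------
# BED-like interval export (0-based half-open on export only)

def write_display_bed(intervals: list[tuple[str, int, int, str]], path: str | Path) -> None:
    """Write per-protein display-class segments as BED-like rows.

    ``intervals`` holds (protein_id, start0, end0, label) with 0-based
    half-open coordinates (converted from internal 1-based inclusive by the
    mask layer). Rows are ordered by protein_id then start.
    """
    with open(path, "w") as fh:
        for pid, s, e, label in sorted(intervals):
            fh.write(f"{pid}\t{s}\t{e}\t{label}\n")
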