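"""Expression stratification: UNDETECTED vs four expression quantiles.

Genes are stratified within each cancer type. A gene whose median RSEM value
is exactly 0 is UNDETECTED; detectably expressed genes (> 0) are split at
the 25/50/75th percentiles of their values within that cancer type, with
values exactly at a boundary assigned to the lower quartile.
"""
from __future__ import annotations

import numpy as np

from .io import ExpressionTable
from .types import ConfigurationError, ExpressionStratum, MappedVariant


def assign_strata(
    expr: ExpressionTable, cancer_type: str
) -> dict[str, ExpressionStratum]:
    """Map every gene with expression data in ``cancer_type`` to a stratum."""
    if cancer_type not in expr.cancer_types:
        raise ConfigurationError(
            f"cancer type {cancer_type!r} absent from expression table "
            f"(available: {expr.cancer_types})"
        )
    genes = expr.genes(cancer_type)
    values = np.array([expr.median(g, cancer_type) for g in genes], dtype=float)
    strata: dict[str, ExpressionStratum] = {}
    expressed = values > 0
    for g, v in zip(np.array(genes)[~expressed], values[~expressed]):
        strata[str(g)] = ExpressionStratum.UNDETECTED
    if expressed.any():
        ev = values[expressed]
        q25, q50, q75 = np.percentile(ev, [25, 50, 75])
        for g, v in zip(np.array(genes)[expressed], ev):
            if v <= q25:
                s = ExpressionStratum.Q1
            elif v <= q50:
                s = ExpressionStratum.Q2
            elif v <= q75:
                s = ExpressionStratum.Q3
            else:
                s = ExpressionStratum.Q4
            strata[str(g)] = s
    return strata


def strata_by_cancer(
    expr: ExpressionTable, cancer_types: list[str] | None = None
) -> dict[str, dict[str, ExpressionStratum]]:
    """Stratum maps for several cancer types (all in the table by default)."""
    cts = expr.cancer_types if cancer_types is None else list(cancer_types)
    return {ct: assign_strata(expr, ct) for ct in cts}


def stratum_of_variant(
    variant: MappedVariant,
    strata: dict[str, dict[str, ExpressionStratum]],
) -> ExpressionStratum | None:
    """Stratum of the variant's gene in the variant's cancer type.

    Returns None (caller excludes and counts the variant) when the gene or
    cancer type has no expression data.
    """
    per_ct = strata.get(variant.cancer_type)
    if per_ct is None or variant.gene_id is None:
        return None
    return per_ct.get(variant.gene_id)
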