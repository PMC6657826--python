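"""Residue-level display masks and site classification.

A protein's *panel mask* marks every residue covered by at least one
strong-binder 9-mer of any allele in the prediction panel. In patient mode a
*copy-count track* additionally records, per residue, how many copies of
displaying alleles the patient carries (summing genotype copy counts over
carried alleles whose windows cover the residue). Masks are built on the
wild-type sequence and are mutation-independent.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import (
    BindingWindow,
    DataError,
    DisplayClass,
    HlaGenotype,
    MappedVariant,
    Mode,
    ProteinRecord,
)

# integer site codes used by the vectorized classifier
CODE_OUT = 0
CODE_D0 = 1
CODE_D1 = 2
CODE_D2 = 3
CODE_IN = 4

_CODE_TO_CLASS = {
    CODE_OUT: DisplayClass.OUT,
    CODE_D0: DisplayClass.D0_IN_PANEL,
    CODE_D1: DisplayClass.D1,
    CODE_D2: DisplayClass.D2,
    CODE_IN: DisplayClass.IN,
}


@dataclass
class DisplayMask:
    """Per-residue display state of one protein (optionally for one patient)."""

    protein_id: str
    panel_mask: np.ndarray  # bool, length = protein length
    copy_count: np.ndarray | None = None  # int, patient mode only

    @property
    def length(self) -> int:
        return int(self.panel_mask.shape[0])


def _burn_windows(
    length: int, windows: list[BindingWindow], peptide_length: int
) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for w in windows:
        if not 1 <= w.start <= length - peptide_length + 1:
            raise DataError(
                f"window {w.protein_id}:{w.start} out of bounds for length {length}"
            )
        mask[w.start - 1 : w.start - 1 + peptide_length] = True
    return mask


def build_panel_mask(
    protein: ProteinRecord,
    windows: list[BindingWindow],
    peptide_length: int = 9,
) -> DisplayMask:
    """Union mask over all (threshold-filtered) windows of the panel."""
    for w in windows:
        if w.protein_id != protein.protein_id:
            raise DataError(
                f"window for {w.protein_id} passed with protein {protein.protein_id}"
            )
    return DisplayMask(
        protein.protein_id, _burn_windows(protein.length, windows, peptide_length)
    )


def build_allele_masks(
    protein: ProteinRecord,
    windows_by_allele: dict[str, list[BindingWindow]],
    peptide_length: int = 9,
) -> dict[str, np.ndarray]:
    """Per-allele boolean coverage masks for one protein."""
    return {
        allele: _burn_windows(protein.length, ws, peptide_length)
        for allele, ws in windows_by_allele.items()
    }


def build_patient_mask(
    protein: ProteinRecord,
    windows_by_allele: dict[str, list[BindingWindow]],
    genotype: HlaGenotype,
    panel: tuple[str, ...],
    peptide_length: int = 9,
) -> DisplayMask:
    """Panel mask plus the patient's displaying-allele copy-count track.

    ``copy_count[i]`` sums, over alleles the patient carries, the genotype
    copy count of each allele with a window covering residue ``i``. Carried
    alleles outside the prediction panel (or without any predictions)
    contribute nothing.
    """
    panel_set = set(panel)
    allele_masks = build_allele_masks(
        protein,
        {a: ws for a, ws in windows_by_allele.items() if a in panel_set},
        peptide_length,
    )
    panel_mask = np.zeros(protein.length, dtype=bool)
    for m in allele_masks.values():
        panel_mask |= m
    copy_count = np.zeros(protein.length, dtype=np.int16)
    for allele, m in allele_masks.items():
        n = genotype.copies(allele)
        if n:
            copy_count += n * m.astype(np.int16)
    return DisplayMask(protein.protein_id, panel_mask, copy_count)


def classify_positions(mask: DisplayMask, mode: Mode) -> np.ndarray:
    """Vectorized site classification; returns integer codes per residue.

    Pan mode: CODE_IN inside the panel mask, CODE_OUT elsewhere. Patient
    mode: CODE_OUT outside the panel mask; inside it, the copy-count track
    maps 0 -> CODE_D0 (excluded downstream), 1 -> CODE_D1, >=2 -> CODE_D2.
    """
    if mode is Mode.PAN_ALLELE:
        return np.where(mask.panel_mask, CODE_IN, CODE_OUT).astype(np.int8)
    if mask.copy_count is None:
        raise DataError("patient-mode classification needs a copy-count track")
    codes = np.full(mask.length, CODE_OUT, dtype=np.int8)
    inside = mask.panel_mask
    cc = mask.copy_count
    codes[inside & (cc == 0)] = CODE_D0
    codes[inside & (cc == 1)] = CODE_D1
    codes[inside & (cc >= 2)] = CODE_D2
    return codes


def classify_site(
    variant: MappedVariant | int, mask: DisplayMask, mode: Mode
) -> DisplayClass:
    """Display class of one variant site (or a raw 1-based position)."""
    pos = variant if isinstance(variant, int) else variant.position
    if not 1 <= pos <= mask.length:
        raise DataError(
            f"position {pos} outside mask of length {mask.length} "
            f"({mask.protein_id})"
        )
    return _CODE_TO_CLASS[int(classify_positions(mask, mode)[pos - 1])]


def mask_intervals(mask: DisplayMask, mode: Mode) -> list[tuple[str, int, int, str]]:
    """Display-class segments as BED-like (protein, start0, end0, label) rows.

    Coordinates are converted to 0-based half-open for export; internally
    everything stays 1-based inclusive.
    """
    codes = classify_positions(mask, mode)
    out: list[tuple[str, int, int, str]] = []
    start = 0
    for i in range(1, mask.length + 1):
        if i == mask.length or codes[i] != codes[start]:
            out.append(
                (mask.protein_id, start, i, _CODE_TO_CLASS[int(codes[start])].value)
            )
            start = i
    return out
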