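"""Absolute qPCR quantification of 16S (bacteria) and mcrA (methanogens).

Standards are synthetic dsDNA fragments of known length and concentration,
so copy numbers follow from the standard dsDNA mass-to-molecules
conversion (average 660 g per mol per base pair, Avogadro's number).
Sample quantities are scaled from the extracted aliquot (~100 mg of
lyophilized culture residue) to copies per gram, and to copies per bottle
via the residue dry mass. log10 is the canonical reporting transform.
"""

from __future__ import annotations

import math

from .constants import AVOGADRO, DSDNA_BP_G_PER_MOL

GENES = ("bac_16S", "arc_mcrA")


class QpcrError(ValueError):
    """Invalid qPCR quantification input."""


def copies_per_microliter(dna_conc_ng_ul: float, fragment_length_bp: float) -> float:
    """Copies/uL of a dsDNA fragment from its mass concentration and length.

    copies/uL = conc (ng/uL) x 1e-9 (g/ng) / (length x 660 g mol^-1 bp^-1)
                x Avogadro
    """
    if dna_conc_ng_ul < 0:
        raise QpcrError(f"DNA concentration must be >= 0, got {dna_conc_ng_ul}")
    if fragment_length_bp <= 0:
        raise QpcrError(f"fragment length must be > 0, got {fragment_length_bp}")
    grams_per_ul = dna_conc_ng_ul * 1e-9
    mol_per_ul = grams_per_ul / (fragment_length_bp * DSDNA_BP_G_PER_MOL)
    return mol_per_ul * AVOGADRO


def copies_in_eluate(copies_per_ul: float, eluate_volume_ul: float) -> float:
    """Total copies recovered in the DNA eluate.

    The eluate volume enters the scaling explicitly (the chain is
    copies/uL -> eluate -> per-gram), rather than being folded silently
    into another factor.
    """
    if copies_per_ul < 0 or eluate_volume_ul <= 0:
        raise QpcrError("copies must be >= 0 and eluate volume > 0")
    return copies_per_ul * eluate_volume_ul


def copies_per_gram(copies_in_eluate_: float, aliquot_mass_mg: float) -> float:
    """Scale copies in the eluate of one extraction to a 1-g residue basis."""
    if aliquot_mass_mg <= 0:
        raise QpcrError(f"aliquot mass must be > 0, got {aliquot_mass_mg}")
    if copies_in_eluate_ < 0:
        raise QpcrError(f"copies must be >= 0, got {copies_in_eluate_}")
    return copies_in_eluate_ * (1000.0 / aliquot_mass_mg)


def copies_per_bottle(copies_per_g: float, residue_mass_g: float) -> float:
    """Copies per bottle: copies/g of residue times residue dry mass (g)."""
    if copies_per_g < 0 or residue_mass_g < 0:
        raise QpcrError("copies/g and residue mass must be >= 0")
    return copies_per_g * residue_mass_g


def log10_copies(copies: float) -> float:
    """log10 reporting transform; NaN for zero copies."""
    if copies < 0:
        raise QpcrError(f"copies must be >= 0, got {copies}")
    return math.nan if copies == 0 else math.log10(copies)
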