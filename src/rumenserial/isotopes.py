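"""13C isotope ratios and delta enrichment of VFA from GC-MS isotopologs.

TBDMS-derivatized acetate, propionate, and butyrate give molecular-ion
isotopolog peaks at m/z 117/118/119, 131/132/133, and 145/146/147 (M+0,
M+1, M+2). Isotopologs beyond M+2 are below detection and ignored. The
13C/12C isotope ratio weights each peak by its count of 13C atoms in the
numerator and 12C atoms in the denominator:

    IR = sum_k k * AI_k / sum_k (n - k) * AI_k,   k = 0..2

which for the 2-carbon acetate reduces to (AI1 + 2 AI2) / (2 AI0 + AI1).
Enrichment is expressed in delta notation against the unlabeled standard
bottle of the same treatment cell: delta = (IR_sample / IR_std - 1) x 1000.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: Carbon counts and M+0 molecular-ion m/z of the TBDMS derivatives.
VFA_CARBONS = {"acetate": 2, "propionate": 3, "butyrate": 4}
VFA_BASE_MZ = {"acetate": 117, "propionate": 131, "butyrate": 145}


class SpectrumError(ValueError):
    """Invalid isotopolog spectrum."""


class PairingError(ValueError):
    """Labeled sample cannot be matched with a natural-abundance standard."""


@dataclass(frozen=True)
class IsotopologSpectrum:
    """Absolute intensities of the M+0, M+1, M+2 peaks of one VFA."""

    analyte: str
    intensities: tuple  # (AI_M0, AI_M1, AI_M2), arbitrary units >= 0
    base_mz: int | None = None

    def __post_init__(self) -> None:
        if self.analyte not in VFA_CARBONS:
            raise SpectrumError(f"unknown analyte {self.analyte!r}")
        if len(self.intensities) != 3:
            raise SpectrumError(
                f"expected 3 intensities (M+0..M+2), got {len(self.intensities)}"
            )
        if any(ai < 0 for ai in self.intensities):
            raise SpectrumError(f"negative intensity in {self.intensities}")
        expected_mz = VFA_BASE_MZ[self.analyte]
        if self.base_mz is not None and self.base_mz != expected_mz:
            raise SpectrumError(
                f"base m/z {self.base_mz} inconsistent with {self.analyte} "
                f"(expected {expected_mz})"
            )

    @property
    def n_carbons(self) -> int:
        return VFA_CARBONS[self.analyte]


@dataclass(frozen=True)
class EnrichmentResult:
    analyte: str
    isotope_ratio: float
    delta_permil: float


def isotope_ratio(spectrum: IsotopologSpectrum, noise_floor: float = 0.0) -> float:
    """13C/12C isotope ratio of one spectrum.

    Intensities at or below ``noise_floor`` are clamped to zero before the
    ratio is formed. The ratio is invariant to uniform intensity scaling.
    """
    ai = [0.0 if a <= noise_floor else float(a) for a in spectrum.intensities]
    n = spectrum.n_carbons
    numerator = sum(k * ai[k] for k in range(3))
    denominator = sum((n - k) * ai[k] for k in range(3))
    if denominator <= 0:
        raise SpectrumError(
            f"isotope ratio undefined for {spectrum.analyte}: 12C-weighted "
            f"denominator is {denominator} (all-zero or degenerate spectrum)"
        )
    return numerator / denominator


def delta_enrichment(ir_labeled: float, ir_standard: float) -> float:
    """Delta-notation enrichment, permil: (IR_labeled / IR_std - 1) x 1000."""
    if ir_standard <= 0:
        raise SpectrumError(f"standard isotope ratio must be > 0, got {ir_standard}")
    if ir_labeled < 0:
        raise SpectrumError(f"labeled isotope ratio must be >= 0, got {ir_labeled}")
    return (ir_labeled / ir_standard - 1.0) * 1000.0


def pair_with_standard(
    spectra: pd.DataFrame,
    cell_keys: tuple = ("substrate", "dilution_level"),
    noise_floor: float = 0.0,
) -> pd.DataFrame:
    """Join labeled spectra to their treatment-matched standards.

    ``spectra`` has one row per bottle x analyte with columns ``analyte``,
    ``ai_m0``, ``ai_m1``, ``ai_m2``, boolean ``is_standard``, and the
    treatment cell keys (substrate x dilution level by default; one
    unlabeled standard bottle per cell determines natural abundance).
    Returns one row per labeled bottle x analyte with ``ir``,
    ``ir_standard``, and ``delta_permil``.
    """
    required = {"analyte", "ai_m0", "ai_m1", "ai_m2", "is_standard", *cell_keys}
    missing = required - set(spectra.columns)
    if missing:
        raise PairingError(f"spectra table missing columns {sorted(missing)}")

    def _ir(row) -> float:
        spec = IsotopologSpectrum(
            analyte=row["analyte"],
            intensities=(row["ai_m0"], row["ai_m1"], row["ai_m2"]),
        )
        return isotope_ratio(spec, noise_floor=noise_floor)

    group_keys = [*cell_keys, "analyte"]
    standards = spectra[spectra["is_standard"].astype(bool)]
    labeled = spectra[~spectra["is_standard"].astype(bool)]
    std_ir: dict[tuple, float] = {}
    for key, grp in standards.groupby(group_keys):
        if len(grp) > 1:
            raise PairingError(f"multiple standards for cell {key}")
        std_ir[key] = _ir(grp.iloc[0])

    out = []
    for key, grp in labeled.groupby(group_keys):
        if key not in std_ir:
            raise PairingError(f"no natural-abundance standard for cell {key}")
        ir_std = std_ir[key]
        for _, row in grp.iterrows():
            ir = _ir(row)
            rec = {k: row[k] for k in spectra.columns if k not in ("ai_m0", "ai_m1", "ai_m2")}
            rec.update(
                ir=ir, ir_standard=ir_std, delta_permil=delta_enrichment(ir, ir_std)
            )
            out.append(rec)
    return pd.DataFrame(out)
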