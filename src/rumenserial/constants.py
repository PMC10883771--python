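"""Physical and reporting constants used across the pipeline.

These are fixed defaults of the measurement system, not tunable model
parameters; overriding any of them should be a deliberate, logged act.
"""

#: Standard atmosphere, Pa. Gauge pressures are converted to absolute by
#: adding this value.
ATM_PA: float = 101_325.0

#: Ideal gas constant, J mol^-1 K^-1.
R_GAS: float = 8.314

#: Molar fraction of O2 in the atmosphere, used to estimate residual air in
#: evacuated exetainer vials from the O2 measured on the GC.
O2_ATMOSPHERIC: float = 0.2095

#: Offset (mV) added to redox potentials measured against an Ag/AgCl
#: electrode in saturated KCl to re-reference them to the standard hydrogen
#: electrode (SHE).
SHE_OFFSET_MV: float = 197.0

#: Average molar mass of one double-stranded DNA base pair, g mol^-1 bp^-1.
DSDNA_BP_G_PER_MOL: float = 660.0

#: Avogadro's number, mol^-1.
AVOGADRO: float = 6.02214e23

#: Natural abundance of 13C (per-carbon probability).
NATURAL_13C_ABUNDANCE: float = 0.0107

#: Incubation temperature, degrees C, and the default 72-h batch interval.
INCUBATION_TEMP_C: float = 39.0
TRANSFER_INTERVAL_H: float = 72.0

#: Bottle geometry defaults: 40 mL liquid working volume, 60 mL headspace.
TOTAL_LIQUID_VOLUME_ML: float = 40.0
HEADSPACE_VOLUME_ML: float = 60.0
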