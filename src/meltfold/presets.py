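"""Published study conditions used as generator inputs and worked examples.

Thermodynamic parameter sets for the SRE sense-strand segments and the
self-complementary reference octamers, in the association convention
(ΔH, ΔS < 0 for folding), together with the concentrations at which each
method was run.  These are *inputs* to the synthetic-data generators and
examples; nothing in the analysis code depends on them.
"""

from .equilibria import EquilibriumConditions, ThermoParams

__all__ = [
    "SRESEG16_UV_HAIRPIN",
    "SRESEG16_NMR_HAIRPIN",
    "SRESEG16_UV_DUPLEX",
    "SRESEG16_NMR_DUPLEX",
    "CTTCGAAG_NMR_DUPLEX",
    "COND_UV_SRESEG16",
    "COND_NMR_SRESEG16",
    "COND_NMR_CTTCGAAG",
    "K_DU_FLUOR_PER_M",
    "FLUOR_TEMPERATURE_C",
]

#: SREseg16, UV absorption series (3.08 μM), unimolecular hairpin model.
SRESEG16_UV_HAIRPIN = ThermoParams(dH=-137e3, dS=-414.0, label="SREseg16 UV hairpin")

#: SREseg16, NMR shift profiles (1.14 mM), unimolecular hairpin model.
SRESEG16_NMR_HAIRPIN = ThermoParams(dH=-137e3, dS=-409.0, label="SREseg16 NMR hairpin")

#: SREseg16 fitted instead with the bimolecular (mismatched-duplex) model.
SRESEG16_UV_DUPLEX = ThermoParams(dH=-217e3, dS=-555.0, label="SREseg16 UV duplex")
SRESEG16_NMR_DUPLEX = ThermoParams(dH=-211e3, dS=-577.0, label="SREseg16 NMR duplex")

#: Reference self-complementary octamer duplex CTTCGAAG, NMR (1.06 mM).
CTTCGAAG_NMR_DUPLEX = ThermoParams(dH=-252e3, dS=-732.0, label="CTTCGAAG NMR duplex")

COND_UV_SRESEG16 = EquilibriumConditions(c=3.08e-6)
COND_NMR_SRESEG16 = EquilibriumConditions(c=1.14e-3)
COND_NMR_CTTCGAAG = EquilibriumConditions(c=1.06e-3)

#: Homoduplex association constant from the fluorescence titration, M^-1
#: (8 μM^-1), and the ambient temperature of that experiment.
K_DU_FLUOR_PER_M = 8e6
FLUOR_TEMPERATURE_C = 21.0
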