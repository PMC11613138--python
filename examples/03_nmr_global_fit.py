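"""Global van't Hoff fit of NMR chemical-shift melting profiles.

In fast exchange the observed shift is the population-weighted mean of
the folded and unfolded state shifts.  One shared (Tm, ΔH) is fitted
across all aromatic resonances (each keeping its own linear state
shifts); per-resonance fits then show the melting cooperativity.
"""

import numpy as np

from meltfold import meltfit, presets, synth

cfg = synth.SynthConfig(seed=2)
profiles = synth.synth_shift_profiles(cfg)  # 26 aromatic/methyl resonances, 1.14 mM

fit = meltfit.fit_shift_profiles(profiles, "hairpin", presets.COND_NMR_SRESEG16)
print(f"global fit over {len(profiles)} resonances:")
print(f"  Tm = {fit.tm_celsius:.2f} +/- {fit.stderr['Tm']:.2f} C")
print(f"  dH = {fit.params.dH / 1e3:.1f} +/- {fit.stderr['dH'] / 1e3:.1f} kJ/mol")
print(f"  dS = {fit.params.dS:.0f} +/- {fit.stderr['dS']:.0f} J/mol/K")
print(f"generator truth: Tm = 61.81 C, dH = -137 kJ/mol, dS = -409 J/mol/K\n")

per = meltfit.per_resonance_tm(profiles, "hairpin", presets.COND_NMR_SRESEG16)
tms = np.array([r["Tm_celsius"] for r in per if not r["flag"]])
ses = np.array([r["stderr"] for r in per if not r["flag"]])
print(f"per-resonance Tm: {len(tms)} resonances, median {np.median(tms):.1f} C, "
      f"spread {tms.max() - tms.min():.1f} C "
      f"(median single-resonance uncertainty {np.median(ses):.1f} C)")
print("a one-Tm generator yields per-resonance melting points scattered only\n"
      "by their individual fit uncertainties: cooperative, two-state melting")
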