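# meltfold

Analysis toolkit for deciding how a partially palindromic DNA
oligonucleotide folds: into a unimolecular **hairpin** or a bimolecular
**mismatched homoduplex** — and for quantifying how much of each is
present — from multi-technique melting data.  The motivating system is the
sense strand of the serum response element (SRE) of the *c-Fos* promoter:
segments of 12–36 nt centred on the CArG-box (`SREsegN`) carry two
inverted-repeat arms around a central A/T hexamer, so a single strand can
close a stable hairpin (the building block of a cruciform) or pair with a
second copy of itself into a duplex containing tandem mismatches.

The package is written for spectroscopists analysing thermal melting
experiments of short nucleic acids: UV absorbance temperature series, NMR
chemical-shift profiles, NOESY volumes and fluorescence titrations, plus
seeded synthetic-data generators so every stage can be exercised at desk
scale.

## The models

All observables share one structure: a two-state transition with linear
pre- and post-transition baselines,

    y(T) = f(T)·(a_f + b_f·t) + (1 − f(T))·(a_u + b_u·t),

with the folded fraction `f(T)` driven by van't Hoff association
constants `K(T) = exp(−(ΔH − T·ΔS)/(R·T))`:

* **hairpin** (model i): `f_h = K_h/(1+K_h)`, `Tm = ΔH/ΔS`
  — concentration independent;
* **homoduplex** (model ii): mass balance `c = c_un + 2c_du`,
  `c_du = (K_du/c_ref)·c_un²`, giving `Tm = ΔH/(ΔS + R·ln(c/c_ref))`
  — Tm shifts with total strand concentration `c`;
* **coupled** (model iii): both species compete for the unfolded pool,
  `c = c_un + K_h·c_un + 2(K_du/c_ref)·c_un²`.

Because (i) and (ii) fit any single-concentration melting curve equally
well, the coupled model is only identifiable from data at well-separated
concentrations — the μM regime of UV absorbance against the mM regime of
NMR.  A simultaneous fit of both yields the duplex strand fraction as a
function of temperature and concentration.

Supporting stages: SVD factor analysis of the spectral series
(`Y_i = Σ_j W_j·V_ij·S_j`) with a three-criterion estimate of the factor
dimension; NOESY cross-peak calibration `d = 2.9 Å·(I_ref/I)^{1/6}`
referenced to the cytosine H5–H6 volume; non-negative least-squares
unmixing of FAM/Cy3 quench/unquench fluorescence patterns and equilibrium
fitting of the homoduplex association constant from a labeled/unlabeled
titration.

## Worked example

```sh
python examples/02_uv_melting_svd.py
```

```
singular values (relative): [1.000e+00 5.369e-02 1.185e-02 1.200e-03 2.600e-04 2.500e-04]
factor dimension M = 4
...
hairpin fit: Tm = 57.80 C  dH = -137.1 kJ/mol  dS = -414 J/mol/K
generator truth: Tm = 57.77 C, dH = -137.0 kJ/mol
```

Four singular values stand above the noise floor (the fifth is below one
per mille of the first): the mean spectrum, the folded−unfolded
difference, and one linear drift profile per state — exactly what a clean
two-state melt produces.  The shared-parameter fit of the weighted scores
recovers the generator's melting temperature to a few hundredths of a
degree and the folding enthalpy to ~0.1 kJ/mol.

The other scripts in `examples/` walk through fold-topology enumeration
(`01`), the global and per-resonance NMR shift fits (`03`), the joint
UV+NMR coupled-model fit and the duplex-fraction curve (`04`), NOE
distance calibration and MD restraint export (`05`), and the fluorescence
titration for `K_du` (`06`).  A thin CLI mirrors the library:

```sh
meltfold pipeline --seed 0 --out out/       # synth -> SVD -> fits -> report
meltfold svd --in spectra.csv --out decomp/
meltfold fit-nmr --in shifts.csv --model hairpin --out fit.json
```

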