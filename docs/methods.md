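# Methods

This note records the models implemented in `meltfold`, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the known limitations.

## Thermodynamic models

All equilibria use the **association convention**: `K = folded/unfolded`,
so folding has ΔH < 0 and ΔS < 0 and `K(T) = exp(−(ΔH − T·ΔS)/(R·T))`
with R = 8.314 J mol⁻¹ K⁻¹ exactly.  Temperatures are kelvin internally;
every file format and user-facing interface uses °C
(`T_K = T_C + 273.15`).  ΔCp is taken as zero (van't Hoff analysis);
salt corrections and nearest-neighbour predictions are out of scope.

* Hairpin (unimolecular): `f_h = K_h/(1+K_h)`; `Tm = ΔH/ΔS`, independent
  of concentration.
* Homoduplex (bimolecular): with `K' = K_du/c_ref` (`c_ref` = 1 M by
  convention) and total strand concentration `c`, the mass balance
  `2K'c_un² + c_un − c = 0` is solved by the cancellation-safe root
  `c_un = 2c/(1 + √(1+8K'c))`; `f_du = 1 − c_un/c` counts *strands* in
  duplexes (`2c_du/c`).  `Tm` solves `K_du(Tm) = c_ref/c`, i.e.
  `Tm = ΔH/(ΔS + R·ln(c/c_ref))`.
* Coupled model: `2K'c_un² + (1+K_h)c_un − c = 0`, same safe root with
  `b = 1+K_h`.  Exponents are clipped at ±500 inside the fit engine so
  extreme trial parameters cannot overflow.

A grid cross-check against a brute-force root bracketing (`brentq` on the
mass balance) holds to 1e−10 relative error; fraction conservation
`f_h + f_un + f_du = 1` is enforced to 1e−12.

## SVD factor analysis

`Y (n×p)` (spectra in rows) is decomposed exactly by `numpy.linalg.svd`.
Signs are fixed deterministically: each spectral profile is oriented so
its largest-magnitude element is positive, with the sign propagated to
the score column.  The factor dimension M is the largest component index
satisfying all of:

1. weight: `W_j/W_1 ≥ 10⁻³`;
2. residual: the per-point rms of the rank-(j−1) truncation exceeds the
   noise floor;
3. smoothness: lag-1 autocorrelation of the score column `V_·j ≥ 0.5`
   (noise components have erratic, decorrelated scores).

M is at least 1.  The thresholds in (1) and (3) are implementation
choices, overridable per call.  When no noise level is supplied, the
floor is estimated from the tail singular values: treating the smallest
`t = max(2, r−6)` components as noise, `σ̂² = Σ_tail W² / ((n−m)(p−m))`
with `m = r−t` — the expected Frobenius energy of an i.i.d. Gaussian
residual block after removing m signal components.  On the default
synthetic series this estimator lands within ~10 % of the injected σ.

## Melt fitting

Every observable is modelled as
`y(T) = f(T)·(a_f + b_f·t) + (1−f(T))·(a_u + b_u·t)` with t in °C
(baseline intercepts are referenced to 0 °C).  UV fits use the *weighted*
score columns `W_j·V_·j` (so per-point noise is comparable across
components and unit weights are appropriate); NMR fits use δ(T) per
resonance, weighted by the per-point σ when supplied.

Internal fit parameters are **(Tm, ΔH)** rather than (ΔH, ΔS) for
conditioning; ΔS is derived afterwards (`ΔS = ΔH/Tm` for the hairpin,
`ΔH/Tm − R ln(c/c_ref)` for the duplex) and its uncertainty follows by
the delta method.  Since the baselines enter linearly, they are
eliminated by variable projection (a per-curve linear solve inside the
residual), and a bounded trust-region least-squares search runs over the
two (or, jointly, four) nonlinear parameters from a deterministic
multi-start grid: Tm₀ from the temperature of steepest change
(amplitude-weighted median across curves) ± 5 K, ΔH₀ = −150 kJ/mol
× {0.6, 1, 1.6}.  `x_scale` separates the ~10² K and ~10⁵ J/mol scales.
Parameter covariance comes from the profiled Jacobian scaled by the
reduced χ² — the profile-likelihood curvature, which is the correct
marginal information for the nonlinear parameters.

A budget-exhausted optimizer return still carries the best attempt; this
matters only for noiseless closure data where the cost floor is ~10⁻²⁵
and relative tolerances cannot trigger.

`per_resonance_tm` fits each profile separately and flags a resonance
"no transition" when its fitted curve is indistinguishable from a
straight line within the data window (maximum deviation below 3× the
per-point noise) — this also catches transitions pushed outside the
measured range.

### Joint UV+NMR coupled fit

Four shared nonlinear parameters: hairpin (Tm, ΔH) and duplex (Tm at the
highest dataset concentration, ΔH).  Folded hairpin and duplex strands
share one folded observable baseline by default (separable via
`share_folded_baseline=False`, which gives each curve a third linear
state); this choice is a genuine open question of the analysis and the
shared variant is the parsimonious default.  Per-curve weights are
estimated robustly from second differences (MAD/√6), flooring at a tiny
positive value for noiseless data, so the two methods contribute on
comparable χ² scales.  A single-method input raises a "not separable"
error — at one concentration the uni- and bimolecular models are
observationally equivalent — and concentrations closer than 10× warn.
Duplex parameters with stderr(Tm) > 20 K or stderr(ΔH) > |ΔH| mark the
result non-identifiable rather than failing.

The recovered duplex strand fraction at a fixed low temperature is a
tail extrapolation and intrinsically carries a few percentage points of
spread at the study's noise levels; the acceptance script therefore
reports the median over several replicate datasets.

## NOE calibration

Isolated-spin-pair rule, `d = d_ref·(I_ref/I)^(1/6)` with d_ref = 2.9 Å,
I_ref = the arithmetic mean of all intranucleotide cytosine H5×H6
volumes.  Symmetric (above/below diagonal) peaks are averaged before
conversion.  Thymine methyl (M7) volumes are divided by 3 (pseudo-atom
convention for the three-proton integral).  No spin-diffusion or
relaxation-matrix correction is applied.  Restraint export uses flat
wells `d·(1±f) ∓/± a` with defaults f = 0.2, a = 0.  The B-DNA reference
distances used by `compare_to_bdna` (intra 3.7 Å, inter 3.2 Å for
H1′–H6/H8) are synthetic stand-in constants at standard B-form values;
only deviations from them are interpreted, never the absolute numbers.

## Fluorescence titration

Patterns are the four concatenated FAM/Cy3 excitation+emission spectra;
photophysics is not modelled — quench/unquench lives entirely in the
reference patterns.  Unmixing is non-negative least squares
(`scipy.optimize.nnls`) with normalized weights; a residual above 3× the
noise estimate flags a pattern outside the reference span.

The titration model neglects labeled–labeled duplexes (valid because
c_labeled ≤ 0.1 μM ≪ c_unlabeled): the unlabeled pool equilibrates on
its own through the coupled model, its free unfolded concentration u
partitions the labeled strand as
`f = K'u / (1 + K_h + K'u)`.  K_h at the titration temperature (21 °C)
is supplied from the melt fits, not refitted.  K_du is found by a
weighted grid search + bounded refinement on log₁₀K with a Δχ² = 1
profile-likelihood interval; a flat response returns an upper bound
instead of a point estimate.

## Synthetic-data generators

The generators produce data with exactly the statistical structure the
fits assume (model closure is exact at zero noise) and are pure
functions of (config, seed); independent `SeedSequence` streams keep the
four observables decoupled.  Grids follow the experimental protocols:
UV 220–320 nm, 5–85 °C in 4 °C steps; NMR every 2 °C.

* **UV series**: smooth analytic absorbance bands near 260 nm (peak
  0.7 AU, hyperchromicity 12 % on melting), not digitized spectra — only
  the difference structure matters to the pipeline.  Each state drifts
  linearly in amplitude and in shape: the folded band shifts position
  (0.04 nm/°C, first-derivative profile), the unfolded band broadens
  (0.04 nm/°C, second-derivative profile).  Noiseless output is exactly
  rank 4, and with the default noise (σ = 4·10⁻⁴ AU, routine
  photometric noise at 0.5–1 AU) the dimension criteria return M = 4
  with the fifth singular value below one per mille of the first.
* **Shift profiles**: population-weighted means of linear-in-T state
  shifts.  The default resonance table is generated from the SREseg16
  sequence itself — one H6/H8 per residue, H2 per adenine, M7 per
  thymine, 26 resonances in all, the full aromatic set a global fit
  uses — with mixed-sign folded−unfolded amplitudes of 0.08–0.3 ppm
  drawn once from a fixed internal seed (the table is a constant) and
  per-point noise 0.002 ppm.
* **NOESY volumes**: `I = scale·d⁻⁶·(1+ε)`, 5 % relative noise, methyl
  volumes tripled (mirroring the converter's pseudo-atom division).
* **Titration patterns**: duplex-fraction-weighted mixtures of the two
  reference patterns plus 0.2 % full-scale Gaussian noise, floored at
  zero; the quenched (hairpin) reference is attenuated per block
  (FAM ~4×, Cy3 ~2×) with a 2 nm band shift so the references are
  genuinely non-collinear.

What passing tests on these data do **not** show: robustness to baseline
curvature, ΔCp ≠ 0, exchange-broadened line shapes, spin diffusion,
inner-filter/FRET corrections, or wavelength miscalibration — none of
which the generators emulate.

## Problem sizes

The test suite and acceptance script run everything at the study's own
desk scale: 21×101 UV matrices, 26 resonances × 36 temperatures, 9-point
titrations; recovery statistics use 20 seeded replicates, and the joint
fit's duplex fraction is summarized as the median of 15 replicate
datasets.

## Known limitations

* The hairpin fold enumerator implements the contiguous-stem topology
  only (stem growth stops at the first non-WC pair): no bulges, internal
  loops, or alternative registers, and no free-energy-based structure
  prediction.
* Segment lengths above 20 nt require flanking sequence not included in
  the shipped table and raise an error rather than guessing.
* Oligo Calc monomer masses are hard-coded for linear, unmodified,
  5′-OH single strands; other conventions (5′-phosphate, alternative
  average-isotope tables) are not provided.
* The per-resonance melting-point spread reflects single-resonance fit
  uncertainty; resolving sub-degree cooperativity requires shift
  precision at the line-fit level (≈5·10⁻⁴ ppm), not the default noise.
* The fluorescence species model ignores labeled–labeled duplexes and
  any hairpin–duplex exchange kinetics.
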