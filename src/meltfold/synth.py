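"""Seeded synthetic-data generators for every observable in the pipeline.

These stand in for the study's raw measurements, which are not deposited.
Each generator is a pure function of its configuration and seed and
produces data with exactly the statistical structure the corresponding
analysis assumes: two-state melting with linear pre-/post-transition
baselines (UV and NMR observables), concentration-coupled homoduplex
competition, r⁻⁶ NOE intensities, and quench/unquench fluorescence
patterns, all with i.i.d. Gaussian noise.

Default grids follow the experimental protocols: UV spectra 220–320 nm
over 5–85 °C in 4 °C steps; NMR shift profiles every 2 °C.  The endpoint
UV spectra are smooth analytic absorbance bands near 260 nm — only their
difference structure (hyperchromicity + per-state drift) matters to the
analysis, not their photometric realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .equilibria import (
    R_GAS,
    EquilibriumConditions,
    ThermoParams,
    assoc_constant,
    celsius_to_kelvin,
    combined_fractions,
    duplex_fractions,
    hairpin_fractions,
)
from .factors import SpectralSeries
from .fluor import FLUOR_BLOCKS, FluorescencePattern, TitrationPoint, labeled_duplex_fraction
from .meltfit import ShiftProfile
from .noe import CrossPeak
from . import presets

__all__ = [
    "SynthConfig",
    "DEFAULT_RESONANCE_TABLE",
    "folded_weight",
    "synth_uv_series",
    "synth_shift_profiles",
    "synth_noesy_peaks",
    "make_reference_patterns",
    "synth_titration",
    "solve_duplex_entropy",
]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the generators (one seed drives everything).

    Noise defaults: 4·10⁻⁴ absorbance units per point (routine UV-vis
    photometric noise at 0.5–1 AU), 0.002 ppm per shift point (digital
    resolution of a well-phased 500 MHz spectrum), 5 % NOESY volume
    scatter, 0.2 % of full scale per fluorescence point.
    """

    seed: int = 0
    uv_temperatures: np.ndarray = field(
        default_factory=lambda: np.arange(5.0, 86.0, 4.0)
    )
    nmr_temperatures: np.ndarray = field(
        default_factory=lambda: np.arange(5.0, 76.0, 2.0)
    )
    wavelengths: np.ndarray = field(
        default_factory=lambda: np.arange(220.0, 321.0, 1.0)
    )
    uv_noise_sigma: float = 4e-4  # absorbance units
    shift_noise_sigma: float = 0.002  # ppm
    noe_noise_rel: float = 0.05
    fluor_noise_rel: float = 0.002  # of full scale
    uv_peak_absorbance: float = 0.7
    hyperchromicity: float = 0.12
    uv_folded_drift: float = 5e-4  # relative amplitude / °C
    uv_unfolded_drift: float = 1.0e-3
    uv_folded_shift: float = 0.04  # folded-state band shift, nm / °C
    uv_unfolded_broadening: float = 0.04  # unfolded-state broadening, nm / °C
    drift_reference_celsius: float = 45.0

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


def folded_weight(
    thermo: ThermoParams,
    model: str,
    cond: EquilibriumConditions,
    T_K: np.ndarray,
    duplex: ThermoParams | None = None,
) -> np.ndarray:
    """Folded strand fraction on a temperature grid for any of the models.

    ``model`` "hairpin" or "duplex" uses ``thermo`` alone; "combined"
    treats ``thermo`` as the hairpin and requires ``duplex``; folded
    hairpin and duplex strands count together (shared folded observable).
    """
    out = np.empty(len(T_K))
    for i, T in enumerate(T_K):
        if model == "hairpin":
            st = hairpin_fractions(assoc_constant(thermo, T), T=T)
            out[i] = st.f_h
        elif model == "duplex":
            st = duplex_fractions(assoc_constant(thermo, T), cond, T=T)
            out[i] = st.f_du
        elif model == "combined":
            if duplex is None:
                raise ValueError("combined model requires duplex params")
            st = combined_fractions(
                assoc_constant(thermo, T), assoc_constant(duplex, T), cond, T=T
            )
            out[i] = st.f_h + st.f_du
        else:
            raise ValueError(f"unknown model {model!r}")
    return out


def _gauss(x: np.ndarray, mu: float, sig: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sig) ** 2)


def endpoint_spectra(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Folded and unfolded endpoint absorbance bands on cfg.wavelengths."""
    wl = cfg.wavelengths
    folded = _gauss(wl, 258.0, 16.0) + 0.32 * _gauss(wl, 281.0, 13.0) + 0.55 * _gauss(wl, 215.0, 12.0)
    folded *= cfg.uv_peak_absorbance / folded.max()
    unfolded = _gauss(wl, 260.5, 17.5) + 0.30 * _gauss(wl, 283.0, 14.0) + 0.50 * _gauss(wl, 216.0, 12.5)
    unfolded *= cfg.uv_peak_absorbance * (1.0 + cfg.hyperchromicity) / unfolded.max()
    return folded, unfolded


def synth_uv_series(
    cfg: SynthConfig,
    thermo: ThermoParams = presets.SRESEG16_UV_HAIRPIN,
    model: str = "hairpin",
    cond: EquilibriumConditions = presets.COND_UV_SRESEG16,
    duplex: ThermoParams | None = None,
    name: str = "synthetic UV series",
) -> SpectralSeries:
    """Temperature series of UV spectra for a two-state (or coupled) melt.

    Each state's spectrum drifts linearly with temperature: in amplitude
    (relative slope α), and in shape — the folded band shifts position
    (first-derivative profile D_f = −dS_f/dλ, rate s_f nm/°C) while the
    unfolded band broadens (second-derivative profile B_u = w²·d²S_u/dλ²,
    rate b_u nm/°C):

    Y(T, λ) = f·[S_f·(1+α_f·Δt) + s_f·Δt·D_f]
            + (1−f)·[S_u·(1+α_u·Δt) + b_u·Δt·B_u] + ε,

    Δt = t − t_ref (°C), ε ~ N(0, σ_UV).  Noiseless output is therefore
    exactly rank ≤ 4: mean, transition difference, and one drift profile
    per state (the amplitude drift adds no new spectral shape; shift and
    broadening profiles have odd/even symmetry about the band and so stay
    independent).  The drift components appear mostly below (folded) and
    above (unfolded) the transition, respectively.
    """
    t = cfg.uv_temperatures
    wl = cfg.wavelengths
    f = folded_weight(thermo, model, cond, celsius_to_kelvin(t), duplex=duplex)
    S_f, S_u = endpoint_spectra(cfg)
    D_f = -np.gradient(S_f, wl)
    B_u = 17.5 * np.gradient(np.gradient(S_u, wl), wl)
    dt = (t - cfg.drift_reference_celsius)[:, None]
    Y = (
        f[:, None] * (S_f[None, :] * (1.0 + cfg.uv_folded_drift * dt)
                      + cfg.uv_folded_shift * dt * D_f[None, :])
        + (1.0 - f)[:, None] * (S_u[None, :] * (1.0 + cfg.uv_unfolded_drift * dt)
                                + cfg.uv_unfolded_broadening * dt * B_u[None, :])
    )
    if cfg.uv_noise_sigma > 0:
        Y = Y + cfg.rng(1).normal(0.0, cfg.uv_noise_sigma, size=Y.shape)
    return SpectralSeries(
        wavelengths=cfg.wavelengths,
        temperatures=t,
        Y=Y,
        name=name,
        concentration=cond.c,
    )


#: Random-coil (unfolded) ¹H shifts by base and atom, ppm — round figures
#: of the usual DNA values.
_COIL_SHIFTS = {
    ("A", "H8"): 8.22, ("G", "H8"): 7.92, ("A", "H2"): 7.90,
    ("T", "H6"): 7.40, ("C", "H6"): 7.62, ("T", "M7"): 1.72,
}


def default_resonance_table(seq=None) -> tuple[tuple, ...]:
    """(label, delta_f0, delta_f1, delta_u0, delta_u1) rows for every
    aromatic/methyl resonance of a sequence (H6 or H8 per residue, H2 for
    adenines, M7 for thymines) — the full set a global shift fit uses.

    Folded−unfolded amplitudes are mixed-sign, 0.08–0.3 ppm, drawn once
    from a fixed internal seed so the table is a deterministic constant;
    state slopes are a few 10⁻⁴ ppm/°C.
    """
    from .oligo import build_sre_segment

    if seq is None:
        seq = build_sre_segment(16)
    rng = np.random.default_rng(20161)  # fixed: the table is a constant
    rows = []
    for base, pos in zip(seq.bases, seq.positions):
        atoms = ["H8" if base in "AG" else "H6"]
        if base == "A":
            atoms.append("H2")
        if base == "T":
            atoms.append("M7")
        for atom in atoms:
            coil = _COIL_SHIFTS[(base, atom)]
            amp = rng.choice([-1.0, 1.0]) * rng.uniform(0.08, 0.30)
            rows.append(
                (
                    f"{base}{pos} {atom}",
                    round(coil + amp, 3),
                    round(rng.uniform(-3e-4, 3e-4), 6),
                    coil,
                    round(rng.uniform(3e-4, 7e-4), 6),
                )
            )
    return tuple(rows)


DEFAULT_RESONANCE_TABLE = default_resonance_table()


def synth_shift_profiles(
    cfg: SynthConfig,
    resonance_table: Sequence[tuple] = DEFAULT_RESONANCE_TABLE,
    thermo: ThermoParams = presets.SRESEG16_NMR_HAIRPIN,
    model: str = "hairpin",
    cond: EquilibriumConditions = presets.COND_NMR_SRESEG16,
    duplex: ThermoParams | None = None,
) -> list[ShiftProfile]:
    """Fast-exchange chemical-shift melting profiles δ(T) per resonance.

    δ(T) is the population-weighted mean of linear-in-T folded and
    unfolded state shifts, plus Gaussian noise.
    """
    t = cfg.nmr_temperatures
    f = folded_weight(thermo, model, cond, celsius_to_kelvin(t), duplex=duplex)
    rng = cfg.rng(2)
    out = []
    for label, df0, df1, du0, du1 in resonance_table:
        delta = f * (df0 + df1 * t) + (1.0 - f) * (du0 + du1 * t)
        if cfg.shift_noise_sigma > 0:
            delta = delta + rng.normal(0.0, cfg.shift_noise_sigma, size=delta.shape)
        out.append(
            ShiftProfile(nucleus=label, T=t, delta=delta, sigma=cfg.shift_noise_sigma or None)
        )
    return out


def synth_noesy_peaks(
    geometry: Sequence[tuple],
    scale: float,
    cfg: SynthConfig,
) -> list[CrossPeak]:
    """Cross-peak volumes I = scale·d⁻⁶·(1+ε) from a known geometry.

    ``geometry``: ((res_a, atom_a), (res_b, atom_b), distance_Å) triples;
    include at least one cytosine H5–H6 pair at 2.9 Å so the standard
    calibration applies.  Methyl (M7) volumes are tripled, mirroring the
    three-proton integral the converter divides back out.
    """
    rng = cfg.rng(3)
    peaks = []
    for atom_a, atom_b, d in geometry:
        if d <= 0:
            raise ValueError("distances must be > 0")
        v = scale * d**-6
        if atom_a[1] == "M7" or atom_b[1] == "M7":
            v *= 3.0
        if cfg.noe_noise_rel > 0:
            v *= 1.0 + rng.normal(0.0, cfg.noe_noise_rel)
        peaks.append(CrossPeak(atom_a=tuple(atom_a), atom_b=tuple(atom_b), volume=v))
    return peaks


def _fluor_grid() -> tuple[np.ndarray, tuple[int, ...], tuple[str, ...]]:
    grids = [np.arange(lo, hi + 1e-9, 2.0) for _, lo, hi in FLUOR_BLOCKS]
    edges = np.cumsum([0] + [len(g) for g in grids])
    return np.concatenate(grids), tuple(int(e) for e in edges), tuple(
        name for name, *_ in FLUOR_BLOCKS
    )


def make_reference_patterns(cfg: SynthConfig, scale: float = 1e5) -> tuple[
    FluorescencePattern, FluorescencePattern
]:
    """(hairpin_reference, duplex_reference) four-block patterns.

    The closed hairpin holds FAM and Cy3 adjacent, so its pattern is
    strongly quenched (FAM most); the duplex pattern is unquenched with a
    small band shift so the two references are genuinely non-collinear.
    """
    wl, edges, names = _fluor_grid()
    centers = {"fam_emission": 521.0, "fam_excitation": 494.0,
               "cy3_emission": 563.0, "cy3_excitation": 549.0}
    widths = {"fam_emission": 24.0, "fam_excitation": 21.0,
              "cy3_emission": 19.0, "cy3_excitation": 24.0}
    amp_du = {"fam_emission": 1.0, "fam_excitation": 0.9,
              "cy3_emission": 0.8, "cy3_excitation": 0.7}
    quench = {"fam_emission": 0.22, "fam_excitation": 0.25,
              "cy3_emission": 0.48, "cy3_excitation": 0.45}
    du = np.empty(len(wl))
    hp = np.empty(len(wl))
    for i, name in enumerate(names):
        seg = slice(edges[i], edges[i + 1])
        du[seg] = scale * amp_du[name] * _gauss(wl[seg], centers[name], widths[name])
        hp[seg] = (
            scale * amp_du[name] * quench[name]
            * _gauss(wl[seg], centers[name] + 2.0, widths[name] * 1.05)
        )
    duplex = FluorescencePattern("duplex reference", du, edges, names)
    hairpin = FluorescencePattern("hairpin reference", hp, edges, names)
    return hairpin, duplex


def synth_titration(
    cfg: SynthConfig,
    K_du: float,
    K_h: float,
    references: tuple[FluorescencePattern, FluorescencePattern] | None = None,
    ratios: Sequence[float] = (0.0, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0, 3000.0),
    c_labeled: float = 1e-7,
) -> list[TitrationPoint]:
    """Labeled/unlabeled titration series with noisy mixed patterns.

    ``ratios`` are c_unlabeled : c_labeled; the labeled strand stays at
    0.1 μM.  Each pattern is the duplex-fraction-weighted mix of the
    (hairpin, duplex) references plus Gaussian noise, floored at zero.
    """
    if references is None:
        references = make_reference_patterns(cfg)
    ref_h, ref_du = references
    rng = cfg.rng(4)
    sigma = cfg.fluor_noise_rel * max(ref_du.intensities.max(), ref_h.intensities.max())
    points = []
    for r in ratios:
        if r < 0:
            raise ValueError("ratios must be >= 0")
        c_u = r * c_labeled
        f = labeled_duplex_fraction(K_du, K_h, c_labeled, c_u)
        y = (1.0 - f) * ref_h.intensities + f * ref_du.intensities
        if sigma > 0:
            y = np.clip(y + rng.normal(0.0, sigma, size=y.shape), 0.0, None)
        points.append(
            TitrationPoint(
                c_labeled=c_labeled,
                c_unlabeled=c_u,
                pattern=FluorescencePattern(
                    f"titration 1:{r:g}", y, ref_h.block_edges, ref_h.block_names
                ),
            )
        )
    return points


def solve_duplex_entropy(
    f_du_target: float,
    T_celsius: float,
    cond: EquilibriumConditions,
    hairpin: ThermoParams,
    dH_duplex: float,
) -> ThermoParams:
    """Duplex ΔS such that the coupled model gives a target duplex strand
    fraction at one temperature and concentration (ΔH fixed)."""
    T = celsius_to_kelvin(T_celsius)
    K_h = assoc_constant(hairpin, T)

    def f_du_of_dS(dS: float) -> float:
        K_du = assoc_constant(ThermoParams(dH_duplex, dS), T)
        return combined_fractions(K_h, K_du, cond, T=T).f_du - f_du_target

    dS = brentq(f_du_of_dS, -3000.0, 500.0, xtol=1e-10)
    return ThermoParams(dH=dH_duplex, dS=float(dS), label="duplex (solved)")
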