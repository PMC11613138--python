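"""Coupled hairpin/homoduplex equilibrium thermochemistry.

Three two-state van't Hoff models describe the melting of a partially
palindromic strand at total strand concentration ``c``:

(i)   hairpin only        —  unfolded ⇌ hairpin,       K_h  = c_h / c_un
(ii)  homoduplex only     —  2·unfolded ⇌ duplex,      K_du = c_du·c_ref / c_un²
(iii) combined            —  both equilibria share the unfolded pool.

Association convention throughout: K = folded/unfolded, so folding has
ΔH < 0 and ΔS < 0, and K(T) = exp(−(ΔH − T·ΔS)/(R·T)).  Temperatures are
kelvin internally; helpers convert °C ↔ K at the interfaces.

Strand fractions are reported per strand: f_h = c_h/c, f_un = c_un/c,
f_du = 2·c_du/c (a duplex holds two strands), so f_h + f_un + f_du = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "R_GAS",
    "ThermoParams",
    "EquilibriumConditions",
    "EquilibriumState",
    "celsius_to_kelvin",
    "kelvin_to_celsius",
    "gibbs_energy",
    "assoc_constant",
    "hairpin_fractions",
    "duplex_fractions",
    "combined_fractions",
    "melting_temperature",
]

#: Molar gas constant, J mol^-1 K^-1 (value used throughout, exactly).
R_GAS = 8.314


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + 273.15


def kelvin_to_celsius(t_k: float) -> float:
    return t_k - 273.15


@dataclass(frozen=True)
class ThermoParams:
    """Van't Hoff association parameters.

    dH : J/mol, enthalpy change of association (negative for folding)
    dS : J/(mol K), entropy change of association (negative for folding)
    """

    dH: float
    dS: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dH) and math.isfinite(self.dS)):
            raise ValueError("dH and dS must be finite")


@dataclass(frozen=True)
class EquilibriumConditions:
    """Total strand concentration c (mol/L), reference c_ref (mol/L, 1 M by
    convention) and optionally a temperature (K)."""

    c: float
    c_ref: float = 1.0
    T: float | None = None

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("c must be > 0")
        if self.c_ref <= 0:
            raise ValueError("c_ref must be > 0")
        if self.T is not None and self.T <= 0:
            raise ValueError("T must be > 0 K")


@dataclass(frozen=True)
class EquilibriumState:
    """Species fractions (per strand) at one temperature."""

    T: float
    K_h: float
    K_du: float
    f_h: float
    f_un: float
    f_du: float

    def __post_init__(self) -> None:
        if self.K_h < 0 or self.K_du < 0:
            raise ValueError("association constants must be >= 0")
        total = self.f_h + self.f_un + self.f_du
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"fractions sum to {total!r}, not 1")
        for f in (self.f_h, self.f_un, self.f_du):
            if not -1e-15 <= f <= 1 + 1e-15:
                raise ValueError("fractions must lie in [0, 1]")


def gibbs_energy(params: ThermoParams, T: float) -> float:
    """ΔG of association (J/mol) at temperature T (K)."""
    if T <= 0:
        raise ValueError("T must be > 0 K")
    return params.dH - T * params.dS


def assoc_constant(params: ThermoParams, T: float) -> float:
    """Dimensionless association constant K(T) = exp(−ΔG/(R·T))."""
    return math.exp(-gibbs_energy(params, T) / (R_GAS * T))


def hairpin_fractions(K_h: float, T: float = float("nan")) -> EquilibriumState:
    """Model (i): only hairpins form.  f_h = K_h/(1+K_h)."""
    if K_h < 0:
        raise ValueError("K_h must be >= 0")
    f_h = K_h / (1.0 + K_h)
    return EquilibriumState(T=T, K_h=K_h, K_du=0.0, f_h=f_h, f_un=1.0 - f_h, f_du=0.0)


def _unfolded_concentration(K_h: float, Kp: float, c: float) -> float:
    """Positive root of 2·K'·c_un² + (1+K_h)·c_un − c = 0, cancellation-safe.

    K' = K_du/c_ref (L/mol).  Written as 2c / (b + sqrt(b² + 8K'c)) with
    b = 1+K_h so no subtraction of near-equal quantities occurs for any
    K', K_h ≥ 0.
    """
    b = 1.0 + K_h
    return 2.0 * c / (b + math.sqrt(b * b + 8.0 * Kp * c))


def duplex_fractions(K_du: float, cond: EquilibriumConditions, T: float = float("nan")) -> EquilibriumState:
    """Model (ii): only duplexes form.

    Mass balance c = c_un + 2·c_du with c_du = (K_du/c_ref)·c_un².
    """
    if K_du < 0:
        raise ValueError("K_du must be >= 0")
    Kp = K_du / cond.c_ref
    c_un = _unfolded_concentration(0.0, Kp, cond.c)
    f_un = c_un / cond.c
    return EquilibriumState(
        T=T, K_h=0.0, K_du=K_du, f_h=0.0, f_un=f_un, f_du=1.0 - f_un
    )


def combined_fractions(
    K_h: float, K_du: float, cond: EquilibriumConditions, T: float = float("nan")
) -> EquilibriumState:
    """Model (iii): hairpins and duplexes compete for the unfolded pool.

    Mass balance c = c_un + c_h + 2·c_du, with c_h = K_h·c_un and
    c_du = (K_du/c_ref)·c_un².
    """
    if K_h < 0 or K_du < 0:
        raise ValueError("association constants must be >= 0")
    Kp = K_du / cond.c_ref
    c_un = _unfolded_concentration(K_h, Kp, cond.c)
    f_un = c_un / cond.c
    f_h = K_h * f_un
    f_du = 1.0 - f_un - f_h
    # clip the tiny negative round-off the closed form can leave
    if -1e-15 < f_du < 0.0:
        f_du = 0.0
        f_un = 1.0 - f_h
    return EquilibriumState(T=T, K_h=K_h, K_du=K_du, f_h=f_h, f_un=f_un, f_du=f_du)


def fractions_at(
    hairpin: ThermoParams | None,
    duplex: ThermoParams | None,
    cond: EquilibriumConditions,
    T: float,
) -> EquilibriumState:
    """Convenience: evaluate the combined model from thermodynamic params."""
    K_h = assoc_constant(hairpin, T) if hairpin is not None else 0.0
    K_du = assoc_constant(duplex, T) if duplex is not None else 0.0
    return combined_fractions(K_h, K_du, cond, T=T)


def melting_temperature(
    params: ThermoParams,
    model: str = "hairpin",
    cond: EquilibriumConditions | None = None,
) -> float:
    """Transition temperature (K) of half-conversion.

    hairpin: Tm = ΔH/ΔS (concentration independent).
    duplex:  K_du(Tm) = c_ref/c  ⇒  Tm = ΔH/(ΔS + R·ln(c/c_ref)).
    """
    if model == "hairpin":
        if params.dS == 0:
            raise ValueError("no physical Tm: dS = 0")
        tm = params.dH / params.dS
        if tm <= 0:
            raise ValueError("no physical Tm: dH/dS <= 0")
        return tm
    if model == "duplex":
        if cond is None:
            raise ValueError("duplex Tm requires concentration conditions")
        denom = params.dS + R_GAS * math.log(cond.c / cond.c_ref)
        if denom == 0:
            raise ValueError("no physical Tm: zero denominator")
        tm = params.dH / denom
        if tm <= 0:
            raise ValueError("no physical Tm: sign of dS + R ln(c/c_ref) inconsistent with dH")
        return tm
    raise ValueError(f"unknown model {model!r}")
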