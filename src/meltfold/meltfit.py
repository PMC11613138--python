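"""Nonlinear least-squares melting analysis.

All observables — SVD score columns from UV spectral series and per-nucleus
NMR chemical-shift profiles — are modelled the same way: the measured value
at temperature T is the population-weighted mean of a folded and an
unfolded state value, each drifting linearly with temperature,

    y(T) = f(T) · (a_f + b_f·t) + (1 − f(T)) · (a_u + b_u·t),   t in °C,

with the folded fraction f(T) driven by a two-state van't Hoff model
(unimolecular hairpin, bimolecular duplex, or the coupled combination).

Fitting strategy: the thermodynamic parameters enter nonlinearly, the
baselines linearly, so the baselines are eliminated by variable projection
(a linear solve per evaluation) and a Levenberg–Marquardt search with a
deterministic multi-start grid runs over (Tm, ΔH) only.  (Tm, ΔH) is used
internally instead of (ΔH, ΔS) for conditioning; ΔS is derived afterwards.
Parameter covariance comes from the profiled Jacobian, scaled by the
reduced chi-square.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .equilibria import (
    R_GAS,
    EquilibriumConditions,
    ThermoParams,
    celsius_to_kelvin,
    kelvin_to_celsius,
)
from .factors import FactorDecomposition

__all__ = [
    "ShiftProfile",
    "ShiftStateModel",
    "MeltFitResult",
    "JointFitResult",
    "FitError",
    "NotSeparableError",
    "folded_fraction",
    "combined_state_fractions",
    "fit_melt_curves",
    "fit_uv_scores",
    "fit_shift_profiles",
    "per_resonance_tm",
    "fit_joint",
    "duplex_fraction_curve",
    "estimate_noise_from_curve",
]

_EXP_CLIP = 500.0  # caps exponents so trial parameters cannot overflow


class FitError(RuntimeError):
    """Optimization failed; carries the best attempt if one exists."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


class NotSeparableError(ValueError):
    """Hairpin and duplex contributions cannot be separated from the data."""


@dataclass(frozen=True)
class ShiftStateModel:
    """Linear-in-temperature state shifts: δ_state(t) = δ0 + δ1·t (t in °C)."""

    delta_f0: float
    delta_f1: float
    delta_u0: float
    delta_u1: float


@dataclass(frozen=True)
class ShiftProfile:
    """Temperature profile of one resonance's chemical shift."""

    nucleus: str
    T: np.ndarray  # °C, sorted ascending
    delta: np.ndarray  # ppm
    sigma: float | None = None  # per-point uncertainty, ppm

    def __post_init__(self) -> None:
        T = np.asarray(self.T, dtype=float)
        d = np.asarray(self.delta, dtype=float)
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "delta", d)
        if T.ndim != 1 or d.shape != T.shape or len(T) < 5:
            raise ValueError(
                f"profile {self.nucleus!r}: need matched 1-D arrays of >= 5 points"
            )
        if np.any(np.diff(T) <= 0):
            raise ValueError(f"profile {self.nucleus!r}: temperatures must be sorted")


# ---------------------------------------------------------------------------
# species fractions, vectorised over temperature


def _assoc_constant_arr(dH: float, dS: float, T_K: np.ndarray) -> np.ndarray:
    expo = -(dH - T_K * dS) / (R_GAS * T_K)
    return np.exp(np.clip(expo, -_EXP_CLIP, _EXP_CLIP))


def _entropy_from_tm(dH: float, Tm_K: float, model: str, cond: EquilibriumConditions) -> float:
    if model == "hairpin":
        return dH / Tm_K
    if model == "duplex":
        return dH / Tm_K - R_GAS * math.log(cond.c / cond.c_ref)
    raise ValueError(f"unknown model {model!r}")


def folded_fraction(
    dH: float, Tm_K: float, model: str, cond: EquilibriumConditions, T_K: np.ndarray
) -> np.ndarray:
    """Folded strand fraction on a temperature grid for one two-state model.

    Tm_K is the half-conversion temperature *at the concentration in cond*
    (for the duplex model ΔS is reconstructed from it via
    ΔS = ΔH/Tm − R·ln(c/c_ref)).
    """
    T_K = np.asarray(T_K, dtype=float)
    dS = _entropy_from_tm(dH, Tm_K, model, cond)
    K = _assoc_constant_arr(dH, dS, T_K)
    if model == "hairpin":
        return K / (1.0 + K)
    Kp = K / cond.c_ref
    c_un = 2.0 * cond.c / (1.0 + np.sqrt(1.0 + 8.0 * Kp * cond.c))
    return 1.0 - c_un / cond.c


def combined_state_fractions(
    hairpin: ThermoParams,
    duplex: ThermoParams,
    cond: EquilibriumConditions,
    T_K: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(f_h, f_du, f_un) arrays of the coupled model on a temperature grid."""
    T_K = np.asarray(T_K, dtype=float)
    K_h = _assoc_constant_arr(hairpin.dH, hairpin.dS, T_K)
    K_du = _assoc_constant_arr(duplex.dH, duplex.dS, T_K)
    Kp = K_du / cond.c_ref
    b = 1.0 + K_h
    c_un = 2.0 * cond.c / (b + np.sqrt(b * b + 8.0 * Kp * cond.c))
    f_un = c_un / cond.c
    f_h = K_h * f_un
    f_du = np.clip(1.0 - f_un - f_h, 0.0, 1.0)
    return f_h, f_du, f_un


# ---------------------------------------------------------------------------
# results


@dataclass
class MeltFitResult:
    """Fitted two-state melting parameters for one model.

    ``params`` holds (ΔH, ΔS) in J/mol and J/(mol K); ``Tm`` is kelvin and
    consistent with the params and model.  ``covariance`` is over the
    internal (Tm, ΔH) parameterization; ``stderr`` adds the delta-method
    value for ΔS.  ``baselines`` holds one (a_f, b_f, a_u, b_u) row per
    fitted curve (°C convention: intercept at 0 °C).
    """

    model: str
    params: ThermoParams
    Tm: float
    cond: EquilibriumConditions
    baselines: np.ndarray
    covariance: np.ndarray
    stderr: dict
    rss: float
    ndata: int
    nparams: int
    success: bool = True
    message: str = ""
    curve_labels: tuple = ()

    @property
    def tm_celsius(self) -> float:
        return kelvin_to_celsius(self.Tm)

    def folded_fraction(self, T_celsius: np.ndarray) -> np.ndarray:
        T_K = celsius_to_kelvin(np.asarray(T_celsius, dtype=float))
        return folded_fraction(self.params.dH, self.Tm, self.model, self.cond, T_K)

    def predict(self, curve_index: int, T_celsius: np.ndarray) -> np.ndarray:
        t = np.asarray(T_celsius, dtype=float)
        f = self.folded_fraction(t)
        a_f, b_f, a_u, b_u = self.baselines[curve_index]
        return f * (a_f + b_f * t) + (1.0 - f) * (a_u + b_u * t)


@dataclass
class JointFitResult:
    """Simultaneous UV+NMR fit of the coupled hairpin+duplex model."""

    hairpin_params: ThermoParams
    duplex_params: ThermoParams
    Tm_hairpin: float  # K
    Tm_duplex: float  # K, at the reference (highest) concentration
    cond_ref: EquilibriumConditions
    baselines: list
    covariance: np.ndarray  # over (Tm_h, dH_h, Tm_du, dH_du)
    stderr: dict
    rss: float
    ndata: int
    non_identifiable: bool = False
    message: str = ""

    def fraction_at(self, T_celsius: float, c: float) -> tuple[float, float, float]:
        """(f_h, f_du, f_un) at one temperature (°C) and concentration (M)."""
        cond = EquilibriumConditions(c=c, c_ref=self.cond_ref.c_ref)
        f_h, f_du, f_un = combined_state_fractions(
            self.hairpin_params, self.duplex_params, cond,
            np.array([celsius_to_kelvin(T_celsius)]),
        )
        return float(f_h[0]), float(f_du[0]), float(f_un[0])


def duplex_fraction_curve(
    res: JointFitResult, T_grid_celsius: np.ndarray, c: float
) -> np.ndarray:
    """f_du(T) of the fitted coupled model on a °C grid at concentration c."""
    cond = EquilibriumConditions(c=c, c_ref=res.cond_ref.c_ref)
    _, f_du, _ = combined_state_fractions(
        res.hairpin_params, res.duplex_params, cond,
        celsius_to_kelvin(np.asarray(T_grid_celsius, dtype=float)),
    )
    return f_du


# ---------------------------------------------------------------------------
# generic variable-projection engine


def estimate_noise_from_curve(y: np.ndarray) -> float:
    """Robust per-point noise from second differences (MAD-based)."""
    y = np.asarray(y, dtype=float)
    if len(y) < 4:
        return 0.0
    d2 = np.diff(y, 2)
    return float(1.4826 * np.median(np.abs(d2)) / np.sqrt(6.0))


def _init_tm(curves: list[dict]) -> float:
    """Initial Tm (K): temperature of steepest change, amplitude-weighted."""
    cands, weights = [], []
    for cv in curves:
        t, y = cv["T"], cv["y"]
        if len(t) < 4:
            continue
        dy = np.gradient(y, t)
        k = int(np.argmax(np.abs(dy)))
        cands.append(t[k])
        weights.append(np.ptp(y))
    if not cands:
        return celsius_to_kelvin(50.0)
    order = np.argsort(cands)
    cands = np.asarray(cands)[order]
    weights = np.asarray(weights)[order]
    cum = np.cumsum(weights)
    k = int(np.searchsorted(cum, 0.5 * cum[-1]))
    return celsius_to_kelvin(float(cands[min(k, len(cands) - 1)]))


def _design_residual(theta, curves, fraction_fn):
    """VarPro residual: per curve solve the linear baselines, stack residuals."""
    res_parts = []
    betas = []
    for cv in curves:
        t = cv["T"]
        f = fraction_fn(theta, cv)
        X = np.column_stack([f, f * t, 1.0 - f, (1.0 - f) * t])
        w = cv["weight"]
        beta, *_ = np.linalg.lstsq(X * w, cv["y"] * w, rcond=None)
        betas.append(beta)
        res_parts.append((cv["y"] - X @ beta) * w)
    return np.concatenate(res_parts), betas


def _run_multistart(curves, fraction_fn, starts, bounds, tol=1e-15, max_nfev_per_param=400):
    best = None
    any_converged = False
    # (Tm, dH) style parameters differ by ~4 orders of magnitude; x_scale
    # keeps the trust region sane
    x_scale = [10.0 if abs(lo) < 1e4 else 1e4 for lo in bounds[0]]
    for x0 in starts:
        x0 = np.clip(x0, bounds[0], bounds[1])
        try:
            sol = least_squares(
                lambda th: _design_residual(th, curves, fraction_fn)[0],
                x0,
                bounds=bounds,
                method="trf",
                x_scale=x_scale,
                xtol=tol,
                ftol=tol,
                gtol=tol,
                max_nfev=max_nfev_per_param * len(x0),
            )
        except Exception:
            continue
        if sol.status < 0:
            continue
        any_converged = any_converged or sol.status > 0
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("no optimizer start converged")
    # status 0 (budget exhausted) still carries the best attempt; at a
    # near-zero cost floor the relative tolerances simply cannot trigger
    return best


def _covariance(sol, ndata, nlin) -> tuple[np.ndarray, float]:
    """Covariance of the nonlinear params from the profiled Jacobian."""
    ntheta = len(sol.x)
    dof = max(ndata - ntheta - nlin, 1)
    s2 = 2.0 * sol.cost / dof
    JTJ = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(JTJ) * s2
    except np.linalg.LinAlgError:
        cov = np.full((ntheta, ntheta), np.inf)
    return cov, s2


def fit_melt_curves(
    curves: list[dict],
    model: str,
    cond: EquilibriumConditions,
    dH_init: float = -150e3,
    n_starts: int = 5,
) -> MeltFitResult:
    """Fit one shared (Tm, ΔH) two-state model to a set of melt curves.

    Each curve dict needs keys ``T`` (°C array), ``y`` (observable array),
    optional ``sigma`` (scalar), ``label`` and ``cond`` (defaults to the
    shared conditions — a per-curve cond lets multi-concentration duplex
    data share one ΔS).
    """
    if model not in ("hairpin", "duplex"):
        raise ValueError(f"unknown model {model!r}")
    work = []
    for cv in curves:
        t = np.asarray(cv["T"], dtype=float)
        y = np.asarray(cv["y"], dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("curve T and y must be matched 1-D arrays")
        sigma = cv.get("sigma")
        weight = 1.0 / sigma if sigma else 1.0
        work.append(
            {
                "T": t,
                "y": y,
                "weight": weight,
                "label": cv.get("label", ""),
                "cond": cv.get("cond", cond),
            }
        )
    t_all = np.concatenate([cv["T"] for cv in work])
    t_lo, t_hi = celsius_to_kelvin(t_all.min()), celsius_to_kelvin(t_all.max())

    def fraction_fn(theta, cv):
        Tm, dH = theta
        # Tm is defined at the shared cond; per-curve cond reuses the
        # derived ΔS so concentration shifts are honoured.
        dS = _entropy_from_tm(dH, Tm, model, cond)
        ccv = cv["cond"]
        if model == "hairpin" or ccv is cond:
            return folded_fraction(dH, Tm, model, ccv if model == "hairpin" else cond,
                                   celsius_to_kelvin(cv["T"]))
        # duplex with a different concentration: recompute Tm at that c
        denom = dS + R_GAS * math.log(ccv.c / ccv.c_ref)
        tm_c = dH / denom if denom * dH > 0 else Tm
        return folded_fraction(dH, tm_c, model, ccv, celsius_to_kelvin(cv["T"]))

    tm0 = _init_tm(work)
    starts = [
        (tm0, dH_init),
        (tm0 - 5.0, dH_init),
        (tm0 + 5.0, dH_init),
        (tm0, 0.6 * dH_init),
        (tm0, 1.6 * dH_init),
    ][: max(1, n_starts)]
    bounds = ([t_lo - 40.0, -1.5e6], [t_hi + 60.0, -1e2])
    sol = _run_multistart(work, fraction_fn, starts, bounds)
    _, betas = _design_residual(sol.x, work, fraction_fn)

    Tm, dH = sol.x
    dS = _entropy_from_tm(dH, Tm, model, cond)
    nlin = 4 * len(work)
    cov, s2 = _covariance(sol, sum(len(cv["y"]) for cv in work), nlin)
    # delta method for ΔS = dH/Tm (− const): grad = (−dH/Tm², 1/Tm)
    g = np.array([-dH / Tm**2, 1.0 / Tm])
    stderr = {
        "Tm": float(np.sqrt(max(cov[0, 0], 0.0))),
        "dH": float(np.sqrt(max(cov[1, 1], 0.0))),
        "dS": float(np.sqrt(max(g @ cov @ g, 0.0))),
    }
    return MeltFitResult(
        model=model,
        params=ThermoParams(dH=float(dH), dS=float(dS)),
        Tm=float(Tm),
        cond=cond,
        baselines=np.array(betas),
        covariance=cov,
        stderr=stderr,
        rss=float(2.0 * sol.cost),
        ndata=sum(len(cv["y"]) for cv in work),
        nparams=2 + nlin,
        success=True,
        message=sol.message,
        curve_labels=tuple(cv["label"] for cv in work),
    )


# ---------------------------------------------------------------------------
# public fits


def fit_uv_scores(
    decomp: FactorDecomposition,
    M: int,
    model: str,
    cond: EquilibriumConditions,
    sigma: float | None = None,
) -> MeltFitResult:
    """Joint two-state fit of the first M weighted SVD score columns.

    The fitted observables are W_j·V_ij (scores carrying their statistical
    weight), so the per-point noise is comparable across components and
    unit weighting is appropriate.
    """
    if M < 2:
        raise ValueError("need M >= 2 score columns to constrain the transition")
    if M > decomp.rank:
        raise ValueError(f"M={M} exceeds rank {decomp.rank}")
    t = decomp.temperatures
    curves = [
        {
            "T": t,
            "y": decomp.W[j] * decomp.V[:, j],
            "sigma": sigma,
            "label": f"score_{j + 1}",
        }
        for j in range(M)
    ]
    return fit_melt_curves(curves, model=model, cond=cond)


def fit_shift_profiles(
    profiles: Sequence[ShiftProfile],
    model: str = "hairpin",
    cond: EquilibriumConditions | None = None,
    shared: bool = True,
) -> MeltFitResult | list[MeltFitResult]:
    """Global (shared-parameter) van't Hoff fit of chemical-shift profiles.

    With ``shared=True`` one (Tm, ΔH) drives every resonance, each keeping
    its own folded/unfolded linear state shifts — the joint fit used for
    the headline thermodynamic values.  ``shared=False`` fits each profile
    independently and returns a list.
    """
    if not profiles:
        raise ValueError("no profiles given")
    if cond is None:
        cond = EquilibriumConditions(c=1e-3)
    curves = [
        {"T": p.T, "y": p.delta, "sigma": p.sigma, "label": p.nucleus}
        for p in profiles
    ]
    if shared:
        return fit_melt_curves(curves, model=model, cond=cond)
    return [fit_melt_curves([cv], model=model, cond=cond) for cv in curves]


def per_resonance_tm(
    profiles: Sequence[ShiftProfile],
    model: str = "hairpin",
    cond: EquilibriumConditions | None = None,
    amplitude_snr_min: float = 3.0,
) -> list[dict]:
    """Per-resonance melting points (separate fits), with failure flags.

    A resonance whose folded−unfolded amplitude at Tm is below
    ``amplitude_snr_min`` times the residual scatter is flagged
    ``"no transition"`` instead of reporting a meaningless Tm.
    """
    out = []
    for p in profiles:
        rec = {"nucleus": p.nucleus, "Tm_celsius": math.nan, "stderr": math.nan, "flag": ""}
        try:
            fit = fit_shift_profiles([p], model=model, cond=cond, shared=True)
        except (FitError, ValueError) as exc:
            rec["flag"] = f"fit failed: {exc}"
            out.append(rec)
            continue
        # "no transition": the fitted curve is indistinguishable from a
        # straight line within the data window (flat amplitude, or a Tm
        # pushed outside the measured range)
        y_hat = fit.predict(0, p.T)
        coef = np.polyfit(p.T, y_hat, 1)
        amplitude = float(np.max(np.abs(y_hat - np.polyval(coef, p.T))))
        noise = p.sigma if p.sigma else estimate_noise_from_curve(p.delta)
        if amplitude < amplitude_snr_min * max(noise, 1e-300):
            rec["flag"] = "no transition"
            out.append(rec)
            continue
        rec["Tm_celsius"] = fit.tm_celsius
        rec["stderr"] = fit.stderr["Tm"]
        out.append(rec)
    return out


def fit_joint(
    uv: tuple[FactorDecomposition, int, EquilibriumConditions] | None,
    nmr: tuple[Sequence[ShiftProfile], EquilibriumConditions] | None,
    share_folded_baseline: bool = True,
    require_separable: bool = True,
    dH_hairpin_init: float = -140e3,
    dH_duplex_init: float = -220e3,
) -> JointFitResult:
    """Simultaneous coupled-model (hairpin + homoduplex) fit of UV and NMR.

    The two methods probe concentrations differing by orders of magnitude;
    only that contrast makes the bimolecular duplex term identifiable, so a
    single-method input raises :class:`NotSeparableError` (pass
    ``require_separable=False`` to force the fit and receive a result
    flagged ``non_identifiable``).  Folded hairpin and duplex share one
    folded observable baseline by default.
    """
    datasets = []
    if uv is not None:
        decomp, M, cond_uv = uv
        for j in range(M):
            datasets.append(
                {
                    "T": decomp.temperatures,
                    "y": decomp.W[j] * decomp.V[:, j],
                    "cond": cond_uv,
                    "label": f"uv score_{j + 1}",
                }
            )
    if nmr is not None:
        profiles, cond_nmr = nmr
        for p in profiles:
            datasets.append(
                {"T": p.T, "y": p.delta, "cond": cond_nmr, "label": f"nmr {p.nucleus}"}
            )
    if uv is None and nmr is None:
        raise ValueError("no data given")
    concs = sorted({cv["cond"].c for cv in datasets})
    if len(concs) < 2:
        if require_separable:
            raise NotSeparableError(
                "not separable: the coupled hairpin+duplex model needs data at "
                "well-separated concentrations (a single method/concentration "
                "cannot distinguish uni- from bimolecular folding)"
            )
    elif concs[-1] / concs[0] < 10.0:
        warnings.warn(
            "concentrations differ by < 10x; hairpin and duplex contributions "
            "may not be separable",
            stacklevel=2,
        )

    cond_ref = max((cv["cond"] for cv in datasets), key=lambda c: c.c)
    work = []
    for cv in datasets:
        t = np.asarray(cv["T"], dtype=float)
        y = np.asarray(cv["y"], dtype=float)
        sig = estimate_noise_from_curve(y)
        if sig <= 0:
            sig = max(1e-12, 1e-9 * max(np.ptp(y), 1.0))
        work.append(
            {"T": t, "y": y, "weight": 1.0 / sig, "cond": cv["cond"], "label": cv["label"]}
        )

    def fraction_fn(theta, cv):
        Tm_h, dH_h, Tm_du, dH_du = theta
        dS_h = dH_h / Tm_h
        dS_du = dH_du / Tm_du - R_GAS * math.log(cond_ref.c / cond_ref.c_ref)
        f_h, f_du, _ = combined_state_fractions(
            ThermoParams(dH_h, dS_h),
            ThermoParams(dH_du, dS_du),
            cv["cond"],
            celsius_to_kelvin(cv["T"]),
        )
        if share_folded_baseline:
            return f_h + f_du
        return f_h  # separate-duplex variant handled via extra column below

    if not share_folded_baseline:
        # extend the linear design with an own duplex column per curve
        def residual_design(theta, cv):
            Tm_h, dH_h, Tm_du, dH_du = theta
            dS_h = dH_h / Tm_h
            dS_du = dH_du / Tm_du - R_GAS * math.log(cond_ref.c / cond_ref.c_ref)
            f_h, f_du, f_un = combined_state_fractions(
                ThermoParams(dH_h, dS_h), ThermoParams(dH_du, dS_du),
                cv["cond"], celsius_to_kelvin(cv["T"]),
            )
            t = cv["T"]
            return np.column_stack(
                [f_h, f_h * t, f_un, f_un * t, f_du, f_du * t]
            )

        def vp_residual(theta):
            parts = []
            for cv in work:
                X = residual_design(theta, cv)
                w = cv["weight"]
                beta, *_ = np.linalg.lstsq(X * w, cv["y"] * w, rcond=None)
                parts.append((cv["y"] - X @ beta) * w)
            return np.concatenate(parts)

    # initialise the hairpin branch from a hairpin-only fit
    pre = fit_melt_curves(
        [dict(cv, sigma=None) for cv in work], model="hairpin",
        cond=cond_ref, dH_init=dH_hairpin_init,
    )
    tm_h0, dh_h0 = pre.Tm, pre.params.dH

    t_all = np.concatenate([cv["T"] for cv in work])
    t_lo, t_hi = celsius_to_kelvin(t_all.min()), celsius_to_kelvin(t_all.max())
    bounds = (
        [t_lo - 40.0, -1.5e6, t_lo - 40.0, -1.5e6],
        [t_hi + 60.0, -1e2, t_hi + 80.0, -1e2],
    )
    starts = [
        (tm_h0, dh_h0, tm_h0 - 6.0, dH_duplex_init),
        (tm_h0, dh_h0, tm_h0 + 3.0, dH_duplex_init),
        (tm_h0, dh_h0, tm_h0 + 10.0, dH_duplex_init),
        (tm_h0, dh_h0, tm_h0 + 3.0, 0.7 * dH_duplex_init),
        (tm_h0, dh_h0, tm_h0 + 3.0, 1.4 * dH_duplex_init),
    ]
    if share_folded_baseline:
        sol = _run_multistart(work, fraction_fn, starts, bounds,
                              tol=1e-12, max_nfev_per_param=100)
        _, betas = _design_residual(sol.x, work, fraction_fn)
    else:
        best = None
        for x0 in starts:
            x0 = np.clip(x0, bounds[0], bounds[1])
            s = least_squares(vp_residual, x0, bounds=bounds, method="trf",
                              xtol=1e-14, ftol=1e-14, gtol=1e-14)
            if s.status > 0 and (best is None or s.cost < best.cost):
                best = s
        if best is None:
            raise FitError("joint fit did not converge from any start")
        sol = best
        betas = []
        for cv in work:
            X = residual_design(sol.x, cv)
            w = cv["weight"]
            beta, *_ = np.linalg.lstsq(X * w, cv["y"] * w, rcond=None)
            betas.append(beta)

    Tm_h, dH_h, Tm_du, dH_du = sol.x
    dS_h = dH_h / Tm_h
    dS_du = dH_du / Tm_du - R_GAS * math.log(cond_ref.c / cond_ref.c_ref)
    ndata = sum(len(cv["y"]) for cv in work)
    nlin = (4 if share_folded_baseline else 6) * len(work)
    cov, _ = _covariance(sol, ndata, nlin)
    stderr = {
        "Tm_hairpin": float(np.sqrt(max(cov[0, 0], 0.0))),
        "dH_hairpin": float(np.sqrt(max(cov[1, 1], 0.0))),
        "Tm_duplex": float(np.sqrt(max(cov[2, 2], 0.0))),
        "dH_duplex": float(np.sqrt(max(cov[3, 3], 0.0))),
    }
    non_ident = (
        len(concs) < 2
        or not np.isfinite(stderr["Tm_duplex"])
        or stderr["Tm_duplex"] > 20.0
        or stderr["dH_duplex"] > abs(dH_du)
    )
    return JointFitResult(
        hairpin_params=ThermoParams(float(dH_h), float(dS_h), "hairpin"),
        duplex_params=ThermoParams(float(dH_du), float(dS_du), "duplex"),
        Tm_hairpin=float(Tm_h),
        Tm_duplex=float(Tm_du),
        cond_ref=cond_ref,
        baselines=[np.asarray(b) for b in betas],
        covariance=cov,
        stderr=stderr,
        rss=float(2.0 * sol.cost),
        ndata=ndata,
        non_identifiable=bool(non_ident),
        message=sol.message,
    )
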