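"""Fluorescence-pattern unmixing and homoduplex association-constant fitting.

A strand doubly labeled with FAM (3') and Cy3 (5') reports its fold: in
the closed hairpin the two fluorophores sit next to each other and quench;
in a duplex with an unlabeled partner they are held apart and fluoresce.
Each sample is characterised by a *pattern* — four concatenated spectra
(FAM emission, FAM excitation, Cy3 emission, Cy3 excitation).  Measured
patterns are unmixed against reference patterns by non-negative least
squares, and a titration of doubly labeled strand with increasing excess
of unlabeled strand yields the homoduplex association constant K_du.

Species model for the labeled strand (labeled–labeled duplexes neglected,
valid because c_labeled ≪ c_unlabeled):

    f_duplex = K'·u / (1 + K_h + K'·u),

where u is the free unfolded unlabeled-strand concentration from the
coupled hairpin+duplex model at the unlabeled concentration and
K' = K_du/c_ref.  Photophysics is not modelled: quench/unquench lives
entirely in the reference patterns.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar, nnls

from .equilibria import EquilibriumConditions
from .meltfit import estimate_noise_from_curve

__all__ = [
    "FluorescencePattern",
    "TitrationPoint",
    "AssociationFitResult",
    "unmix_pattern",
    "labeled_duplex_fraction",
    "fit_association_constant",
    "FLUOR_BLOCKS",
]

#: The four spectral blocks of a pattern and their wavelength grids (nm).
FLUOR_BLOCKS = (
    ("fam_emission", 499.0, 681.0),
    ("fam_excitation", 403.0, 515.0),
    ("cy3_emission", 549.0, 681.0),
    ("cy3_excitation", 403.0, 553.0),
)


@dataclass(frozen=True)
class FluorescencePattern:
    """Concatenated four-block fluorescence pattern of one sample."""

    sample: str
    intensities: np.ndarray
    block_edges: tuple[int, ...]  # cumulative start indices, len = n_blocks+1
    block_names: tuple[str, ...] = tuple(name for name, *_ in FLUOR_BLOCKS)

    def __post_init__(self) -> None:
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", y)
        if y.ndim != 1 or len(y) == 0:
            raise ValueError("pattern must be a non-empty 1-D vector")
        if np.any(y < 0):
            raise ValueError("negative intensities")
        if self.block_edges[0] != 0 or self.block_edges[-1] != len(y):
            raise ValueError("block_edges must span the full vector")

    def grid_matches(self, other: "FluorescencePattern") -> bool:
        return (
            self.block_edges == other.block_edges
            and self.block_names == other.block_names
        )

    def block(self, name: str) -> np.ndarray:
        i = self.block_names.index(name)
        return self.intensities[self.block_edges[i] : self.block_edges[i + 1]]


@dataclass(frozen=True)
class TitrationPoint:
    """One labeled/unlabeled mixture in the titration series."""

    c_labeled: float  # mol/L, kept <= 1e-7 to avoid self-absorption
    c_unlabeled: float  # mol/L
    pattern: FluorescencePattern

    def __post_init__(self) -> None:
        if self.c_labeled <= 0:
            raise ValueError("c_labeled must be > 0")
        if self.c_unlabeled < 0:
            raise ValueError("c_unlabeled must be >= 0")


def unmix_pattern(
    pattern: FluorescencePattern,
    references: Sequence[FluorescencePattern],
    noise_sigma: float | None = None,
) -> dict:
    """Non-negative least-squares decomposition against reference patterns.

    Returns raw weights, normalized fractions, the residual norm and a
    flag when the pattern falls outside the reference span (residual above
    3× the noise estimate).
    """
    if len(references) < 2:
        raise ValueError("need at least 2 reference patterns")
    for r in references:
        if not pattern.grid_matches(r):
            raise ValueError(f"reference {r.sample!r} on a different grid")
    A = np.column_stack([r.intensities for r in references])
    w, rnorm = nnls(A, pattern.intensities)
    total = w.sum()
    fractions = w / total if total > 0 else w
    sigma = noise_sigma
    if sigma is None:
        sigma = estimate_noise_from_curve(pattern.intensities)
    resid_rms = rnorm / math.sqrt(len(pattern.intensities))
    outside = sigma > 0 and resid_rms > 3.0 * sigma
    if outside:
        warnings.warn(
            f"pattern {pattern.sample!r}: residual {resid_rms:.3g} exceeds 3x "
            f"noise estimate {sigma:.3g}; outside the reference span?",
            stacklevel=2,
        )
    return {
        "weights": w,
        "fractions": fractions,
        "residual_rms": resid_rms,
        "outside_span": bool(outside),
    }


def labeled_duplex_fraction(
    K_du: float,
    K_h: float,
    c_labeled: float,
    c_unlabeled: float,
    c_ref: float = 1.0,
) -> float:
    """Fraction of labeled strands bound in (hetero)duplexes.

    K_du in M⁻¹ when c_ref = 1 M (dimensionless K_du/c_ref is what enters).
    The unlabeled pool equilibrates on its own (hairpin + homoduplex); its
    free unfolded concentration u then partitions the trace labeled strand
    between hairpin (K_h), free, and heteroduplex (K'·u).
    """
    if K_du < 0 or K_h < 0:
        raise ValueError("association constants must be >= 0")
    if c_labeled < 0 or c_unlabeled < 0:
        raise ValueError("concentrations must be >= 0")
    if K_du == 0.0 or c_unlabeled == 0.0:
        return 0.0
    Kp = K_du / c_ref
    b = 1.0 + K_h
    u = 2.0 * c_unlabeled / (b + math.sqrt(b * b + 8.0 * Kp * c_unlabeled))
    x = Kp * u
    return x / (1.0 + K_h + x)


@dataclass
class AssociationFitResult:
    """Point estimate and profile-likelihood interval for K_du."""

    K_du: float  # M^-1
    ci_low: float
    ci_high: float
    upper_bound_only: bool
    K_h: float
    fractions_observed: np.ndarray
    fractions_fitted: np.ndarray
    c_unlabeled: np.ndarray
    rss: float

    @property
    def K_du_per_uM(self) -> float:
        return self.K_du * 1e-6

    @property
    def ci_per_uM(self) -> tuple[float, float]:
        return self.ci_low * 1e-6, self.ci_high * 1e-6


def fit_association_constant(
    titration: Sequence[TitrationPoint],
    references: Sequence[FluorescencePattern],
    K_h: float,
    duplex_reference_index: int = 1,
    sigma_fraction: float | None = None,
    log10K_bounds: tuple[float, float] = (2.0, 12.0),
) -> AssociationFitResult:
    """Estimate K_du from a labeled/unlabeled titration series.

    Each point's pattern is unmixed against the references (index
    ``duplex_reference_index`` = unquenched duplex state) to give the
    observed labeled-duplex fraction; :func:`labeled_duplex_fraction` is
    then fitted over K_du by weighted least squares on a log10 K grid
    search + refinement, with a 1σ profile-likelihood interval (Δχ² = 1).
    A flat titration response yields an upper bound instead of an estimate.
    """
    if len(titration) < 4:
        raise ValueError("need >= 4 titration points")
    c_u = np.array([tp.c_unlabeled for tp in titration], dtype=float)
    span = c_u[c_u > 0]
    if len(span) and span.max() / span.min() < 100.0:
        warnings.warn("titration spans < 2 decades of unlabeled concentration",
                      stacklevel=2)
    f_obs = np.array(
        [
            unmix_pattern(tp.pattern, references)["fractions"][duplex_reference_index]
            for tp in titration
        ]
    )
    c_l = np.array([tp.c_labeled for tp in titration], dtype=float)
    if sigma_fraction is None:
        sigma_fraction = max(float(np.std(np.diff(f_obs))) / math.sqrt(2.0), 1e-6)

    def model(K):
        return np.array(
            [labeled_duplex_fraction(K, K_h, cl, cu) for cl, cu in zip(c_l, c_u)]
        )

    def chi2(log10K):
        r = (f_obs - model(10.0**log10K)) / sigma_fraction
        return float(r @ r)

    grid = np.linspace(*log10K_bounds, 81)
    chi = np.array([chi2(g) for g in grid])
    k0 = grid[int(np.argmin(chi))]
    ref = minimize_scalar(
        chi2, bracket=None, bounds=(max(k0 - 0.5, grid[0]), min(k0 + 0.5, grid[-1])),
        method="bounded", options={"xatol": 1e-6},
    )
    best_log = float(ref.x)
    best_chi = float(ref.fun)
    K_best = 10.0**best_log

    # profile-likelihood 1-sigma interval on the log grid
    fine = np.linspace(grid[0], grid[-1], 600)
    chif = np.array([chi2(g) for g in fine])
    inside = fine[chif <= best_chi + 1.0]
    ci_low = 10.0 ** float(inside.min()) if len(inside) else 0.0
    ci_high = 10.0 ** float(inside.max()) if len(inside) else math.inf
    # flat response: the lower edge of the interval touches the search floor
    upper_only = len(inside) > 0 and inside.min() <= grid[0] + 1e-9
    if chif.max() - chif.min() < 1.0:  # chi2 flat across the whole range
        upper_only = True
        ci_low = 0.0
    return AssociationFitResult(
        K_du=K_best,
        ci_low=0.0 if upper_only else ci_low,
        ci_high=ci_high,
        upper_bound_only=bool(upper_only),
        K_h=K_h,
        fractions_observed=f_obs,
        fractions_fitted=model(K_best),
        c_unlabeled=c_u,
        rss=best_chi * sigma_fraction**2,
    )
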