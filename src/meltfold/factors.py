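"""SVD factor analysis of temperature-dependent spectral series.

A series of n absorbance spectra Y_i(λ) measured along a temperature ramp
is decomposed as Y_i = Σ_j W_j · V_ij · S_j: orthonormal spectral profiles
S_j (rows), orthonormal score columns V_·j, and non-negative singular
values W_j in descending order.  The factor dimension M — the number of
profiles needed to reconstruct the series within experimental error — is
estimated from three criteria: the singular-value drop, the truncation
residual reaching the noise floor, and the smoothness of the score columns
(noise components have erratic, decorrelated scores).

A clean two-state melt with linear pre-/post-transition baselines in both
states has factor dimension 4: the mean spectrum, the folded−unfolded
difference, and one linear-drift component per state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SpectralSeries",
    "FactorDecomposition",
    "decompose",
    "estimate_dimension",
    "reconstruct",
    "estimate_noise_sigma",
]


@dataclass(frozen=True)
class SpectralSeries:
    """n spectra on a common wavelength grid along a temperature ramp.

    Y has shape (n, p): one row per temperature, one column per wavelength.
    Temperatures are °C and must be sorted ascending.
    """

    wavelengths: np.ndarray
    temperatures: np.ndarray
    Y: np.ndarray
    name: str = ""
    concentration: float | None = None  # mol/L
    path_length_cm: float = 1.0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        t = np.asarray(self.temperatures, dtype=float)
        Y = np.asarray(self.Y, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "Y", Y)
        if Y.ndim != 2:
            raise ValueError("Y must be a 2-D matrix (n_temperatures, n_wavelengths)")
        n, p = Y.shape
        if n < 3 or p < 2:
            raise ValueError(f"need n >= 3 spectra of p >= 2 points, got {n}x{p}")
        if len(t) != n or len(wl) != p:
            raise ValueError("axis lengths inconsistent with Y shape")
        if np.any(~np.isfinite(Y)) or np.any(~np.isfinite(t)) or np.any(~np.isfinite(wl)):
            raise ValueError("NaN/inf in spectral series")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def p(self) -> int:
        return self.Y.shape[1]


@dataclass(frozen=True)
class FactorDecomposition:
    """Result of the SVD Y = V · diag(W) · S.

    S : (r, p) orthonormal spectral profiles (rows)
    V : (n, r) orthonormal score columns
    W : (r,) singular values, descending
    residual_rms[m] : per-point rms of the rank-m truncation error, m = 0…r
    """

    S: np.ndarray
    V: np.ndarray
    W: np.ndarray
    wavelengths: np.ndarray
    temperatures: np.ndarray
    residual_rms: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.residual_rms is None:
            n, p = self.V.shape[0], self.S.shape[1]
            tail = np.concatenate([np.cumsum((self.W**2)[::-1])[::-1], [0.0]])
            object.__setattr__(self, "residual_rms", np.sqrt(tail / (n * p)))

    @property
    def rank(self) -> int:
        return len(self.W)


def _fix_signs(S: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orientation: largest-|·| element of each profile > 0."""
    S = S.copy()
    V = V.copy()
    for j in range(S.shape[0]):
        k = int(np.argmax(np.abs(S[j])))
        if S[j, k] < 0:
            S[j] *= -1.0
            V[:, j] *= -1.0
    return S, V


def decompose(series: SpectralSeries) -> FactorDecomposition:
    """Exact SVD of the spectral matrix with a deterministic sign convention."""
    U, w, Vt = np.linalg.svd(series.Y, full_matrices=False)
    S, V = _fix_signs(Vt, U)
    return FactorDecomposition(
        S=S,
        V=V,
        W=w,
        wavelengths=series.wavelengths,
        temperatures=series.temperatures,
    )


def estimate_noise_sigma(decomp: FactorDecomposition, n_signal_max: int | None = None) -> float:
    """Per-point noise level estimated from the tail singular values.

    The smallest t = max(2, r−6) singular values are treated as pure noise
    (n_signal_max overrides the number m = r−t of components protected as
    potential signal).  For an i.i.d. Gaussian residual the energy of the
    noise block after removing m signal components is ≈ (n−m)(p−m)·σ², so
    σ̂ = sqrt(Σ_tail W² / ((n−m)(p−m))).
    """
    n, r = decomp.V.shape
    p = decomp.S.shape[1]
    if n_signal_max is None:
        t = max(2, r - 6)
    else:
        t = max(1, r - int(n_signal_max))
    m = r - t
    energy = float(np.sum(decomp.W[m:] ** 2))
    return float(np.sqrt(energy / ((n - m) * (p - m))))


def _lag1_autocorr(x: np.ndarray) -> float:
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0.0:
        return 0.0
    return float(np.dot(x[:-1], x[1:]) / denom)


def estimate_dimension(
    decomp: FactorDecomposition,
    noise_sigma: float | None = None,
    weight_ratio_min: float = 1e-3,
    smoothness_min: float = 0.5,
) -> int:
    """Factor dimension M from the three joint criteria.

    A component j counts as signal if (i) W_j/W_1 ≥ weight_ratio_min,
    (ii) the truncation residual with j−1 components still exceeds the
    noise floor (supplied per-point σ, or estimated from the tail singular
    values), and (iii) its score column is smooth: lag-1 autocorrelation of
    V_·j ≥ smoothness_min.  M is the largest such j (at least 1).
    """
    sigma = estimate_noise_sigma(decomp) if noise_sigma is None else float(noise_sigma)
    W = decomp.W
    if W[0] == 0.0:
        return 1
    M = 1
    for j in range(1, decomp.rank + 1):
        if W[j - 1] / W[0] < weight_ratio_min:
            continue
        if decomp.residual_rms[j - 1] <= sigma:
            continue
        if _lag1_autocorr(decomp.V[:, j - 1]) < smoothness_min:
            continue
        M = j
    return M


def reconstruct(decomp: FactorDecomposition, M: int) -> SpectralSeries:
    """Rank-M reconstruction Y_M = Σ_{j≤M} W_j V_·j S_j."""
    if not 1 <= M <= decomp.rank:
        raise ValueError(f"M must be in 1..{decomp.rank}, got {M}")
    Y = (decomp.V[:, :M] * decomp.W[:M]) @ decomp.S[:M]
    return SpectralSeries(
        wavelengths=decomp.wavelengths,
        temperatures=decomp.temperatures,
        Y=Y,
        name=f"rank-{M} reconstruction",
    )
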