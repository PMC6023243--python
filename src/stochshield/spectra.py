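"""Per-edge power spectral densities and lagged covariances.

The observed fluctuation process M^T X of a reversible first-order network is
a sum of Ornstein-Uhlenbeck modes, so its two-sided power spectral density in
angular frequency splits edge by edge:

    S_k(omega) = (j_k / 2 pi) | sum_{i>=2} (M^T v_i)(w_i^T zeta_k)
                                / (lambda_i + i omega) |^2,

with S(omega) = sum_k S_k(omega) and the Wiener-Khinchin normalization
``integral_{-inf}^{inf} S_k d omega = R_k``.  The M-projected lagged
covariance has the matching eigen-sum with ``exp(lambda_i tau)`` weights and
C_k(0) = R_k.  All frequencies here are angular (rad per model time unit) and
all densities two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy import integrate

from .network import (
    MarkovNetworkModel,
    NonReversibleError,
    SpectralDecomposition,
    laplacian,
    spectral_decomposition,
    stationary_summary,
)

__all__ = [
    "SpectralDensityTable",
    "LaggedCovarianceTable",
    "default_omega_grid",
    "psd",
    "psd_integral_check",
    "lagged_covariance",
    "crossing_frequency",
]


@dataclass(frozen=True)
class SpectralDensityTable:
    """Two-sided per-edge PSD values on an angular-frequency grid.

    ``per_edge[k-1, :]`` is S_k(omega); ``total`` their pointwise sum;
    ``subset_sums`` holds sums over requested edge subsets keyed by label.
    """

    omega: np.ndarray
    per_edge: np.ndarray
    total: np.ndarray
    subset_sums: Dict[str, np.ndarray]
    imaginary_residual: float


@dataclass(frozen=True)
class LaggedCovarianceTable:
    """M-projected per-edge lagged covariances C_k(tau); C_k(0) = R_k."""

    tau: np.ndarray
    per_edge: np.ndarray
    total: np.ndarray


def default_omega_grid(n_points: int = 400) -> np.ndarray:
    """Log-spaced angular-frequency grid over [1e-3, 1e3]."""
    return np.logspace(-3, 3, n_points)


def _mode_amplitudes(model: MarkovNetworkModel, decomposition=None):
    """Eigenvalues, per-walker fluxes and y_ik = (M^T v_i)(w_i^T zeta_k)."""
    summary = stationary_summary(model)
    if not summary.detailed_balance:
        raise NonReversibleError("spectral formulas require detailed balance")
    if decomposition is None:
        decomposition = spectral_decomposition(laplacian(model), summary.pi)
    lam = decomposition.eigenvalues[1:]
    V = decomposition.right_vectors[:, 1:]
    W = decomposition.left_vectors[:, 1:]
    Z = model.stoichiometry_matrix()
    a = V.T @ model.measurement
    Y = a[:, None] * (W.T @ Z)  # (n-1, m)
    return lam, summary.per_walker_flux, Y, decomposition


def _psd_values(lam, flux, Y, omega) -> Tuple[np.ndarray, float]:
    """S_k on a grid via the complex mode sum; returns (values, imag residual)."""
    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    # z_k(omega) = sum_i y_ik / (lambda_i + i omega); S_k = (j_k/2pi) z z*
    denom = lam[:, None] + 1j * omega[None, :]          # (n-1, W)
    zz = np.einsum("ik,iw->kw", Y.astype(complex), 1.0 / denom)
    S = (flux[:, None] / (2.0 * np.pi)) * (zz * np.conj(zz))
    imag_resid = float(np.max(np.abs(S.imag)) / max(np.max(np.abs(S.real)), 1e-300))
    return S.real, imag_resid


def psd(
    model: MarkovNetworkModel,
    omega_grid: np.ndarray | None = None,
    subsets: Dict[str, Sequence[int]] | None = None,
) -> SpectralDensityTable:
    """Analytic two-sided per-edge power spectral density.

    Parameters
    ----------
    omega_grid : array, optional
        Positive angular frequencies; defaults to 400 log-spaced points over
        [1e-3, 1e3].
    subsets : dict, optional
        label -> 1-based edge indices whose S_k to sum into ``subset_sums``.
    """
    if omega_grid is None:
        omega_grid = default_omega_grid()
    omega_grid = np.asarray(omega_grid, dtype=float)
    if np.any(omega_grid <= 0):
        raise ValueError("omega grid must be strictly positive")
    lam, flux, Y, _ = _mode_amplitudes(model)
    S, imag_resid = _psd_values(lam, flux, Y, omega_grid)
    total = S.sum(axis=0)
    subset_sums = {}
    if subsets:
        for label, idx in subsets.items():
            idx0 = np.asarray(idx, dtype=int) - 1
            subset_sums[label] = S[idx0, :].sum(axis=0)
    return SpectralDensityTable(
        omega=omega_grid,
        per_edge=S,
        total=total,
        subset_sums=subset_sums,
        imaginary_residual=imag_resid,
    )


def psd_integral_check(
    model: MarkovNetworkModel,
    decomposition: SpectralDecomposition | None = None,
) -> np.ndarray:
    """Per-edge values of ``2 * integral_0^inf S_k(omega) d omega``.

    Adaptive quadrature on the closed-form S_k (not a stored grid); equals
    R_k by the Wiener-Khinchin theorem.
    """
    lam, flux, Y, _ = _mode_amplitudes(model, decomposition)
    out = np.empty(len(flux))
    scale = np.abs(lam).max()
    for k in range(len(flux)):
        yk = Y[:, k]
        jk = flux[k]

        def integrand(w, yk=yk, jk=jk):
            z = np.sum(yk / (lam + 1j * w))
            return (jk / (2.0 * np.pi)) * (z * np.conj(z)).real

        val, err = integrate.quad(
            integrand, 0.0, np.inf, limit=200, points=None,
        )
        if not np.isfinite(val) or err > 1e-8 * max(abs(val), scale):
            raise RuntimeError(
                f"quadrature for edge {k + 1} did not converge: value={val}, err={err}"
            )
        out[k] = 2.0 * val
    return out


def lagged_covariance(
    model: MarkovNetworkModel,
    tau_grid: np.ndarray,
) -> LaggedCovarianceTable:
    """M-projected per-edge stationary lagged covariance C_k(tau), tau >= 0."""
    tau_grid = np.atleast_1d(np.asarray(tau_grid, dtype=float))
    if np.any(tau_grid < 0):
        raise ValueError("tau must be nonnegative (use C(-tau) = C(tau))")
    lam, flux, Y, _ = _mode_amplitudes(model)
    K = -1.0 / (lam[:, None] + lam[None, :])              # (n-1, n-1)
    E = np.exp(lam[:, None] * tau_grid[None, :])          # (n-1, T)
    # C_k(tau) = j_k sum_{i,j} e^{lambda_i tau} K_ij y_ik y_jk
    per_edge = flux[:, None] * np.einsum("ik,ij,it,jk->kt", Y, K, E, Y)
    return LaggedCovarianceTable(
        tau=tau_grid,
        per_edge=per_edge,
        total=per_edge.sum(axis=0),
    )


def crossing_frequency(
    model: MarkovNetworkModel,
    subset_a: Sequence[int],
    subset_b: Sequence[int],
    bracket: Tuple[float, float] = (1e-2, 1e2),
    rtol: float = 1e-6,
):
    """Angular frequency where the PSD sums of two edge subsets cross.

    Scans the bracket on a log grid for sign changes of
    ``S_A(omega) - S_B(omega)`` and bisects the first one; returns ``None``
    when there is no sign change, and warns (returning the smallest crossing)
    when there are several.
    """
    A = set(int(k) for k in subset_a)
    B = set(int(k) for k in subset_b)
    if not A or not B:
        raise ValueError("both edge subsets must be nonempty")
    if A & B:
        raise ValueError(f"edge subsets must be disjoint; common edges {sorted(A & B)}")
    m = model.n_edges
    for k in A | B:
        if not (1 <= k <= m):
            raise ValueError(f"edge index {k} outside 1..{m}")

    lam, flux, Y, _ = _mode_amplitudes(model)
    ia = np.array(sorted(A)) - 1
    ib = np.array(sorted(B)) - 1

    def diff(w):
        S, _ = _psd_values(lam, flux, Y, w)
        return float(S[ia, 0].sum() - S[ib, 0].sum())

    lo, hi = bracket
    if not (0 < lo < hi):
        raise ValueError("bracket must be a positive increasing interval")
    grid = np.logspace(np.log10(lo), np.log10(hi), 200)
    vals = np.array([diff(w) for w in grid])
    signs = np.sign(vals)
    idx = np.nonzero(np.diff(signs) != 0)[0]
    if idx.size == 0:
        return None
    if idx.size > 1:
        warnings.warn(
            f"{idx.size} PSD sign changes in bracket {bracket}; returning the smallest",
            RuntimeWarning,
        )
    a, b = grid[idx[0]], grid[idx[0] + 1]
    fa = vals[idx[0]]
    while (b - a) / b > rtol:
        mid = np.sqrt(a * b)
        fm = diff(mid)
        if fa * fm <= 0:
            b = mid
        else:
            a, fa = mid, fm
    return float(np.sqrt(a * b))
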