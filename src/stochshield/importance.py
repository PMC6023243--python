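"""Per-edge decomposition of the stationary observable variance.

For a reversible first-order network the stationary variance of the observable
``M^T N`` splits exactly into a sum of contributions ``R_k``, one per directed
edge — the *edge importance*.  ``R_k`` is computed from the biorthonormal
spectral decomposition of the graph Laplacian:

    R_k = j_k * sum_{i,j >= 2} (-1 / (lambda_i + lambda_j))
              * (M^T v_i)(w_i^T zeta_k)(zeta_k^T w_j)(v_j^T M)

normalized to a single random walker.  Equivalently ``R_k = M^T C_k M`` where
``C_k`` solves the Lyapunov equation ``L C_k + C_k L^T = -B_k B_k^T``.

For the 3-state chain 1 <-> 2 <-> 3 with state 3 observable, the fraction of
the variance generated by the hidden edges (pair 1 <-> 2) has the closed form

    eta = (a21 / (a12 + a21)) * (a23 / (a12 + a21 + a23 + a32)) = F1 * F2,

with inversion (eta > 1/2) requiring a fast opening rate a23 and a slow return
rate a12.  This module provides the spectral formula, Lyapunov solvers, the
closed form with its reversal diagnostics and upper bounds, the canonical
rescaling that forces inversion, and the inversion threshold on the
one-parameter beta slice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from .network import (
    MarkovNetworkModel,
    NonReversibleError,
    SpectralDecomposition,
    laplacian,
    noise_matrix,
    spectral_decomposition,
    stationary_summary,
)

__all__ = [
    "EdgeImportance",
    "CovarianceDecomposition",
    "ThreeStateRates",
    "ReversalDiagnostics",
    "edge_importance",
    "lyapunov_solve",
    "covariance_decomposition",
    "observable_variance",
    "eta_closed_form",
    "eta_bounds",
    "canonical_transform",
    "beta_inversion_threshold",
    "BETA_SLICE_THRESHOLD",
]

#: Analytic inversion threshold on the slice (1/beta, 1, beta, 1):
#: eta = (beta/(1+beta))^3 = 1/2  =>  beta = 2^(-1/3) / (1 - 2^(-1/3)).
BETA_SLICE_THRESHOLD = 2 ** (-1 / 3) / (1 - 2 ** (-1 / 3))


@dataclass(frozen=True)
class EdgeImportance:
    """Per-directed-edge contributions to the stationary observable variance.

    ``per_edge[k-1]`` is ``R_k`` in per-walker units; ``relative`` is
    ``R_k / sum R``; ``pair_relative`` aggregates the two directed edges of
    each unordered state pair.
    """

    per_edge: np.ndarray
    total: float
    relative: np.ndarray
    pair_relative: Dict[Tuple[int, int], float]
    pair_edges: Dict[Tuple[int, int], Tuple[int, ...]]

    def pair_share(self, i: int, j: int) -> float:
        """Relative importance of the unordered state pair {i, j}."""
        return self.pair_relative[tuple(sorted((i, j)))]


@dataclass(frozen=True)
class CovarianceDecomposition:
    """Stationary covariance C and its unique per-edge split C = sum_k C_k."""

    C: np.ndarray
    C_k: tuple
    lyapunov_residual: float


@dataclass(frozen=True)
class ThreeStateRates:
    """Rates of the 3-state chain 1 <-> 2 <-> 3.

    ``a12, a21`` are the hidden-edge rates, ``a23, a32`` the rates into and
    out of the terminal state; ``observable_state`` is 3 (end observable,
    shielded) or 2 (middle observable, unshielded).
    """

    a12: float
    a21: float
    a23: float
    a32: float
    observable_state: int = 3

    def __post_init__(self) -> None:
        for name in ("a12", "a21", "a23", "a32"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v!r}")
        if self.observable_state not in (2, 3):
            raise ValueError("observable_state must be 2 or 3")

    def as_tuple(self) -> Tuple[float, float, float, float]:
        return (self.a12, self.a21, self.a23, self.a32)


@dataclass(frozen=True)
class ReversalDiagnostics:
    """Closed-form hidden-edge fraction eta with the quantities governing it.

    eta = F1 * F2; ``nu = lambda_3/lambda_2`` is the global timescale
    separation, ``tau12, tau23`` the isolated two-state relaxation times
    ``1/(a_ij + a_ji)``, ``deltaJ`` the relative hidden-edge flux excess, and
    ``bounds`` the four upper bounds on eta (occupancy, rate-ratio,
    relaxation-time, and flux bounds).  ``inverted`` flags eta > 1/2.
    """

    eta: float
    F1: float
    F2: float
    nu: float
    tau12: float
    tau23: float
    deltaJ: float
    pi: np.ndarray
    bounds: Tuple[float, float, float, float]
    inverted: bool


def edge_importance(
    model: MarkovNetworkModel,
    decomposition: SpectralDecomposition | None = None,
) -> EdgeImportance:
    """Per-edge contributions R_k to the stationary observable variance.

    Requires detailed balance (the spectral formula needs a real,
    biorthogonally diagonalizable Laplacian).  ``R_k`` is per-walker; multiply
    by ``model.n_walkers`` for the population process.
    """
    summary = stationary_summary(model)
    if not summary.detailed_balance:
        raise NonReversibleError(
            "edge importance requires detailed balance; reversibility residual "
            f"= {summary.db_residual:.3g}"
        )
    L = laplacian(model)
    if decomposition is None:
        decomposition = spectral_decomposition(L, summary.pi)

    lam = decomposition.eigenvalues[1:]
    # lambda_i + lambda_j < 0 for all nontrivial pairs: no zero denominators.
    assert np.all(lam < 0), "nontrivial eigenvalues must be strictly negative"
    V = decomposition.right_vectors[:, 1:]
    W = decomposition.left_vectors[:, 1:]
    M = model.measurement
    Z = model.stoichiometry_matrix()

    a = V.T @ M                      # (n-1,)  M^T v_i
    G = W.T @ Z                      # (n-1, m)  w_i^T zeta_k
    K = -1.0 / (lam[:, None] + lam[None, :])
    Y = a[:, None] * G               # y_ik = (M^T v_i)(w_i^T zeta_k)
    per_edge = summary.per_walker_flux * np.einsum("ik,ij,jk->k", Y, K, Y)
    per_edge = np.clip(per_edge, 0.0, None)

    total = float(per_edge.sum())
    relative = per_edge / total
    pair_relative: Dict[Tuple[int, int], float] = {}
    pair_edges: Dict[Tuple[int, int], list] = {}
    for e in model.edges:
        key = tuple(sorted((e.source, e.target)))
        pair_relative[key] = pair_relative.get(key, 0.0) + relative[e.index - 1]
        pair_edges.setdefault(key, []).append(e.index)
    return EdgeImportance(
        per_edge=per_edge,
        total=total,
        relative=relative,
        pair_relative=pair_relative,
        pair_edges={k: tuple(v) for k, v in pair_edges.items()},
    )


def lyapunov_solve(
    L: np.ndarray,
    F: np.ndarray,
    decomposition: SpectralDecomposition,
) -> np.ndarray:
    """Unique zero-row-sum symmetric solution C of ``L C + C L^T = -F``.

    ``F`` must be symmetric with zero row and column sums (as ``B B^T`` is);
    on that subspace the solution is the spectral sum
    ``C = sum_{i,j>=2} (-1/(lambda_i+lambda_j)) v_i (w_i^T F w_j) v_j^T``.
    """
    F = np.asarray(F, dtype=float)
    n = F.shape[0]
    scale = max(np.max(np.abs(F)), 1e-300)
    if np.max(np.abs(F - F.T)) > 1e-10 * scale:
        raise ValueError("F must be symmetric")
    if np.max(np.abs(F.sum(axis=0))) > 1e-10 * scale:
        raise ValueError("F must have zero column sums")

    lam = decomposition.eigenvalues[1:]
    V = decomposition.right_vectors[:, 1:]
    W = decomposition.left_vectors[:, 1:]
    H = W.T @ F @ W
    K = -1.0 / (lam[:, None] + lam[None, :])
    C = V @ (K * H) @ V.T
    return (C + C.T) / 2.0


def covariance_decomposition(model: MarkovNetworkModel) -> CovarianceDecomposition:
    """Stationary covariance C and its unique per-edge pieces C_k (per-walker).

    ``C_k`` solves ``L C_k + C_k L^T = -B_k B_k^T``; their sum solves the
    full Lyapunov equation, and ``M^T C_k M = R_k``.
    """
    summary = stationary_summary(model)
    if not summary.detailed_balance:
        raise NonReversibleError("covariance decomposition requires detailed balance")
    L = laplacian(model)
    dec = spectral_decomposition(L, summary.pi)
    B, B_k = noise_matrix(model, summary, per_walker=True)
    C_k = tuple(lyapunov_solve(L, Bk @ Bk.T, dec) for Bk in B_k)
    C = np.sum(C_k, axis=0)
    resid = np.max(np.abs(L @ C + C @ L.T + B @ B.T))
    return CovarianceDecomposition(C=C, C_k=C_k, lyapunov_residual=float(resid))


def observable_variance(pi: np.ndarray, M: np.ndarray, n_walkers: int = 1) -> float:
    """Stationary variance of M^T N for a multinomial(N_tot, pi) snapshot.

    Equals ``N_tot * (sum_i M_i^2 pi_i - (M^T pi)^2) = M^T C M``.
    """
    pi = np.asarray(pi, dtype=float)
    M = np.asarray(M, dtype=float)
    mean = M @ pi
    return float(n_walkers * ((M**2) @ pi - mean**2))


def _three_state_pi(r: ThreeStateRates) -> np.ndarray:
    z = r.a12 * r.a23 + r.a12 * r.a32 + r.a21 * r.a32
    return np.array([r.a21 * r.a32, r.a12 * r.a32, r.a12 * r.a23]) / z


def eta_closed_form(rates: ThreeStateRates) -> ReversalDiagnostics:
    """Closed-form hidden-edge variance fraction eta with diagnostics.

    Only the end-observable chain (observable_state=3) admits this form.
    """
    if rates.observable_state != 3:
        raise ValueError("the closed form for eta applies to observable_state=3")
    a12, a21, a23, a32 = rates.as_tuple()
    F1 = a21 / (a12 + a21)
    trace = a12 + a21 + a23 + a32
    F2 = a23 / trace
    eta = F1 * F2

    # Nontrivial eigenvalues: roots of lambda^2 + (sum alpha) lambda + Z = 0.
    z = a12 * a23 + a12 * a32 + a21 * a32
    disc = math.sqrt(max(trace**2 - 4.0 * z, 0.0))
    lam2 = (-trace + disc) / 2.0
    lam3 = (-trace - disc) / 2.0
    nu = lam3 / lam2

    tau12 = 1.0 / (a12 + a21)
    tau23 = 1.0 / (a23 + a32)
    deltaJ = (a21 - a23) / (a21 + a23)
    pi = _three_state_pi(rates)
    bounds = eta_bounds(rates)
    return ReversalDiagnostics(
        eta=eta,
        F1=F1,
        F2=F2,
        nu=nu,
        tau12=tau12,
        tau23=tau23,
        deltaJ=deltaJ,
        pi=pi,
        bounds=bounds,
        inverted=eta > 0.5,
    )


def eta_bounds(rates: ThreeStateRates) -> Tuple[float, float, float, float]:
    """The four upper bounds on eta, in order: occupancy bound
    ((1-pi2)/(1+pi2))^2, rate bound a23/(a23+a32), relaxation-time bound
    tau12/(tau12+tau23), and flux bound 1/2 - deltaJ/2."""
    a12, a21, a23, a32 = rates.as_tuple()
    pi2 = _three_state_pi(rates)[1]
    occupancy = ((1.0 - pi2) / (1.0 + pi2)) ** 2
    rate = a23 / (a23 + a32)
    tau12 = 1.0 / (a12 + a21)
    tau23 = 1.0 / (a23 + a32)
    relaxation = tau12 / (tau12 + tau23)
    deltaJ = (a21 - a23) / (a21 + a23)
    flux = 0.5 - deltaJ / 2.0
    return (occupancy, rate, relaxation, flux)


def canonical_transform(rates: ThreeStateRates, eps: float) -> ThreeStateRates:
    """Rescale a12 -> eps*a12 (slow the exit from the hidden state) and
    a23 -> a23/eps (speed the opening); eta -> 1 as eps -> 0."""
    if not (np.isfinite(eps) and eps > 0):
        raise ValueError(f"eps must be positive, got {eps!r}")
    return ThreeStateRates(
        a12=eps * rates.a12,
        a21=rates.a21,
        a23=rates.a23 / eps,
        a32=rates.a32,
        observable_state=rates.observable_state,
    )


def _eta_beta(beta: float) -> float:
    """eta on the slice alpha = (1/beta, 1, beta, 1): (beta/(1+beta))^3."""
    return (beta / (1.0 + beta)) ** 3


def beta_inversion_threshold(
    resolution: float = 1e-9,
    bracket: Tuple[float, float] = (1.0, 100.0),
) -> float:
    """beta at which eta crosses 1/2 on the slice (1/beta, 1, beta, 1).

    eta(beta) is strictly increasing on this slice, so plain bisection on
    eta(beta) - 1/2 converges; ``resolution`` is the absolute tolerance on
    beta.
    """
    if not resolution > 0:
        raise ValueError("resolution must be positive")
    lo, hi = bracket
    flo = _eta_beta(lo) - 0.5
    fhi = _eta_beta(hi) - 0.5
    if flo * fhi > 0:
        raise ValueError(f"no sign change of eta - 1/2 in bracket {bracket}")
    while hi - lo > resolution:
        mid = (lo + hi) / 2.0
        if (_eta_beta(mid) - 0.5) * flo <= 0:
            hi = mid
        else:
            lo = mid
    return (lo + hi) / 2.0
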