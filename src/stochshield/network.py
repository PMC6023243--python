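"""Core representation of first-order Markov transition networks.

A population of ``n_walkers`` independent random walkers moves among ``n``
states along ``m`` directed edges with positive per-capita rates.  This module
builds and validates the network, assembles its graph Laplacian ``L`` (the
transpose of the generator: columns index source states and sum to zero),
computes the stationary distribution and per-edge fluxes, the per-edge noise
matrices used by the Langevin description, and the biorthonormal spectral
decomposition of ``L`` on which all downstream variance and power-spectrum
formulas rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "EdgeSpec",
    "MarkovNetworkModel",
    "SpectralDecomposition",
    "StationarySummary",
    "ModelValidationError",
    "NonReversibleError",
    "build_model",
    "laplacian",
    "spectral_decomposition",
    "stationary_summary",
    "noise_matrix",
]

#: |lambda| below this fraction of max|lambda_i| is treated as the zero mode.
ZERO_EIGENVALUE_RTOL = 1e-10

#: Relative tolerance for the detailed-balance (reversibility) check.
DETAILED_BALANCE_RTOL = 1e-8


class ModelValidationError(ValueError):
    """Raised when a network definition violates a structural invariant."""


class NonReversibleError(ValueError):
    """Raised when an operation requiring detailed balance meets a
    non-reversible network (or a complex Laplacian spectrum)."""


@dataclass(frozen=True)
class EdgeSpec:
    """One directed edge ``source -> target`` with per-capita rate ``alpha``.

    Indices are 1-based, matching model files and reports; internal arrays
    are 0-based.
    """

    index: int
    source: int
    target: int
    rate: float

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ModelValidationError(
                f"edge {self.index}: self-loop {self.source}->{self.target} not allowed"
            )
        if not np.isfinite(self.rate) or self.rate <= 0.0:
            raise ModelValidationError(
                f"edge {self.index} ({self.source}->{self.target}): "
                f"rate must be positive and finite, got {self.rate!r}"
            )


@dataclass(frozen=True)
class MarkovNetworkModel:
    """A validated first-order transition network.

    Attributes
    ----------
    n_states : int
        Number of states ``n``.
    state_labels : tuple of str
        Human-readable state names, in state order.
    edges : tuple of EdgeSpec
        The ``m`` directed edges, in file/definition order.
    measurement : ndarray, shape (n,)
        Observable weights ``M`` (e.g. 1 for conducting states, 0 otherwise).
    n_walkers : int
        Total population ``N_tot``.
    """

    n_states: int
    state_labels: tuple
    edges: tuple
    measurement: np.ndarray = field(repr=False)
    n_walkers: int = 1

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def stoichiometry(self, k: int) -> np.ndarray:
        """Stoichiometry vector zeta_k = e_target - e_source for 1-based edge k."""
        e = self.edges[k - 1]
        z = np.zeros(self.n_states)
        z[e.source - 1] = -1.0
        z[e.target - 1] = +1.0
        return z

    def stoichiometry_matrix(self) -> np.ndarray:
        """n x m matrix whose k-th column is zeta_k."""
        Z = np.zeros((self.n_states, self.n_edges))
        for e in self.edges:
            Z[e.source - 1, e.index - 1] = -1.0
            Z[e.target - 1, e.index - 1] = +1.0
        return Z

    def rates(self) -> np.ndarray:
        """Per-capita rates alpha_k in edge order, shape (m,)."""
        return np.array([e.rate for e in self.edges])

    def reciprocal_edge(self, k: int):
        """1-based index of the edge target->source reciprocal to edge k, or None."""
        e = self.edges[k - 1]
        for other in self.edges:
            if other.source == e.target and other.target == e.source:
                return other.index
        return None


@dataclass(frozen=True)
class SpectralDecomposition:
    """Biorthonormal eigentriples of the graph Laplacian.

    Eigenvalues are sorted descending, ``lambda_1 = 0 > lambda_2 >= ... >=
    lambda_n``.  Column ``i`` of ``right_vectors`` is ``v_i`` and of
    ``left_vectors`` is ``w_i`` with ``w_i^T v_j = delta_ij``; ``v_1`` is the
    stationary distribution and ``w_1`` the all-ones vector.
    """

    eigenvalues: np.ndarray
    right_vectors: np.ndarray
    left_vectors: np.ndarray
    biorthogonality_residual: float
    imaginary_residual: float

    @property
    def n(self) -> int:
        return self.eigenvalues.size


@dataclass(frozen=True)
class StationarySummary:
    """Stationary distribution, per-edge fluxes and the reversibility verdict."""

    pi: np.ndarray
    per_walker_flux: np.ndarray
    population_flux: np.ndarray
    detailed_balance: bool
    db_residual: float


def build_model(
    states: Sequence,
    edges: Sequence,
    measurement: Sequence[float],
    n_walkers: int = 1,
) -> MarkovNetworkModel:
    """Validate and assemble a :class:`MarkovNetworkModel`.

    Parameters
    ----------
    states : sequence
        Either state labels (strings) or ``(id, label)`` records with ids
        contiguous ``1..n`` in order.
    edges : sequence
        ``EdgeSpec`` instances or ``(source, target, rate)`` triples; edge
        index is the 1-based position in this sequence.
    measurement : sequence of float
        Observable weight per state, length ``n``.
    n_walkers : int
        Population size ``N_tot``.

    Raises
    ------
    ModelValidationError
        For duplicate directed edges, dangling state references, nonpositive
        rates, or a graph that is not strongly connected.
    """
    labels = []
    for idx, s in enumerate(states, start=1):
        if isinstance(s, str):
            labels.append(s)
        else:
            sid, lab = s
            if sid != idx:
                raise ModelValidationError(
                    f"state ids must be contiguous 1..n in order; got id {sid} at position {idx}"
                )
            labels.append(str(lab))
    n = len(labels)
    if n < 2:
        raise ModelValidationError("a network needs at least 2 states")

    edge_specs = []
    for k, e in enumerate(edges, start=1):
        if isinstance(e, EdgeSpec):
            if e.index != k:
                e = EdgeSpec(k, e.source, e.target, e.rate)
        else:
            src, tgt, rate = e
            e = EdgeSpec(k, int(src), int(tgt), float(rate))
        if not (1 <= e.source <= n) or not (1 <= e.target <= n):
            raise ModelValidationError(
                f"edge {k}: references state outside 1..{n}: {e.source}->{e.target}"
            )
        edge_specs.append(e)
    if len(edge_specs) < 2:
        raise ModelValidationError("a network needs at least 2 edges")

    seen = {}
    for e in edge_specs:
        key = (e.source, e.target)
        if key in seen:
            raise ModelValidationError(
                f"duplicate directed edge {e.source}->{e.target} "
                f"(edges {seen[key]} and {e.index})"
            )
        seen[key] = e.index

    M = np.asarray(measurement, dtype=float)
    if M.shape != (n,):
        raise ModelValidationError(
            f"measurement must have length {n}, got shape {M.shape}"
        )
    if not np.all(np.isfinite(M)):
        raise ModelValidationError("measurement entries must be finite")

    if not (isinstance(n_walkers, (int, np.integer)) and n_walkers >= 1):
        raise ModelValidationError(f"n_walkers must be a positive integer, got {n_walkers!r}")

    # Strong connectivity (irreducibility) via Tarjan on the directed graph.
    rows = [e.source - 1 for e in edge_specs]
    cols = [e.target - 1 for e in edge_specs]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, comp = connected_components(adj, directed=True, connection="strong")
    if n_comp != 1:
        main = np.bincount(comp).argmax()
        stranded = [i + 1 for i in range(n) if comp[i] != main]
        raise ModelValidationError(
            f"graph is not strongly connected; states {stranded} are not "
            "mutually reachable with the rest"
        )

    return MarkovNetworkModel(
        n_states=n,
        state_labels=tuple(labels),
        edges=tuple(edge_specs),
        measurement=M,
        n_walkers=int(n_walkers),
    )


def laplacian(model: MarkovNetworkModel) -> np.ndarray:
    """Graph Laplacian ``L = (A - D)^T``, the transpose of the generator.

    ``L[j-1, i-1]`` holds the rate of edge ``i -> j``; diagonal entries are
    minus the total out-rate of the column's state, so every column sums to 0.
    """
    n = model.n_states
    L = np.zeros((n, n))
    for e in model.edges:
        L[e.target - 1, e.source - 1] += e.rate
        L[e.source - 1, e.source - 1] -= e.rate
    return L


def stationary_summary(model: MarkovNetworkModel) -> StationarySummary:
    """Stationary distribution pi, per-edge fluxes, and detailed balance.

    ``pi`` is the normalized null right eigenvector of ``L``.  The per-walker
    flux on edge k is ``j_k = alpha_k * pi_source``, the population flux
    ``J_k = N_tot * j_k``.  Detailed balance requires every edge to have a
    reciprocal partner with ``pi_i alpha_ij = pi_j alpha_ji`` to relative
    tolerance 1e-8.
    """
    L = laplacian(model)
    ns = linalg.null_space(L, rcond=1e-10)
    if ns.shape[1] != 1:
        raise ModelValidationError(
            f"Laplacian null space has dimension {ns.shape[1]} != 1 (reducible network)"
        )
    v = ns[:, 0]
    if v.sum() < 0:
        v = -v
    pi = np.clip(v, 0.0, None)
    pi = pi / pi.sum()

    rates = model.rates()
    src = np.array([e.source - 1 for e in model.edges])
    j = rates * pi[src]
    J = model.n_walkers * j

    jmax = j.max()
    db = True
    db_residual = 0.0
    for e in model.edges:
        rk = model.reciprocal_edge(e.index)
        if rk is None:
            db = False
            db_residual = np.inf
            break
        resid = abs(j[e.index - 1] - j[rk - 1]) / jmax
        db_residual = max(db_residual, resid)
        if resid > DETAILED_BALANCE_RTOL:
            db = False
    return StationarySummary(
        pi=pi,
        per_walker_flux=j,
        population_flux=J,
        detailed_balance=db,
        db_residual=db_residual,
    )


def spectral_decomposition(L: np.ndarray, pi: np.ndarray) -> SpectralDecomposition:
    """Biorthonormal eigendecomposition of a reversible graph Laplacian.

    Under detailed balance the similarity transform
    ``S = D^{-1/2} L D^{1/2}`` with ``D = diag(pi)`` is symmetric, so the
    spectrum is real and an orthogonal eigenbasis of ``S`` maps to a
    biorthonormal left/right pair for ``L``.  The zero mode is snapped to its
    known form (``v_1 = pi``, ``w_1 = 1``).

    Falls back to a general eigensolver when the symmetrized matrix is not
    symmetric (non-reversible network) and raises :class:`NonReversibleError`
    if the spectrum then has a material imaginary part or the matrix is
    defective.
    """
    L = np.asarray(L, dtype=float)
    pi = np.asarray(pi, dtype=float)
    n = L.shape[0]
    sqrt_pi = np.sqrt(pi)
    S = (L / sqrt_pi[None, :]) * sqrt_pi[:, None]
    sym_resid = np.max(np.abs(S - S.T)) / max(np.max(np.abs(S)), 1e-300)

    if sym_resid < 1e-8:
        lam, U = np.linalg.eigh((S + S.T) / 2.0)
        order = np.argsort(lam)[::-1]
        lam = lam[order]
        U = U[:, order]
        V = U * sqrt_pi[:, None]
        W = U / sqrt_pi[:, None]
        imag_resid = 0.0
    else:
        lam_c, Vc = linalg.eig(L)
        scale = np.max(np.abs(lam_c))
        imag_resid = np.max(np.abs(lam_c.imag)) / max(scale, 1e-300)
        if imag_resid > 1e-10:
            worst = lam_c[np.argmax(np.abs(lam_c.imag))]
            raise NonReversibleError(
                f"complex Laplacian eigenvalue {worst:.6g}: network is not "
                "reversible; the edge-importance formulas do not apply"
            )
        lam = lam_c.real
        order = np.argsort(lam)[::-1]
        lam = lam[order]
        V = Vc[:, order].real
        try:
            W = np.linalg.inv(V).T
        except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate input
            raise NonReversibleError(
                "defective Laplacian: no full biorthogonal eigenbasis exists"
            ) from exc

    scale = np.max(np.abs(lam))
    if np.sum(np.abs(lam) < ZERO_EIGENVALUE_RTOL * scale) != 1:
        raise NonReversibleError(
            "expected exactly one zero eigenvalue within tolerance; "
            f"eigenvalues: {lam}"
        )
    lam = lam.copy()
    lam[0] = 0.0
    # Snap the trivial pair to its analytic form; the remaining columns are
    # untouched so biorthonormality is preserved.
    V = V.copy()
    W = W.copy()
    V[:, 0] = pi
    W[:, 0] = 1.0

    G = W.T @ V
    biorth = float(np.max(np.abs(G - np.eye(n))))
    return SpectralDecomposition(
        eigenvalues=lam,
        right_vectors=V,
        left_vectors=W,
        biorthogonality_residual=biorth,
        imaginary_residual=float(imag_resid),
    )


def noise_matrix(
    model: MarkovNetworkModel,
    summary: StationarySummary,
    per_walker: bool = True,
):
    """Noise coefficient matrix ``B`` and its per-edge pieces ``B_k``.

    Column k of ``B`` is ``sqrt(flux_k) * zeta_k`` with the per-walker flux
    ``j_k`` by default (population flux ``J_k`` when ``per_walker=False``).
    ``B_k`` is ``B`` with every column but k zeroed, so
    ``B B^T = sum_k B_k B_k^T``.
    """
    flux = summary.per_walker_flux if per_walker else summary.population_flux
    Z = model.stoichiometry_matrix()
    B = Z * np.sqrt(flux)[None, :]
    B_k = []
    for k in range(model.n_edges):
        Bk = np.zeros_like(B)
        Bk[:, k] = B[:, k]
        B_k.append(Bk)
    return B, B_k
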