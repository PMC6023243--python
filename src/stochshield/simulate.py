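"""Exact and approximate simulation of the population process.

Two simulators are provided.  ``ssa_simulate`` runs Gillespie's exact
stochastic simulation algorithm on the discrete population ``N(t)``: the
propensity of edge k is ``alpha_k * N_source``, waiting times are exponential
in the total propensity, and the next edge is drawn proportionally to its
propensity.  ``langevin_simulate`` integrates the linear Langevin equation for
the centered fluctuation process ``X ~ N - Nbar``,

    dX = L X dt + B dW,

by Euler-Maruyama, together with any number of stochastically shielded
approximations ``dY = L Y dt + sum_{k in retained} B_k dW_k`` that reuse the
*same* Gaussian increments on the retained edges (common random numbers).  The
pathwise discrepancy U = Y - X then satisfies a linear equation driven only by
the suppressed edges, and its stationary observable mean square equals the sum
of the suppressed edges' importances R_k — the quantity ``discrepancy``
estimates empirically and compares against that analytic value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np
from scipy import signal

from .importance import edge_importance
from .network import (
    MarkovNetworkModel,
    laplacian,
    noise_matrix,
    spectral_decomposition,
    stationary_summary,
)

__all__ = [
    "JumpTrajectory",
    "TrajectorySet",
    "DiscrepancyResult",
    "ssa_simulate",
    "resample_jump_trajectory",
    "langevin_simulate",
    "discrepancy",
    "empirical_psd",
    "FULL_LABEL",
]

FULL_LABEL = "full"


@dataclass(frozen=True)
class JumpTrajectory:
    """Event-driven sample path of the discrete population process.

    ``states_after_event[i]`` is the population vector right after
    ``event_times[i]``; row 0 is the initial condition at time 0 with
    ``edge_indices[0] = 0``.
    """

    event_times: np.ndarray
    states_after_event: np.ndarray
    edge_indices: np.ndarray
    seed: int
    t_max: float


@dataclass(frozen=True)
class TrajectorySet:
    """Time-gridded Langevin paths of the full process and its shielded
    approximations, driven by one shared per-edge noise stream."""

    times: np.ndarray
    paths: Dict[str, np.ndarray]
    retained_sets: Dict[str, tuple]
    seed: int
    dt: float
    model: MarkovNetworkModel = field(repr=False)

    @property
    def full(self) -> np.ndarray:
        return self.paths[FULL_LABEL]


@dataclass(frozen=True)
class DiscrepancyResult:
    """Empirical vs analytic stationary MSE of the shielding error M^T(Y-X)."""

    label: str
    mse: float
    theoretical: float
    ratio: float
    suppressed_edges: tuple


def ssa_simulate(
    model: MarkovNetworkModel,
    initial: Sequence[int],
    t_max: float,
    seed: int,
) -> JumpTrajectory:
    """Gillespie's exact SSA for ``N_tot`` walkers up to time ``t_max``."""
    if not t_max > 0:
        raise ValueError(f"t_max must be positive, got {t_max!r}")
    N = np.asarray(initial, dtype=np.int64).copy()
    if N.shape != (model.n_states,) or np.any(N < 0) or N.sum() != model.n_walkers:
        raise ValueError(
            f"initial population must be nonnegative, length {model.n_states}, "
            f"summing to n_walkers={model.n_walkers}"
        )
    rng = np.random.default_rng(seed)
    rates = model.rates()
    src = np.array([e.source - 1 for e in model.edges])
    tgt = np.array([e.target - 1 for e in model.edges])

    times = [0.0]
    states = [N.copy()]
    edges_taken = [0]
    t = 0.0
    # Draw uniforms in blocks to keep the Python event loop lean.
    block = 8192
    u_wait = np.empty(0)
    u_edge = np.empty(0)
    ptr = block
    while True:
        prop = rates * N[src]
        total = prop.sum()
        # total > 0 always: the graph is strongly connected and N_tot >= 1.
        if ptr >= block:
            u_wait = rng.random(block)
            u_edge = rng.random(block)
            ptr = 0
        t += -np.log(u_wait[ptr]) / total
        if t > t_max:
            break
        k = int(np.searchsorted(np.cumsum(prop), u_edge[ptr] * total))
        ptr += 1
        N[src[k]] -= 1
        N[tgt[k]] += 1
        times.append(t)
        states.append(N.copy())
        edges_taken.append(k + 1)
    return JumpTrajectory(
        event_times=np.array(times),
        states_after_event=np.array(states),
        edge_indices=np.array(edges_taken),
        seed=seed,
        t_max=float(t_max),
    )


def resample_jump_trajectory(traj: JumpTrajectory, grid: np.ndarray) -> np.ndarray:
    """Sample a jump path on a time grid with the right-continuous step
    convention: the state at grid time t is the state after the last event
    at or before t."""
    grid = np.asarray(grid, dtype=float)
    idx = np.searchsorted(traj.event_times, grid, side="right") - 1
    idx = np.clip(idx, 0, len(traj.event_times) - 1)
    return traj.states_after_event[idx]


def default_dt(model: MarkovNetworkModel) -> float:
    """min(0.01, 0.1/|lambda_n|): resolves the fastest relaxation mode."""
    summary = stationary_summary(model)
    dec = spectral_decomposition(laplacian(model), summary.pi)
    return min(0.01, 0.1 / abs(dec.eigenvalues[-1]))


def langevin_simulate(
    model: MarkovNetworkModel,
    t_max: float,
    dt: float | None = None,
    seed: int = 0,
    retained_sets: Dict[str, Sequence[int]] | None = None,
) -> TrajectorySet:
    """Euler-Maruyama paths of the centered fluctuation process.

    The full process (all edges retained) is always simulated under the label
    ``"full"``.  Each entry of ``retained_sets`` maps a label to the 1-based
    edges whose noise is kept; the same Gaussian increment stream (one per
    edge per step, derived from ``seed``) drives every path, so approximations
    differ from the full path only through the omitted noise terms.  All paths
    start at 0.  Noise amplitudes use per-walker fluxes; rescale by
    sqrt(N_tot) to compare with a population of N_tot walkers.
    """
    summary = stationary_summary(model)
    L = laplacian(model)
    dec = spectral_decomposition(L, summary.pi)
    if dt is None:
        dt = min(0.01, 0.1 / abs(dec.eigenvalues[-1]))
    if not dt > 0:
        raise ValueError("dt must be positive")
    if dt > 0.1 / abs(dec.eigenvalues[-1]):
        warnings.warn(
            f"dt={dt} exceeds 0.1/|lambda_n|={0.1 / abs(dec.eigenvalues[-1]):.3g}; "
            "Euler-Maruyama may be inaccurate or unstable",
            RuntimeWarning,
        )
    retained_sets = dict(retained_sets or {})
    m = model.n_edges
    masks: Dict[str, np.ndarray] = {FULL_LABEL: np.ones(m, dtype=bool)}
    stored: Dict[str, tuple] = {FULL_LABEL: tuple(range(1, m + 1))}
    for label, kept in retained_sets.items():
        kept = tuple(sorted(int(k) for k in kept))
        if any(not (1 <= k <= m) for k in kept):
            raise ValueError(f"retained set {label!r} references edges outside 1..{m}")
        mask = np.zeros(m, dtype=bool)
        for k in kept:
            mask[k - 1] = True
        masks[label] = mask
        stored[label] = kept

    B, _ = noise_matrix(model, summary, per_walker=True)
    n_steps = int(np.round(t_max / dt))
    times = np.arange(n_steps + 1) * dt
    n = model.n_states
    labels = list(masks)
    X = {lab: np.zeros((n_steps + 1, n)) for lab in labels}
    cur = {lab: np.zeros(n) for lab in labels}
    A = np.eye(n) + dt * L
    sdt = np.sqrt(dt)
    Bm = {lab: B * masks[lab][None, :] for lab in labels}

    rng = np.random.default_rng(seed)
    chunk = 4096
    step = 0
    while step < n_steps:
        nloc = min(chunk, n_steps - step)
        xi = rng.standard_normal((nloc, m))
        for i in range(nloc):
            for lab in labels:
                cur[lab] = A @ cur[lab] + sdt * (Bm[lab] @ xi[i])
                X[lab][step + i + 1] = cur[lab]
        step += nloc
    return TrajectorySet(
        times=times,
        paths=X,
        retained_sets=stored,
        seed=seed,
        dt=float(dt),
        model=model,
    )


def discrepancy(
    trajectories: TrajectorySet,
    label: str,
    burn_in: float | None = None,
) -> DiscrepancyResult:
    """Stationary mean-square shielding error of one approximation.

    Compares the empirical MSE of ``M^T (Y - X)`` over the post-burn-in
    window to the analytic value: the summed importance R_k of the suppressed
    edges.
    """
    if label not in trajectories.paths:
        raise KeyError(f"unknown trajectory label {label!r}")
    model = trajectories.model
    if burn_in is None:
        summary = stationary_summary(model)
        dec = spectral_decomposition(laplacian(model), summary.pi)
        burn_in = 10.0 / abs(dec.eigenvalues[1])
    keep = trajectories.times >= burn_in
    if keep.sum() < 2:
        raise ValueError(
            f"burn_in={burn_in} leaves fewer than 2 samples of t_max="
            f"{trajectories.times[-1]}"
        )
    M = model.measurement
    U = trajectories.paths[label] - trajectories.full
    mse = float(np.mean((U[keep] @ M) ** 2))

    kept = set(trajectories.retained_sets[label])
    suppressed = tuple(k for k in range(1, model.n_edges + 1) if k not in kept)
    imp = edge_importance(model)
    theo = float(sum(imp.per_edge[k - 1] for k in suppressed))
    ratio = mse / theo if theo > 0 else (0.0 if mse == 0 else np.inf)
    return DiscrepancyResult(
        label=label,
        mse=mse,
        theoretical=theo,
        ratio=ratio,
        suppressed_edges=suppressed,
    )


def empirical_psd(
    trajectories: TrajectorySet,
    label: str,
    burn_in: float = 0.0,
    nperseg: int = 1024,
):
    """Welch periodogram of the observed path in the two-sided angular
    convention (so that summing S(omega) d omega over the real line recovers
    the sample variance).

    Returns ``(omega, S)`` with omega > 0.
    """
    if label not in trajectories.paths:
        raise KeyError(f"unknown trajectory label {label!r}")
    keep = trajectories.times >= burn_in
    y = trajectories.paths[label][keep] @ trajectories.model.measurement
    if y.size < 2**14:
        raise ValueError(
            f"need at least 2^14 samples after burn-in, got {y.size}"
        )
    fs = 1.0 / trajectories.dt
    f, Pxx = signal.welch(y, fs=fs, nperseg=nperseg, detrend="constant")
    # One-sided density in Hz -> two-sided density in angular frequency:
    # var = int_0^inf P df = int_{-inf}^{inf} S domega with omega = 2 pi f,
    # hence S(omega) = P(omega / 2 pi) / (4 pi).
    omega = 2.0 * np.pi * f[1:]
    S = Pxx[1:] / (4.0 * np.pi)
    return omega, S
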