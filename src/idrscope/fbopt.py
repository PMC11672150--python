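"""Force-balance optimization of stickiness parameters against FRET data.

The per-type stickiness values lambda of the coarse-grained model (residue
beads and dye beads in one vector) are iterated to minimize

    loss(lambda) = sum_c (<E>_c(lambda) - E_c^exp)^2
                   + alpha * sum_k (lambda_k - lambda0_k)^2,

an L2 starting-point regularization keeping the solution close to the
initial parameter set.  The gradient of a simulated average with respect to
lambda_k is estimated by linear response on the stored equilibrium frames:

    d<E>/dlambda_k = -beta * ( <E u_k> - <E><u_k> ),

where u_k(frame) = sum over nonbonded pairs involving bead type k of
dU_pair/dlambda_k (dU/dlambda_ij = -eps inside the WCA minimum, Phi_LJ(r)
outside, times dlambda_ij/dlambda_k = 1/2 per participating bead).  Updates
are plain gradient descent with learning rate eta (default 5.0, halved on a
sustained loss increase), re-simulating after each step.  Frozen entries
(e.g. residue lambdas while optimizing dye beads only) receive zero updates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .cgsim import (
    KB,
    CGTopology,
    HPSParameterSet,
    Trajectory,
    build_topology,
    fret_from_trajectory,
    run_langevin,
)

try:
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        if args and callable(args[0]):
            return args[0]
        return wrap

__all__ = [
    "ConstructTarget",
    "OptimizationState",
    "lambda_vector",
    "apply_lambda_vector",
    "per_frame_dU_dlambda",
    "estimate_gradient",
    "iterate",
    "optimize_lambdas",
    "grid_search_dye_lambda",
]


@dataclass
class ConstructTarget:
    """One labeled construct with its measured mean efficiency."""

    construct: "object"              # cgsim.FRETConstruct
    E_target: float
    E_error: float = 0.01
    topology: CGTopology | None = None


def lambda_vector(params: HPSParameterSet,
                  type_order: list[str]) -> np.ndarray:
    return np.array([params.lam[t] for t in type_order], dtype=float)


def apply_lambda_vector(params: HPSParameterSet, type_order: list[str],
                        lam: np.ndarray) -> HPSParameterSet:
    new = HPSParameterSet(
        lam=dict(params.lam), sigma=dict(params.sigma),
        charge=dict(params.charge), mass=dict(params.mass),
        epsilon=params.epsilon, cutoff_sr=params.cutoff_sr,
        cutoff_dh=params.cutoff_dh,
        ionic_strength_mM=params.ionic_strength_mM,
        temperature_K=params.temperature_K, dielectric=params.dielectric,
    )
    for t, v in zip(type_order, lam):
        new.lam[t] = float(v)
    return new


@njit(cache=True)
def _du_dlam_kernel(frames, type_idx, sig_ij, excl, eps, rc_sr, n_types):
    n_frames = frames.shape[0]
    n = frames.shape[1]
    out = np.zeros((n_frames, n_types))
    for f in range(n_frames):
        for i in range(n):
            for j in range(i + 1, n):
                if excl[i, j]:
                    continue
                dx = frames[f, i, 0] - frames[f, j, 0]
                dy = frames[f, i, 1] - frames[f, j, 1]
                dz = frames[f, i, 2] - frames[f, j, 2]
                r = np.sqrt(dx * dx + dy * dy + dz * dz)
                if r >= rc_sr or r <= 0.0:
                    continue
                sig = sig_ij[i, j]
                s6 = (sig / r) ** 6
                phi = 4.0 * eps * (s6 * s6 - s6)
                rmin = 1.122462048309373 * sig
                # dU/dlambda_ij
                du = -eps if r <= rmin else phi
                if type_idx[i] >= 0:
                    out[f, type_idx[i]] += 0.5 * du
                if type_idx[j] >= 0:
                    out[f, type_idx[j]] += 0.5 * du
    return out


def per_frame_dU_dlambda(
    frames: np.ndarray,
    topology: CGTopology,
    params: HPSParameterSet,
    type_order: list[str],
) -> np.ndarray:
    """u_k per frame: (n_frames, n_types) array of dU/dlambda_k.

    Bead types absent from ``type_order`` (i.e. not optimized) still shape
    the pair term through sigma, but accumulate no derivative entry.
    """
    types = topology.bead_types
    tmap = {t: k for k, t in enumerate(type_order)}
    type_idx = np.array([tmap.get(t, -1) for t in types], dtype=np.int64)
    sig = np.array([params.sigma[t] for t in types])
    sig_ij = 0.5 * (sig[:, None] + sig[None, :])
    n = len(types)
    excl = np.zeros((n, n), dtype=np.bool_)
    for a, b in topology.bonds:
        excl[a, b] = excl[b, a] = True
    return _du_dlam_kernel(np.asarray(frames, dtype=float), type_idx, sig_ij,
                           excl, params.epsilon, params.cutoff_sr,
                           len(type_order))


def estimate_gradient(
    sims: list[tuple[np.ndarray, np.ndarray]],
    targets: list[float],
    u_frames: list[np.ndarray],
    lam: np.ndarray,
    lam0: np.ndarray,
    alpha: float,
    temperature_K: float = 300.0,
    min_frames: int = 20,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Loss gradient from stored frames.

    ``sims``: per construct (per-frame E, per-frame weights or None);
    ``u_frames``: per construct (n_frames, n_types) dU/dlambda arrays.
    Returns (gradient, loss, simulated means).
    """
    beta = 1.0 / (KB * temperature_K)
    n_types = len(lam)
    grad = 2.0 * alpha * (lam - lam0)
    loss = float(alpha * np.sum((lam - lam0) ** 2))
    means = np.empty(len(sims))
    for c, ((E, _w), u) in enumerate(zip(sims, u_frames)):
        if len(E) < min_frames:
            raise ValueError(
                f"construct {c}: only {len(E)} frames (< {min_frames})")
        if u.shape != (len(E), n_types):
            raise ValueError("u_frames shape mismatch")
        e_mean = float(E.mean())
        means[c] = e_mean
        mismatch = e_mean - targets[c]
        loss += mismatch ** 2
        dE_dlam = -beta * (np.mean(E[:, None] * u, axis=0)
                           - e_mean * u.mean(axis=0))
        grad += 2.0 * mismatch * dE_dlam
    return grad, loss, means


@dataclass
class OptimizationState:
    """Append-only record of a force-balance run."""

    type_order: list[str]
    lam: np.ndarray
    lam0: np.ndarray
    eta: float = 5.0
    alpha: float = 1e-4
    iteration: int = 0
    loss: float = np.inf
    sim_means: np.ndarray | None = None
    history: list[dict] = field(default_factory=list)
    freeze_mask: np.ndarray | None = None   # True = frozen

    def checkpoint(self) -> dict:
        return {
            "iteration": self.iteration,
            "lambda": {t: float(v) for t, v in zip(self.type_order, self.lam)},
            "loss": float(self.loss),
            "eta": self.eta,
            "sim_means": (None if self.sim_means is None
                          else [float(x) for x in self.sim_means]),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"history": self.history,
                       "current": self.checkpoint()}, fh, indent=1)


def _simulate_all(
    targets: list[ConstructTarget],
    params: HPSParameterSet,
    type_order: list[str],
    n_steps: int,
    seed: int,
    stride: int,
    friction_ps: float = 1.0,
) -> tuple[list, list, list[Trajectory]]:
    sims, u_frames, trajs = [], [], []
    for c, tgt in enumerate(targets):
        if tgt.topology is None:
            tgt.topology = build_topology(tgt.construct)
        traj = run_langevin(tgt.topology, params, n_steps=n_steps,
                            seed=seed + 1000 * c, stride=stride,
                            friction_ps=friction_ps)
        frames = traj.equilibrated()
        _, E = fret_from_trajectory(traj, tgt.topology.dye_center_beads,
                                    tgt.construct.R0_nm)
        sims.append((E, None))
        u_frames.append(per_frame_dU_dlambda(frames, tgt.topology, params,
                                             type_order))
        trajs.append(traj)
    return sims, u_frames, trajs


def iterate(
    state: OptimizationState,
    targets: list[ConstructTarget],
    base_params: HPSParameterSet,
    n_steps: int,
    seed: int,
    stride: int = 500,
    friction_ps: float = 1.0,
) -> OptimizationState:
    """One force-balance step: simulate, estimate gradient, update lambda."""
    params = apply_lambda_vector(base_params, state.type_order, state.lam)
    sims, u_frames, _ = _simulate_all(targets, params, state.type_order,
                                      n_steps, seed + state.iteration,
                                      stride, friction_ps)
    grad, loss, means = estimate_gradient(
        sims, [t.E_target for t in targets], u_frames, state.lam,
        state.lam0, state.alpha, base_params.temperature_K)
    if state.freeze_mask is not None:
        grad = np.where(state.freeze_mask, 0.0, grad)
    state.loss = loss
    state.sim_means = means
    state.history.append(state.checkpoint())
    state.lam = state.lam - state.eta * grad
    state.iteration += 1
    return state


def optimize_lambdas(
    targets: list[ConstructTarget],
    base_params: HPSParameterSet,
    type_order: list[str],
    seed: int,
    eta: float = 5.0,
    alpha: float = 1e-4,
    n_steps_per_iter: int = 100_000,
    stride: int = 500,
    max_iter: int = 20,
    plateau_rtol: float = 1e-3,
    patience: int = 3,
    eta_floor: float = 1e-3,
    freeze_mask: np.ndarray | None = None,
    checkpoint_path=None,
    friction_ps: float = 1.0,
) -> OptimizationState:
    """Full gradient-descent loop with eta adaptation and plateau stopping.

    Divergence handling: after two consecutive loss increases eta is halved
    and the step retried from the best-so-far lambda; optimization aborts if
    eta falls below ``eta_floor``.
    """
    lam0 = lambda_vector(base_params, type_order)
    state = OptimizationState(type_order=type_order, lam=lam0.copy(),
                              lam0=lam0, eta=eta, alpha=alpha,
                              freeze_mask=freeze_mask)
    best_lam, best_loss = state.lam.copy(), np.inf
    increase_streak = 0
    recent: list[float] = []
    while state.iteration < max_iter:
        state.eta = eta
        iterate(state, targets, base_params, n_steps_per_iter, seed,
                stride, friction_ps)
        if checkpoint_path is not None:
            state.save(checkpoint_path)
        if state.loss < best_loss:
            best_loss, best_lam = state.loss, state.history[-1]["lambda"]
            best_lam = np.array([best_lam[t] for t in type_order])
            increase_streak = 0
        else:
            increase_streak += 1
            if increase_streak >= 2:
                eta *= 0.5
                increase_streak = 0
                state.lam = best_lam.copy()
                if eta < eta_floor:
                    break
        recent.append(state.loss)
        if len(recent) > patience:
            recent.pop(0)
            span = max(recent) - min(recent)
            if span < plateau_rtol * max(abs(max(recent)), 1e-12):
                break
    state.lam = best_lam
    state.loss = best_loss
    return state


def grid_search_dye_lambda(
    targets: list[ConstructTarget],
    base_params: HPSParameterSet,
    dye_types: list[str],
    linker_type: str = "dye_lin",
    grid: np.ndarray | None = None,
    n_steps: int = 50_000,
    seed: int = 0,
    stride: int = 500,
) -> tuple[float, float, float]:
    """Coarse (dye, linker) lambda grid search minimizing the initial loss.

    All colored dye-bead types share one grid value; returns
    (best dye lambda, best linker lambda, best loss).
    """
    if grid is None:
        grid = np.arange(0.0, 1.21, 0.2)
    best = (None, None, np.inf)
    for ld in grid:
        for ll in grid:
            params = HPSParameterSet(
                lam=dict(base_params.lam), sigma=dict(base_params.sigma),
                charge=dict(base_params.charge), mass=dict(base_params.mass),
                epsilon=base_params.epsilon, cutoff_sr=base_params.cutoff_sr,
                cutoff_dh=base_params.cutoff_dh,
                ionic_strength_mM=base_params.ionic_strength_mM,
                temperature_K=base_params.temperature_K,
                dielectric=base_params.dielectric,
            )
            for t in dye_types:
                params.lam[t] = float(ld)
            params.lam[linker_type] = float(ll)
            loss = 0.0
            for c, tgt in enumerate(targets):
                if tgt.topology is None:
                    tgt.topology = build_topology(tgt.construct)
                traj = run_langevin(tgt.topology, params, n_steps=n_steps,
                                    seed=seed + 1000 * c, stride=stride)
                e_mean, _ = fret_from_trajectory(
                    traj, tgt.topology.dye_center_beads, tgt.construct.R0_nm)
                loss += (e_mean - tgt.E_target) ** 2
            if loss < best[2]:
                best = (float(ld), float(ll), float(loss))
    return best
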