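"""Weighted-ensemble structural analytics for disordered chains.

All routines accept per-frame weights (e.g. maximum-entropy posteriors) and
reduce to the unweighted formulas at uniform weights.  Distances follow the
root-mean-square-then-average convention: the inner average is the weighted
mean squared distance over frames for a residue pair, the outer average runs
over all pairs at the same sequence separation,

    <R_ij>(s) = mean_{|i-j|=s} sqrt( sum_f w_f r_ij(f)^2 ).

Internal scaling profiles are fit with the homopolymer law
<R>(s) = A0 * s^nu; scaled distance maps divide each pairwise RMS distance
by the best-fit homopolymer prediction, exposing local compaction (<1) and
expansion (>1).  Contact maps, contact networks (mean contact probability
per residue excluding |i-j| <= 2; edges above a fraction of the per-chain
maximum), gyration-tensor shape metrics, Debye-formula SAXS profiles and an
OLS regression suite with Lin's concordance coefficient complete the set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "InternalScalingProfile",
    "internal_scaling",
    "scaled_distance_map",
    "contact_map",
    "contact_network",
    "shape_metrics",
    "saxs_profile",
    "guinier_rg",
    "lin_concordance",
    "regression_suite",
]

#: Residue classes used to color contact-network nodes.
RESIDUE_CLASSES = {
    "G": "glycine",
    "S": "polar", "T": "polar", "N": "polar", "Q": "polar",
    "R": "basic", "K": "basic", "H": "basic",
    "D": "acidic", "E": "acidic",
    "F": "aromatic", "W": "aromatic", "Y": "aromatic",
    "M": "aliphatic", "V": "aliphatic", "I": "aliphatic", "L": "aliphatic",
    "A": "aliphatic",
    "P": "proline",
    "C": "cysteine",
}


def _norm_weights(frames: np.ndarray, weights: np.ndarray | None) -> np.ndarray:
    n = frames.shape[0]
    if weights is None:
        return np.full(n, 1.0 / n)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError("weights must have one entry per frame")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    return w / w.sum()


def _pairwise_sq(frames: np.ndarray) -> np.ndarray:
    """(n_frames, N, N) squared distances."""
    diff = frames[:, :, None, :] - frames[:, None, :, :]
    return np.einsum("fijk,fijk->fij", diff, diff)


def rms_distance_matrix(frames: np.ndarray,
                        weights: np.ndarray | None = None) -> np.ndarray:
    """Weighted RMS inter-bead distance matrix sqrt(<r_ij^2>_w)."""
    w = _norm_weights(frames, weights)
    d2 = _pairwise_sq(frames)
    return np.sqrt(np.einsum("f,fij->ij", w, d2))


@dataclass
class InternalScalingProfile:
    separations: np.ndarray
    distances: np.ndarray            # <R>(s), same length unit as input
    A0: float
    nu: float
    fit_window: tuple[int, int]

    def predicted(self, s: np.ndarray | None = None) -> np.ndarray:
        s = self.separations if s is None else np.asarray(s)
        return self.A0 * s.astype(float) ** self.nu


def internal_scaling(
    frames: np.ndarray,
    weights: np.ndarray | None = None,
    fit_window: tuple[int, int] | None = None,
) -> InternalScalingProfile:
    """Internal scaling profile and homopolymer fit <R>(s) = A0 s^nu.

    ``fit_window`` is an inclusive (min, max) range of sequence separations;
    the default is [5, N-5].  Requires at least three separations in the
    window.
    """
    n = frames.shape[1]
    rms = rms_distance_matrix(frames, weights)
    seps = np.arange(1, n)
    prof = np.array([
        np.mean([rms[i, i + s] for i in range(n - s)]) for s in seps
    ])
    if fit_window is None:
        fit_window = (5, n - 5)
    lo, hi = fit_window
    sel = (seps >= lo) & (seps <= hi)
    if sel.sum() < 3:
        raise ValueError("fewer than 3 separations in the fit window")
    popt, _ = curve_fit(
        lambda s, a0, nu: a0 * s ** nu,
        seps[sel].astype(float), prof[sel], p0=[prof[0], 0.5],
        maxfev=10000,
    )
    return InternalScalingProfile(
        separations=seps, distances=prof,
        A0=float(popt[0]), nu=float(popt[1]), fit_window=(lo, hi),
    )


def scaled_distance_map(
    frames: np.ndarray,
    weights: np.ndarray | None = None,
    fit: InternalScalingProfile | None = None,
    min_spacing: int = 10,
) -> np.ndarray:
    """RMS distances divided by the best-fit homopolymer prediction.

    Entries with |i-j| < min_spacing are masked as NaN.  Values below one
    mark local compaction, above one local expansion.
    """
    if fit is None:
        raise ValueError("a homopolymer fit is required (run internal_scaling)")
    rms = rms_distance_matrix(frames, weights)
    n = rms.shape[0]
    i, j = np.indices((n, n))
    sep = np.abs(i - j)
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = rms / (fit.A0 * sep.astype(float) ** fit.nu)
    scaled[sep < min_spacing] = np.nan
    return scaled


def contact_map(
    frames: np.ndarray,
    weights: np.ndarray | None = None,
    threshold: float = 1.0,
    mode: str = "bead",
    atom_residues: np.ndarray | None = None,
) -> np.ndarray:
    """Weighted probability that residue pairs are within ``threshold``.

    ``mode='bead'`` uses the bead-bead distance; ``mode='closest-heavy'``
    uses the minimum distance over all atoms mapped to each residue
    (``atom_residues`` gives the residue index per atom column).  The
    threshold is in the coordinate unit of ``frames`` (1.0 nm = 10 A by
    default).
    """
    if mode not in ("bead", "closest-heavy"):
        raise ValueError(f"unknown contact mode {mode!r}")
    w = _norm_weights(frames, weights)
    if mode == "bead":
        d2 = _pairwise_sq(frames)
        contacts = d2 < threshold ** 2
        return np.einsum("f,fij->ij", w, contacts.astype(float))
    if atom_residues is None:
        raise ValueError("closest-heavy mode needs atom_residues mapping")
    atom_residues = np.asarray(atom_residues)
    n_res = int(atom_residues.max()) + 1
    prob = np.zeros((n_res, n_res))
    d = np.sqrt(_pairwise_sq(frames))
    for i in range(n_res):
        ai = atom_residues == i
        for j in range(i, n_res):
            aj = atom_residues == j
            dmin = d[:, ai][:, :, aj].reshape(d.shape[0], -1).min(axis=1)
            p = float(np.sum(w * (dmin < threshold)))
            prob[i, j] = prob[j, i] = p
    return prob


def contact_network(
    cmap: np.ndarray,
    edge_fraction: float = 0.35,
    min_separation: int = 3,
    sequence: str | None = None,
) -> nx.Graph:
    """Residue contact network.

    Node weight = mean contact probability to residues more than two apart
    in sequence; edges where the pairwise probability reaches
    ``edge_fraction`` of the per-chain maximum (computed over pairs beyond
    the near-diagonal).  Node ``residue_class`` metadata is attached when a
    sequence is given.
    """
    n = cmap.shape[0]
    i, j = np.indices((n, n))
    far = np.abs(i - j) >= min_separation
    g = nx.Graph()
    for k in range(n):
        mask = far[k]
        node_attrs = {
            "mean_contact": float(cmap[k, mask].mean()) if mask.any() else 0.0
        }
        if sequence is not None:
            node_attrs["residue_class"] = RESIDUE_CLASSES.get(
                sequence[k].upper(), "other")
        g.add_node(k, **node_attrs)
    pmax = cmap[far].max() if np.any(far) else 0.0
    cut = edge_fraction * pmax
    for a in range(n):
        for b in range(a + min_separation, n):
            if pmax > 0 and cmap[a, b] >= cut and cmap[a, b] > 0:
                g.add_edge(a, b, weight=float(cmap[a, b]))
    return g


def shape_metrics(
    frames: np.ndarray, weights: np.ndarray | None = None
) -> dict[str, float]:
    """Weighted ensemble Rg, asphericity and RMS end-to-end distance.

    Per frame the gyration tensor eigenvalues l1 >= l2 >= l3 give
    Rg = sqrt(l1+l2+l3) and asphericity
    delta = 1 - 3 (l1 l2 + l2 l3 + l3 l1) / (l1+l2+l3)^2
    (0 for isotropic mass distributions, 1 for a rod).
    """
    w = _norm_weights(frames, weights)
    centered = frames - frames.mean(axis=1, keepdims=True)
    gyr = np.einsum("fni,fnj->fij", centered, centered) / frames.shape[1]
    evals = np.linalg.eigvalsh(gyr)                 # ascending
    tr = evals.sum(axis=1)
    pairsum = (evals[:, 0] * evals[:, 1] + evals[:, 1] * evals[:, 2]
               + evals[:, 2] * evals[:, 0])
    rg2 = tr
    with np.errstate(invalid="ignore"):
        delta = 1.0 - 3.0 * pairsum / tr ** 2
    ree2 = np.sum((frames[:, -1] - frames[:, 0]) ** 2, axis=1)
    return {
        "Rg": float(np.sqrt(np.sum(w * rg2))),
        "asphericity": float(np.sum(w * delta)),
        "Ree": float(np.sqrt(np.sum(w * ree2))),
        "Rg_per_frame_mean": float(np.sum(w * np.sqrt(rg2))),
    }


def saxs_profile(
    frames: np.ndarray,
    weights: np.ndarray | None = None,
    q_grid: np.ndarray | None = None,
    form_factors: np.ndarray | None = None,
) -> pd.DataFrame:
    """Debye-formula scattering profile normalized to I(0).

    I(q) = < sum_ij f_i f_j sinc(q r_ij) >_w, returned as columns (q,
    I_over_I0).  Form factors default to unity per bead, appropriate when
    only the normalized shape I(q)/I(0) is compared.
    """
    if q_grid is None or len(q_grid) == 0:
        raise ValueError("q_grid must be a non-empty array (1/nm)")
    q_grid = np.asarray(q_grid, dtype=float)
    w = _norm_weights(frames, weights)
    n = frames.shape[1]
    f = np.ones(n) if form_factors is None else np.asarray(form_factors)
    d = np.sqrt(_pairwise_sq(frames))               # (F, N, N)
    ff = np.outer(f, f)
    intens = np.empty(len(q_grid))
    for k, q in enumerate(q_grid):
        qr = q * d
        s = np.where(qr > 0, np.sin(np.where(qr > 0, qr, 1.0)) /
                     np.where(qr > 0, qr, 1.0), 1.0)
        intens[k] = np.sum(w * np.einsum("ij,fij->f", ff, s))
    i0 = np.sum(w) * ff.sum()
    return pd.DataFrame({"q": q_grid, "I_over_I0": intens / i0})


def guinier_rg(profile: pd.DataFrame, qmax_rg: float = 1.0) -> float:
    """Radius of gyration from a Guinier fit ln I = ln I0 - (q Rg)^2 / 3.

    Iterates the q-window so that q_max * Rg <= ``qmax_rg``.
    """
    q = profile["q"].to_numpy()
    I = profile["I_over_I0"].to_numpy()
    pos = (q > 0) & (I > 0)
    q, I = q[pos], I[pos]
    rg = 1.0
    for _ in range(50):
        sel = q * rg <= qmax_rg
        if sel.sum() < 3:
            sel = np.zeros_like(q, dtype=bool)
            sel[:3] = True
        slope, _ = np.polyfit(q[sel] ** 2, np.log(I[sel]), 1)
        new_rg = float(np.sqrt(max(-3.0 * slope, 0.0)))
        if abs(new_rg - rg) < 1e-12:
            break
        rg = new_rg
    return rg


def lin_concordance(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient.

    rho_c = 2 cov(x, y) / (var x + var y + (mean x - mean y)^2), combining
    correlation (precision) with deviation from the identity line
    (accuracy).  Population (1/n) variance convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx, vy = x.var(), y.var()
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    return float(2.0 * cov / (vx + vy + (x.mean() - y.mean()) ** 2))


@dataclass
class RegressionResult:
    features: tuple[str, ...]
    rho2: float
    coef: np.ndarray
    intercept: float
    loo_rho2: np.ndarray = field(default_factory=lambda: np.array([]))


def _ols_rho2(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, float]:
    A = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    rho2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return rho2, beta[1:], float(beta[0])


def regression_suite(
    features: pd.DataFrame,
    response: np.ndarray | pd.Series,
    max_order: int = 3,
    leave_one_out: bool = True,
) -> pd.DataFrame:
    """OLS fits of the response on all 1..max_order feature combinations.

    Returns one row per combination with the coefficient of determination
    rho2, Lin's concordance rho_c between fitted and observed values, and
    (optionally) the distribution of rho2 over leave-one-out refits.
    """
    y = np.asarray(response, dtype=float)
    names = list(features.columns)
    rows = []
    for order in range(1, max_order + 1):
        for combo in combinations(names, order):
            X = features[list(combo)].to_numpy(dtype=float)
            rho2, coef, icpt = _ols_rho2(X, y)
            fitted = X @ coef + icpt
            row = {
                "features": "+".join(combo),
                "order": order,
                "rho2": rho2,
                "rho_c": lin_concordance(fitted, y),
                "coef": coef,
                "intercept": icpt,
            }
            if leave_one_out:
                loo = []
                for k in range(len(y)):
                    keep = np.arange(len(y)) != k
                    loo.append(_ols_rho2(X[keep], y[keep])[0])
                loo = np.array(loo)
                row["loo_rho2_min"] = float(loo.min())
                row["loo_rho2_max"] = float(loo.max())
                row["loo_rho2"] = loo
            rows.append(row)
    return pd.DataFrame(rows).sort_values("rho2", ascending=False,
                                          ignore_index=True)
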