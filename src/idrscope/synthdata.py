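"""Synthetic inputs with known ground truth for every pipeline stage.

Emulates the study design — 57-residue disordered linkers bracketed by
GSGSC/CTLGPR expression overhangs, conformational ensembles with known
end-to-end statistics, and pulsed-interleaved-excitation photon streams
with known true transfer efficiency, background and crosstalk — so that
burst analysis, polymer inversion, reweighting and ensemble analytics can
all be tested against planted truth.  Every generator is deterministic
under its seed and returns a truth dictionary alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqfeat import (
    DEFAULT_PREFIX_OVERHANG,
    DEFAULT_SUFFIX_OVERHANG,
    SequenceRecord,
    compute_features,
    kappa,
)
from .smfret import ACCEPTOR, AEX, DEX, DONOR, TICK_PS, PhotonStream

__all__ = [
    "gen_sequences",
    "gen_gaussian_chain",
    "gen_rod",
    "gen_ensemble",
    "gen_photons",
    "PhotonTruth",
]

_NEUTRAL_POOL = "GSTNQAPVLY"      # draw pool for uncharged positions


def _one_sequence(rng, length, fcr, ncpr):
    n_plus = round(length * (fcr + ncpr) / 2)
    n_minus = round(length * (fcr - ncpr) / 2)
    if n_plus < 0 or n_minus < 0 or n_plus + n_minus > length:
        raise ValueError(f"infeasible FCR={fcr}, NCPR={ncpr}")
    pool = (["K"] * n_plus + ["E"] * n_minus
            + list(rng.choice(list(_NEUTRAL_POOL),
                              size=length - n_plus - n_minus)))
    rng.shuffle(pool)
    return pool


def gen_sequences(
    n: int,
    seed: int,
    length: int = 57,
    fcr: float = 0.3,
    ncpr: float = 0.0,
    kappa_band: tuple[float, float] | None = None,
    with_overhangs: bool = True,
    max_swaps: int = 20000,
) -> list[SequenceRecord]:
    """Composition-constrained random IDR-like sequences.

    Charged-residue counts follow the requested FCR/NCPR; when a
    ``kappa_band`` is given, charge positions are annealed by accept/reject
    swaps until the charge-patterning factor falls inside the band.
    Overhangs (GSGSC / CTLGPR) are appended unless disabled; feature values
    are verified through the descriptor module.
    """
    rng = np.random.default_rng(seed)
    if kappa_band is not None and fcr * length < 2:
        raise ValueError("kappa target requires at least two charged residues")
    records = []
    for k in range(n):
        seq = _one_sequence(rng, length, fcr, ncpr)
        if kappa_band is not None:
            lo, hi = kappa_band
            for _ in range(max_swaps):
                cur = kappa("".join(seq))
                if lo <= cur <= hi:
                    break
                i, j = rng.integers(0, length, size=2)
                seq[i], seq[j] = seq[j], seq[i]
                new = kappa("".join(seq))
                better = (abs(np.clip(new, lo, hi) - new)
                          <= abs(np.clip(cur, lo, hi) - cur))
                if not better:
                    seq[i], seq[j] = seq[j], seq[i]
            else:
                raise ValueError(
                    f"could not reach kappa in [{lo}, {hi}] for FCR={fcr}")
        core = "".join(seq)
        full = (DEFAULT_PREFIX_OVERHANG + core + DEFAULT_SUFFIX_OVERHANG
                if with_overhangs else core)
        rec = SequenceRecord(f"synth{k:03d}", full)
        if with_overhangs:
            rec = rec.with_overhangs_masked()
        compute_features(rec)        # validates
        records.append(rec)
    return records


def gen_gaussian_chain(
    n_frames: int,
    n_beads: int,
    seed: int,
    bond_nm: float = 0.38,
) -> tuple[np.ndarray, dict]:
    """Ideal-chain frames: i.i.d. Gaussian bond vectors, variance b^2/3 per axis.

    Returns (frames of shape (n_frames, n_beads, 3) in nm, truth dict with
    the exact generative mean squared end-to-end distance
    (n_beads - 1) * b^2).
    """
    rng = np.random.default_rng(seed)
    steps = rng.normal(scale=bond_nm / np.sqrt(3.0),
                       size=(n_frames, n_beads - 1, 3))
    frames = np.concatenate(
        [np.zeros((n_frames, 1, 3)), np.cumsum(steps, axis=1)], axis=1)
    truth = {
        "model": "gaussian-chain",
        "bond_nm": bond_nm,
        "R2_exact": (n_beads - 1) * bond_nm ** 2,
        "seed": seed,
    }
    return frames, truth


def gen_rod(n_frames: int, n_beads: int, seed: int,
            bond_nm: float = 0.38) -> tuple[np.ndarray, dict]:
    """Rigid collinear rod frames with random orientation per frame."""
    rng = np.random.default_rng(seed)
    axis = rng.normal(size=(n_frames, 3))
    axis /= np.linalg.norm(axis, axis=1, keepdims=True)
    t = np.arange(n_beads) * bond_nm
    frames = axis[:, None, :] * t[None, :, None]
    truth = {"model": "rod", "bond_nm": bond_nm,
             "R2_exact": ((n_beads - 1) * bond_nm) ** 2, "seed": seed}
    return frames, truth


def gen_ensemble(
    model: str,
    n_frames: int,
    n_beads: int,
    seed: int,
    bond_nm: float = 0.38,
    weights: str = "uniform",
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Dispatch generator: (frames, weights, truth) for 'gaussian-chain' | 'rod'."""
    if model == "gaussian-chain":
        frames, truth = gen_gaussian_chain(n_frames, n_beads, seed, bond_nm)
    elif model == "rod":
        frames, truth = gen_rod(n_frames, n_beads, seed, bond_nm)
    else:
        raise ValueError(f"unknown ensemble model {model!r}")
    if weights == "uniform":
        w = np.full(n_frames, 1.0 / n_frames)
    elif weights == "random":
        rng = np.random.default_rng(seed + 1)
        w = rng.dirichlet(np.ones(n_frames))
    else:
        raise ValueError(f"unknown weight mode {weights!r}")
    return frames, w, truth


@dataclass
class PhotonTruth:
    """Sidecar describing the generative model of a synthetic photon stream."""

    E_true: float
    n_bursts: int
    burst_size_mean: float
    background_rate_hz: float
    crosstalk: float
    aex_fraction: float
    seed: int
    burst_starts_ticks: list[int] = field(default_factory=list)


def gen_photons(
    n_bursts: int,
    E_true: float,
    seed: int,
    burst_size_mean: float = 100.0,
    burst_rate_hz: float = 50.0,
    photon_rate_hz: float = 200e3,
    background_rate_hz: float = 0.0,
    crosstalk: float = 0.0,
    aex_fraction: float = 0.3,
    duration_margin: float = 1.5,
) -> tuple[PhotonStream, PhotonTruth]:
    """Poisson-cluster photon stream with known true transfer efficiency.

    Bursts arrive as a Poisson process; each burst carries a Poisson photon
    count (mean ``burst_size_mean``) split between donor- and
    acceptor-excitation periods; donor-excitation photons are acceptor
    detected with probability E_true, and donor-detected photons leak into
    the acceptor channel with probability ``crosstalk``.  Uniform background
    photons are added channel-symmetrically.  Returns the stream plus a
    truth sidecar.
    """
    rng = np.random.default_rng(seed)
    tick_s = TICK_PS * 1e-12
    if n_bursts == 0:
        empty = np.array([], dtype=np.int64)
        return (PhotonStream(empty, empty, empty),
                PhotonTruth(E_true, 0, burst_size_mean, background_rate_hz,
                            crosstalk, aex_fraction, seed))
    # sequential burst starts with a guaranteed minimum separation so that
    # the planted burst count is recoverable exactly
    min_sep_s = duration_margin * 5e-3
    gaps_s = min_sep_s + rng.exponential(1.0 / burst_rate_hz, size=n_bursts)
    times, channels, periods = [], [], []
    start_ticks = []
    t_end = 0.0
    for g in gaps_s:
        t0 = t_end + g
        n_ph = max(int(rng.poisson(burst_size_mean)), 60)
        gaps = rng.exponential(1.0 / photon_rate_hz, size=n_ph)
        t = t0 + np.cumsum(gaps)
        per = rng.uniform(size=n_ph) < aex_fraction
        ch = np.empty(n_ph, dtype=np.int8)
        # acceptor-excitation photons: acceptor emission
        ch[per] = ACCEPTOR
        # donor-excitation photons: acceptor with prob E_true, else donor
        dex = ~per
        fret = rng.uniform(size=int(dex.sum())) < E_true
        dch = np.where(fret, ACCEPTOR, DONOR).astype(np.int8)
        # donor-detected photons leak into the acceptor channel
        leak = (dch == DONOR) & (rng.uniform(size=len(dch)) < crosstalk)
        dch[leak] = ACCEPTOR
        ch[dex] = dch
        times.append(t)
        channels.append(ch)
        periods.append(np.where(per, AEX, DEX).astype(np.int8))
        start_ticks.append(int(t[0] / tick_s))
        t_end = t[-1]

    total_s = t_end + min_sep_s
    if background_rate_hz > 0:
        n_bg = rng.poisson(background_rate_hz * total_s)
        tb = rng.uniform(0, total_s, size=n_bg)
        cb = rng.integers(0, 2, size=n_bg).astype(np.int8)
        pb = np.where(rng.uniform(size=n_bg) < aex_fraction, AEX, DEX)
        times.append(tb)
        channels.append(cb)
        periods.append(pb.astype(np.int8))

    t_all = np.concatenate(times)
    order = np.argsort(t_all, kind="stable")
    stream = PhotonStream(
        (t_all[order] / tick_s).astype(np.int64),
        np.concatenate(channels)[order],
        np.concatenate(periods)[order],
    )
    truth = PhotonTruth(E_true, n_bursts, burst_size_mean,
                        background_rate_hz, crosstalk, aex_fraction, seed,
                        start_ticks)
    return stream, truth
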