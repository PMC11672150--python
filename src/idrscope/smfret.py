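"""Photon-level single-molecule FRET burst analysis.

Photons recorded under pulsed interleaved excitation carry an arrival time
(integer ticks, 16 ps by default), a detection channel (donor or acceptor
emission) and an excitation-period tag (donor or acceptor excitation).
Bursts are contiguous runs of photons whose interphoton times stay below a
threshold (150 us), retained above a minimum photon count (50).  A
dual-channel criterion removes bursts that do not independently qualify in
both excitation periods, suppressing bleaching and blinking artifacts.

Per burst, raw counts in the three detection channels
(donor-excitation/donor-emission DD, donor-excitation/acceptor-emission DA,
acceptor-excitation/acceptor-emission AA) are corrected in the standard
order background -> spectral crosstalk and direct acceptor excitation ->
detection/quantum-yield ratio gamma, yielding

    S = n_tot,Dex / (n_tot,Dex + n_tot,Aex)        (stoichiometry)
    E = n_A / (n_A + n_D)                          (transfer efficiency)

Only bursts with 0.2 < S < 0.8 (strict) enter the efficiency histogram,
which is fit with Gaussian peak functions to extract mean efficiencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "TICK_PS",
    "PhotonStream",
    "Burst",
    "CorrectionSet",
    "find_bursts",
    "dual_channel_filter",
    "correct_and_score",
    "score_bursts",
    "fit_histogram",
    "GaussianPeak",
    "HistogramFit",
]

#: Default timing resolution of one clock tick, in picoseconds.
TICK_PS = 16

DONOR, ACCEPTOR = 0, 1          # detection channels
DEX, AEX = 0, 1                 # excitation periods


@dataclass
class PhotonStream:
    """Sorted photon record table: arrival ticks, channel, excitation period."""

    times: np.ndarray
    channels: np.ndarray
    periods: np.ndarray
    tick_ps: float = TICK_PS

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.int64)
        self.channels = np.asarray(self.channels, dtype=np.int8)
        self.periods = np.asarray(self.periods, dtype=np.int8)
        if not (len(self.times) == len(self.channels) == len(self.periods)):
            raise ValueError("photon record columns must have equal length")
        if len(self.times) and np.any(np.diff(self.times) < 0):
            raise ValueError("photon arrival times must be non-decreasing")
        for arr, vocab in ((self.channels, (DONOR, ACCEPTOR)),
                           (self.periods, (DEX, AEX))):
            if len(arr) and not np.isin(arr, vocab).all():
                raise ValueError("channel/period tags outside vocabulary")

    def __len__(self) -> int:
        return len(self.times)

    @classmethod
    def from_table(cls, df: pd.DataFrame, tick_ps: float = TICK_PS) -> "PhotonStream":
        return cls(df["time_tick"].to_numpy(), df["channel"].to_numpy(),
                   df["period"].to_numpy(), tick_ps)

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame({"time_tick": self.times, "channel": self.channels,
                             "period": self.periods})


@dataclass
class Burst:
    """One photon burst with raw and corrected counts and derived E, S."""

    start: int
    stop: int
    indices: np.ndarray
    counts: dict[str, int]
    n_D: float = np.nan
    n_A: float = np.nan
    n_tot_dex: float = np.nan
    n_tot_aex: float = np.nan
    E: float = np.nan
    S: float = np.nan
    valid: bool = True
    stoichiometry_ok: bool = True
    meta: dict = field(default_factory=dict)

    @property
    def n_photons(self) -> int:
        return len(self.indices)

    @property
    def duration_ticks(self) -> int:
        return int(self.stop - self.start)


@dataclass
class CorrectionSet:
    """Instrumental corrections for burst counts.

    Background rates in photons/s per detection signal; ``crosstalk`` is the
    donor-leakage fraction into the acceptor channel; ``direct_excitation``
    the acceptor direct-excitation contribution relative to the
    acceptor-excitation counts; ``gamma`` the detection-efficiency /
    quantum-yield ratio applied to the donor counts.
    """

    bg_dd: float = 0.0
    bg_da: float = 0.0
    bg_aa: float = 0.0
    crosstalk: float = 0.0
    direct_excitation: float = 0.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if min(self.bg_dd, self.bg_da, self.bg_aa, self.crosstalk,
               self.direct_excitation) < 0:
            raise ValueError("correction factors must be non-negative")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    @classmethod
    def identity(cls) -> "CorrectionSet":
        return cls()


def _raw_counts(stream: PhotonStream, idx: np.ndarray) -> dict[str, int]:
    ch = stream.channels[idx]
    per = stream.periods[idx]
    return {
        "DD": int(np.sum((per == DEX) & (ch == DONOR))),
        "DA": int(np.sum((per == DEX) & (ch == ACCEPTOR))),
        "AA": int(np.sum((per == AEX) & (ch == ACCEPTOR))),
        "AD": int(np.sum((per == AEX) & (ch == DONOR))),
    }


def _runs(times: np.ndarray, max_gap_ticks: float, min_photons: int):
    """Maximal runs of successive interphoton gaps < max_gap_ticks."""
    if len(times) == 0:
        return
    breaks = np.nonzero(np.diff(times) >= max_gap_ticks)[0]
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks + 1, [len(times)]))
    for a, b in zip(starts, stops):
        if b - a >= min_photons:
            yield int(a), int(b)


def find_bursts(
    stream: PhotonStream,
    max_interphoton_us: float = 150.0,
    min_photons: int = 50,
) -> list[Burst]:
    """All-photon burst search: contiguous runs with small interphoton gaps."""
    gap_ticks = max_interphoton_us * 1e6 / stream.tick_ps
    bursts = []
    for a, b in _runs(stream.times, gap_ticks, min_photons):
        idx = np.arange(a, b)
        bursts.append(Burst(
            start=int(stream.times[a]),
            stop=int(stream.times[b - 1]),
            indices=idx,
            counts=_raw_counts(stream, idx),
        ))
    return bursts


def dual_channel_filter(
    bursts: list[Burst],
    stream: PhotonStream,
    max_interphoton_us: float = 300.0,
    min_photons_per_period: int = 10,
) -> list[Burst]:
    """Keep bursts that independently satisfy the burst criterion per period.

    Within each burst, the photons of the donor-excitation period and those
    of the acceptor-excitation period must each contain a qualifying run
    spanning at least half of the burst duration.  This removes bursts from
    single-labeled molecules and from dyes that bleach or blink mid-burst.
    """
    gap_ticks = max_interphoton_us * 1e6 / stream.tick_ps
    kept = []
    for burst in bursts:
        ok = True
        half_span = 0.5 * max(burst.duration_ticks, 1)
        for period in (DEX, AEX):
            t = stream.times[burst.indices][stream.periods[burst.indices] == period]
            qualifying = [
                (a, b) for a, b in _runs(t, gap_ticks, min_photons_per_period)
                if t[b - 1] - t[a] >= half_span
            ]
            if not qualifying:
                ok = False
                break
        if ok:
            kept.append(burst)
    return kept


def correct_and_score(
    burst: Burst,
    corrections: CorrectionSet | None = None,
    tick_ps: float = TICK_PS,
) -> Burst:
    """Apply corrections to one burst and compute (E, S) in place.

    Order: background subtraction, then crosstalk and direct-excitation
    removal, then gamma.  Bursts whose corrected denominators are
    non-positive are flagged invalid (never silently dropped); bursts with S
    outside the open interval (0.2, 0.8) are flagged excluded.
    """
    c = corrections or CorrectionSet.identity()
    duration_s = burst.duration_ticks * tick_ps * 1e-12
    dd = burst.counts["DD"] - c.bg_dd * duration_s
    da = burst.counts["DA"] - c.bg_da * duration_s
    aa = burst.counts["AA"] - c.bg_aa * duration_s
    da = da - c.crosstalk * dd - c.direct_excitation * aa

    burst.n_D = c.gamma * dd
    burst.n_A = da
    burst.n_tot_dex = burst.n_D + burst.n_A
    burst.n_tot_aex = aa

    tot = burst.n_tot_dex + burst.n_tot_aex
    if burst.n_tot_dex <= 0 or tot <= 0:
        burst.valid = False
        burst.stoichiometry_ok = False
        return burst
    burst.S = burst.n_tot_dex / tot
    burst.E = burst.n_A / burst.n_tot_dex
    burst.stoichiometry_ok = 0.2 < burst.S < 0.8
    return burst


def score_bursts(
    bursts: list[Burst],
    corrections: CorrectionSet | None = None,
    tick_ps: float = TICK_PS,
) -> pd.DataFrame:
    """Correct and score a burst list; returns one row per burst."""
    rows = []
    for b in bursts:
        correct_and_score(b, corrections, tick_ps)
        rows.append({
            "start": b.start, "stop": b.stop, "n_photons": b.n_photons,
            **b.counts, "n_D": b.n_D, "n_A": b.n_A,
            "n_tot_dex": b.n_tot_dex, "n_tot_aex": b.n_tot_aex,
            "E": b.E, "S": b.S, "valid": b.valid,
            "stoichiometry_ok": b.stoichiometry_ok,
        })
    return pd.DataFrame(rows)


@dataclass
class GaussianPeak:
    mean: float
    sigma: float
    amplitude: float


@dataclass
class HistogramFit:
    peaks: list["GaussianPeak"]
    bin_edges: np.ndarray
    counts: np.ndarray
    converged: bool
    message: str = ""

    @property
    def means(self) -> list[float]:
        return [p.mean for p in self.peaks]


def _gauss_mix(x: np.ndarray, *params: float) -> np.ndarray:
    out = np.zeros_like(x)
    for i in range(0, len(params), 3):
        a, mu, sig = params[i:i + 3]
        out = out + a * np.exp(-0.5 * ((x - mu) / sig) ** 2)
    return out


def fit_histogram(
    E_values: np.ndarray,
    n_peaks: int = 1,
    bin_width: float = 0.02,
    bounds: tuple[float, float] = (-0.1, 1.1),
) -> HistogramFit:
    """Least-squares Gaussian mixture fit of the efficiency histogram.

    Fixed-bin histogram (default width 0.02 on [-0.1, 1.1]); initial peak
    positions are seeded from the highest well-separated histogram modes;
    peaks are returned sorted by mean.  Non-convergence is reported in the
    result rather than raised.
    """
    E_values = np.asarray(E_values, dtype=float)
    if len(E_values) < 100:
        raise ValueError("need at least 100 bursts for a histogram fit")
    edges = np.arange(bounds[0], bounds[1] + bin_width / 2, bin_width)
    counts, _ = np.histogram(E_values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    order = np.argsort(counts)[::-1]
    seeds: list[float] = []
    for i in order:
        if len(seeds) == n_peaks:
            break
        if all(abs(centers[i] - s) > 5 * bin_width for s in seeds):
            seeds.append(float(centers[i]))
    while len(seeds) < n_peaks:
        seeds.append(float(np.mean(E_values)))

    p0 = []
    for s in sorted(seeds):
        p0 += [float(counts.max()), s, 0.05]
    lo = [0.0, bounds[0], bin_width / 4] * n_peaks
    hi = [np.inf, bounds[1], 0.5] * n_peaks
    try:
        popt, _ = curve_fit(_gauss_mix, centers, counts, p0=p0,
                            bounds=(lo, hi), maxfev=20000)
    except RuntimeError as err:  # non-convergence: report with diagnostics
        return HistogramFit([], edges, counts, False, str(err))
    peaks = sorted(
        (GaussianPeak(mean=popt[i + 1], sigma=popt[i + 2], amplitude=popt[i])
         for i in range(0, len(popt), 3)),
        key=lambda p: p.mean,
    )
    return HistogramFit(peaks, edges, counts, True, "")
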