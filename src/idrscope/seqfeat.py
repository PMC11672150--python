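"""Sequence-composition and charge-patterning descriptors for disordered regions.

Implements the descriptors commonly used to map the sequence space of
intrinsically disordered regions: normalized Kyte-Doolittle hydrophobicity,
fraction of charged residues (FCR), net charge per residue (NCPR), the
Das-Pappu charge-patterning factor kappa, sequence charge decoration (SCD),
and per-residue / residue-group composition fractions.

Charge convention: Asp and Glu carry -1, Lys and Arg +1, His and the termini
are neutral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SequenceRecord",
    "SequenceFeatures",
    "KYTE_DOOLITTLE",
    "RESIDUE_CHARGE",
    "normalized_hydrophobicity",
    "charge_fractions",
    "kappa",
    "scd",
    "composition_features",
    "compute_features",
    "feature_table",
    "read_fasta",
    "write_feature_table",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Kyte-Doolittle hydropathy index, range [-4.5, 4.5].
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Formal residue charge at neutral pH; His treated as neutral.
RESIDUE_CHARGE: dict[str, int] = {aa: 0 for aa in AMINO_ACIDS}
RESIDUE_CHARGE.update({"D": -1, "E": -1, "K": 1, "R": 1})

#: Residue groups used for composition features.
RESIDUE_GROUPS: dict[str, str] = {
    "aromatic": "FWY",
    "aliphatic": "AVILM",
    "polar": "STNQ",
    "K+R": "KR",
    "D+E": "DE",
}

# Cloning overhangs left by thrombin cleavage; masked (together with the
# labeling Cys they contain) before feature calculation.
DEFAULT_PREFIX_OVERHANG = "GSGSC"
DEFAULT_SUFFIX_OVERHANG = "CTLGPR"


class SequenceError(ValueError):
    """Raised for sequences with non-canonical residues or empty cores."""


@dataclass
class SequenceRecord:
    """A named amino-acid sequence with an optional overhang mask.

    ``mask`` marks residues *excluded* from feature calculation (True =
    masked).  :meth:`with_overhangs_masked` masks the standard expression
    overhangs when present.
    """

    id: str
    sequence: str
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (len(self.sequence),):
                raise ValueError("mask length must match sequence length")

    def with_overhangs_masked(
        self,
        prefix: str = DEFAULT_PREFIX_OVERHANG,
        suffix: str = DEFAULT_SUFFIX_OVERHANG,
    ) -> "SequenceRecord":
        mask = np.zeros(len(self.sequence), dtype=bool)
        if prefix and self.sequence.startswith(prefix):
            mask[: len(prefix)] = True
        if suffix and self.sequence.endswith(suffix):
            mask[len(self.sequence) - len(suffix):] = True
        return SequenceRecord(self.id, self.sequence, mask)

    @property
    def core(self) -> str:
        """Unmasked part of the sequence, validated against the 20 canonical types."""
        if self.mask is None:
            seq = self.sequence
        else:
            seq = "".join(
                aa for aa, m in zip(self.sequence, self.mask) if not m
            )
        if not seq:
            raise SequenceError(f"{self.id}: empty sequence after masking")
        for pos, aa in enumerate(seq):
            if aa not in KYTE_DOOLITTLE:
                raise SequenceError(
                    f"{self.id}: non-canonical residue {aa!r} at unmasked position {pos}"
                )
        return seq


def _as_core(seq: SequenceRecord | str) -> str:
    if isinstance(seq, SequenceRecord):
        return seq.core
    return SequenceRecord("seq", seq).core


def normalized_hydrophobicity(seq: SequenceRecord | str) -> float:
    """Mean Kyte-Doolittle hydropathy rescaled to [0, 1].

    H = (1/N) sum_i (KD_i + 4.5) / 9 over unmasked residues.
    """
    core = _as_core(seq)
    return float(np.mean([(KYTE_DOOLITTLE[aa] + 4.5) / 9.0 for aa in core]))


def charge_fractions(seq: SequenceRecord | str) -> tuple[float, float]:
    """Return (FCR, NCPR): fraction of charged residues and net charge per residue."""
    core = _as_core(seq)
    q = np.array([RESIDUE_CHARGE[aa] for aa in core], dtype=float)
    f_plus = float(np.mean(q > 0))
    f_minus = float(np.mean(q < 0))
    return f_plus + f_minus, f_plus - f_minus


def _charges(core: str) -> np.ndarray:
    return np.array([RESIDUE_CHARGE[aa] for aa in core], dtype=float)


def _sigma(q: np.ndarray) -> float:
    """Local charge asymmetry sigma = (f+ - f-)^2 / (f+ + f-); 0 if uncharged."""
    f_plus = np.mean(q > 0)
    f_minus = np.mean(q < 0)
    fcr = f_plus + f_minus
    if fcr == 0:
        return 0.0
    return float((f_plus - f_minus) ** 2 / fcr)


def _delta(q: np.ndarray, blob: int) -> float:
    """Mean squared deviation of blob-wise sigma from the global sigma.

    Blob windows slide one residue at a time and are fully contained in the
    sequence (no partial end blobs).
    """
    n = len(q)
    if n < blob:
        return 0.0
    sig_global = _sigma(q)
    windows = np.lib.stride_tricks.sliding_window_view(q, blob)
    f_plus = np.mean(windows > 0, axis=1)
    f_minus = np.mean(windows < 0, axis=1)
    fcr = f_plus + f_minus
    with np.errstate(divide="ignore", invalid="ignore"):
        sig = np.where(fcr > 0, (f_plus - f_minus) ** 2 / np.where(fcr > 0, fcr, 1.0), 0.0)
    return float(np.mean((sig - sig_global) ** 2))


from functools import lru_cache


@lru_cache(maxsize=4096)
def _delta_max_cached(plus: int, minus: int, zero: int,
                      blobs: tuple[int, ...]) -> float:
    """Normalization: maximal blob-averaged delta over charge-preserving
    rearrangements.

    Two candidate families are scanned exhaustively: (a) one contiguous
    all-positive and one contiguous all-negative block placed independently
    among the neutral residues (the optimum for long polyampholytes), and
    (b) the single +/- double block split at any internal position by the
    full neutral block (the optimum for nearly-uncharged-free sequences).
    Depends only on the composition, hence cached.
    """
    best = 0.0
    for t1 in range(zero + 1):
        for t2 in range(zero - t1 + 1):
            arr = np.concatenate([
                np.zeros(t1), np.ones(plus), np.zeros(t2), -np.ones(minus),
                np.zeros(zero - t1 - t2),
            ])
            best = max(best, float(np.mean([_delta(arr, g) for g in blobs])))
    block = np.concatenate([np.ones(plus), -np.ones(minus)])
    for s in range(len(block) + 1):
        arr = np.concatenate([block[:s], np.zeros(zero), block[s:]])
        best = max(best, float(np.mean([_delta(arr, g) for g in blobs])))
    return best


def _delta_max(q: np.ndarray, blobs: tuple[int, ...]) -> float:
    plus = int(np.count_nonzero(q > 0))
    minus = int(np.count_nonzero(q < 0))
    return _delta_max_cached(plus, minus, len(q) - plus - minus, tuple(blobs))


def kappa(seq: SequenceRecord | str, blobs: tuple[int, int] = (5, 6)) -> float:
    """Das-Pappu charge-patterning factor.

    Blob-averaged squared deviation of the local charge asymmetry from the
    global value, averaged over the given blob sizes, normalized by the same
    quantity for the most segregated charge-preserving rearrangement (one
    contiguous all-positive/all-negative block, its position among the
    neutral residues scanned exhaustively).  Sliding windows are fully
    contained in the sequence (no partial end blobs).  Returns NaN when fewer than two charged residues are present.
    """
    core = _as_core(seq)
    q = _charges(core)
    if np.count_nonzero(q) < 2:
        return float("nan")
    num = float(np.mean([_delta(q, g) for g in blobs]))
    # the observed arrangement is itself a charge-preserving rearrangement,
    # so the normalizing maximum can never fall below num
    den = max(_delta_max(q, blobs), num)
    if den == 0:
        return float("nan")
    return float(num / den)


def scd(seq: SequenceRecord | str) -> float:
    """Sequence charge decoration: (1/N) sum_{i<j} q_i q_j sqrt(j - i)."""
    core = _as_core(seq)
    q = _charges(core)
    n = len(q)
    idx = np.nonzero(q)[0]
    if len(idx) < 2:
        return 0.0
    sep = idx[None, :] - idx[:, None]
    qq = np.outer(q[idx], q[idx])
    upper = np.triu(np.ones_like(sep, dtype=bool), k=1)
    return float(np.sum(qq[upper] * np.sqrt(sep[upper])) / n)


def composition_features(seq: SequenceRecord | str) -> dict[str, float]:
    """Per-amino-acid fractions ``f_X`` plus residue-group fractions."""
    core = _as_core(seq)
    n = len(core)
    feats = {f"f_{aa}": core.count(aa) / n for aa in AMINO_ACIDS}
    for name, members in RESIDUE_GROUPS.items():
        feats[f"f_{name}"] = sum(core.count(aa) for aa in members) / n
    return feats


@dataclass
class SequenceFeatures:
    """Full descriptor set for one sequence."""

    id: str
    length: int
    hydrophobicity: float
    fcr: float
    ncpr: float
    kappa: float
    scd: float
    composition: dict[str, float] = field(default_factory=dict)

    def as_row(self) -> dict[str, float]:
        row: dict[str, float] = {
            "id": self.id,
            "N": self.length,
            "hydrophobicity": self.hydrophobicity,
            "FCR": self.fcr,
            "NCPR": self.ncpr,
            "kappa": self.kappa,
            "SCD": self.scd,
        }
        row.update(self.composition)
        return row


def compute_features(seq: SequenceRecord | str) -> SequenceFeatures:
    """Compute the full feature set for one (possibly masked) sequence."""
    if isinstance(seq, str):
        seq = SequenceRecord("seq", seq)
    core = seq.core
    fcr, ncpr = charge_fractions(seq)
    return SequenceFeatures(
        id=seq.id,
        length=len(core),
        hydrophobicity=normalized_hydrophobicity(seq),
        fcr=fcr,
        ncpr=ncpr,
        kappa=kappa(seq),
        scd=scd(seq),
        composition=composition_features(seq),
    )


def feature_table(records: list[SequenceRecord]) -> pd.DataFrame:
    """One row of descriptors per sequence, in input order."""
    return pd.DataFrame([compute_features(r).as_row() for r in records])


def read_fasta(path, mask_overhangs: bool = False) -> list[SequenceRecord]:
    """Read a multi-record (possibly line-wrapped) FASTA file."""
    from Bio import SeqIO

    records = [
        SequenceRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if mask_overhangs:
        records = [r.with_overhangs_masked() for r in records]
    return records


def write_feature_table(records: list[SequenceRecord], path) -> pd.DataFrame:
    """Write a TSV feature table (fixed column order); returns the frame."""
    df = feature_table(records)
    df.to_csv(path, sep="\t", index=False)
    return df
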