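"""Rotamer-library dye attachment with steric clash rejection.

Explicit fluorophore conformers (rotamers) are rigidly attached at labeled
cysteines of atomistic ensemble frames, rejecting poses that clash with the
chain, and the surviving donor-acceptor center distances give per-frame mean
transfer efficiencies suitable for maximum-entropy reweighting.

A rotamer is a rigid set of heavy-atom coordinates expressed in the local
attachment frame: origin at the gamma-sulfur, +z along the C-beta ->
S-gamma axis (ideal S-gamma geometry is enforced by construction), plus the
index of the dye-center atom used for distance measurement.  Per frame and
site, ``n_trials`` rotamers are drawn with replacement; a trial fails if
any dye atom comes within ``clash_radius`` of a protein atom (the
attachment residue excluded).  If both sites collect at least
``min_success`` successful attachments, all donor-acceptor rotamer pairs
are combined, mutually clashing pairs are discarded (same radius), and the
surviving center-center distances are recorded; otherwise the frame is
rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Rotamer",
    "RotamerLibrary",
    "AttachmentSite",
    "FrameResult",
    "make_synthetic_library",
    "attach_dyes",
    "frame_mean_efficiency",
    "ensemble_efficiencies",
]


@dataclass
class Rotamer:
    """Rigid rotamer coordinates (local frame, nm) and dye-center index."""

    coords: np.ndarray
    center_index: int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if not 0 <= self.center_index < len(self.coords):
            raise ValueError("dye-center index outside rotamer")


@dataclass
class RotamerLibrary:
    """Named rotamer set for one dye."""

    name: str
    rotamers: list[Rotamer]

    def __post_init__(self) -> None:
        if not self.rotamers:
            raise ValueError("rotamer library must contain >= 1 rotamer")

    def __len__(self) -> int:
        return len(self.rotamers)


@dataclass
class AttachmentSite:
    """Attachment geometry of one labeling site within a frame.

    ``cb_index`` and ``sg_index`` are atom columns of the frame coordinate
    array (C-beta and S-gamma of the labeled Cys); ``residue_atoms`` lists
    all atom columns of that residue, excluded from clash checks.
    """

    cb_index: int
    sg_index: int
    residue_atoms: np.ndarray = field(default_factory=lambda: np.array([], int))


def make_synthetic_library(
    name: str,
    n_rotamers: int,
    seed: int,
    n_atoms: int = 6,
    reach_nm: float = 1.2,
    spread: float = 0.35,
) -> RotamerLibrary:
    """Small synthetic rotamer library for tests and demonstrations.

    Each rotamer is a jittered arc extending to ``reach_nm`` along +z with
    random lateral displacements of scale ``spread``; the dye center is the
    terminal atom.  (A stand-in for an external rotamer library; clearly
    synthetic, not chemically derived.)
    """
    rng = np.random.default_rng(seed)
    rotamers = []
    for _ in range(n_rotamers):
        z = np.linspace(0.15, reach_nm, n_atoms)
        lateral = rng.normal(scale=spread, size=(n_atoms, 2)) * (z / z[-1])[:, None]
        coords = np.column_stack([lateral, z])
        rotamers.append(Rotamer(coords, center_index=n_atoms - 1))
    return RotamerLibrary(name, rotamers)


def _attachment_rotation(cb: np.ndarray, sg: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping local +z onto the C-beta -> S-gamma axis."""
    z = sg - cb
    nz = np.linalg.norm(z)
    if nz < 1e-9:
        raise ValueError("degenerate C-beta/S-gamma geometry")
    z = z / nz
    ref = np.array([1.0, 0.0, 0.0])
    if abs(z @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    x = ref - (ref @ z) * z
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def _place(rotamer: Rotamer, rot: np.ndarray, origin: np.ndarray) -> np.ndarray:
    return rotamer.coords @ rot.T + origin


def _clashes(dye_xyz: np.ndarray, other_xyz: np.ndarray,
             radius: float) -> bool:
    if len(other_xyz) == 0:
        return False
    d2 = np.sum((dye_xyz[:, None, :] - other_xyz[None, :, :]) ** 2, axis=-1)
    return bool(np.min(d2) < radius ** 2)


@dataclass
class FrameResult:
    """Accepted dye-pair distances (nm) for one frame, or a rejection."""

    accepted: bool
    distances: np.ndarray
    n_success_site1: int = 0
    n_success_site2: int = 0
    reason: str = ""


def attach_dyes(
    frame_xyz: np.ndarray,
    site1: AttachmentSite,
    site2: AttachmentSite,
    library1: RotamerLibrary,
    library2: RotamerLibrary,
    seed: int,
    n_trials: int = 50,
    clash_radius: float = 0.5,
    min_success: int = 20,
) -> FrameResult:
    """Attach dye rotamers at both sites of one frame (coordinates in nm).

    Returns the surviving center-center distance set, or a rejected
    ``FrameResult`` when either site fails to reach ``min_success``
    non-clashing attachments in ``n_trials`` draws.  Distinct successful
    rotamers are combined pairwise; mutually clashing dye pairs are removed
    with the same radius.  Deterministic under ``seed``.
    """
    frame_xyz = np.asarray(frame_xyz, dtype=float)
    rng = np.random.default_rng(seed)
    placements: list[dict[int, np.ndarray]] = []
    successes: list[int] = []
    for site, library in ((site1, library1), (site2, library2)):
        for idx in (site.cb_index, site.sg_index):
            if not 0 <= idx < len(frame_xyz):
                raise ValueError(
                    f"attachment atom index {idx} missing from frame")
        rot = _attachment_rotation(frame_xyz[site.cb_index],
                                   frame_xyz[site.sg_index])
        origin = frame_xyz[site.sg_index]
        env = np.delete(frame_xyz, np.asarray(site.residue_atoms, int),
                        axis=0)
        accepted: dict[int, np.ndarray] = {}
        n_success = 0
        draws = rng.integers(0, len(library), size=n_trials)
        for ridx in draws:
            ridx = int(ridx)
            if ridx in accepted:
                n_success += 1          # same pose, known to fit
                continue
            xyz = _place(library.rotamers[ridx], rot, origin)
            if not _clashes(xyz, env, clash_radius):
                accepted[ridx] = xyz
                n_success += 1
        placements.append(accepted)
        successes.append(n_success)

    if min(successes) < min_success:
        return FrameResult(False, np.array([]), successes[0], successes[1],
                           reason="insufficient successful attachments")

    c1 = library1.rotamers
    c2 = library2.rotamers
    dists = []
    for i1, xyz1 in placements[0].items():
        for i2, xyz2 in placements[1].items():
            if _clashes(xyz1, xyz2, clash_radius):
                continue
            p1 = xyz1[c1[i1].center_index]
            p2 = xyz2[c2[i2].center_index]
            dists.append(float(np.linalg.norm(p1 - p2)))
    if not dists:
        return FrameResult(False, np.array([]), successes[0], successes[1],
                           reason="all dye pairs mutually clashing")
    return FrameResult(True, np.array(dists), successes[0], successes[1])


def frame_mean_efficiency(distances: np.ndarray, R0_nm: float = 6.0) -> float:
    """Mean Foerster efficiency over surviving dye-pair distances (nm)."""
    distances = np.asarray(distances, dtype=float)
    if distances.size == 0:
        raise ValueError("empty distance set; frame should be excluded")
    return float(np.mean(1.0 / (1.0 + (distances / R0_nm) ** 6)))


def sites_from_pdb(path, residue1: int, residue2: int):
    """Attachment sites and coordinates from a multi-model PDB ensemble.

    ``residue1``/``residue2`` are 0-based residue indices of the labeled
    cysteines; their CB and SG atoms define the attachment frames.  Returns
    (frames array in nm, site1, site2).
    """
    import mdtraj as md

    traj = md.load(str(path))
    top = traj.topology
    sites = []
    for ridx in (residue1, residue2):
        res = top.residue(ridx)
        atoms = {a.name: a.index for a in res.atoms}
        if "CB" not in atoms or "SG" not in atoms:
            raise ValueError(
                f"residue {ridx} ({res.name}) lacks CB/SG attachment atoms")
        sites.append(AttachmentSite(
            cb_index=atoms["CB"], sg_index=atoms["SG"],
            residue_atoms=np.array([a.index for a in res.atoms])))
    return np.asarray(traj.xyz, dtype=float), sites[0], sites[1]


def ensemble_efficiencies(
    frames: np.ndarray,
    site1: AttachmentSite,
    site2: AttachmentSite,
    library1: RotamerLibrary,
    library2: RotamerLibrary,
    seed: int,
    R0_nm: float = 6.0,
    **kwargs,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame mean efficiencies over an ensemble.

    Returns (frame indices of accepted frames, E_frame array) ready for
    maximum-entropy reweighting.
    """
    idx, effs = [], []
    for f, xyz in enumerate(frames):
        res = attach_dyes(xyz, site1, site2, library1, library2,
                          seed=seed + f, **kwargs)
        if res.accepted:
            idx.append(f)
            effs.append(frame_mean_efficiency(res.distances, R0_nm))
    return np.array(idx, dtype=int), np.array(effs, dtype=float)
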