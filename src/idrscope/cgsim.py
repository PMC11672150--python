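"""Coarse-grained stickiness (HPS) model with explicit dye beads.

One bead per residue, linked by stiff harmonic bonds (r0 = 0.38 nm,
k = 481.4 kJ nm^-2 mol^-1).  Nonbonded interactions combine

* an Ashbaugh-Hatch (modified Weeks-Chandler-Andersen) potential whose
  attractive part is scaled by the arithmetic mean of the per-bead
  "stickiness" parameters lambda:

      U(r) = Phi_LJ(r) + (1 - lam_ij) * eps      for r <= 2^(1/6) sigma_ij
           = lam_ij * Phi_LJ(r)                  otherwise,

  with Phi_LJ = 4 eps [(sigma_ij/r)^12 - (sigma_ij/r)^6],
  lam_ij = (lam_i + lam_j)/2, sigma_ij = (sigma_i + sigma_j)/2; and

* a Debye-Hueckel screened Coulomb term between charged beads with the
  Debye length set by the ionic strength.

Fluorophores are represented as small bead subgraphs (negatively charged,
neutral, positively charged and linker bead types) attached at the labeling
cysteines; harmonic angle potentials (k = 48.14 kJ rad^-2 mol^-1, theta0 =
pi/2 at branch points and pi elsewhere) act only on the colored dye beads,
not on the linker beads.  Dye beads have a mass of 100 amu.

Dynamics are propagated with a BAOAB-discretized Langevin integrator
(default 300 K, 10 fs time step, friction 1 ps^-1); identical seeds give
bit-identical trajectories.  Units: nm, ps, amu, kJ/mol, elementary charge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import constants as _const

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        if args and callable(args[0]):
            return args[0]
        return wrap

__all__ = [
    "KB",
    "KE",
    "HPSParameterSet",
    "FRETConstruct",
    "CGTopology",
    "Trajectory",
    "DEFAULT_DYE_SPECS",
    "build_topology",
    "pair_energy",
    "debye_length_nm",
    "run_langevin",
    "total_potential_energy",
    "potential_energy_reference",
    "fret_from_trajectory",
]

#: Boltzmann constant, kJ mol^-1 K^-1.
KB = _const.R / 1000.0
#: Coulomb prefactor e^2 / (4 pi eps0), kJ mol^-1 nm e^-2.
KE = (
    _const.e ** 2 * _const.N_A
    / (4.0 * np.pi * _const.epsilon_0) / 1000.0 * 1e9
)

BOND_R0 = 0.38            # nm
BOND_K = 481.4            # kJ nm^-2 mol^-1
ANGLE_K = 48.14           # kJ rad^-2 mol^-1
DYE_BEAD_MASS = 100.0     # amu

AA3 = "ACDEFGHIKLMNPQRSTVWY"

# Per-residue stickiness (Kapcha-Rossky-derived scale of the HPS lineage),
# bead diameter (nm, from average residue volumes) and mass (amu).
_RESIDUE_TABLE: dict[str, tuple[float, float, float]] = {
    # aa: (lambda, sigma_nm, mass_amu)
    "A": (0.730, 0.504, 71.08),
    "R": (0.000, 0.656, 156.19),
    "N": (0.432, 0.568, 114.10),
    "D": (0.378, 0.558, 115.09),
    "C": (0.595, 0.548, 103.14),
    "Q": (0.514, 0.602, 128.13),
    "E": (0.459, 0.592, 129.12),
    "G": (0.649, 0.450, 57.05),
    "H": (0.514, 0.608, 137.14),
    "I": (0.973, 0.618, 113.16),
    "L": (0.973, 0.618, 113.16),
    "K": (0.514, 0.636, 128.17),
    "M": (0.838, 0.618, 131.19),
    "F": (1.000, 0.636, 147.18),
    "P": (1.000, 0.556, 97.12),
    "S": (0.595, 0.518, 87.08),
    "T": (0.676, 0.562, 101.10),
    "W": (0.946, 0.678, 186.21),
    "Y": (0.865, 0.646, 163.18),
    "V": (0.892, 0.586, 99.07),
}

_RESIDUE_CHARGE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0}

#: Dye bead categories used in the lambda table.
DYE_BEAD_TYPES = ("dye_neg", "dye_neu", "dye_pos", "dye_lin")

_DEFAULT_DYE_LAMBDA = {"dye_neg": 0.3, "dye_neu": 0.5,
                       "dye_pos": 0.3, "dye_lin": 0.2}
_DEFAULT_DYE_SIGMA = {"dye_neg": 0.60, "dye_neu": 0.60,
                      "dye_pos": 0.60, "dye_lin": 0.45}


def _dye_spec(name, net_charge, n_core, n_linker=3):
    """Synthetic dye bead graph: linker chain into a branched colored core.

    The core is a chain of ``n_core`` colored beads; charged beads (to reach
    ``net_charge``) branch off the central core bead.  The dye center is the
    middle core bead.  Geometry is an approximation that preserves bead
    count, connectivity, net charge and branch structure.
    """
    beads, bonds = [], []
    for i in range(n_linker):
        beads.append({"name": f"L{i}", "type": "dye_lin", "charge": 0.0})
        bonds.append([i - 1, i])       # bond [-1, 0] attaches to the Cys bead
    core0 = n_linker
    for i in range(n_core):
        beads.append({"name": f"C{i}", "type": "dye_neu", "charge": 0.0})
        bonds.append([core0 + i - 1, core0 + i])
    center = core0 + n_core // 2
    for i in range(abs(int(net_charge))):
        btype = "dye_neg" if net_charge < 0 else "dye_pos"
        beads.append({"name": f"Q{i}", "type": btype,
                      "charge": float(np.sign(net_charge))})
        bonds.append([center, len(beads) - 1])
    return {"name": name, "beads": beads, "bonds": bonds,
            "dye_center": center, "net_charge": float(net_charge)}


#: Shipped default dye specifications (synthetic geometries; net charges
#: Alexa 488 = Alexa 594 = -2, Cy3B = 0, CF660R = -1).
DEFAULT_DYE_SPECS: dict[str, dict] = {
    "Alexa488": _dye_spec("Alexa488", -2, n_core=3),
    "Alexa594": _dye_spec("Alexa594", -2, n_core=4),
    "Cy3B": _dye_spec("Cy3B", 0, n_core=3),
    "CF660R": _dye_spec("CF660R", -1, n_core=4),
}


@dataclass
class HPSParameterSet:
    """Per-bead-type stickiness/diameter/charge/mass plus global settings."""

    lam: dict[str, float] = field(default_factory=dict)
    sigma: dict[str, float] = field(default_factory=dict)
    charge: dict[str, float] = field(default_factory=dict)
    mass: dict[str, float] = field(default_factory=dict)
    epsilon: float = 0.8368          # kJ/mol (0.2 kcal/mol)
    cutoff_sr: float = 2.0           # nm, short-range cutoff
    cutoff_dh: float = 3.5           # nm, Debye-Hueckel cutoff
    ionic_strength_mM: float = 165.0
    temperature_K: float = 300.0
    dielectric: float = 80.0

    @classmethod
    def default(cls, **overrides) -> "HPSParameterSet":
        lam, sigma, charge, mass = {}, {}, {}, {}
        for aa, (l, s, m) in _RESIDUE_TABLE.items():
            lam[aa], sigma[aa], mass[aa] = l, s, m
            charge[aa] = _RESIDUE_CHARGE.get(aa, 0.0)
        for t in DYE_BEAD_TYPES:
            lam[t] = _DEFAULT_DYE_LAMBDA[t]
            sigma[t] = _DEFAULT_DYE_SIGMA[t]
            charge[t] = 0.0          # bead charge set per dye-spec bead
            mass[t] = DYE_BEAD_MASS
        ps = cls(lam=lam, sigma=sigma, charge=charge, mass=mass)
        for key, val in overrides.items():
            setattr(ps, key, val)
        return ps

    def debye_length_nm(self) -> float:
        return debye_length_nm(self.ionic_strength_mM, self.temperature_K,
                               self.dielectric)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "lambda": self.lam, "sigma": self.sigma,
                "charge": self.charge, "mass": self.mass,
                "epsilon": self.epsilon, "cutoff_sr": self.cutoff_sr,
                "cutoff_dh": self.cutoff_dh,
                "ionic_strength_mM": self.ionic_strength_mM,
                "temperature_K": self.temperature_K,
                "dielectric": self.dielectric,
            }, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "HPSParameterSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(lam=d["lambda"], sigma=d["sigma"], charge=d["charge"],
                   mass=d["mass"], epsilon=d["epsilon"],
                   cutoff_sr=d["cutoff_sr"], cutoff_dh=d["cutoff_dh"],
                   ionic_strength_mM=d["ionic_strength_mM"],
                   temperature_K=d["temperature_K"],
                   dielectric=d["dielectric"])


def debye_length_nm(ionic_strength_mM: float, T: float = 300.0,
                    eps_r: float = 80.0) -> float:
    """Debye screening length (nm) of a 1:1 electrolyte."""
    I = ionic_strength_mM * _const.N_A  # ions/m^3 per mol/m^3 (mM = mol/m^3)
    lam2 = (eps_r * _const.epsilon_0 * _const.k * T) / (2.0 * _const.e ** 2 * I)
    return float(np.sqrt(lam2) * 1e9)


@dataclass
class FRETConstruct:
    """A labeled chain: sequence, two labeling sites (0-based), dye pair, R0."""

    sequence: str
    site1: int
    site2: int
    dye1: str = "Cy3B"
    dye2: str = "CF660R"
    R0_nm: float = 6.0


@dataclass
class CGTopology:
    """Bead chain plus optional dye subgraphs, with bonded terms."""

    bead_types: list[str]
    bead_charges: np.ndarray
    bonds: np.ndarray                 # (n_bonds, 2) int
    angles: np.ndarray                # (n_angles, 3) int
    angle_theta0: np.ndarray          # rad
    dye_center_beads: tuple[int, int] | None = None
    labels: list[str] = field(default_factory=list)

    @property
    def n_beads(self) -> int:
        return len(self.bead_types)

    def to_dict(self) -> dict:
        return {
            "bead_types": list(self.bead_types),
            "bead_charges": [float(q) for q in self.bead_charges],
            "bonds": [[int(a), int(b)] for a, b in self.bonds],
            "angles": [[int(a), int(b), int(c)] for a, b, c in self.angles],
            "angle_theta0": [float(t) for t in self.angle_theta0],
            "dye_center_beads": (list(self.dye_center_beads)
                                 if self.dye_center_beads else None),
            "labels": list(self.labels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CGTopology":
        return cls(
            bead_types=list(d["bead_types"]),
            bead_charges=np.asarray(d["bead_charges"], dtype=float),
            bonds=np.asarray(d["bonds"], dtype=np.int64).reshape(-1, 2),
            angles=np.asarray(d["angles"], dtype=np.int64).reshape(-1, 3),
            angle_theta0=np.asarray(d["angle_theta0"], dtype=float),
            dye_center_beads=(tuple(d["dye_center_beads"])
                              if d.get("dye_center_beads") else None),
            labels=list(d.get("labels", [])),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "CGTopology":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


class TopologyError(ValueError):
    pass


def _attach_dye(types, charges, bonds, labels, spec: dict, site: int) -> int:
    """Append one dye subgraph bonded to ``site``; returns dye-center index."""
    if not isinstance(spec, dict) or "beads" not in spec or "bonds" not in spec:
        raise TopologyError("malformed dye spec: need 'beads' and 'bonds'")
    offset = len(types)
    for bead in spec["beads"]:
        if bead["type"] not in DYE_BEAD_TYPES:
            raise TopologyError(f"unknown dye bead type {bead['type']!r}")
        types.append(bead["type"])
        charges.append(float(bead.get("charge", 0.0)))
        labels.append(f"{spec.get('name', 'dye')}:{bead['name']}")
    for a, b in spec["bonds"]:
        ia = site if a == -1 else offset + a
        ib = site if b == -1 else offset + b
        bonds.append((ia, ib))
    return offset + int(spec["dye_center"])


def _dye_angles(types, bonds, first_dye_bead: int):
    """Harmonic angles centered on colored (non-linker) dye beads only."""
    n = len(types)
    neighbors = [[] for _ in range(n)]
    for a, b in bonds:
        neighbors[a].append(b)
        neighbors[b].append(a)
    triplets, theta0 = [], []
    for b in range(first_dye_bead, n):
        if types[b] == "dye_lin" or not types[b].startswith("dye"):
            continue
        nbrs = sorted(neighbors[b])
        if len(nbrs) < 2:
            continue
        t0 = np.pi / 2.0 if len(nbrs) >= 3 else np.pi
        for i in range(len(nbrs)):
            for j in range(i + 1, len(nbrs)):
                triplets.append((nbrs[i], b, nbrs[j]))
                theta0.append(t0)
    return triplets, theta0


def build_topology(
    construct: FRETConstruct,
    dye_specs: dict[str, dict] | None = None,
    with_dyes: bool = True,
    strict_cys: bool = False,
) -> CGTopology:
    """Residue chain plus dye subgraphs attached at the labeling sites."""
    seq = construct.sequence.upper()
    for aa in seq:
        if aa not in _RESIDUE_TABLE:
            raise TopologyError(f"unknown residue {aa!r}")
    types: list[str] = list(seq)
    charges = [_RESIDUE_CHARGE.get(aa, 0.0) for aa in seq]
    labels = [f"{aa}{i + 1}" for i, aa in enumerate(seq)]
    bonds = [(i, i + 1) for i in range(len(seq) - 1)]

    centers = None
    first_dye_bead = len(types)
    if with_dyes:
        specs = dye_specs or DEFAULT_DYE_SPECS
        cts = []
        for site, dye in ((construct.site1, construct.dye1),
                          (construct.site2, construct.dye2)):
            if not (0 <= site < len(seq)):
                raise TopologyError(f"labeling site {site} outside sequence")
            if seq[site] != "C":
                msg = f"labeling site {site} is {seq[site]}, not Cys"
                if strict_cys:
                    raise TopologyError(msg)
                import warnings

                warnings.warn(msg, stacklevel=2)
            if dye not in specs:
                raise TopologyError(f"no dye spec for {dye!r}")
            cts.append(_attach_dye(types, charges, bonds, labels,
                                   specs[dye], site))
        centers = (cts[0], cts[1])

    triplets, theta0 = _dye_angles(types, bonds, first_dye_bead)
    return CGTopology(
        bead_types=types,
        bead_charges=np.asarray(charges, dtype=float),
        bonds=np.asarray(bonds, dtype=np.int64).reshape(-1, 2),
        angles=np.asarray(triplets, dtype=np.int64).reshape(-1, 3),
        angle_theta0=np.asarray(theta0, dtype=float),
        dye_center_beads=centers,
        labels=labels,
    )


# ---------------------------------------------------------------------------
# pair potential


def pair_energy(r, type_i: str, type_j: str, params: HPSParameterSet,
                q_i: float | None = None, q_j: float | None = None):
    """Nonbonded pair energy (kJ/mol) at separation r (nm), without cutoffs.

    Ashbaugh-Hatch short-range term plus (if both beads are charged) the
    unscreened-prefactor Debye-Hueckel term.  Charges default to the
    parameter-set values for the two types.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair separation must be positive")
    lam = 0.5 * (params.lam[type_i] + params.lam[type_j])
    sig = 0.5 * (params.sigma[type_i] + params.sigma[type_j])
    eps = params.epsilon
    s6 = (sig / r) ** 6
    phi = 4.0 * eps * (s6 * s6 - s6)
    rmin = 2.0 ** (1.0 / 6.0) * sig
    u = np.where(r <= rmin, phi + (1.0 - lam) * eps, lam * phi)
    qi = params.charge[type_i] if q_i is None else q_i
    qj = params.charge[type_j] if q_j is None else q_j
    if qi * qj != 0.0:
        ld = params.debye_length_nm()
        u = u + KE * qi * qj / (params.dielectric * r) * np.exp(-r / ld)
    return u if u.shape else float(u)


# ---------------------------------------------------------------------------
# simulation kernels


@njit(cache=True)
def _forces_energy(pos, lam_ij, sig_ij, qq_ij, excl, eps, rc_sr, rc_dh,
                   ld, bonds, bond_r0, bond_k,
                   angles, ang_t0, ang_k, forces):
    n = pos.shape[0]
    for i in range(n):
        for d in range(3):
            forces[i, d] = 0.0
    epot = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if excl[i, j]:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            r = np.sqrt(r2)
            if r < 1e-9:
                r = 1e-9
            fmag = 0.0   # dU/dr (scalar); force = -(dU/dr) * rhat
            if r < rc_sr:
                sig = sig_ij[i, j]
                lam = lam_ij[i, j]
                s6 = (sig / r) ** 6
                s12 = s6 * s6
                phi = 4.0 * eps * (s12 - s6)
                dphi = 4.0 * eps * (-12.0 * s12 + 6.0 * s6) / r
                rmin = 1.122462048309373 * sig
                if r <= rmin:
                    epot += phi + (1.0 - lam) * eps
                    fmag += dphi
                else:
                    epot += lam * phi
                    fmag += lam * dphi
            qq = qq_ij[i, j]
            if qq != 0.0 and r < rc_dh:
                u = qq / r * np.exp(-r / ld)
                epot += u
                fmag += -u * (1.0 / r + 1.0 / ld)
            if fmag != 0.0:
                fx = -fmag * dx / r
                fy = -fmag * dy / r
                fz = -fmag * dz / r
                forces[i, 0] += fx
                forces[i, 1] += fy
                forces[i, 2] += fz
                forces[j, 0] -= fx
                forces[j, 1] -= fy
                forces[j, 2] -= fz
    for bi in range(bonds.shape[0]):
        a = bonds[bi, 0]
        b = bonds[bi, 1]
        dx = pos[a, 0] - pos[b, 0]
        dy = pos[a, 1] - pos[b, 1]
        dz = pos[a, 2] - pos[b, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-9:
            r = 1e-9
        dr = r - bond_r0
        epot += 0.5 * bond_k * dr * dr
        fmag = bond_k * dr
        fx = -fmag * dx / r
        fy = -fmag * dy / r
        fz = -fmag * dz / r
        forces[a, 0] += fx
        forces[a, 1] += fy
        forces[a, 2] += fz
        forces[b, 0] -= fx
        forces[b, 1] -= fy
        forces[b, 2] -= fz
    for ai in range(angles.shape[0]):
        a = angles[ai, 0]
        b = angles[ai, 1]
        c = angles[ai, 2]
        bax = pos[a, 0] - pos[b, 0]
        bay = pos[a, 1] - pos[b, 1]
        baz = pos[a, 2] - pos[b, 2]
        bcx = pos[c, 0] - pos[b, 0]
        bcy = pos[c, 1] - pos[b, 1]
        bcz = pos[c, 2] - pos[b, 2]
        la = np.sqrt(bax * bax + bay * bay + baz * baz)
        lc = np.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
        if la < 1e-9:
            la = 1e-9
        if lc < 1e-9:
            lc = 1e-9
        cosb = (bax * bcx + bay * bcy + baz * bcz) / (la * lc)
        if cosb > 1.0:
            cosb = 1.0
        if cosb < -1.0:
            cosb = -1.0
        theta = np.arccos(cosb)
        dth = theta - ang_t0[ai]
        epot += 0.5 * ang_k * dth * dth
        sinb = np.sqrt(1.0 - cosb * cosb)
        if sinb < 1e-6:
            sinb = 1e-6
        coef = ang_k * dth / sinb   # = -dU/dcos(theta)... chain rule below
        # dcos/dra = bc/(la*lc) - cos * ba/la^2  etc.
        dax = coef * ((bcx / (la * lc)) - cosb * bax / (la * la))
        day = coef * ((bcy / (la * lc)) - cosb * bay / (la * la))
        daz = coef * ((bcz / (la * lc)) - cosb * baz / (la * la))
        dcx = coef * ((bax / (la * lc)) - cosb * bcx / (lc * lc))
        dcy = coef * ((bay / (la * lc)) - cosb * bcy / (lc * lc))
        dcz = coef * ((baz / (la * lc)) - cosb * bcz / (lc * lc))
        forces[a, 0] += dax
        forces[a, 1] += day
        forces[a, 2] += daz
        forces[c, 0] += dcx
        forces[c, 1] += dcy
        forces[c, 2] += dcz
        forces[b, 0] -= dax + dcx
        forces[b, 1] -= day + dcy
        forces[b, 2] -= daz + dcz
    return epot


@njit(cache=True)
def _baoab(pos, masses, lam_ij, sig_ij, qq_ij, excl, eps, rc_sr, rc_dh, ld,
           bonds, bond_r0, bond_k, angles, ang_t0, ang_k,
           dt, friction, kT, n_steps, stride, seed, e_abort):
    np.random.seed(seed)
    n = pos.shape[0]
    vel = np.empty((n, 3))
    for i in range(n):
        s = np.sqrt(kT / masses[i])
        for d in range(3):
            vel[i, d] = s * np.random.standard_normal()
    forces = np.empty((n, 3))
    epot = _forces_energy(pos, lam_ij, sig_ij, qq_ij, excl, eps, rc_sr,
                          rc_dh, ld, bonds, bond_r0, bond_k, angles,
                          ang_t0, ang_k, forces)
    c1 = np.exp(-friction * dt)
    c2 = np.sqrt(1.0 - c1 * c1)
    n_save = n_steps // stride
    traj = np.empty((n_save, n, 3))
    epots = np.empty(n_save)
    ekins = np.empty(n_save)
    isave = 0
    for step in range(n_steps):
        for i in range(n):
            f = 0.5 * dt / masses[i]
            for d in range(3):
                vel[i, d] += f * forces[i, d]
                pos[i, d] += 0.5 * dt * vel[i, d]
        for i in range(n):
            s = np.sqrt(kT / masses[i])
            for d in range(3):
                vel[i, d] = c1 * vel[i, d] + c2 * s * np.random.standard_normal()
        for i in range(n):
            for d in range(3):
                pos[i, d] += 0.5 * dt * vel[i, d]
        epot = _forces_energy(pos, lam_ij, sig_ij, qq_ij, excl, eps, rc_sr,
                              rc_dh, ld, bonds, bond_r0, bond_k, angles,
                              ang_t0, ang_k, forces)
        for i in range(n):
            f = 0.5 * dt / masses[i]
            for d in range(3):
                vel[i, d] += f * forces[i, d]
        if np.abs(epot) > e_abort or np.isnan(epot):
            return traj[:isave], epots[:isave], ekins[:isave], -1
        if (step + 1) % stride == 0:
            for i in range(n):
                for d in range(3):
                    traj[isave, i, d] = pos[i, d]
            ek = 0.0
            for i in range(n):
                ek += 0.5 * masses[i] * (vel[i, 0] ** 2 + vel[i, 1] ** 2
                                         + vel[i, 2] ** 2)
            epots[isave] = epot
            ekins[isave] = ek
            isave += 1
    return traj, epots, ekins, 0


@dataclass
class Trajectory:
    """Saved frames (nm) with per-frame energies and run metadata."""

    frames: np.ndarray               # (n_frames, n_beads, 3)
    potential: np.ndarray
    kinetic: np.ndarray
    dt_ps: float
    stride: int
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def equilibrated(self, fraction: float | None = None) -> np.ndarray:
        frac = self.meta.get("equilibration_fraction", 0.0) \
            if fraction is None else fraction
        start = int(np.floor(self.n_frames * frac))
        return self.frames[start:]


def _pair_tables(topology: CGTopology, params: HPSParameterSet):
    types = topology.bead_types
    n = len(types)
    lam = np.array([params.lam[t] for t in types])
    sig = np.array([params.sigma[t] for t in types])
    q = topology.bead_charges
    lam_ij = 0.5 * (lam[:, None] + lam[None, :])
    sig_ij = 0.5 * (sig[:, None] + sig[None, :])
    qq_ij = KE * np.outer(q, q) / params.dielectric
    excl = np.zeros((n, n), dtype=np.bool_)
    for a, b in topology.bonds:
        excl[a, b] = excl[b, a] = True
    return lam_ij, sig_ij, qq_ij, excl


def _initial_positions(topology: CGTopology, seed: int) -> np.ndarray:
    """Loose random-walk start along bonds (bond length 0.38 nm)."""
    rng = np.random.default_rng(seed)
    n = topology.n_beads
    pos = np.zeros((n, 3))
    placed = np.zeros(n, dtype=bool)
    placed[0] = True
    # breadth-first placement over the bond graph
    adj = [[] for _ in range(n)]
    for a, b in topology.bonds:
        adj[a].append(b)
        adj[b].append(a)
    queue = [0]
    while queue:
        cur = queue.pop(0)
        for nb in adj[cur]:
            if not placed[nb]:
                done = np.nonzero(placed)[0]
                for _ in range(100):  # avoid hard-core overlaps at start
                    step = rng.normal(size=3)
                    step *= BOND_R0 / np.linalg.norm(step)
                    cand = pos[cur] + step
                    d = np.linalg.norm(pos[done] - cand, axis=1)
                    d = d[done != cur]
                    if d.size == 0 or d.min() > 0.5:
                        break
                pos[nb] = cand
                placed[nb] = True
                queue.append(nb)
    return pos


class SimulationDiverged(RuntimeError):
    pass


def run_langevin(
    topology: CGTopology,
    params: HPSParameterSet,
    n_steps: int,
    seed: int,
    dt_fs: float = 10.0,
    friction_ps: float = 1.0,
    temperature_K: float | None = None,
    stride: int = 1000,
    equilibration_fraction: float = 1.0 / 6.0,
    initial_positions: np.ndarray | None = None,
    energy_abort: float = 1e7,
) -> Trajectory:
    """Propagate BAOAB Langevin dynamics; identical seeds are bit-identical.

    ``stride`` is in steps (default 1000 steps = 10 ps at dt = 10 fs); the
    first ``equilibration_fraction`` of frames is marked as equilibration
    (1/6 mirrors discarding 100 ns of a 600 ns run).
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    T = params.temperature_K if temperature_K is None else temperature_K
    lam_ij, sig_ij, qq_ij, excl = _pair_tables(topology, params)
    masses = np.array([params.mass[t] for t in topology.bead_types])
    pos = (_initial_positions(topology, seed) if initial_positions is None
           else np.array(initial_positions, dtype=float))
    dt = dt_fs * 1e-3  # ps
    angles = topology.angles if len(topology.angles) else \
        np.zeros((0, 3), dtype=np.int64)
    traj, epot, ekin, status = _baoab(
        pos, masses, lam_ij, sig_ij, qq_ij, excl, params.epsilon,
        params.cutoff_sr, params.cutoff_dh, params.debye_length_nm(),
        topology.bonds.astype(np.int64), BOND_R0, BOND_K,
        angles.astype(np.int64), topology.angle_theta0, ANGLE_K,
        dt, friction_ps, KB * T, int(n_steps), int(stride),
        int(seed) % (2 ** 31), float(energy_abort),
    )
    if status != 0:
        raise SimulationDiverged(
            f"potential energy exceeded {energy_abort} kJ/mol after "
            f"{len(epot)} saved frames"
        )
    return Trajectory(
        frames=traj, potential=epot, kinetic=ekin, dt_ps=dt, stride=stride,
        meta={
            "seed": int(seed), "temperature_K": T, "friction_ps": friction_ps,
            "equilibration_fraction": equilibration_fraction,
            "n_steps": int(n_steps),
        },
    )


def total_potential_energy(
    positions: np.ndarray, topology: CGTopology, params: HPSParameterSet
) -> float:
    """Potential energy of one configuration via the simulation kernel."""
    lam_ij, sig_ij, qq_ij, excl = _pair_tables(topology, params)
    forces = np.empty_like(positions)
    angles = topology.angles if len(topology.angles) else \
        np.zeros((0, 3), dtype=np.int64)
    return float(_forces_energy(
        np.asarray(positions, dtype=float), lam_ij, sig_ij, qq_ij, excl,
        params.epsilon, params.cutoff_sr, params.cutoff_dh,
        params.debye_length_nm(), topology.bonds.astype(np.int64), BOND_R0,
        BOND_K, angles.astype(np.int64), topology.angle_theta0, ANGLE_K,
        forces,
    ))


def potential_energy_reference(
    positions: np.ndarray, topology: CGTopology, params: HPSParameterSet
) -> float:
    """Independent O(N^2) double-loop energy evaluation (pure numpy)."""
    pos = np.asarray(positions, dtype=float)
    n = topology.n_beads
    types = topology.bead_types
    ld = params.debye_length_nm()
    excl = set()
    for a, b in topology.bonds:
        excl.add((min(a, b), max(a, b)))
    e = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in excl:
                continue
            r = float(np.linalg.norm(pos[i] - pos[j]))
            lam = 0.5 * (params.lam[types[i]] + params.lam[types[j]])
            sig = 0.5 * (params.sigma[types[i]] + params.sigma[types[j]])
            if r < params.cutoff_sr:
                s6 = (sig / r) ** 6
                phi = 4.0 * params.epsilon * (s6 * s6 - s6)
                if r <= 2 ** (1 / 6) * sig:
                    e += phi + (1.0 - lam) * params.epsilon
                else:
                    e += lam * phi
            qq = topology.bead_charges[i] * topology.bead_charges[j]
            if qq != 0.0 and r < params.cutoff_dh:
                e += KE * qq / (params.dielectric * r) * np.exp(-r / ld)
    for a, b in topology.bonds:
        r = float(np.linalg.norm(pos[a] - pos[b]))
        e += 0.5 * BOND_K * (r - BOND_R0) ** 2
    for (a, b, c), t0 in zip(topology.angles, topology.angle_theta0):
        v1 = pos[a] - pos[b]
        v2 = pos[c] - pos[b]
        cosb = np.clip(np.dot(v1, v2)
                       / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1)
        e += 0.5 * ANGLE_K * (np.arccos(cosb) - t0) ** 2
    return e


def fret_from_trajectory(
    traj: Trajectory | np.ndarray,
    dye_pair_beads: tuple[int, int],
    R0_nm: float,
    equilibrated_only: bool = True,
) -> tuple[float, np.ndarray]:
    """Per-frame Foerster efficiency between the dye-center beads.

    Returns (mean efficiency over post-equilibration frames, per-frame E).
    """
    if dye_pair_beads is None:
        raise ValueError("dye-center beads missing from topology")
    if isinstance(traj, Trajectory):
        frames = traj.equilibrated() if equilibrated_only else traj.frames
    else:
        frames = np.asarray(traj)
    i, j = dye_pair_beads
    if frames.shape[1] <= max(i, j):
        raise ValueError("dye bead index outside trajectory")
    r = np.linalg.norm(frames[:, i] - frames[:, j], axis=1)
    E = 1.0 / (1.0 + (r / R0_nm) ** 6)
    return float(E.mean()), E
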