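"""Torsion angles, hydrogen-bond descriptors and ring-current geometry.

Torsions follow the standard right-hand (IUPAC) sign convention and are
reported in [-180, 180).  Hydrogen-bond geometry is expressed in either a
donor-centered frame (r = H..O distance, theta at the acceptor oxygen
along O=C or O-C, rho the H..O-C-X dihedral) or the equivalent
acceptor-centered frame anchored on a residue's carbonyl oxygen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .config import RingConfig, SearchConfig
from .errors import GridShieldWarning, UndefinedTorsionError
from .grids import wrap_angle
from .model_io import ProteinModel, ResidueRecord
from .residues import AMINE_HYDROGENS, CHI_ATOMS, RING_ATOMS, SIDECHAIN_ACCEPTORS

_COLLINEAR_TOL = 1e-8


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion (degrees, [-180, 180)) about the p2->p3 axis."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = p3 - p2
    b2 = p4 - p3
    nb1 = np.linalg.norm(b1)
    if nb1 < _COLLINEAR_TOL:
        raise UndefinedTorsionError("central atoms coincide")
    b1u = b1 / nb1
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    if np.linalg.norm(v) < _COLLINEAR_TOL or np.linalg.norm(w) < _COLLINEAR_TOL:
        raise UndefinedTorsionError("collinear points leave the torsion undefined")
    ang = np.degrees(np.arctan2(np.dot(np.cross(b1u, v), w), np.dot(v, w)))
    return wrap_angle(float(ang))


def angle(p1, p2, p3) -> float:
    """Bond angle at p2, degrees in [0, 180]."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    u, v = _unit(p1 - p2), _unit(p3 - p2)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


@dataclass
class TorsionState:
    """Backbone and side-chain torsions of one residue, degrees.

    Angles undefined at termini or due to missing atoms are None; chi is
    truncated at the first undefined torsion.
    """

    phi: float | None = None
    psi: float | None = None
    omega: float | None = None
    chi: tuple[float, ...] = ()


def _try_dihedral(*points):
    if any(p is None for p in points):
        return None
    try:
        return dihedral(*points)
    except UndefinedTorsionError:
        return None


def torsions(model: ProteinModel, i: int) -> TorsionState:
    """Compute phi/psi/omega/chi for residue at list position ``i``."""
    res = model.residues[i]
    prev = model.neighbor(i, -1)
    nxt = model.neighbor(i, +1)

    def coord(r: ResidueRecord | None, name: str):
        if r is None:
            return None
        a = r.atom(name)
        return None if a is None else a.position

    prev_res = model.residues[prev] if prev is not None else None
    next_res = model.residues[nxt] if nxt is not None else None
    n, ca, c = coord(res, "N"), coord(res, "CA"), coord(res, "C")
    phi = _try_dihedral(coord(prev_res, "C"), n, ca, c)
    psi = _try_dihedral(n, ca, c, coord(next_res, "N"))
    omega = _try_dihedral(coord(prev_res, "CA"), coord(prev_res, "C"), n, ca)
    chis = []
    for quad in CHI_ATOMS[res.res_type]:
        pts = [coord(res, name) for name in quad]
        val = _try_dihedral(*pts)
        if val is None:
            if any(p is None for p in pts):
                warnings.warn(
                    f"{res.res_type}{res.seq_index}: side-chain atoms missing; "
                    f"chi truncated at chi{len(chis) + 1}",
                    GridShieldWarning, stacklevel=2)
            break
        chis.append(val)
    return TorsionState(phi=phi, psi=psi, omega=omega, chi=tuple(chis))


# ---------------------------------------------------------------------------
# hydrogen-bond geometry


@dataclass
class HBondGeometry:
    r: float
    theta: float
    rho: float
    donor_kind: str       # amide_H | amine_H | alpha_H
    acceptor_class: str   # amide_carbonyl | carboxyl | hydroxyl
    frame: str            # donor_centered | acceptor_centered
    donor_residue: int | None = None    # list positions, for bookkeeping
    acceptor_residue: int | None = None


def _acceptor_sites(model: ProteinModel, j: int):
    """Yield (O, C, rho_ref, acceptor_class) coordinate triples of residue j."""
    res = model.residues[j]
    if res.has_atom("O") and res.has_atom("C"):
        nxt = model.neighbor(j, +1)
        if nxt is not None and model.residues[nxt].has_atom("N"):
            ref = model.residues[nxt].coord("N")
        elif res.has_atom("CA"):
            ref = res.coord("CA")  # C-terminal fallback for the rho frame
        else:
            ref = None
        if ref is not None:
            yield res.coord("O"), res.coord("C"), ref, "amide_carbonyl"
    for entry in SIDECHAIN_ACCEPTORS.get(res.res_type, ()):
        o_name, c_name, ref_names, cls = entry
        if not (res.has_atom(o_name) and res.has_atom(c_name)):
            continue
        ref = None
        for rn in ref_names:
            if res.has_atom(rn):
                ref = res.coord(rn)
                break
        if ref is not None:
            yield res.coord(o_name), res.coord(c_name), ref, cls


def _geometry_for(h: np.ndarray, o: np.ndarray, c: np.ndarray,
                  ref: np.ndarray) -> tuple[float, float, float] | None:
    r = float(np.linalg.norm(h - o))
    th = angle(h, o, c)
    try:
        rho = dihedral(h, o, c, ref)
    except UndefinedTorsionError:
        rho = 0.0  # collinear H..O=C (theta ~ 180): rho is degenerate
    return r, th, rho


def find_primary_hbond(model: ProteinModel, i: int, donor: str,
                       search: SearchConfig | None = None,
                       donor_atom: str | None = None) -> HBondGeometry | None:
    """Nearest in-range acceptor for residue i's amide H or H-alpha donor.

    Acceptors in residue i itself and the backbone carbonyl of residue
    i-1 (already part of the tripeptide baseline) are excluded.  The
    returned r is clamped to the donor kind's scanned minimum.
    """
    search = search or SearchConfig()
    res = model.residues[i]
    if donor not in ("amide_H", "alpha_H"):
        raise ValueError(f"donor must be amide_H/alpha_H, got {donor!r}")
    if donor_atom is None:
        donor_atom = "H" if donor == "amide_H" else "HA"
    if not res.has_atom(donor_atom):
        return None
    h = res.coord(donor_atom)
    r_min, r_max = search.r_range(donor)
    prev = model.neighbor(i, -1)
    best: HBondGeometry | None = None
    for j in range(len(model.residues)):
        if j == i:
            continue
        for o, c, ref, cls in _acceptor_sites(model, j):
            if j == prev and cls == "amide_carbonyl":
                continue  # covered by the tripeptide backbone term
            geom = _geometry_for(h, o, c, ref)
            if geom is None:
                continue
            r, th, rho = geom
            if r > r_max or th < search.theta_min:
                continue
            if best is None or r < best.r:
                best = HBondGeometry(max(r, r_min), th, rho, donor, cls,
                                     "donor_centered", donor_residue=i,
                                     acceptor_residue=j)
    return best


def _donor_hydrogens(model: ProteinModel, j: int):
    """Yield (H coordinate, donor_kind) for residue j."""
    res = model.residues[j]
    if res.has_atom("H"):
        yield res.coord("H"), "amide_H"
    for h_name, _n_name in AMINE_HYDROGENS.get(res.res_type, ()):
        if res.has_atom(h_name):
            yield res.coord(h_name), "amine_H"
    for h_name in ("HA", "HA2", "HA3"):
        if res.has_atom(h_name):
            yield res.coord(h_name), "alpha_H"


def find_secondary_hbonds(model: ProteinModel, i: int,
                          search: SearchConfig | None = None
                          ) -> list[HBondGeometry]:
    """Donors bonded to residue i's backbone carbonyl oxygen.

    Geometries are acceptor-centered on the carbonyl O; by default only
    the nearest in-range donor per kind is kept
    (``search.secondary_mode="sum"`` keeps all).
    """
    search = search or SearchConfig()
    res = model.residues[i]
    if not (res.has_atom("O") and res.has_atom("C")):
        return []
    o = res.coord("O")
    c = res.coord("C")
    nxt = model.neighbor(i, +1)
    if nxt is not None and model.residues[nxt].has_atom("N"):
        ref = model.residues[nxt].coord("N")
    elif res.has_atom("CA"):
        ref = res.coord("CA")
    else:
        return []
    found: list[HBondGeometry] = []
    for j in range(len(model.residues)):
        if j == i or j == nxt:  # i+1 amide is covalently adjacent
            continue
        for h, kind in _donor_hydrogens(model, j):
            dk = "alpha_H" if kind == "alpha_H" else "amide_H"
            r_min, r_max = search.r_range(dk)
            geom = _geometry_for(h, o, c, ref)
            if geom is None:
                continue
            r, th, rho = geom
            if r > r_max or th < search.theta_min:
                continue
            found.append(HBondGeometry(max(r, r_min), th, rho, kind,
                                       "amide_carbonyl", "acceptor_centered",
                                       donor_residue=j, acceptor_residue=i))
    if search.secondary_mode == "sum":
        return found
    nearest: dict[str, HBondGeometry] = {}
    for g in found:
        if g.donor_kind not in nearest or g.r < nearest[g.donor_kind].r:
            nearest[g.donor_kind] = g
    return sorted(nearest.values(), key=lambda g: g.donor_kind)


# ---------------------------------------------------------------------------
# ring currents


@dataclass
class RingSystem:
    ring_id: str
    res_type: str
    seq_index: int
    intensity: float
    center: np.ndarray
    normal: np.ndarray


def ring_systems(model: ProteinModel,
                 ring_config: RingConfig | None = None) -> list[RingSystem]:
    """One RingSystem per aromatic ring (Trp contributes two)."""
    ring_config = ring_config or RingConfig()
    out: list[RingSystem] = []
    for res in model:
        for ring_key, atom_names in RING_ATOMS.get(res.res_type, ()):
            if not all(res.has_atom(a) for a in atom_names):
                warnings.warn(
                    f"{res.res_type}{res.seq_index}: incomplete ring "
                    f"{ring_key} skipped", GridShieldWarning, stacklevel=2)
                continue
            coords = np.array([res.coord(a) for a in atom_names])
            center = coords.mean(axis=0)
            _, _, vt = np.linalg.svd(coords - center)
            normal = _unit(vt[-1])
            out.append(RingSystem(
                ring_id=f"{res.chain_id}{res.seq_index}:{ring_key}",
                res_type=res.res_type, seq_index=res.seq_index,
                intensity=float(ring_config.intensities[ring_key]),
                center=center, normal=normal))
    return out


def ring_current(proton_pos, rings: list[RingSystem],
                 B: float | None = None, cutoff: float | None = None,
                 ring_config: RingConfig | None = None) -> float:
    """Point-dipole ring-current shielding: sum of i*B*(1-3cos^2 theta)/r^3.

    Rings whose center is beyond the cutoff contribute exactly zero.
    """
    ring_config = ring_config or RingConfig()
    B = ring_config.B if B is None else B
    cutoff = ring_config.cutoff if cutoff is None else cutoff
    if cutoff <= 0:
        raise ValueError("ring cutoff must be positive")
    p = np.asarray(proton_pos, dtype=float)
    total = 0.0
    for ring in rings:
        rvec = ring.center - p
        r = float(np.linalg.norm(rvec))
        if r < 1e-9:
            raise ValueError(f"proton coincides with ring center {ring.ring_id}")
        if r > cutoff:
            continue
        cos_t = float(np.dot(rvec / r, ring.normal))
        total += ring.intensity * B * (1.0 - 3.0 * cos_t * cos_t) / r**3
    return total
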