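"""Synthetic libraries, toy structures and noisy observations.

Everything here is deliberately non-physical: surfaces are smooth closed
forms chosen so that every interpolation result can be re-checked against
the generating function, with amplitudes that merely mimic realistic
shielding scales.  The bundle layout, axis lattices and constants match
what the real predictor consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .errors import GridShieldError
from .grids import (
    AxisSpec,
    GridLibrary,
    ShieldingGrid,
    interpolate,
    load_library,
    save_library,
)
from .model_io import AtomRecord, Ensemble, ProteinModel, ResidueRecord, ShiftTable
from .predictor import TermMask, predict_model
from .residues import ATOM_TYPES, CHI_COUNT, ONE_TO_THREE, STANDARD_RESIDUES

# ---------------------------------------------------------------------------
# closed-form surfaces


@dataclass(frozen=True)
class SurfaceSpec:
    """A re-evaluable closed-form surface used to fill synthetic grids."""

    form: str                       # constant | cosine_mix | radial_decay
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.form not in ("constant", "cosine_mix", "radial_decay"):
            raise GridShieldError(f"unknown surface form {self.form!r}")

    def evaluate(self, coords) -> float:
        c = [float(x) for x in coords]
        p = self.params
        if self.form == "constant":
            return float(p["c"])
        if self.form == "cosine_mix":
            val = float(p["base"])
            for amp, freq, phase, x in zip(p["amps"], p["freqs"],
                                           p["phases"], c):
                val += amp * math.cos(math.radians(freq * x - phase))
            return val
        # radial_decay over (r, theta, rho); exactly 0 at the r maximum
        r, theta = c[0], c[1]
        rho = c[2] if len(c) > 2 else 0.0
        shape = (p["r_max"] - r) / (p["r_max"] - p["r_min"])
        return (p["amp"] * shape * math.cos(math.radians(theta))
                * (1.0 + 0.3 * math.cos(math.radians(rho))))

    def sample(self, axes: list[AxisSpec]) -> np.ndarray:
        meshes = np.meshgrid(*[ax.nodes for ax in axes], indexing="ij")
        flat = np.stack([m.ravel() for m in meshes], axis=1)
        vals = np.array([self.evaluate(row) for row in flat])
        return vals.reshape([ax.n for ax in axes])

    def to_json(self) -> dict:
        return {"form": self.form, "params": self.params}

    @staticmethod
    def from_json(d: dict) -> "SurfaceSpec":
        return SurfaceSpec(d["form"], d["params"])

    @staticmethod
    def random_cosine(rng: np.random.Generator, n_axes: int,
                      base: float, amp: float) -> "SurfaceSpec":
        return SurfaceSpec("cosine_mix", {
            "base": base,
            "amps": [float(a) for a in rng.uniform(0.2, 1.0, n_axes) * amp],
            "freqs": [int(f) for f in rng.integers(1, 4, n_axes)],
            "phases": [float(x) for x in rng.uniform(-180, 180, n_axes)],
        })


#: loose realism: baseline shielding scale per atom type, ppm
_BASELINES = {"CA": 120.0, "CB": 150.0, "C": 60.0, "HA": 26.0, "HN": 24.0,
              "N": 120.0}

HBOND_R_AXES = {
    # (start, spacing, n): the scan lattices of the source parameterization
    "HB1": (1.5, 0.125, 13),
    "HB2": (1.5, 0.125, 13),
    "HaB1": (1.8, 0.2, 12),
    "HaB2": (1.8, 0.2, 12),
}
HBOND_CLASSES = {
    "HB1": ("amide_carbonyl", "carboxyl", "hydroxyl"),
    "HB2": ("amide_H", "amine_H"),
    "HaB1": ("amide_carbonyl", "carboxyl", "hydroxyl"),
    "HaB2": ("alpha_H",),
}


def phi_psi_scan(spacing: float = 20.0, inclusive: bool = True) -> np.ndarray:
    """Enumerate (phi, psi) pairs of a backbone scan.

    With ``inclusive=True`` both -180 and +180 endpoints are emitted, the
    bookkeeping used when counting scan conformations; the resulting grids
    store the half-open [-180, 180) lattice.
    """
    if abs(360.0 / spacing - round(360.0 / spacing)) > 1e-9:
        raise GridShieldError(f"spacing {spacing} does not divide 360")
    n = int(round(360.0 / spacing)) + (1 if inclusive else 0)
    axis = -180.0 + spacing * np.arange(n)
    phi, psi = np.meshgrid(axis, axis, indexing="ij")
    return np.stack([phi.ravel(), psi.ravel()], axis=1)


def make_library(path, residues=("ALA", "VAL", "SER"), spacing: float = 20.0,
                 seed: int = 0, surface: SurfaceSpec | None = None,
                 include_hbond: bool = True, rho_spacing: float = 20.0,
                 chi_spacing: float | None = None,
                 delta_sigma_w: float = 2.07, water_sign: float = -1.0,
                 atoms=ATOM_TYPES) -> GridLibrary:
    """Generate a complete synthetic bundle on disk and load it back.

    sigma_A is computed from the generator's own Ala neighbour surface at
    (-120, 140), so the neighbour-term zero identity holds by
    construction.  A global ``surface`` overrides the seeded per-grid
    surfaces (useful for constant libraries).
    """
    if abs(360.0 / spacing - round(360.0 / spacing)) > 1e-9:
        raise GridShieldError(f"spacing {spacing} does not divide 360")
    chi_spacing = chi_spacing if chi_spacing is not None else spacing
    if abs(360.0 / chi_spacing - round(360.0 / chi_spacing)) > 1e-9:
        raise GridShieldError(f"chi spacing {chi_spacing} does not divide 360")
    residues = tuple(residues)
    for res in residues:
        if res not in STANDARD_RESIDUES:
            raise GridShieldError(f"unknown residue type {res!r}")
    if "ALA" not in residues:
        residues = ("ALA", *residues)
    rng = np.random.default_rng(seed)
    grids: dict[str, ShieldingGrid] = {}
    sigma_A: dict[str, float] = {}

    def backbone_axes(res: str) -> list[AxisSpec]:
        axes = [AxisSpec("phi", -180.0, spacing, int(round(360 / spacing)), True),
                AxisSpec("psi", -180.0, spacing, int(round(360 / spacing)), True)]
        for k in range(CHI_COUNT[res]):
            axes.append(AxisSpec(f"chi{k + 1}", -180.0, chi_spacing,
                                 int(round(360 / chi_spacing)), True))
        return axes

    def make_spec(n_axes: int, atom: str) -> SurfaceSpec:
        if surface is not None:
            return surface
        return SurfaceSpec.random_cosine(rng, n_axes, _BASELINES[atom], 3.0)

    # deterministic draw order: residues, then atoms, then roles
    for res in sorted(residues):
        axes = backbone_axes(res)
        mode = "cubic" if CHI_COUNT[res] <= 1 else "nearest"
        for atom in atoms:
            if atom == "CB" and res == "GLY":
                continue
            center = make_spec(len(axes), atom)
            prev = make_spec(len(axes), atom)
            nxt = prev if res == "ALA" else make_spec(len(axes), atom)
            for role, spec in (("center", center), ("prev", prev), ("next", nxt)):
                gid = f"{role}__{res}__{atom}"
                grids[gid] = ShieldingGrid(gid, list(axes), spec.sample(axes),
                                           mode, meta={"spec": spec.to_json()})
            if res == "ALA":
                # reference taken from the grid itself (not the closed form)
                # so the neighbour zero-identity holds for any spacing
                sigma_A[atom] = interpolate(grids[f"prev__{res}__{atom}"],
                                            [-120.0, 140.0])

    if include_hbond:
        n_rho = int(round(360.0 / rho_spacing))
        for term in sorted(HBOND_R_AXES):
            r0, dr, nr = HBOND_R_AXES[term]
            axes = [AxisSpec("r", r0, dr, nr, False),
                    AxisSpec("theta", 90.0, 10.0, 10, False),
                    AxisSpec("rho", -180.0, rho_spacing, n_rho, True)]
            for cls in HBOND_CLASSES[term]:
                for atom in atoms:
                    if atom == "CB" and term != "HaB1":
                        continue
                    if surface is not None:
                        spec = surface
                    else:
                        spec = SurfaceSpec("radial_decay", {
                            "amp": float(rng.uniform(0.5, 2.0)),
                            "r_min": r0, "r_max": r0 + dr * (nr - 1)})
                    gid = f"hbond__{term}__{cls}__{atom}"
                    grids[gid] = ShieldingGrid(gid, list(axes),
                                               spec.sample(axes), "cubic",
                                               meta={"spec": spec.to_json()})

    manifest = {
        "sigma_A": sigma_A,
        "phi_std": -120.0,
        "psi_std": 140.0,
        "delta_sigma_w": delta_sigma_w,
        "water_sign": water_sign,
        "rho_sign_convention": "right_handed",
        "provenance": {"generator": "gridshield.synth.make_library",
                       "seed": seed, "spacing": spacing,
                       "chi_spacing": chi_spacing,
                       "residues": sorted(residues)},
    }
    lib = GridLibrary(None, manifest, grids)
    save_library(lib, path)
    return load_library(path)


# ---------------------------------------------------------------------------
# toy structure builder

_B = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231,
      "CA-CB": 1.530, "CA-HA": 1.090}
_A = {"C-N-CA": 121.7, "N-CA-C": 111.2, "CA-C-N": 116.2, "N-CA-CB": 110.4,
      "CA-C-O": 120.5}


def _unit(v):
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GridShieldError("degenerate geometry in structure builder")
    return v / n


def nerf(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d with |cd| = bond, angle(b,c,d) and dihedral(a,b,c,d)."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = bond * np.array([-math.cos(ang),
                               math.sin(ang) * math.cos(tor),
                               math.sin(ang) * math.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


#: side-chain internal-coordinate templates: entries
#: (atom, (ref_a, ref_b, ref_c), bond, angle, torsion) where torsion is a
#: number or ("chi", k, offset) resolved against the residue's chi list.
_SIDECHAINS: dict[str, list] = {
    "ALA": [],
    "GLY": [],
    "SER": [("OG", ("N", "CA", "CB"), 1.417, 110.8, ("chi", 1, 0.0)),
            ("HG", ("CA", "CB", "OG"), 0.96, 109.5, 180.0)],
    "CYS": [("SG", ("N", "CA", "CB"), 1.808, 113.8, ("chi", 1, 0.0))],
    "THR": [("OG1", ("N", "CA", "CB"), 1.433, 109.6, ("chi", 1, 0.0)),
            ("CG2", ("N", "CA", "CB"), 1.521, 110.5, ("chi", 1, -122.0)),
            ("HG1", ("CA", "CB", "OG1"), 0.96, 109.5, 180.0)],
    "VAL": [("CG1", ("N", "CA", "CB"), 1.521, 110.5, ("chi", 1, 0.0)),
            ("CG2", ("N", "CA", "CB"), 1.521, 110.5, ("chi", 1, -122.0))],
    "LEU": [("CG", ("N", "CA", "CB"), 1.530, 116.3, ("chi", 1, 0.0)),
            ("CD1", ("CA", "CB", "CG"), 1.521, 110.7, ("chi", 2, 0.0)),
            ("CD2", ("CA", "CB", "CG"), 1.521, 110.7, ("chi", 2, 122.0))],
    "ILE": [("CG1", ("N", "CA", "CB"), 1.530, 110.4, ("chi", 1, 0.0)),
            ("CG2", ("N", "CA", "CB"), 1.521, 110.5, ("chi", 1, -122.0)),
            ("CD1", ("CA", "CB", "CG1"), 1.513, 113.8, ("chi", 2, 0.0))],
    "ASP": [("CG", ("N", "CA", "CB"), 1.516, 112.6, ("chi", 1, 0.0)),
            ("OD1", ("CA", "CB", "CG"), 1.249, 118.4, ("chi", 2, 0.0)),
            ("OD2", ("CA", "CB", "CG"), 1.249, 118.4, ("chi", 2, 180.0))],
    "ASN": [("CG", ("N", "CA", "CB"), 1.516, 112.6, ("chi", 1, 0.0)),
            ("OD1", ("CA", "CB", "CG"), 1.231, 120.8, ("chi", 2, 0.0)),
            ("ND2", ("CA", "CB", "CG"), 1.328, 116.4, ("chi", 2, 180.0)),
            ("HD21", ("CB", "CG", "ND2"), 1.01, 120.0, 0.0),
            ("HD22", ("CB", "CG", "ND2"), 1.01, 120.0, 180.0)],
    "GLU": [("CG", ("N", "CA", "CB"), 1.530, 114.1, ("chi", 1, 0.0)),
            ("CD", ("CA", "CB", "CG"), 1.516, 112.6, ("chi", 2, 0.0)),
            ("OE1", ("CB", "CG", "CD"), 1.249, 118.4, ("chi", 3, 0.0)),
            ("OE2", ("CB", "CG", "CD"), 1.249, 118.4, ("chi", 3, 180.0))],
    "GLN": [("CG", ("N", "CA", "CB"), 1.530, 114.1, ("chi", 1, 0.0)),
            ("CD", ("CA", "CB", "CG"), 1.516, 112.6, ("chi", 2, 0.0)),
            ("OE1", ("CB", "CG", "CD"), 1.231, 120.8, ("chi", 3, 0.0)),
            ("NE2", ("CB", "CG", "CD"), 1.328, 116.4, ("chi", 3, 180.0)),
            ("HE21", ("CG", "CD", "NE2"), 1.01, 120.0, 0.0),
            ("HE22", ("CG", "CD", "NE2"), 1.01, 120.0, 180.0)],
    "MET": [("CG", ("N", "CA", "CB"), 1.530, 114.1, ("chi", 1, 0.0)),
            ("SD", ("CA", "CB", "CG"), 1.803, 112.7, ("chi", 2, 0.0)),
            ("CE", ("CB", "CG", "SD"), 1.791, 100.9, ("chi", 3, 0.0))],
    "LYS": [("CG", ("N", "CA", "CB"), 1.530, 114.1, ("chi", 1, 0.0)),
            ("CD", ("CA", "CB", "CG"), 1.520, 111.3, ("chi", 2, 0.0)),
            ("CE", ("CB", "CG", "CD"), 1.520, 111.3, ("chi", 3, 0.0)),
            ("NZ", ("CG", "CD", "CE"), 1.489, 111.5, ("chi", 4, 0.0)),
            ("HZ1", ("CD", "CE", "NZ"), 1.01, 109.5, 60.0),
            ("HZ2", ("CD", "CE", "NZ"), 1.01, 109.5, 180.0),
            ("HZ3", ("CD", "CE", "NZ"), 1.01, 109.5, -60.0)],
    "ARG": [("CG", ("N", "CA", "CB"), 1.530, 114.1, ("chi", 1, 0.0)),
            ("CD", ("CA", "CB", "CG"), 1.520, 111.3, ("chi", 2, 0.0)),
            ("NE", ("CB", "CG", "CD"), 1.461, 111.8, ("chi", 3, 0.0)),
            ("CZ", ("CG", "CD", "NE"), 1.329, 124.4, ("chi", 4, 0.0)),
            ("NH1", ("CD", "NE", "CZ"), 1.326, 120.0, 0.0),
            ("NH2", ("CD", "NE", "CZ"), 1.326, 120.0, 180.0),
            ("HE", ("CZ", "NE", "CD"), 1.01, 118.0, 180.0)],
    "PRO": [("CG", ("N", "CA", "CB"), 1.492, 104.5, ("chi", 1, 0.0)),
            ("CD", ("CA", "CB", "CG"), 1.503, 106.1, ("chi", 2, 0.0))],
    "PHE": [("CG", ("N", "CA", "CB"), 1.502, 113.8, ("chi", 1, 0.0)),
            ("CD1", ("CA", "CB", "CG"), 1.390, 120.7, ("chi", 2, 0.0)),
            ("CD2", ("CA", "CB", "CG"), 1.390, 120.7, ("chi", 2, 180.0)),
            ("CE1", ("CB", "CG", "CD1"), 1.390, 120.0, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.390, 120.0, 180.0),
            ("CZ", ("CG", "CD1", "CE1"), 1.390, 120.0, 0.0)],
    "TYR": [("CG", ("N", "CA", "CB"), 1.502, 113.8, ("chi", 1, 0.0)),
            ("CD1", ("CA", "CB", "CG"), 1.390, 120.7, ("chi", 2, 0.0)),
            ("CD2", ("CA", "CB", "CG"), 1.390, 120.7, ("chi", 2, 180.0)),
            ("CE1", ("CB", "CG", "CD1"), 1.390, 120.0, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.390, 120.0, 180.0),
            ("CZ", ("CG", "CD1", "CE1"), 1.390, 120.0, 0.0),
            ("OH", ("CD1", "CE1", "CZ"), 1.360, 120.0, 180.0),
            ("HH", ("CE1", "CZ", "OH"), 0.96, 109.0, 0.0)],
    "HIS": [("CG", ("N", "CA", "CB"), 1.504, 113.8, ("chi", 1, 0.0)),
            ("ND1", ("CA", "CB", "CG"), 1.378, 122.7, ("chi", 2, 0.0)),
            ("CD2", ("CA", "CB", "CG"), 1.356, 131.0, ("chi", 2, 180.0)),
            ("CE1", ("CB", "CG", "ND1"), 1.321, 109.0, 180.0),
            ("NE2", ("CB", "CG", "CD2"), 1.374, 107.0, 180.0),
            ("HE2", ("CG", "CD2", "NE2"), 1.01, 125.0, 180.0)],
    "TRP": [("CG", ("N", "CA", "CB"), 1.498, 113.8, ("chi", 1, 0.0)),
            ("CD1", ("CA", "CB", "CG"), 1.365, 127.0, ("chi", 2, 0.0)),
            ("CD2", ("CA", "CB", "CG"), 1.433, 126.6, ("chi", 2, 180.0)),
            ("NE1", ("CB", "CG", "CD1"), 1.374, 110.1, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.409, 107.0, 180.0),
            ("HE1", ("CG", "CD1", "NE1"), 1.01, 125.0, 180.0),
            ("CE3", ("CE2", "CG", "CD2"), 1.398, 133.9, 180.0),
            ("CZ2", ("CG", "CD2", "CE2"), 1.394, 122.4, 180.0),
            ("CZ3", ("CG", "CD2", "CE3"), 1.382, 118.6, 180.0),
            ("CH2", ("CD2", "CE2", "CZ2"), 1.368, 117.5, 0.0)],
}


@dataclass(frozen=True)
class HBondPrescription:
    """Ask for an acceptor at exact (r, theta, rho) from a chosen donor."""

    r: float
    theta: float
    rho: float
    donor_residue: int = 1        # list position in the built chain
    donor_kind: str = "amide_H"

    def __post_init__(self):
        if self.r <= 0:
            raise GridShieldError("prescribed r must be positive")
        if not 0.0 <= self.theta <= 180.0:
            raise GridShieldError("prescribed theta must lie in [0, 180]")


def _to_three(sequence) -> list[str]:
    if isinstance(sequence, str):
        return [ONE_TO_THREE[c] for c in sequence]
    return [ONE_TO_THREE.get(s, s) for s in sequence]


def make_toy_structure(sequence, phi_psi=None, chis=None,
                       place_hbond: HBondPrescription | None = None,
                       chain_id: str = "A") -> ProteinModel:
    """Build an ideal-geometry chain realizing the requested torsions.

    ``phi_psi`` is one (phi, psi) pair applied to every residue or a
    per-residue list; ``chis`` maps residue position to a chi list
    (default: all chi = 180).  ``place_hbond`` appends an asparagine
    acceptor residue (chain "Z") whose side-chain carbonyl sits at the
    prescribed donor-frame geometry.
    """
    seq3 = _to_three(sequence)
    nres = len(seq3)
    if phi_psi is None:
        phi_psi = (-140.0, 140.0)
    if isinstance(phi_psi, tuple) and np.isscalar(phi_psi[0]):
        phi_psi = [phi_psi] * nres
    if len(phi_psi) != nres:
        raise GridShieldError("phi_psi length must match the sequence")
    chis = chis or {}

    coords: list[dict[str, np.ndarray]] = []
    for i, res in enumerate(seq3):
        phi, psi = phi_psi[i]
        at: dict[str, np.ndarray] = {}
        if i == 0:
            at["N"] = np.zeros(3)
            at["CA"] = np.array([_B["N-CA"], 0.0, 0.0])
            ang = math.radians(_A["N-CA-C"])
            at["C"] = at["CA"] + _B["CA-C"] * np.array(
                [-math.cos(ang), math.sin(ang), 0.0])
        else:
            p = coords[i - 1]
            at["N"] = nerf(p["N"], p["CA"], p["C"], _B["C-N"],
                           _A["CA-C-N"], phi_psi[i - 1][1])
            at["CA"] = nerf(p["CA"], p["C"], at["N"], _B["N-CA"],
                            _A["C-N-CA"], 180.0)  # omega fixed trans
            at["C"] = nerf(p["C"], at["N"], at["CA"], _B["CA-C"],
                           _A["N-CA-C"], phi)
        at["O"] = nerf(at["N"], at["CA"], at["C"], _B["C-O"],
                       _A["CA-C-O"], psi + 180.0)
        coords.append(at)

    model_residues: list[ResidueRecord] = []
    for i, res in enumerate(seq3):
        at = coords[i]
        u_n = _unit(at["N"] - at["CA"])
        u_c = _unit(at["C"] - at["CA"])
        bis = -_unit(u_n + u_c)
        perp = _unit(np.cross(u_n, u_c))
        ca, sa = math.cos(math.radians(54.75)), math.sin(math.radians(54.75))
        if res == "GLY":
            at["HA2"] = at["CA"] + _B["CA-HA"] * _unit(bis * ca + perp * sa)
            at["HA3"] = at["CA"] + _B["CA-HA"] * _unit(bis * ca - perp * sa)
        else:
            at["CB"] = at["CA"] + _B["CA-CB"] * _unit(bis * ca - perp * sa)
            at["HA"] = at["CA"] + _B["CA-HA"] * _unit(bis * ca + perp * sa)
        if i > 0 and res != "PRO":
            c_prev = coords[i - 1]["C"]
            direction = -_unit(_unit(c_prev - at["N"]) + _unit(at["CA"] - at["N"]))
            at["H"] = at["N"] + 1.01 * direction
        chi = list(chis.get(i, []))
        for entry in _SIDECHAINS[res]:
            name, refs, bond, ang, tor = entry
            if isinstance(tor, tuple):
                _, k, offset = tor
                base = chi[k - 1] if k - 1 < len(chi) else 180.0
                tor = base + offset
            at[name] = nerf(at[refs[0]], at[refs[1]], at[refs[2]],
                            bond, ang, tor)
        atoms = [AtomRecord(name, name[0], pos)
                 for name, pos in at.items()]
        model_residues.append(ResidueRecord(res, i + 1, chain_id, atoms))

    if place_hbond is not None:
        model_residues.append(
            _acceptor_residue(model_residues, place_hbond))
    return ProteinModel(model_residues, model_index=0)


def _acceptor_residue(residues: list[ResidueRecord],
                      rx: HBondPrescription) -> ResidueRecord:
    """Asparagine whose OD1=CG-ND2 amide realizes the prescribed frame."""
    donor = residues[rx.donor_residue]
    if rx.donor_kind == "amide_H":
        h_name, anchor = "H", "N"
    else:
        h_name, anchor = ("HA2", "CA") if donor.res_type == "GLY" else ("HA", "CA")
    if not donor.has_atom(h_name):
        raise GridShieldError(
            f"donor residue {donor.res_type}{donor.seq_index} lacks {h_name}")
    h = donor.coord(h_name)
    d = _unit(h - donor.coord(anchor))
    o = h + rx.r * d
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, d)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    axis = _unit(np.cross(d, ref))
    ang = math.radians(rx.theta)
    # rotate the O->H direction (-d) by theta about axis (Rodrigues)
    v = -d
    c_dir = (v * math.cos(ang) + np.cross(axis, v) * math.sin(ang)
             + axis * np.dot(axis, v) * (1.0 - math.cos(ang)))
    cg = o + 1.231 * c_dir
    at: dict[str, np.ndarray] = {"OD1": o, "CG": cg}
    at["ND2"] = nerf(h, o, cg, 1.328, 120.8, rx.rho)
    at["CB"] = nerf(h, o, cg, 1.516, 120.8, rx.rho + 180.0)
    at["CA"] = nerf(o, cg, at["CB"], 1.530, 112.6, 60.0)
    at["N"] = nerf(cg, at["CB"], at["CA"], 1.458, 110.0, 180.0)
    at["C"] = nerf(cg, at["CB"], at["CA"], 1.525, 111.0, -60.0)
    at["O"] = nerf(at["CB"], at["CA"], at["C"], 1.231, 120.5, 0.0)
    if np.linalg.norm(at["O"] - h) < rx.r or np.linalg.norm(at["N"] - h) < 1.2:
        raise GridShieldError("prescribed geometry is sterically impossible")
    atoms = [AtomRecord(name, name[0], pos) for name, pos in at.items()]
    seq = residues[-1].seq_index + 1
    return ResidueRecord("ASN", seq, "Z", atoms)


# ---------------------------------------------------------------------------
# synthetic observations


def make_observations(lib: GridLibrary, structure: ProteinModel, a: float,
                      b: float, noise_sd: float, seed: int = 0,
                      mask: TermMask | None = None,
                      config: RunConfig | None = None,
                      predictions=None) -> ShiftTable:
    """Noisy linear observations delta = b - a*sigma + eps from a prediction.

    Pass precomputed ``predictions`` (the breakdowns of ``structure``) to
    skip re-predicting when drawing many noise realizations.
    """
    rng = np.random.default_rng(seed)
    breakdowns = (predictions if predictions is not None
                  else predict_model(structure, lib, mask, config))
    entries: dict[tuple[int, str], float] = {}
    res_types: dict[int, str] = {}
    for bd in breakdowns:
        eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        entries[(bd.seq_index, bd.atom_type)] = b - a * bd.sigma_total + eps
        res_types[bd.seq_index] = bd.res_type
    return ShiftTable(entries, res_types)


def write_shift_table(table: ShiftTable, path) -> None:
    """Write a ShiftTable in the flat 4-column exchange format."""
    with open(path, "w") as fh:
        fh.write("# seq_index res_type atom_type shift\n")
        for (seq, atom), val in sorted(table.entries.items()):
            rt = table.res_types.get(seq, "UNK")
            fh.write(f"{seq}\t{rt}\t{atom}\t{val:.9f}\n")


def make_ensemble(base: ProteinModel, n_models: int, jitter: float = 0.0,
                  seed: int = 0) -> Ensemble:
    """Replicate a model n times, optionally with Gaussian coordinate jitter."""
    rng = np.random.default_rng(seed)
    models = []
    for k in range(n_models):
        residues = []
        for res in base:
            atoms = []
            for atom in res.atoms:
                pos = atom.position + (rng.normal(0, jitter, 3) if jitter else 0.0)
                atoms.append(AtomRecord(atom.name, atom.element, pos, atom.serial))
            residues.append(ResidueRecord(res.res_type, res.seq_index,
                                          res.chain_id, atoms))
        models.append(ProteinModel(residues, model_index=k))
    return Ensemble(models)
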