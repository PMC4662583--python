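"""Individual contributions to an atom's chemical shielding.

Each function returns a :class:`TermValue`; absent partners or neighbours
contribute exactly zero (the total is a sum of corrections to a
tripeptide baseline, not a mean-field model).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError, MissingAtomError, MissingChiError
from .geometry import HBondGeometry, TorsionState
from .grids import GridLibrary, interpolate

TERM_IDS = ("BB", "BB_prev", "BB_next", "HB1", "HB2", "HaB1", "HaB2", "RC", "W")

PRIMARY_TERMS = ("HB1", "HaB1")
SECONDARY_TERMS = ("HB2", "HaB2")


@dataclass(frozen=True)
class TermValue:
    term_id: str
    value: float
    provenance: str

    def __post_init__(self):
        if self.term_id not in TERM_IDS:
            raise ConfigurationError(f"unknown term id {self.term_id!r}")


def _grid_coords(grid, tors: TorsionState, res_label: str, strict: bool):
    """Map a TorsionState onto the grid's (phi, psi, chi...) axes."""
    if tors.phi is None or tors.psi is None:
        raise MissingAtomError(
            f"{res_label}: phi/psi undefined; no backbone prediction")
    coords = []
    for k, ax in enumerate(grid.axes):
        if k == 0:
            coords.append(tors.phi)
        elif k == 1:
            coords.append(tors.psi)
        else:
            ci = k - 2
            if ci < len(tors.chi):
                coords.append(tors.chi[ci])
            elif strict:
                raise MissingChiError(
                    f"{res_label}: chi{ci + 1} undefined but grid "
                    f"{grid.grid_id} has a {ax.name} axis (strict mode)")
            else:
                coords.append(ax.start)  # permissive fallback
    return coords


def backbone_term(lib: GridLibrary, res_type: str, tors: TorsionState,
                  atom: str, strict: bool = True) -> TermValue:
    """Tripeptide baseline shielding at the residue's own torsions."""
    grid = lib.center_grid(res_type, atom)
    val = interpolate(grid, _grid_coords(grid, tors, res_type, strict))
    return TermValue("BB", val, grid.grid_id)


def neighbor_term(lib: GridLibrary, side: str, neighbor_res_type: str,
                  neighbor_torsions: TorsionState | None, atom: str,
                  strict: bool = True) -> TermValue:
    """Shielding change due to the i-1 or i+1 side chain.

    Evaluated as the neighbour-type surface at the neighbour's torsions
    minus the alanine reference constant sigma_A at (phi_std, psi_std).
    Missing neighbours contribute 0 with provenance "absent".
    """
    term_id = "BB_prev" if side == "prev" else "BB_next"
    if neighbor_torsions is None or neighbor_torsions.phi is None \
            or neighbor_torsions.psi is None:
        return TermValue(term_id, 0.0, "absent")
    grid = lib.neighbor_grid(side, neighbor_res_type, atom)
    val = interpolate(grid, _grid_coords(grid, neighbor_torsions,
                                         neighbor_res_type, strict))
    ref = lib.sigma_A.get(atom)
    if ref is None:
        raise ConfigurationError(f"bundle lacks sigma_A for atom {atom}")
    return TermValue(term_id, val - ref, grid.grid_id)


def hbond_term(lib: GridLibrary, term_id: str, geom: HBondGeometry | None,
               atom: str) -> TermValue:
    """Hydrogen-bond correction surface lookup at (r, theta, rho)."""
    if term_id not in PRIMARY_TERMS + SECONDARY_TERMS:
        raise ConfigurationError(f"{term_id!r} is not a hydrogen-bond term")
    if atom == "CB" and term_id != "HaB1":
        # the parameterization model systems carry no C-beta
        raise ConfigurationError(
            f"term {term_id} is undefined for CB by construction")
    if geom is None:
        return TermValue(term_id, 0.0, "no_partner")
    if term_id in PRIMARY_TERMS:
        if geom.frame != "donor_centered":
            raise ConfigurationError(
                f"{term_id} needs a donor-centered geometry, got {geom.frame}")
        class_key = geom.acceptor_class
    else:
        if geom.frame != "acceptor_centered":
            raise ConfigurationError(
                f"{term_id} needs an acceptor-centered geometry, got {geom.frame}")
        class_key = geom.donor_kind
    surface = lib.hbond_surface(term_id, class_key, atom)
    r_axis = surface.axes[0]
    if geom.r > r_axis.stop:  # defensively: beyond the scanned range
        return TermValue(term_id, 0.0, "out_of_range")
    val = interpolate(surface, (geom.r, geom.theta, geom.rho))
    return TermValue(term_id, val, surface.grid_id)


def water_term(has_partner: bool, lib: GridLibrary, atom: str = "HN") -> TermValue:
    """Explicit-water correction for solvent-exposed amide protons."""
    if atom != "HN":
        raise ConfigurationError(f"water term applies to HN only, not {atom}")
    if has_partner:
        return TermValue("W", 0.0, "bonded")
    return TermValue("W", lib.water_sign * lib.delta_sigma_w, "water")
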