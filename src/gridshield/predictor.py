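"""Per-atom shielding assembly and ensemble averaging.

The per-atom-type term mask is data: the default reproduces the published
term selection, and any subset can be supplied for ablation experiments.
Masked-out terms are reported with provenance "masked" and are never
evaluated, so perturbing their underlying surfaces cannot change totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import RunConfig
from .errors import ConfigurationError
from .geometry import (
    find_primary_hbond,
    find_secondary_hbonds,
    ring_current,
    ring_systems,
    torsions,
)
from .grids import GridLibrary
from .model_io import Ensemble, ProteinModel
from .residues import ATOM_TYPES
from .terms import TERM_IDS, TermValue, backbone_term, hbond_term, neighbor_term, water_term

_DEFAULT_MASK = {
    "CA": frozenset({"BB", "BB_prev", "BB_next", "HB2", "HaB2"}),
    "CB": frozenset({"BB", "BB_prev", "BB_next"}),
    "C":  frozenset({"BB", "BB_prev", "BB_next", "HB2", "HaB2"}),
    "HA": frozenset({"BB", "BB_prev", "BB_next", "HB1", "HB2", "HaB1",
                     "HaB2", "RC"}),
    "HN": frozenset({"BB", "BB_prev", "BB_next", "HB1", "HB2", "HaB1",
                     "HaB2", "RC", "W"}),
    "N":  frozenset({"BB", "BB_prev", "BB_next", "HB1", "HB2", "HaB2"}),
}


@dataclass(frozen=True)
class TermMask:
    """Active term subset per atom type; BB is always required."""

    active: dict = field(default_factory=lambda: dict(_DEFAULT_MASK))

    def __post_init__(self):
        for atom, terms in self.active.items():
            if atom not in ATOM_TYPES:
                raise ConfigurationError(f"mask for unknown atom type {atom!r}")
            bad = set(terms) - set(TERM_IDS)
            if bad:
                raise ConfigurationError(f"mask {atom}: unknown terms {sorted(bad)}")
            if "BB" not in terms:
                raise ConfigurationError(f"mask {atom}: BB term is mandatory")

    def is_active(self, atom: str, term_id: str) -> bool:
        return term_id in self.active.get(atom, ())

    def terms_for(self, atom: str) -> frozenset:
        return frozenset(self.active.get(atom, ()))

    def with_override(self, atom: str, terms) -> "TermMask":
        new = dict(self.active)
        new[atom] = frozenset(terms)
        return TermMask(new)

    @staticmethod
    def from_overrides(specs) -> "TermMask":
        """Build from strings like ``CB=BB,BB_prev`` applied to the default."""
        mask = default_mask()
        for spec in specs:
            atom, _, terms = spec.partition("=")
            if not terms:
                raise ConfigurationError(f"bad mask override {spec!r}")
            mask = mask.with_override(atom.strip(),
                                      {t.strip() for t in terms.split(",")})
        return mask


def default_mask() -> TermMask:
    return TermMask()


@dataclass
class TermBreakdown:
    model_index: int
    seq_index: int
    chain_id: str
    res_type: str
    atom_type: str
    terms: dict
    sigma_total: float


@dataclass
class EnsemblePrediction:
    """Mean shielding per (seq_index, atom_type) over an ensemble."""

    values: dict = field(default_factory=dict)   # key -> mean sigma
    counts: dict = field(default_factory=dict)   # key -> number of models
    res_types: dict = field(default_factory=dict)

    def items(self):
        return self.values.items()


def _alpha_hydrogens(res) -> list[str]:
    if res.res_type == "GLY":
        return [n for n in ("HA2", "HA3") if res.has_atom(n)]
    return ["HA"] if res.has_atom("HA") else []


def _average_terms(values: list[TermValue], term_id: str) -> TermValue:
    if not values:
        return TermValue(term_id, 0.0, "no_partner")
    if len(values) == 1:
        return values[0]
    mean = sum(v.value for v in values) / len(values)
    return TermValue(term_id, mean, "avg:" + ";".join(v.provenance for v in values))


def predict_model(model: ProteinModel, lib: GridLibrary,
                  mask: TermMask | None = None,
                  config: RunConfig | None = None) -> list[TermBreakdown]:
    """Evaluate every active term for every predictable atom of one model."""
    mask = mask or default_mask()
    config = config or RunConfig()
    search = config.search
    rings = ring_systems(model, config.ring)
    tors_cache = {i: torsions(model, i) for i in range(len(model.residues))}
    out: list[TermBreakdown] = []

    for i, res in enumerate(model):
        tors = tors_cache[i]
        if tors.phi is None or tors.psi is None:
            continue  # termini / breaks: no backbone prediction
        prev = model.neighbor(i, -1)
        nxt = model.neighbor(i, +1)
        # geometry shared by all atoms of this residue
        prim_amide = (find_primary_hbond(model, i, "amide_H", search)
                      if res.has_atom("H") and res.res_type != "PRO" else None)
        alpha_names = _alpha_hydrogens(res)
        prim_alpha = [g for g in (find_primary_hbond(model, i, "alpha_H", search,
                                                     donor_atom=n)
                                  for n in alpha_names) if g is not None]
        secondaries = find_secondary_hbonds(model, i, search)
        sec_amide = [g for g in secondaries if g.donor_kind in ("amide_H", "amine_H")]
        sec_alpha = [g for g in secondaries if g.donor_kind == "alpha_H"]
        # own and adjacent rings are part of the tripeptide baseline
        excluded = {i, prev, nxt} - {None}
        excluded_seq = {model.residues[p].seq_index for p in excluded}
        local_rings = [rg for rg in rings if rg.seq_index not in excluded_seq]

        for atom_type in ATOM_TYPES:
            if atom_type == "CB" and not res.has_atom("CB"):
                continue
            if atom_type == "HN" and (res.res_type == "PRO" or not res.has_atom("H")):
                continue
            if atom_type == "HA" and not alpha_names:
                continue
            if atom_type in ("CA", "C", "N") and not res.has_atom(atom_type):
                continue
            active = mask.terms_for(atom_type)
            terms: dict[str, TermValue] = {}
            for term_id in TERM_IDS:
                if term_id not in active:
                    terms[term_id] = TermValue(term_id, 0.0, "masked")
                    continue
                terms[term_id] = _evaluate_term(
                    term_id, lib, model, i, res, atom_type, tors,
                    tors_cache, prev, nxt, prim_amide, prim_alpha,
                    sec_amide, sec_alpha, local_rings, alpha_names,
                    config)
            total = sum(tv.value for tid, tv in terms.items() if tid in active)
            out.append(TermBreakdown(model.model_index, res.seq_index,
                                     res.chain_id, res.res_type, atom_type,
                                     terms, total))
    return out


def _evaluate_term(term_id, lib, model, i, res, atom_type, tors, tors_cache,
                   prev, nxt, prim_amide, prim_alpha, sec_amide, sec_alpha,
                   local_rings, alpha_names, config) -> TermValue:
    if term_id == "BB":
        return backbone_term(lib, res.res_type, tors, atom_type, config.strict)
    if term_id == "BB_prev":
        if prev is None:
            return TermValue("BB_prev", 0.0, "absent")
        return neighbor_term(lib, "prev", model.residues[prev].res_type,
                             tors_cache[prev], atom_type, config.strict)
    if term_id == "BB_next":
        if nxt is None:
            return TermValue("BB_next", 0.0, "absent")
        return neighbor_term(lib, "next", model.residues[nxt].res_type,
                             tors_cache[nxt], atom_type, config.strict)
    if term_id == "HB1":
        return hbond_term(lib, "HB1", prim_amide, atom_type)
    if term_id == "HaB1":
        vals = [hbond_term(lib, "HaB1", g, atom_type) for g in prim_alpha]
        return _average_terms(vals, "HaB1")
    if term_id == "HB2":
        vals = [hbond_term(lib, "HB2", g, atom_type) for g in sec_amide]
        if not vals:
            return TermValue("HB2", 0.0, "no_partner")
        total = sum(v.value for v in vals)
        return TermValue("HB2", total, ";".join(v.provenance for v in vals))
    if term_id == "HaB2":
        vals = [hbond_term(lib, "HaB2", g, atom_type) for g in sec_alpha]
        if not vals:
            return TermValue("HaB2", 0.0, "no_partner")
        total = sum(v.value for v in vals)
        return TermValue("HaB2", total, ";".join(v.provenance for v in vals))
    if term_id == "RC":
        if atom_type == "HN":
            positions = [res.coord("H")]
        elif atom_type == "HA":
            positions = [res.coord(n) for n in alpha_names]
        else:
            return TermValue("RC", 0.0, "non_proton")
        vals = [ring_current(p, local_rings, ring_config=config.ring)
                for p in positions]
        return TermValue("RC", sum(vals) / len(vals), "point_dipole")
    if term_id == "W":
        return water_term(prim_amide is not None, lib, atom_type)
    raise ConfigurationError(f"unknown term {term_id!r}")


def predict_ensemble(ens: Ensemble, lib: GridLibrary,
                     mask: TermMask | None = None,
                     config: RunConfig | None = None) -> EnsemblePrediction:
    """Arithmetic mean of sigma_total per (seq_index, atom_type) over models."""
    sums: dict[tuple[int, str], float] = {}
    counts: dict[tuple[int, str], int] = {}
    res_types: dict[int, str] = {}
    for model in ens:
        for b in predict_model(model, lib, mask, config):
            key = (b.seq_index, b.atom_type)
            sums[key] = sums.get(key, 0.0) + b.sigma_total
            counts[key] = counts.get(key, 0) + 1
            res_types[b.seq_index] = b.res_type
    values = {k: sums[k] / counts[k] for k in sums}
    return EnsemblePrediction(values, counts, res_types)
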