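"""Structure and table I/O plus the core structural domain types.

Input structures are PDB-format only (single model or multi-MODEL
ensembles).  Waters and hetero groups — including any aromatic ligands,
which are therefore invisible to the ring-current term — are excluded
from the residue list.  Insertion codes are rejected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    GridShieldError,
    GridShieldWarning,
    InsertionCodeError,
    MissingAtomError,
    NonStandardResidueError,
    ShiftTableError,
    StructureParseError,
)
from .residues import STANDARD_RESIDUES

#: maximum C(i-1)-N(i) distance treated as a peptide bond
PEPTIDE_BOND_MAX = 2.5
#: length of a built amide N-H bond
NH_BOND_LENGTH = 1.01


@dataclass
class AtomRecord:
    name: str
    element: str
    position: np.ndarray
    serial: int = 0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not self.name:
            raise StructureParseError("atom with empty name")
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureParseError(
                f"atom {self.name}: position must be a finite 3-vector")


@dataclass
class ResidueRecord:
    res_type: str
    seq_index: int
    chain_id: str
    atoms: list[AtomRecord] = field(default_factory=list)

    def __post_init__(self):
        if self.res_type not in STANDARD_RESIDUES:
            raise NonStandardResidueError(
                f"non-standard residue {self.res_type!r} at "
                f"{self.chain_id}{self.seq_index}")
        self._by_name = {a.name: a for a in self.atoms}

    def atom(self, name: str) -> AtomRecord | None:
        return self._by_name.get(name)

    def has_atom(self, name: str) -> bool:
        return name in self._by_name

    def coord(self, name: str) -> np.ndarray:
        a = self._by_name.get(name)
        if a is None:
            raise MissingAtomError(
                f"{self.res_type}{self.seq_index} ({self.chain_id}) lacks atom {name}")
        return a.position

    def add_atom(self, atom: AtomRecord) -> None:
        if atom.name in self._by_name:
            raise StructureParseError(
                f"duplicate atom {atom.name} in {self.res_type}{self.seq_index}")
        self.atoms.append(atom)
        self._by_name[atom.name] = atom


class ProteinModel:
    """One structural model: ordered residues plus adjacency.

    Adjacency follows file order within a chain and is severed at chain
    breaks (C-N distance beyond :data:`PEPTIDE_BOND_MAX`) and at chain
    boundaries.
    """

    def __init__(self, residues: list[ResidueRecord], model_index: int = 0,
                 warn_breaks: bool = True):
        self.residues = list(residues)
        self.model_index = model_index
        self._breaks: set[int] = set()  # break between position p-1 and p
        prev_seq: dict[str, int] = {}
        for res in self.residues:
            if res.chain_id in prev_seq and res.seq_index <= prev_seq[res.chain_id]:
                raise StructureParseError(
                    f"seq_index not strictly increasing in chain {res.chain_id} "
                    f"at residue {res.seq_index}")
            prev_seq[res.chain_id] = res.seq_index
        for p in range(1, len(self.residues)):
            a, b = self.residues[p - 1], self.residues[p]
            linked = False
            if a.chain_id == b.chain_id and a.has_atom("C") and b.has_atom("N"):
                linked = (np.linalg.norm(a.coord("C") - b.coord("N"))
                          <= PEPTIDE_BOND_MAX)
            if not linked:
                self._breaks.add(p)
                if warn_breaks and a.chain_id == b.chain_id:
                    warnings.warn(
                        f"chain break between {a.res_type}{a.seq_index} and "
                        f"{b.res_type}{b.seq_index} in chain {a.chain_id}",
                        GridShieldWarning, stacklevel=2)
        for p, res in enumerate(self.residues):
            internal = (self.neighbor(p, -1) is not None
                        and self.neighbor(p, +1) is not None)
            if internal:
                for name in ("N", "CA", "C"):
                    if not res.has_atom(name):
                        raise MissingAtomError(
                            f"non-terminal residue {res.res_type}{res.seq_index} "
                            f"lacks backbone atom {name}")
        self._warn_disulfides()

    def _warn_disulfides(self):
        sg = [(r, r.coord("SG")) for r in self.residues
              if r.res_type == "CYS" and r.has_atom("SG")]
        for i in range(len(sg)):
            for j in range(i + 1, len(sg)):
                if np.linalg.norm(sg[i][1] - sg[j][1]) < 2.5:
                    warnings.warn(
                        f"Cys{sg[i][0].seq_index}-Cys{sg[j][0].seq_index} look "
                        "disulfide-bonded; both are treated as free cysteine",
                        GridShieldWarning, stacklevel=3)

    def __len__(self):
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def neighbor(self, pos: int, delta: int) -> int | None:
        """List position of the chain neighbour, or None across termini/breaks."""
        q = pos + delta
        if q < 0 or q >= len(self.residues):
            return None
        if self.residues[pos].chain_id != self.residues[q].chain_id:
            return None
        if delta == -1 and pos in self._breaks:
            return None
        if delta == +1 and q in self._breaks:
            return None
        return q

    @property
    def sequence(self) -> tuple[tuple[str, int, str], ...]:
        return tuple((r.chain_id, r.seq_index, r.res_type) for r in self.residues)


@dataclass
class Ensemble:
    models: list[ProteinModel]

    def __post_init__(self):
        if not self.models:
            raise StructureParseError("ensemble with no models")
        ref = self.models[0].sequence
        for m in self.models[1:]:
            if m.sequence != ref:
                raise StructureParseError(
                    f"model {m.model_index} sequence differs from model "
                    f"{self.models[0].model_index}")

    def __len__(self):
        return len(self.models)

    def __iter__(self):
        return iter(self.models)


# ---------------------------------------------------------------------------
# structure reading


def read_structure(path, format: str = "pdb") -> Ensemble:
    """Read a PDB file into an :class:`Ensemble` (one model per MODEL record).

    Alternate locations resolve to the highest-occupancy conformer
    (first seen on ties); waters and hetero groups are dropped.
    """
    if format != "pdb":
        raise StructureParseError(f"unsupported format {format!r}; only 'pdb'")
    path = Path(path)
    if not path.is_file():
        raise StructureParseError(f"no such file: {path}")
    from Bio.PDB import PDBParser

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = PDBParser(QUIET=True).get_structure(path.stem, str(path))
    except Exception as exc:  # Bio raises plain ValueError with line info
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc

    models = []
    for bm in structure:
        residues: list[ResidueRecord] = []
        for chain in bm:
            for bres in chain:
                hetfield, resseq, icode = bres.id
                if hetfield.strip():  # water or hetero group
                    continue
                if icode.strip():
                    raise InsertionCodeError(
                        f"insertion code {icode!r} at residue {resseq} "
                        f"(chain {chain.id}) is unsupported")
                resname = bres.get_resname().strip()
                if resname not in STANDARD_RESIDUES:
                    raise NonStandardResidueError(
                        f"non-standard residue {resname!r} at {chain.id}{resseq}")
                atoms = []
                for batom in bres:
                    if batom.is_disordered():
                        children = batom.disordered_get_list()
                        best = max(children,
                                   key=lambda a: (a.get_occupancy() or 0.0))
                        batom = best
                    atoms.append(AtomRecord(
                        name=batom.get_name(),
                        element=(batom.element or "").strip() or batom.get_name()[0],
                        position=np.array(batom.get_coord(), dtype=float),
                        serial=batom.get_serial_number() or 0,
                    ))
                residues.append(ResidueRecord(resname, resseq, chain.id, atoms))
        if residues:
            models.append(ProteinModel(residues, model_index=bm.id))
    if not models:
        raise StructureParseError(f"{path}: no polymer residues found")
    return Ensemble(models)


def write_pdb(models: Ensemble | ProteinModel, path) -> None:
    """Write models to a minimal PDB file (fixture/round-trip support)."""
    if isinstance(models, ProteinModel):
        models = Ensemble([models])
    multi = len(models) > 1
    with open(Path(path), "w") as fh:
        for k, model in enumerate(models, start=1):
            if multi:
                fh.write(f"MODEL     {k:4d}\n")
            serial = 0
            for res in model:
                for atom in res.atoms:
                    serial += 1
                    name = atom.name
                    # PDB column-13 alignment rule for short names
                    fname = f" {name:<3s}" if len(name) < 4 else name
                    x, y, z = atom.position
                    fh.write(
                        f"ATOM  {serial:5d} {fname:<4s}{res.res_type:>4s} "
                        f"{res.chain_id}{res.seq_index:4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                        f"          {atom.element:>2s}\n")
            fh.write("TER\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# hydrogen building


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise GridShieldError("zero-length vector in hydrogen construction")
    return v / n


def ensure_amide_hydrogens(model: ProteinModel, policy: str = "require") -> ProteinModel:
    """Check or build backbone amide hydrogens.

    With ``policy="build"`` a missing H is placed in the
    C(i-1)/N(i)/CA(i) plane on the bisector of the two N bonds, 1.01 A
    from N.  Proline and N-terminal residues are skipped; existing
    hydrogens are never moved.
    """
    if policy not in ("require", "build"):
        raise GridShieldError(f"policy must be require/build, got {policy!r}")
    missing = []
    for p, res in enumerate(model):
        if res.res_type == "PRO":
            continue
        prev = model.neighbor(p, -1)
        if prev is None:
            continue
        if res.has_atom("H"):
            continue
        missing.append((p, prev))
    if not missing:
        return model
    if policy == "require":
        names = ", ".join(f"{model.residues[p].res_type}"
                          f"{model.residues[p].seq_index}" for p, _ in missing)
        raise MissingAtomError(f"residues lacking amide H: {names}")
    new_residues = []
    build = dict(missing)
    for p, res in enumerate(model):
        atoms = [AtomRecord(a.name, a.element, a.position.copy(), a.serial)
                 for a in res.atoms]
        new_res = ResidueRecord(res.res_type, res.seq_index, res.chain_id, atoms)
        if p in build:
            c_prev = model.residues[build[p]].coord("C")
            n = res.coord("N")
            ca = res.coord("CA")
            direction = -_unit(_unit(c_prev - n) + _unit(ca - n))
            new_res.add_atom(AtomRecord("H", "H", n + NH_BOND_LENGTH * direction))
        new_residues.append(new_res)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", GridShieldWarning)
        return ProteinModel(new_residues, model_index=model.model_index)


# ---------------------------------------------------------------------------
# shift tables


@dataclass
class ShiftTable:
    """Experimental (or synthetic) shifts keyed by (seq_index, atom_type)."""

    entries: dict[tuple[int, str], float] = field(default_factory=dict)
    res_types: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        for key, val in self.entries.items():
            if not math.isfinite(val):
                raise ShiftTableError(f"non-finite shift for {key}")

    def get(self, seq_index: int, atom_type: str) -> float | None:
        return self.entries.get((seq_index, atom_type))

    def __len__(self):
        return len(self.entries)

    def cross_check(self, model: ProteinModel) -> None:
        by_seq = {r.seq_index: r.res_type for r in model}
        for seq, rt in self.res_types.items():
            if seq in by_seq and by_seq[seq] != rt:
                raise ShiftTableError(
                    f"residue {seq}: table says {rt}, structure says {by_seq[seq]}")


_ATOM_SYNONYMS = {"H": "HN", "HN": "HN", "CO": "C"}
_VALID_ATOM_TYPES = {"CA", "CB", "C", "HA", "HN", "N"}


def read_shift_table(path) -> ShiftTable:
    """Read a whitespace/comma-delimited table of
    (seq_index, res_type, atom_type, shift).

    ``H`` normalizes to ``HN``; glycine ``HA2``/``HA3`` rows are averaged
    into a single ``HA`` entry.  Duplicate keys are an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=r"[,\s]+", engine="python", header=None,
                     comment="#", skip_blank_lines=True)
    if df.shape[1] != 4:
        raise ShiftTableError(
            f"{path}: expected 4 columns (seq_index res_type atom_type shift), "
            f"got {df.shape[1]}")
    # tolerate a header row
    try:
        int(df.iloc[0, 0])
    except (TypeError, ValueError):
        df = df.iloc[1:].reset_index(drop=True)
    entries: dict[tuple[int, str], float] = {}
    res_types: dict[int, str] = {}
    ha_halves: dict[int, list[float]] = {}
    for row in df.itertuples(index=False):
        try:
            seq = int(row[0])
            shift = float(row[3])
        except (TypeError, ValueError) as exc:
            raise ShiftTableError(f"{path}: bad row {tuple(row)!r}") from exc
        res_type = str(row[1]).upper()
        raw_atom = str(row[2]).upper()
        if seq in res_types and res_types[seq] != res_type:
            raise ShiftTableError(f"{path}: residue {seq} typed both "
                                  f"{res_types[seq]} and {res_type}")
        res_types[seq] = res_type
        if raw_atom in ("HA2", "HA3"):
            ha_halves.setdefault(seq, []).append(shift)
            continue
        atom = _ATOM_SYNONYMS.get(raw_atom, raw_atom)
        if atom not in _VALID_ATOM_TYPES:
            raise ShiftTableError(f"{path}: unknown atom type {raw_atom!r}")
        key = (seq, atom)
        if key in entries:
            raise ShiftTableError(f"{path}: duplicate entry for {key}")
        entries[key] = shift
    for seq, vals in ha_halves.items():
        key = (seq, "HA")
        if key in entries:
            raise ShiftTableError(f"{path}: both HA and HA2/HA3 given for {seq}")
        entries[key] = float(np.mean(vals))
    return ShiftTable(entries, res_types)


# ---------------------------------------------------------------------------
# report writing

TERM_COLUMNS = ("BB", "BB_prev", "BB_next", "HB1", "HB2",
                "HaB1", "HaB2", "RC", "W")

REPORT_COLUMNS = ("model_index", "seq_index", "res_type", "atom_type",
                  *TERM_COLUMNS, "sigma_total", "delta_pred", "delta_exp",
                  "residual")


def write_report(predictions, calibration=None, path=None,
                 exp: ShiftTable | None = None) -> pd.DataFrame:
    """Write the per-atom term breakdown as a TSV with fixed column order.

    ``calibration`` maps atom_type to a fitted result carrying ``a`` and
    ``b``; when present, predicted shifts b - a*sigma and residuals
    against ``exp`` are filled in.
    """
    calibration = calibration or {}
    rows = []
    for b in predictions:
        row = {
            "model_index": b.model_index,
            "seq_index": b.seq_index,
            "res_type": b.res_type,
            "atom_type": b.atom_type,
            "sigma_total": b.sigma_total,
        }
        for term_id in TERM_COLUMNS:
            tv = b.terms.get(term_id)
            row[term_id] = (np.nan if tv is None or tv.provenance == "masked"
                            else tv.value)
        cal = calibration.get(b.atom_type)
        delta_pred = (cal.b - cal.a * b.sigma_total) if cal is not None else np.nan
        delta_exp = exp.get(b.seq_index, b.atom_type) if exp is not None else None
        delta_exp = np.nan if delta_exp is None else delta_exp
        row["delta_pred"] = delta_pred
        row["delta_exp"] = delta_exp
        row["residual"] = delta_pred - delta_exp
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
    if path is not None:
        df.to_csv(Path(path), sep="\t", index=False, float_format="%.9f",
                  na_rep="")
    return df


def write_calibration_report(results: dict, path) -> pd.DataFrame:
    """Per-atom-type calibration summary as TSV."""
    rows = []
    for atom_type in sorted(results):
        r = results[atom_type]
        rows.append({
            "atom_type": atom_type,
            "a": r.a, "b": r.b, "n": r.n,
            "rmsd": r.rmsd, "pearson_r": r.pearson_r,
            "outliers": ";".join(str(k) for k in r.outliers) or "-",
            "a_refit": getattr(r, "a_refit", np.nan),
            "b_refit": getattr(r, "b_refit", np.nan),
            "rmsd_refit": getattr(r, "rmsd_refit", np.nan),
            "pearson_r_refit": getattr(r, "pearson_r_refit", np.nan),
        })
    df = pd.DataFrame(rows, columns=["atom_type", "a", "b", "n", "rmsd",
                                     "pearson_r", "outliers", "a_refit",
                                     "b_refit", "rmsd_refit",
                                     "pearson_r_refit"])
    if path is not None:
        df.to_csv(Path(path), sep="\t", index=False, float_format="%.9f",
                  na_rep="")
    return df
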