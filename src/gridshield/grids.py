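"""Periodic shielding hypersurfaces and the on-disk grid bundle.

A bundle is a directory with ``manifest.json`` plus one raw little-endian
float64 array per grid (C order).  Dihedral axes are periodic and cover
[-180, 180) without a duplicated seam node; interpolation is either
tensor-product cubic (periodic across the seam) or nearest-neighbour,
declared per grid in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import ConfigurationError, GridBundleError, InterpolationError

SCHEMA_VERSION = 1

DIHEDRAL_AXES = frozenset({"phi", "psi", "chi1", "chi2", "chi3", "chi4", "rho"})


def wrap_angle(x: float) -> float:
    """Map an angle in degrees onto [-180, 180)."""
    if not math.isfinite(x):
        raise InterpolationError(f"non-finite angle: {x!r}")
    y = math.fmod(x + 180.0, 360.0)
    if y < 0:
        y += 360.0
    return y - 180.0


@dataclass(frozen=True)
class AxisSpec:
    """One axis of a shielding grid."""

    name: str
    start: float
    spacing: float
    n: int
    periodic: bool

    def __post_init__(self):
        if self.n < 2:
            raise GridBundleError(f"axis {self.name}: needs >= 2 nodes, got {self.n}")
        if self.spacing <= 0:
            raise GridBundleError(f"axis {self.name}: spacing must be positive")
        if self.periodic:
            span = self.spacing * self.n
            if abs(span - 360.0) > 1e-9:
                raise GridBundleError(
                    f"axis {self.name}: periodic axis must cover exactly 360 deg "
                    f"without a seam duplicate; {self.n} nodes x {self.spacing} deg "
                    f"= {span} deg"
                )
            if abs(self.start + 180.0) > 1e-9:
                raise GridBundleError(
                    f"axis {self.name}: periodic axis must start at -180, got {self.start}"
                )

    @property
    def nodes(self) -> np.ndarray:
        return self.start + self.spacing * np.arange(self.n)

    @property
    def stop(self) -> float:
        return self.start + self.spacing * (self.n - 1)

    def to_json(self) -> dict:
        return {
            "name": self.name,
            "start": self.start,
            "spacing": self.spacing,
            "n": self.n,
            "periodic": self.periodic,
        }

    @staticmethod
    def from_json(d: dict) -> "AxisSpec":
        return AxisSpec(d["name"], d["start"], d["spacing"], int(d["n"]),
                        bool(d["periodic"]))


@dataclass
class ShieldingGrid:
    """A dense shielding surface over an ordered list of axes."""

    grid_id: str
    axes: list[AxisSpec]
    values: np.ndarray
    interp_mode: str = "cubic"  # "cubic" | "nearest"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        shape = tuple(ax.n for ax in self.axes)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size != int(np.prod(shape)):
            raise GridBundleError(
                f"grid {self.grid_id}: {self.values.size} values for axes shape {shape}"
            )
        self.values = self.values.reshape(shape)
        if self.interp_mode not in ("cubic", "nearest"):
            raise GridBundleError(f"grid {self.grid_id}: bad mode {self.interp_mode!r}")

    @property
    def axis_names(self) -> tuple[str, ...]:
        return tuple(ax.name for ax in self.axes)


def _canon_coord(ax: AxisSpec, x: float) -> float:
    """Wrap periodic coords; clamp non-periodic coords to the axis range."""
    if x is None:
        raise InterpolationError(f"axis {ax.name}: coordinate is absent")
    if ax.periodic:
        return wrap_angle(float(x))
    return min(max(float(x), ax.start), ax.stop)


def interpolate(grid: ShieldingGrid, coords) -> float:
    """Evaluate a grid at one point.

    Cubic mode uses successive 1-D cubic splines, with true periodic
    boundary conditions on dihedral axes (seam-continuous); nearest mode
    returns the value stored at :func:`nearest_node`.
    """
    coords = list(coords)
    if len(coords) != len(grid.axes):
        raise InterpolationError(
            f"grid {grid.grid_id}: got {len(coords)} coordinates for "
            f"{len(grid.axes)} axes {grid.axis_names}"
        )
    if grid.interp_mode == "nearest":
        return float(grid.values[nearest_node(grid, coords)])
    arr = grid.values
    for ax, x in zip(grid.axes, coords):
        x = _canon_coord(ax, x)
        nodes = ax.nodes
        if ax.periodic:
            # periodic spline needs the seam node repeated with equal value
            xs = np.append(nodes, nodes[0] + 360.0)
            ys = np.concatenate([arr, arr[:1]], axis=0)
            spl = CubicSpline(xs, ys, axis=0, bc_type="periodic")
        else:
            spl = CubicSpline(nodes, arr, axis=0)
        arr = spl(x)
    return float(arr)


def nearest_node(grid: ShieldingGrid, coords) -> tuple[int, ...]:
    """Per-axis nearest node; periodic distance on dihedral axes.

    Exact midpoints break toward the smaller node coordinate.
    """
    coords = list(coords)
    if len(coords) != len(grid.axes):
        raise InterpolationError(
            f"grid {grid.grid_id}: got {len(coords)} coordinates for "
            f"{len(grid.axes)} axes"
        )
    idx = []
    for ax, x in zip(grid.axes, coords):
        x = _canon_coord(ax, x)
        nodes = ax.nodes
        if ax.periodic:
            d = np.abs(((nodes - x) + 180.0) % 360.0 - 180.0)
        else:
            d = np.abs(nodes - x)
        best = np.flatnonzero(d <= d.min() + 1e-12)
        # ties: smallest node coordinate wins
        idx.append(int(best[np.argmin(nodes[best])]))
    return tuple(idx)


# ---------------------------------------------------------------------------
# bundle container


class GridLibrary:
    """A loaded (possibly lazy) bundle of shielding grids and constants.

    Grid ids follow ``kind__<key parts>`` with double-underscore
    separators; see the accessor methods for the naming scheme.
    """

    def __init__(self, root: Path | None, manifest: dict,
                 grids: dict[str, ShieldingGrid] | None = None):
        self.root = Path(root) if root is not None else None
        self.manifest = manifest
        self._grids: dict[str, ShieldingGrid] = dict(grids or {})
        self._entries = {g["id"]: g for g in manifest.get("grids", [])}
        if not self._entries and not self._grids:
            raise GridBundleError("library contains no grids")
        for atom, v in manifest.get("sigma_A", {}).items():
            if not math.isfinite(v):
                raise GridBundleError(f"sigma_A[{atom}] is not finite")

    # -- constants ---------------------------------------------------------
    @property
    def sigma_A(self) -> dict[str, float]:
        sa = self.manifest.get("sigma_A")
        if sa is None:
            raise GridBundleError("bundle manifest lacks sigma_A constants")
        return sa

    @property
    def phi_std(self) -> float:
        return self.manifest.get("phi_std", -120.0)

    @property
    def psi_std(self) -> float:
        return self.manifest.get("psi_std", 140.0)

    @property
    def delta_sigma_w(self) -> float:
        return self.manifest.get("delta_sigma_w", 2.07)

    @property
    def water_sign(self) -> float:
        return self.manifest.get("water_sign", -1.0)

    @property
    def rho_sign_convention(self) -> str:
        return self.manifest.get("rho_sign_convention", "right_handed")

    # -- grid access -------------------------------------------------------
    def _load(self, grid_id: str) -> ShieldingGrid:
        if grid_id in self._grids:
            return self._grids[grid_id]
        entry = self._entries.get(grid_id)
        if entry is None:
            raise ConfigurationError(f"library has no grid {grid_id!r}")
        if self.root is None:
            raise GridBundleError(f"grid {grid_id!r} has no backing file")
        path = self.root / entry["file"]
        expected = int(np.prod([a["n"] for a in entry["axes"]]))
        data = np.fromfile(path, dtype="<f8")
        if data.size != expected:
            raise GridBundleError(
                f"grid {grid_id}: file {path.name} holds {data.size} values, "
                f"manifest promises {expected}"
            )
        grid = ShieldingGrid(
            grid_id=grid_id,
            axes=[AxisSpec.from_json(a) for a in entry["axes"]],
            values=data,
            interp_mode=entry.get("interp_mode", "cubic"),
            meta=entry.get("meta", {}),
        )
        self._grids[grid_id] = grid
        return grid

    def has_grid(self, grid_id: str) -> bool:
        return grid_id in self._grids or grid_id in self._entries

    def grid(self, grid_id: str) -> ShieldingGrid:
        return self._load(grid_id)

    def grid_ids(self) -> list[str]:
        ids = set(self._entries) | set(self._grids)
        return sorted(ids)

    def center_grid(self, res_type: str, atom: str) -> ShieldingGrid:
        return self._load(f"center__{res_type}__{atom}")

    def neighbor_grid(self, side: str, res_type: str, atom: str) -> ShieldingGrid:
        if side not in ("prev", "next"):
            raise ConfigurationError(f"side must be prev/next, got {side!r}")
        return self._load(f"{side}__{res_type}__{atom}")

    def hbond_surface(self, term_id: str, class_key: str, atom: str) -> ShieldingGrid:
        gid = f"hbond__{term_id}__{class_key}__{atom}"
        if not self.has_grid(gid):
            raise ConfigurationError(
                f"no hydrogen-bond surface for term={term_id} class={class_key} "
                f"atom={atom}"
            )
        return self._load(gid)

    # -- validation --------------------------------------------------------
    def validate_consistency(self, tol: float = 1e-9) -> None:
        """Check the neighbor-reference identity on the bundle's own Ala grids.

        If Ala neighbor-effect grids are present, their value at
        (phi_std, psi_std) must equal sigma_A for every atom, so the
        neighbor correction of an Ala in the standard conformation is
        exactly zero.
        """
        for side in ("prev", "next"):
            for atom, ref in self.sigma_A.items():
                gid = f"{side}__ALA__{atom}"
                if not self.has_grid(gid):
                    continue
                grid = self._load(gid)
                coords = [self.phi_std, self.psi_std] + [0.0] * (len(grid.axes) - 2)
                val = interpolate(grid, coords)
                if abs(val - ref) > tol:
                    raise GridBundleError(
                        f"sigma_A inconsistency for {gid}: grid gives {val!r} at "
                        f"({self.phi_std}, {self.psi_std}) but sigma_A[{atom}] = {ref!r}"
                    )


# ---------------------------------------------------------------------------
# bundle I/O


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def save_library(lib: GridLibrary, path) -> Path:
    """Write a library to a bundle directory (manifest.json + .f64 files)."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    entries = []
    for gid in lib.grid_ids():
        grid = lib.grid(gid)
        fname = gid + ".f64"
        arr = np.ascontiguousarray(grid.values, dtype="<f8")
        arr.tofile(root / fname)
        entries.append({
            "id": gid,
            "file": fname,
            "axes": [ax.to_json() for ax in grid.axes],
            "interp_mode": grid.interp_mode,
            "dtype": "<f8",
            "order": "C",
            "sha256": _sha256(root / fname),
            "meta": grid.meta,
        })
    manifest = dict(lib.manifest)
    manifest["schema_version"] = SCHEMA_VERSION
    manifest["grids"] = entries
    with open(root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return root


def load_library(path, verify_checksums: bool = True, lazy: bool = True) -> GridLibrary:
    """Load a bundle directory; arrays are read on first access when lazy."""
    root = Path(path)
    mpath = root / "manifest.json"
    if not mpath.is_file():
        raise GridBundleError(f"no manifest.json under {root}")
    with open(mpath) as fh:
        manifest = json.load(fh)
    for entry in manifest.get("grids", []):
        fpath = root / entry["file"]
        if not fpath.is_file():
            raise GridBundleError(f"bundle missing array file {entry['file']}")
        expected = int(np.prod([a["n"] for a in entry["axes"]])) * 8
        if fpath.stat().st_size != expected:
            raise GridBundleError(
                f"{entry['file']}: {fpath.stat().st_size} bytes on disk, "
                f"manifest implies {expected}"
            )
        # validate axis specs eagerly (seam-duplication errors etc.)
        for a in entry["axes"]:
            AxisSpec.from_json(a)
        if verify_checksums and "sha256" in entry:
            got = _sha256(fpath)
            if got != entry["sha256"]:
                raise GridBundleError(f"{entry['file']}: checksum mismatch")
    lib = GridLibrary(root, manifest)
    if "sigma_A" not in manifest:
        raise GridBundleError("bundle manifest lacks sigma_A constants")
    if not lazy:
        for gid in lib.grid_ids():
            lib.grid(gid)
    lib.validate_consistency()
    return lib


# ---------------------------------------------------------------------------
# plain-text exchange format for hand-written test grids


def grid_from_tsv(path, grid_id: str | None = None,
                  interp_mode: str = "cubic") -> ShieldingGrid:
    """Read a grid from a TSV of node coordinates plus a ``value`` column.

    The header names the axes; a leading ``#`` line of the form
    ``# periodic: phi,psi`` marks periodic axes.  Rows must jointly cover
    the full lattice (any order).
    """
    path = Path(path)
    periodic: set[str] = set()
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            key, _, rest = first[1:].partition(":")
            if key.strip() == "periodic":
                periodic = {s.strip() for s in rest.split(",") if s.strip()}
            header = fh.readline()
        else:
            header = first
        cols = header.split()
        if cols[-1] != "value":
            raise GridBundleError("last TSV column must be 'value'")
        axis_names = cols[:-1]
        rows = [tuple(float(tok) for tok in line.split())
                for line in fh if line.strip()]
    data = np.array(rows, dtype=float)
    axes = []
    for k, name in enumerate(axis_names):
        nodes = np.unique(data[:, k])
        spacings = np.diff(nodes)
        if len(nodes) < 2 or not np.allclose(spacings, spacings[0], atol=1e-9):
            raise GridBundleError(f"axis {name}: nodes not uniformly spaced")
        axes.append(AxisSpec(name, float(nodes[0]), float(spacings[0]),
                             len(nodes), name in periodic))
    shape = tuple(ax.n for ax in axes)
    if len(data) != int(np.prod(shape)):
        raise GridBundleError(
            f"{len(data)} rows do not cover the {shape} lattice")
    values = np.full(shape, np.nan)
    for row in data:
        idx = tuple(int(round((row[k] - axes[k].start) / axes[k].spacing))
                    for k in range(len(axes)))
        values[idx] = row[-1]
    if np.isnan(values).any():
        raise GridBundleError("TSV rows leave lattice nodes unassigned")
    return ShieldingGrid(grid_id or path.stem, axes, values, interp_mode)


def grid_to_tsv(grid: ShieldingGrid, path) -> None:
    """Inverse of :func:`grid_from_tsv`."""
    path = Path(path)
    periodic = [ax.name for ax in grid.axes if ax.periodic]
    with open(path, "w") as fh:
        if periodic:
            fh.write("# periodic: " + ",".join(periodic) + "\n")
        fh.write("\t".join([*grid.axis_names, "value"]) + "\n")
        meshes = np.meshgrid(*[ax.nodes for ax in grid.axes], indexing="ij")
        flat = [m.ravel() for m in meshes]
        for i, v in enumerate(grid.values.ravel()):
            coords = "\t".join(f"{m[i]:.10g}" for m in flat)
            fh.write(f"{coords}\t{float(v)!r}\n")
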