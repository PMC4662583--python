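"""Shared fixtures: seeded synthetic libraries and toy structures."""

import numpy as np
import pytest

from gridshield import (
    GridLibrary,
    SurfaceSpec,
    make_library,
    make_toy_structure,
)
from gridshield.grids import AxisSpec, ShieldingGrid


@pytest.fixture(scope="session")
def tiny_lib(tmp_path_factory) -> GridLibrary:
    """Seeded smooth cosine library over ALA/VAL/SER."""
    root = tmp_path_factory.mktemp("bundles") / "tiny"
    return make_library(root, residues=("ALA", "VAL", "SER"), spacing=20.0,
                        seed=1)


@pytest.fixture(scope="session")
def gly_lib(tmp_path_factory) -> GridLibrary:
    root = tmp_path_factory.mktemp("bundles") / "gly"
    return make_library(root, residues=("ALA", "GLY", "PRO", "TRP"),
                        spacing=20.0, chi_spacing=40.0, seed=3)


@pytest.fixture(scope="session")
def zero_lib(tmp_path_factory) -> GridLibrary:
    """All-zero library: every term must evaluate to exactly 0."""
    root = tmp_path_factory.mktemp("bundles") / "zero"
    return make_library(root, residues=("ALA", "VAL", "SER"), spacing=20.0,
                        seed=0, surface=SurfaceSpec("constant", {"c": 0.0}),
                        delta_sigma_w=0.0)


@pytest.fixture(scope="session")
def const_lib(tmp_path_factory) -> GridLibrary:
    root = tmp_path_factory.mktemp("bundles") / "const"
    return make_library(root, residues=("ALA", "VAL", "SER"), spacing=20.0,
                        seed=0, surface=SurfaceSpec("constant", {"c": 120.0}))


@pytest.fixture()
def penta_ala():
    return make_toy_structure("AAAAA", (-140.0, 140.0))


def constant_grid(grid_id: str, axes, c: float,
                  mode: str = "cubic") -> ShieldingGrid:
    shape = [ax.n for ax in axes]
    return ShieldingGrid(grid_id, list(axes), np.full(shape, float(c)), mode)


def backbone_axes(spacing: float = 20.0, n_chi: int = 0):
    n = int(round(360 / spacing))
    axes = [AxisSpec("phi", -180.0, spacing, n, True),
            AxisSpec("psi", -180.0, spacing, n, True)]
    for k in range(n_chi):
        axes.append(AxisSpec(f"chi{k + 1}", -180.0, spacing, n, True))
    return axes


def hbond_axes(term: str, rho_spacing: float = 20.0):
    from gridshield.synth import HBOND_R_AXES

    r0, dr, nr = HBOND_R_AXES[term]
    return [AxisSpec("r", r0, dr, nr, False),
            AxisSpec("theta", 90.0, 10.0, 10, False),
            AxisSpec("rho", -180.0, rho_spacing,
                     int(round(360 / rho_spacing)), True)]


def manual_library(grids: dict, sigma_A: float | dict = 0.0,
                   delta_sigma_w: float = 2.07,
                   water_sign: float = -1.0) -> GridLibrary:
    """In-memory GridLibrary for hand-crafted term tests."""
    from gridshield.residues import ATOM_TYPES

    if not isinstance(sigma_A, dict):
        sigma_A = {a: float(sigma_A) for a in ATOM_TYPES}
    manifest = {"sigma_A": sigma_A, "phi_std": -120.0, "psi_std": 140.0,
                "delta_sigma_w": delta_sigma_w, "water_sign": water_sign,
                "rho_sign_convention": "right_handed", "grids": []}
    return GridLibrary(None, manifest, grids)
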