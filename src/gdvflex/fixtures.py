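"""Seed-deterministic synthetic structures, graphs and training datasets.

These generators stand in for downloaded structures in tests and examples.
They produce pseudo-atoms (4 per residue, one of them named CA) whose packing
density is protein-like; the graphlet machinery only sees geometry, so
chemically exact side chains are unnecessary.  Everything is reproducible:
the same spec always yields byte-identical output.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .contact_graph import ContactGraph, GraphParams
from .errors import ParameterError
from .flex_model import (
    ModelCoefficients,
    RMSFProfile,
    TrainingProtein,
    TrainingSet,
    published_model,
    transform_features,
)
from .gdv_core import gdv_all_at_once
from .structure_io import AtomTable

_ATOM_NAMES = ("N", "CA", "C", "O")
_ELEMENTS = ("N", "C", "C", "O")

#: idealized alpha-helix backbone geometry
HELIX_RISE = 1.5  # Å per residue along the axis
HELIX_TWIST = 100.0  # degrees per residue
HELIX_RADIUS = 2.3  # Å, Cα distance from the axis

ROD_STEP = 3.5  # Å per residue for the extended rod


def _table_from_coords(coords: np.ndarray, n_res: int) -> AtomTable:
    """Assemble an AtomTable from (n_res*4, 3) coordinates, 4 atoms/residue."""
    n_atoms = n_res * len(_ATOM_NAMES)
    df = pd.DataFrame(
        {
            "serial": np.arange(1, n_atoms + 1),
            "atom_name": list(_ATOM_NAMES) * n_res,
            "alt_loc": "",
            "res_name": "ALA",
            "chain_id": "A",
            "res_seq": np.repeat(np.arange(1, n_res + 1), len(_ATOM_NAMES)),
            "insertion_code": "",
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
            "occupancy": 1.0,
            "b_value": 0.0,
            "element": list(_ELEMENTS) * n_res,
            "record": "ATOM",
        }
    )
    return AtomTable(df)


def _backbone_offsets(theta: np.ndarray, radius: float) -> list[np.ndarray]:
    """Coordinates of N, CA, C, O given per-residue phase angles and z in theta."""
    # theta: (n_res, 2) columns = (angle rad, z)
    ang, z = theta[:, 0], theta[:, 1]

    def ring(dr: float, dang: float, dz: float) -> np.ndarray:
        r = radius + dr
        a = ang + dang
        return np.column_stack([r * np.cos(a), r * np.sin(a), z + dz])

    return [
        ring(-0.6, -0.7, -0.9),  # N
        ring(0.0, 0.0, 0.0),  # CA on the ideal curve
        ring(-0.3, 0.7, 0.6),  # C
        ring(1.0, 1.0, 0.8),  # O, pointing outward
    ]


def _interleave(parts: Sequence[np.ndarray]) -> np.ndarray:
    n_res = parts[0].shape[0]
    out = np.empty((n_res * len(parts), 3))
    for k, p in enumerate(parts):
        out[k :: len(parts)] = p
    return out


def make_helix_structure(n_res: int, seed: int = 0, jitter_sd: float = 0.2) -> AtomTable:
    """Idealized α-helical backbone with seeded coordinate jitter."""
    if n_res < 2:
        raise ParameterError(f"need n_res >= 2, got {n_res}")
    rng = np.random.default_rng(seed)
    i = np.arange(n_res)
    theta = np.column_stack([np.deg2rad(HELIX_TWIST) * i, HELIX_RISE * i])
    coords = _interleave(_backbone_offsets(theta, HELIX_RADIUS))
    coords += rng.normal(0.0, jitter_sd, coords.shape)
    return _table_from_coords(coords, n_res)


def make_rod_structure(
    n_res: int, seed: int = 0, jitter_sd: float = 0.2, step: float = ROD_STEP
) -> AtomTable:
    """Extended straight backbone (``step`` Å/residue along x) with jitter.

    Deliberately non-globular: its radius of gyration grows linearly with
    length, so long rods fail the Rg < N^0.6 compactness filter.
    """
    if n_res < 2:
        raise ParameterError(f"need n_res >= 2, got {n_res}")
    rng = np.random.default_rng(seed)
    i = np.arange(n_res)
    x = step * i
    offsets = [(-1.2, -0.8, 0.0), (0.0, 0.0, 0.0), (1.2, 0.8, 0.0), (1.4, -0.6, 1.0)]
    parts = [np.column_stack([x + dx, np.full(n_res, dy), np.full(n_res, dz)]) for dx, dy, dz in offsets]
    coords = _interleave(parts) + rng.normal(0.0, jitter_sd, (n_res * 4, 3))
    return _table_from_coords(coords, n_res)


#: pseudo-residue packing density for cloud geometries (residues per Å^3),
#: matching the ~110 Å^3 occupied volume of a typical amino acid
_RESIDUE_DENSITY = 0.009


def make_cloud_structure(
    n_res: int,
    seed: int = 0,
    spread: float = 0.9,
    density: float = _RESIDUE_DENSITY,
) -> AtomTable:
    """Globular random cloud: residues uniform in a sphere.

    ``density`` is the residue density (residues/Å^3); the default matches
    protein-like packing, lower values give loose, sparsely connected clouds.
    """
    if n_res < 2:
        raise ParameterError(f"need n_res >= 2, got {n_res}")
    if density <= 0:
        raise ParameterError(f"density must be positive, got {density}")
    rng = np.random.default_rng(seed)
    radius = (3.0 * n_res / (4.0 * np.pi * density)) ** (1.0 / 3.0)
    centers = rng.normal(size=(n_res, 3))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    centers *= radius * rng.random(n_res)[:, None] ** (1.0 / 3.0)
    coords = np.repeat(centers, 4, axis=0)
    coords[1::4] += 0.0  # CA sits on the residue center
    for k in (0, 2, 3):
        coords[k::4] += rng.normal(0.0, spread, (n_res, 3))
    return _table_from_coords(coords, n_res)


def make_two_domain_structure(n_res: int, seed: int = 0) -> AtomTable:
    """Two compact clouds joined end to end, mimicking a two-domain protein."""
    if n_res < 4:
        raise ParameterError(f"need n_res >= 4, got {n_res}")
    rng = np.random.default_rng(seed)
    n1 = n_res // 2
    a = make_cloud_structure(n1, seed=int(rng.integers(2**31)))
    b = make_cloud_structure(n_res - n1, seed=int(rng.integers(2**31)))
    ca, cb = a.coords, b.coords
    # butt the second domain against the first along x, 4 Å apart
    shift = ca[:, 0].max() - cb[:, 0].min() + 4.0
    coords = np.vstack([ca, cb + np.array([shift, 0.0, 0.0])])
    return _table_from_coords(coords, n_res)


def make_random_graph(n: int, p: float, seed: int = 0) -> ContactGraph:
    """Seeded Erdős–Rényi G(n, p) as a ContactGraph."""
    if n < 2:
        raise ParameterError(f"need n >= 2, got {n}")
    if not 0.0 <= p <= 1.0:
        raise ParameterError(f"p must be in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    upper = np.triu(rng.random((n, n)) < p, k=1)
    return ContactGraph(n, np.argwhere(upper))


def _mixed_structure(i: int, n_res: int, rng: np.random.Generator) -> tuple[str, AtomTable]:
    """Structure stream for the training-set generator.

    Alternates loose clouds (3D packing, varied density) with loose rods
    (1D packing, varied pitch).  Spanning packing regimes of different
    dimensionality keeps the fifteen log-orbit features mutually
    identifiable — a single geometric family leaves the triangle orbit
    nearly collinear with the degree orbits and OLS cannot separate them.
    """
    seed = int(rng.integers(2**31))
    if i % 2 == 0:
        density = float(np.exp(rng.uniform(np.log(0.0008), np.log(0.0025))))
        atoms = make_cloud_structure(
            n_res, seed=seed, spread=float(rng.uniform(0.5, 1.2)), density=density
        )
        return "cloud", atoms
    atoms = make_rod_structure(
        n_res,
        seed=seed,
        jitter_sd=float(rng.uniform(0.3, 0.8)),
        step=float(rng.uniform(4.0, 5.5)),
    )
    return "rod", atoms


def synth_flex_dataset(
    n_proteins: int = 50,
    beta_true: Optional[ModelCoefficients] = None,
    noise_sd: float = 0.1,
    seed: int = 0,
    n_res: int = 125,
    params: GraphParams = GraphParams(),
    reference_kind: str = "normalized",
) -> TrainingSet:
    """Synthetic (GDV, RMSF) training set with a known ground-truth model.

    Per protein: a synthetic structure from :func:`_mixed_structure`, real
    orbit counts via the counting pipeline, standardized features, and a
    reference ``features @ beta_true + Gaussian(0, noise_sd)`` on the
    normalized-log scale where the linear model lives.  With
    ``reference_kind="raw"`` the reference is exponentiated to a positive
    raw profile instead, which exercises the log/z target transform at the
    cost of an unidentifiable positive per-protein scale on the
    coefficients (the z-score of the log divides each protein's target by
    its realized standard deviation).
    """
    if n_proteins < 1:
        raise ParameterError(f"need n_proteins >= 1, got {n_proteins}")
    if noise_sd < 0:
        raise ParameterError(f"noise_sd must be >= 0, got {noise_sd}")
    if reference_kind not in ("normalized", "raw"):
        raise ParameterError(f"unknown reference_kind {reference_kind!r}")
    beta = (beta_true or published_model()).beta_array
    intercept = (beta_true or published_model()).intercept
    rng = np.random.default_rng(seed)
    proteins = []
    for i in range(n_proteins):
        geom, atoms = _mixed_structure(i, n_res, rng)
        gdv = gdv_all_at_once(atoms, params)
        feats = transform_features(gdv)
        target = intercept + feats @ beta + rng.normal(0.0, noise_sd, len(feats))
        if reference_kind == "raw":
            reference = RMSFProfile(np.exp(target), kind="raw")
        else:
            reference = RMSFProfile(target, kind="normalized")
        proteins.append(
            TrainingProtein(
                protein_id=f"syn{i:03d}-{geom}",
                gdv=gdv,
                reference=reference,
                ca_mask=atoms.ca_mask,
            )
        )
    return TrainingSet(proteins)
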