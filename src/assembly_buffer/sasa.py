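"""Shrake-Rupley solvent-accessible surface area.

Each atom is inflated by the probe radius (default 1.4 Å, a water molecule)
and sampled with a deterministic Fibonacci sphere lattice; a sample point is
accessible when it lies outside every neighbouring inflated sphere.  The
atom's SASA is the accessible fraction of its inflated-sphere area
4π(r+probe)², and per-residue SASA is the sum over the residue's atoms.

The Fibonacci lattice makes the computation fully deterministic for a given
point count, unlike the randomized point sets some implementations use.
For an isolated atom every point is accessible, so the closed form
4π(r+probe)² is recovered exactly at any point count.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .errors import ParameterError
from .structures import Chain, ComplexStructure

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_N_POINTS = 960


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (n_points, 3)."""
    i = np.arange(n_points)
    z = 1.0 - (2.0 * i + 1.0) / n_points
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def atom_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-atom SASA (Å²) for one set of atoms occluding each other."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if probe_radius <= 0:
        raise ParameterError("probe_radius must be positive")
    if n_points < 100:
        raise ParameterError("n_points must be >= 100 for a usable lattice")
    ext = radii + probe_radius
    sphere = fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    max_ext = ext.max()
    out = np.empty(len(coords))
    for i in range(len(coords)):
        neighbours = tree.query_ball_point(coords[i], ext[i] + max_ext)
        neighbours = [j for j in neighbours if j != i]
        pts = coords[i] + ext[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 >= ext[j] * ext[j]
            if not accessible.any():
                break
        out[i] = 4.0 * np.pi * ext[i] ** 2 * accessible.sum() / n_points
    return out


def compute_sasa(
    structure: ComplexStructure | Chain,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> dict[str, np.ndarray]:
    """Per-residue SASA for every chain of a structure (or a single chain).

    All atoms of the structure occlude each other, so passing a full complex
    yields in-complex SASA while passing one chain yields the isolated-subunit
    SASA.  Returns ``{chain_id: array aligned with chain.residue_ids}``.
    """
    if isinstance(structure, Chain):
        structure = ComplexStructure([structure])
    coords = np.vstack([c.coords for c in structure.chains])
    radii = np.concatenate([c.radii for c in structure.chains])
    per_atom = atom_sasa(coords, radii, probe_radius, n_points)
    result: dict[str, np.ndarray] = {}
    offset = 0
    for chain in structure.chains:
        n = len(chain.coords)
        vals = per_atom[offset : offset + n]
        offset += n
        res = np.zeros(chain.n_residues)
        for k, rid in enumerate(chain.residue_ids):
            res[k] = vals[chain.atom_residue == rid].sum()
        result[chain.chain_id] = res
    return result
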