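"""Spatial density functions: 3-D maps of neighbour-site density around
a central molecule, expressed in the molecule's body frame.

The body frame of a water molecule has its origin at O_W, z along the
C2v symmetry axis (the H-O-H bisector, pointing toward the hydrogens)
and x in the molecular plane toward one hydrogen; ammonia has its origin
at N_A, z along the C3v axis toward the hydrogens and x toward the
projection of one hydrogen.  Because the choice among equivalent
hydrogens is arbitrary, maps are by default averaged over the point
group operations (C2v: 4 operations, C3v: 6), which removes the
ambiguity and enforces the molecular symmetry.

Probability isosurfaces are thresholds on integrated density: the
"top f" region is the set of highest-density voxels that together hold
a fraction f of the map's total integrated density.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import Configuration, minimum_image

__all__ = [
    "SpatialDensityMap",
    "molecular_frame",
    "accumulate_sdf",
    "isolevel_for_fraction",
    "write_cube",
]


@dataclass
class SpatialDensityMap:
    central_species: str
    neighbor_label: str
    radius: float            # A
    voxel_size: float        # A
    edges: np.ndarray        # common bin edges along each axis
    counts: np.ndarray       # (n, n, n) accumulated (symmetry-weighted)
    n_centrals: int          # central molecules x frames accumulated
    symmetrized: bool

    @property
    def density(self) -> np.ndarray:
        """Average neighbour density per central molecule, A^-3."""
        return self.counts / (self.n_centrals * self.voxel_size ** 3)

    @property
    def mean_neighbors(self) -> float:
        """Average number of neighbour sites within the radius."""
        return float(self.counts.sum() / self.n_centrals)


_WATER_OPS = [np.diag(v) for v in
              ([1, 1, 1], [-1, -1, 1], [1, -1, 1], [-1, 1, 1])]


def _c3v_ops() -> list[np.ndarray]:
    ops = []
    for k in range(3):
        a = 2.0 * np.pi * k / 3.0
        rot = np.array([[np.cos(a), -np.sin(a), 0.0],
                        [np.sin(a), np.cos(a), 0.0],
                        [0.0, 0.0, 1.0]])
        ops.append(rot)
        ops.append(rot @ np.diag([1.0, -1.0, 1.0]))
    return ops


_AMMONIA_OPS = _c3v_ops()


def molecular_frame(config: Configuration, mol: int) -> tuple[np.ndarray,
                                                              np.ndarray]:
    """Origin and right-handed rotation matrix (rows x, y, z) of a
    molecule's body frame, deterministic given the site coordinates."""
    sl = config.mol_slice(mol)
    pos = config.positions[sl]
    labels = config.labels[sl].astype(str)
    heavy = int(np.nonzero(~np.char.startswith(labels, "H"))[0][0])
    origin = pos[heavy]
    h_idx = np.nonzero(np.char.startswith(labels, "H"))[0]
    if len(h_idx) < 2:
        raise ValueError("body frame needs at least two hydrogens")
    u = minimum_image(pos[h_idx] - origin, config.box_length)
    u = u / np.linalg.norm(u, axis=1)[:, None]
    z = u.sum(axis=0)
    z = z / np.linalg.norm(z)
    x = u[0] - (u[0] @ z) * z
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    return origin, np.vstack([x, y, z])


def accumulate_sdf(
    frames: Sequence[Configuration] | Configuration,
    central_species: str,
    neighbor_label: str,
    radius: float = 3.5,
    voxel_size: float = 0.25,
    symmetrize: bool = True,
) -> SpatialDensityMap:
    """Bin neighbour sites around every central molecule into a cubic
    voxel grid in the molecular body frame.

    Sites of the central molecule itself are excluded; neighbours beyond
    ``radius`` (minimum image) are ignored.
    """
    if isinstance(frames, Configuration):
        frames = [frames]
    if voxel_size > radius:
        raise ValueError("voxel_size must not exceed the radius")
    template = {"water": "water", "ammonia": "ammonia"}.get(central_species)
    if template is None:
        raise ValueError(f"unknown central species {central_species!r}")
    ops = _WATER_OPS if central_species == "water" else _AMMONIA_OPS
    if not symmetrize:
        ops = [np.eye(3)]
    n_vox = int(np.ceil(2.0 * radius / voxel_size))
    edges = -radius + voxel_size * np.arange(n_vox + 1)
    counts = np.zeros((n_vox, n_vox, n_vox))
    n_centrals = 0
    weight = 1.0 / len(ops)
    for cfg in frames:
        if radius > cfg.box_length / 2.0 + 1e-9:
            raise ValueError("radius exceeds half the box length")
        nbr_sites = cfg.sites_of_label(neighbor_label)
        for mol in cfg.molecules_of(template):
            sel = nbr_sites[cfg.mol_index[nbr_sites] != mol]
            if len(sel) == 0:
                n_centrals += 1
                continue
            origin, rot = molecular_frame(cfg, mol)
            d = minimum_image(cfg.positions[sel] - origin, cfg.box_length)
            r = np.linalg.norm(d, axis=1)
            local = d[r <= radius] @ rot.T
            n_centrals += 1
            for op in ops:
                pts = local @ op.T
                hist, _ = np.histogramdd(pts, bins=(edges, edges, edges))
                counts += weight * hist
    if n_centrals == 0:
        raise ValueError("no central molecules found")
    return SpatialDensityMap(
        central_species=central_species,
        neighbor_label=neighbor_label,
        radius=radius,
        voxel_size=voxel_size,
        edges=edges,
        counts=counts,
        n_centrals=n_centrals,
        symmetrized=symmetrize and len(ops) > 1,
    )


def isolevel_for_fraction(
    sdf_map: SpatialDensityMap,
    top_fraction: float,
) -> tuple[float, np.ndarray]:
    """Density threshold whose super-level set holds ``top_fraction`` of
    the map's integrated density.

    Returns the largest threshold t such that voxels with density >= t
    contain at least the requested fraction, together with the boolean
    voxel mask.  Raises if the map is empty.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must lie in (0, 1]")
    density = sdf_map.density
    total = density.sum()
    if total <= 0:
        raise ValueError("spatial density map is empty")
    order = np.argsort(density.ravel(), kind="stable")[::-1]
    flat = density.ravel()[order]
    cum = np.cumsum(flat)
    k = int(np.searchsorted(cum, top_fraction * total * (1.0 - 1e-12)))
    k = min(k, len(flat) - 1)
    mask = np.zeros(density.size, dtype=bool)
    mask[order[: k + 1]] = True
    # for distinct densities this is exactly the super-level set of the
    # threshold; ranked selection additionally breaks exact ties so a
    # uniform map yields the requested fraction of voxels
    return float(flat[k]), mask.reshape(density.shape)


_BOHR_PER_A = 1.0 / 0.529177210903


def write_cube(sdf_map: SpatialDensityMap, path: str,
               comment: str = "spatial density map") -> None:
    """Write the map as a Gaussian cube file (volumetric text format;
    lengths converted to Bohr as the format requires)."""
    density = sdf_map.density
    n = density.shape[0]
    step = sdf_map.voxel_size * _BOHR_PER_A
    origin = (sdf_map.edges[0] + sdf_map.voxel_size / 2.0) * _BOHR_PER_A
    with open(path, "w") as fh:
        fh.write(f"{comment}\n")
        fh.write(f"{sdf_map.central_species} / {sdf_map.neighbor_label} "
                 f"density, A^-3 per central molecule\n")
        fh.write(f"{1:5d} {origin:12.6f} {origin:12.6f} {origin:12.6f}\n")
        fh.write(f"{n:5d} {step:12.6f} {0.0:12.6f} {0.0:12.6f}\n")
        fh.write(f"{n:5d} {0.0:12.6f} {step:12.6f} {0.0:12.6f}\n")
        fh.write(f"{n:5d} {0.0:12.6f} {0.0:12.6f} {step:12.6f}\n")
        fh.write(f"{1:5d} {0.0:12.6f} {0.0:12.6f} {0.0:12.6f} {0.0:12.6f}\n")
        for i in range(n):
            for j in range(n):
                row = density[i, j]
                for k0 in range(0, n, 6):
                    fh.write(" ".join(f"{v:13.5e}"
                                      for v in row[k0:k0 + 6]) + "\n")
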