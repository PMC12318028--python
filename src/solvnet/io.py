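"""Trajectory formats, run configuration and deterministic test fixtures.

Configurations travel as extended XYZ: the comment line carries the
cubic cell (``Lattice=...``), the frame index and the column layout
(``Properties=...``); per-atom columns are the site label, position,
molecule id, template name and the site's charge/LJ parameters, so a
file round-trips to an identical :class:`~solvnet.model.Configuration`.
Curves and histograms are written as two-column TSV with a commented
header; run configuration is a schema-validated block with
unit-tagged keys (unknown keys are rejected).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .model import (
    Configuration,
    MoleculeTemplate,
    ammonia_template,
    lj_site_template,
    water_template,
)

__all__ = [
    "FormatError",
    "KNOWN_LABELS",
    "write_trajectory",
    "read_trajectory",
    "write_curve",
    "read_curve",
    "RunConfig",
    "make_fixture",
    "config_from_molecules",
    "FIXTURE_NAMES",
]

KNOWN_LABELS = frozenset({"O_W", "H_W", "N_A", "H_A"})

_ELEMENT_OF = {"O_W": "O", "H_W": "H", "N_A": "N", "H_A": "H"}

_PROPERTIES = ("species:S:1:pos:R:3:mol:I:1:template:S:1:"
               "charge:R:1:eps:R:1:sigma:R:1")


class FormatError(ValueError):
    """Malformed trajectory file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


def write_trajectory(frames: Sequence[Configuration] | Configuration,
                     path: str, seed: int | None = None) -> None:
    """Write one or more configurations as multi-frame extended XYZ.

    Coordinates are written with 8 decimals, so configurations whose
    coordinates are finite 8-decimal numbers round-trip bit-identically.
    """
    if isinstance(frames, Configuration):
        frames = [frames]
    with open(path, "w") as fh:
        for cfg in frames:
            _write_frame(fh, cfg, seed)


def _write_frame(fh: IO[str], cfg: Configuration,
                 seed: int | None) -> None:
    box = cfg.box_length
    fh.write(f"{cfg.n_sites}\n")
    comment = (f'Lattice="{box:.8f} 0 0 0 {box:.8f} 0 0 0 {box:.8f}" '
               f"Properties={_PROPERTIES} frame_index={cfg.frame_index}")
    if seed is not None:
        comment += f" seed={seed}"
    fh.write(comment + "\n")
    for k in range(cfg.n_sites):
        x, y, z = cfg.positions[k]
        fh.write(
            f"{cfg.labels[k]} {x:.8f} {y:.8f} {z:.8f} "
            f"{int(cfg.mol_index[k])} "
            f"{cfg.template_names[int(cfg.mol_index[k])]} "
            f"{cfg.charges[k]:.8f} {cfg.lj_eps[k]:.8f} "
            f"{cfg.lj_sigma[k]:.8f}\n")


def read_trajectory(path: str,
                    allow_any_labels: bool = False) -> list[Configuration]:
    """Read a multi-frame extended-XYZ trajectory.

    Site labels must come from {O_W, H_W, N_A, H_A} unless
    ``allow_any_labels`` is set (fixture configurations use free
    labels).  A zero-atom frame is accepted as a degenerate input.
    """
    frames: list[Configuration] = []
    with open(path) as fh:
        lines = fh.readlines()
    ln = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            n_atoms = int(lines[ln].strip())
        except ValueError:
            raise FormatError("expected an atom count", ln + 1)
        if ln + 1 >= len(lines):
            raise FormatError("missing comment line", ln + 2)
        comment = lines[ln + 1]
        keys = _parse_comment(comment, ln + 2)
        if "Lattice" not in keys:
            raise FormatError("no Lattice (box metadata) in comment", ln + 2)
        lattice = [float(v) for v in keys["Lattice"].split()]
        if len(lattice) != 9:
            raise FormatError("Lattice must have 9 components", ln + 2)
        box = lattice[0]
        frame_index = int(keys.get("frame_index", 0))
        rows = lines[ln + 2: ln + 2 + n_atoms]
        if len(rows) < n_atoms:
            raise FormatError("truncated frame", ln + 2 + len(rows))
        frames.append(_parse_frame(rows, box, frame_index,
                                   ln + 3, allow_any_labels))
        ln += 2 + n_atoms
    return frames


def _parse_comment(comment: str, line: int) -> dict[str, str]:
    keys: dict[str, str] = {}
    k = 0
    while k < len(comment):
        eq = comment.find("=", k)
        if eq < 0:
            break
        key = comment[k:eq].strip().split()[-1]
        if eq + 1 < len(comment) and comment[eq + 1] == '"':
            end = comment.find('"', eq + 2)
            if end < 0:
                raise FormatError("unterminated quote in comment", line)
            keys[key] = comment[eq + 2:end]
            k = end + 1
        else:
            end = comment.find(" ", eq + 1)
            end = len(comment) if end < 0 else end
            keys[key] = comment[eq + 1:end].strip()
            k = end + 1
    return keys


def _parse_frame(rows: list[str], box: float, frame_index: int,
                 first_line: int, allow_any_labels: bool) -> Configuration:
    labels, pos, mol, names_by_mol = [], [], [], {}
    charge, eps, sigma = [], [], []
    for offset, row in enumerate(rows):
        parts = row.split()
        if len(parts) < 5:
            raise FormatError("too few columns", first_line + offset)
        label = parts[0]
        if not allow_any_labels and label not in KNOWN_LABELS:
            raise FormatError(f"unknown site label {label!r}",
                              first_line + offset)
        labels.append(label)
        pos.append([float(v) for v in parts[1:4]])
        m = int(parts[4])
        mol.append(m)
        names_by_mol[m] = parts[5] if len(parts) > 5 else "unknown"
        charge.append(float(parts[6]) if len(parts) > 6 else 0.0)
        eps.append(float(parts[7]) if len(parts) > 7 else 0.0)
        sigma.append(float(parts[8]) if len(parts) > 8 else 0.0)
    if not labels:
        import warnings
        warnings.warn("frame with 0 atoms", stacklevel=2)
    n_mol = (max(mol) + 1) if mol else 0
    template_names = [names_by_mol.get(m, "unknown") for m in range(n_mol)]
    return Configuration(
        box_length=box,
        positions=np.array(pos).reshape(-1, 3),
        labels=np.array(labels),
        mol_index=np.array(mol, dtype=np.intp),
        template_names=template_names,
        charges=np.array(charge),
        lj_eps=np.array(eps),
        lj_sigma=np.array(sigma),
        frame_index=frame_index,
    )


def write_curve(path: str, x: np.ndarray, y: np.ndarray,
                header: Mapping[str, object] | None = None,
                columns: tuple[str, str] = ("r_A", "g")) -> None:
    """Two-column TSV with '#'-commented header metadata."""
    with open(path, "w") as fh:
        for key, value in (header or {}).items():
            fh.write(f"# {key}: {value}\n")
        fh.write(f"# {columns[0]}\t{columns[1]}\n")
        for xv, yv in zip(x, y):
            fh.write(f"{xv:.6f}\t{yv:.8f}\n")


def read_curve(path: str) -> tuple[np.ndarray, np.ndarray]:
    data = np.loadtxt(path, comments="#", delimiter="\t")
    return data[:, 0], data[:, 1]


# --- run configuration -----------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CompositionBlock(_Strict):
    ammonia_moles: float = Field(ge=0)
    water_moles: float = Field(ge=0)
    density_g_cm3: float = Field(gt=0)


class IsotopesBlock(_Strict):
    label: str = "H"
    h_fraction: float | None = Field(default=None, ge=0, le=1)


class PotentialsBlock(_Strict):
    cutoff_A: float | None = Field(default=12.0, gt=0)


class TrajectoryBlock(_Strict):
    n_frames: int = Field(default=11, ge=1)
    frame_stride: int = Field(default=50, ge=1)
    equilibration_sweeps: int = Field(default=2000, ge=0)


class BoxBlock(_Strict):
    n_water: int = Field(ge=0)
    n_ammonia: int = Field(default=0, ge=0)


class RunConfig(_Strict):
    """Schema-validated run configuration with unit-tagged keys."""

    composition: CompositionBlock
    box: BoxBlock
    temperature_K: float = Field(gt=0)
    potentials: PotentialsBlock = PotentialsBlock()
    trajectory: TrajectoryBlock = TrajectoryBlock()
    isotopes: IsotopesBlock = IsotopesBlock()
    seed: int = 0
    output_dir: str = "."

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))


# --- fixtures --------------------------------------------------------------

FIXTURE_NAMES = ("ideal_gas", "ice_lattice_fragment", "tetrahedral_cluster",
                 "equilateral_triplet", "dimer")


def config_from_molecules(
    box_length: float,
    molecules: Sequence[tuple[MoleculeTemplate, np.ndarray]],
    frame_index: int = 0,
) -> Configuration:
    """Assemble a configuration from (template, site-coordinates) pairs."""
    labels, mol, names = [], [], []
    charge, eps, sigma, pos = [], [], [], []
    for m, (tpl, coords) in enumerate(molecules):
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        if len(coords) != tpl.n_sites:
            raise ValueError("coordinate count does not match template")
        pos.append(coords)
        labels.extend(s.label for s in tpl.sites)
        charge.extend(s.charge for s in tpl.sites)
        eps.extend(s.lj_epsilon for s in tpl.sites)
        sigma.extend(s.lj_sigma for s in tpl.sites)
        mol.extend([m] * tpl.n_sites)
        names.append(tpl.name)
    return Configuration(
        box_length=box_length,
        positions=np.concatenate(pos),
        labels=np.array(labels),
        mol_index=np.array(mol, dtype=np.intp),
        template_names=names,
        charges=np.array(charge),
        lj_eps=np.array(eps),
        lj_sigma=np.array(sigma),
        frame_index=frame_index,
    )


def _diamond_ice(o_o: float, cells: int) -> Configuration:
    """Isolated diamond-cubic oxygen lattice fragment with a
    proton-ordered hydrogen assignment obeying the ice rules (every
    oxygen donates two hydrogens along bonds; interior oxygens are
    4-coordinated).  The box is padded so the fragment does not bond to
    its periodic images."""
    a = 4.0 * o_o / np.sqrt(3.0)
    fcc = np.array([[0, 0, 0], [0, .5, .5], [.5, 0, .5], [.5, .5, 0]])
    basis_b = fcc + 0.25
    bond_dirs_a = np.array([[1, 1, 1], [1, -1, -1]]) / np.sqrt(3.0) * o_o
    bond_dirs_b = np.array([[1, -1, 1], [1, 1, -1]]) / np.sqrt(3.0) * o_o
    tpl = water_template()
    molecules = []
    r_oh = 1.0
    for cx in range(cells):
        for cy in range(cells):
            for cz in range(cells):
                shift = np.array([cx, cy, cz])
                for sub, dirs in ((fcc, bond_dirs_a), (basis_b, bond_dirs_b)):
                    for site in sub:
                        o = (site + shift) * a
                        h = [o + d / o_o * r_oh for d in dirs]
                        molecules.append((tpl, np.vstack([o, h[0], h[1]])))
    pad = 2.0 * a  # isolate the fragment from its periodic images
    box = cells * a + pad
    return config_from_molecules(
        box, [(tpl, xyz + pad / 2.0) for tpl, xyz in molecules])


def make_fixture(name: str, seed: int = 0, **params) -> Configuration:
    """Deterministic analytic test geometries.

    - ``ideal_gas``: non-interacting single-site particles at random
      positions (``n``, ``box_length``).
    - ``ice_lattice_fragment``: periodic diamond-cubic, proton-ordered
      ice with O-O 2.76 A (``o_o``, ``cells``); every oxygen is
      4-coordinated and all shortest-path rings are hexagons.
    - ``tetrahedral_cluster``: a central water with four waters at the
      vertices of a tetrahedron (``o_o``).
    - ``equilateral_triplet``: three waters at the corners of an
      equilateral triangle (``side``), the 'interstitial' 60-degree
      signature.
    - ``dimer``: a linear water dimer donating along the O-O axis
      (``o_o``).
    """
    rng = np.random.default_rng(seed)
    if name == "ideal_gas":
        n = int(params.pop("n", 100))
        box = float(params.pop("box_length", 20.0))
        tpl = params.pop("template", None) or lj_site_template(
            epsilon=0.0, sigma=0.0)
        _no_extra(params)
        return config_from_molecules(
            box, [(tpl, rng.uniform(0, box, size=3)) for _ in range(n)])
    if name == "ice_lattice_fragment":
        o_o = float(params.pop("o_o", 2.76))
        cells = int(params.pop("cells", 2))
        _no_extra(params)
        return _diamond_ice(o_o, cells)
    if name == "tetrahedral_cluster":
        o_o = float(params.pop("o_o", 2.76))
        box = float(params.pop("box_length", 30.0))
        _no_extra(params)
        tpl = water_template()
        verts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                         dtype=float) / np.sqrt(3.0) * o_o
        centre = np.full(3, box / 2.0)
        molecules = [(tpl, tpl.coordinates() + centre)]
        for v in verts:
            molecules.append((tpl, tpl.coordinates() + centre + v))
        return config_from_molecules(box, molecules)
    if name == "equilateral_triplet":
        side = float(params.pop("side", 3.0))
        box = float(params.pop("box_length", 30.0))
        _no_extra(params)
        tpl = water_template()
        centre = np.full(3, box / 2.0)
        corners = side * np.array([
            [0.0, 0.0, 0.0],
            [1.0, 0.0, 0.0],
            [0.5, np.sqrt(3.0) / 2.0, 0.0],
        ])
        return config_from_molecules(
            box, [(tpl, tpl.coordinates() + centre + c) for c in corners])
    if name == "dimer":
        o_o = float(params.pop("o_o", 2.8))
        box = float(params.pop("box_length", 30.0))
        _no_extra(params)
        tpl = water_template()
        centre = np.full(3, box / 2.0)
        # donor: one O-H aligned with +x toward the acceptor oxygen;
        # acceptor hydrogens point away from the donor
        donor = np.array([
            [0.0, 0.0, 0.0],
            [1.0, 0.0, 0.0],
            [np.cos(np.radians(109.47)), np.sin(np.radians(109.47)), 0.0],
        ])
        half = np.radians(109.47) / 2.0
        acceptor = np.array([
            [o_o, 0.0, 0.0],
            [o_o + np.cos(half), np.sin(half), 0.0],
            [o_o + np.cos(half), -np.sin(half), 0.0],
        ])
        return config_from_molecules(
            box, [(tpl, donor + centre), (tpl, acceptor + centre)])
    raise ValueError(f"unknown fixture {name!r}")


def _no_extra(params: dict) -> None:
    if params:
        raise ValueError(f"unknown fixture parameters {sorted(params)}")
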