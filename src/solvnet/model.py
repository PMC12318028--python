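"""Molecular templates, periodic configurations and the pairwise
reference energy model (Lennard-Jones + Coulomb).

The energy model is the one shared by the Monte Carlo engine and the
hydrogen-bond energetics: rigid molecules interacting through site-site
Lennard-Jones terms (Lorentz-Berthelot mixing: geometric epsilon,
arithmetic sigma) plus Coulomb terms between fixed partial charges,
evaluated under the cubic minimum-image convention.

Units throughout: Angstrom, kJ/mol, elementary charge e, Kelvin.
The Coulomb constant is K_COULOMB = 1389.35 kJ*A/(mol*e^2).

Reference (seed) potentials are an SPC/E-like rigid water and an
OPLS-like rigid ammonia; both are configurable, and any analysis result
is only meaningful quoted alongside the parameter set used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "K_COULOMB",
    "K_BOLTZMANN",
    "N_AVOGADRO",
    "Site",
    "MoleculeTemplate",
    "water_template",
    "ammonia_template",
    "lj_site_template",
    "Configuration",
    "PotentialSet",
    "PackingError",
    "SingularityError",
    "build_box",
    "minimum_image",
    "pair_energy",
    "molecule_energy",
    "total_energy",
    "random_rotation_matrix",
]

K_COULOMB = 1389.35     # kJ*A/(mol*e^2)
K_BOLTZMANN = 0.0083145  # kJ/(mol*K)
N_AVOGADRO = 6.02214076e23

_MOLAR_MASS = {"O": 15.999, "H": 1.008, "N": 14.007}


@dataclass(frozen=True)
class Site:
    label: str        # site type label, e.g. O_W, H_W, N_A, H_A
    element: str
    position: tuple[float, float, float]  # molecular frame, A
    charge: float     # e
    lj_epsilon: float  # kJ/mol
    lj_sigma: float   # A


@dataclass(frozen=True)
class MoleculeTemplate:
    """Rigid molecular geometry with per-site charges and LJ parameters."""

    name: str
    sites: tuple[Site, ...]

    def __post_init__(self) -> None:
        q = sum(s.charge for s in self.sites)
        if abs(q) > 1e-9:
            raise ValueError(f"template {self.name!r} has net charge {q}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def molar_mass(self) -> float:
        return sum(_MOLAR_MASS.get(s.element, 0.0) for s in self.sites)

    def coordinates(self) -> np.ndarray:
        return np.array([s.position for s in self.sites], dtype=float)


def water_template(
    q_o: float = -0.8476,
    q_h: float = 0.4238,
    eps_o: float = 0.650,
    sigma_o: float = 3.166,
    r_oh: float = 1.0,
    hoh_deg: float = 109.47,
) -> MoleculeTemplate:
    """SPC/E-like rigid three-site water; C2v axis along +z, H on the +z side."""
    half = math.radians(hoh_deg) / 2.0
    sx, cz = r_oh * math.sin(half), r_oh * math.cos(half)
    return MoleculeTemplate(
        name="water",
        sites=(
            Site("O_W", "O", (0.0, 0.0, 0.0), q_o, eps_o, sigma_o),
            Site("H_W", "H", (sx, 0.0, cz), q_h, 0.0, 0.0),
            Site("H_W", "H", (-sx, 0.0, cz), q_h, 0.0, 0.0),
        ),
    )


def ammonia_template(
    q_n: float = -1.02,
    q_h: float = 0.34,
    eps_n: float = 0.711,
    sigma_n: float = 3.42,
    r_nh: float = 1.01,
    hnh_deg: float = 106.7,
) -> MoleculeTemplate:
    """OPLS-like rigid four-site ammonia; C3v axis along +z, H on the +z side."""
    cos_g = math.cos(math.radians(hnh_deg))
    cos_t = math.sqrt((cos_g + 0.5) / 1.5)  # polar angle of N-H from C3 axis
    sin_t = math.sqrt(1.0 - cos_t * cos_t)
    sites = [Site("N_A", "N", (0.0, 0.0, 0.0), q_n, eps_n, sigma_n)]
    for k in range(3):
        phi = 2.0 * math.pi * k / 3.0
        sites.append(Site(
            "H_A", "H",
            (r_nh * sin_t * math.cos(phi), r_nh * sin_t * math.sin(phi),
             r_nh * cos_t),
            q_h, 0.0, 0.0))
    return MoleculeTemplate(name="ammonia", sites=tuple(sites))


def lj_site_template(
    label: str = "LJ",
    epsilon: float = 0.650,
    sigma: float = 3.0,
    name: str = "lj",
) -> MoleculeTemplate:
    """Single-site uncharged Lennard-Jones particle (monatomic-liquid model)."""
    return MoleculeTemplate(
        name=name, sites=(Site(label, "X", (0.0, 0.0, 0.0), 0.0, epsilon, sigma),))


class PackingError(RuntimeError):
    """Random insertion failed to place a molecule without overlap."""


class SingularityError(ValueError):
    """Two interaction sites coincide (r = 0)."""


@dataclass
class Configuration:
    """A periodic cubic box of labelled molecular sites.

    Sites of each molecule occupy a contiguous block of the coordinate
    array; ``mol_index`` maps each site to its molecule and
    ``template_names`` records the template of each molecule.  Per-site
    charges and LJ parameters are carried alongside the coordinates so
    that energies are a function of the configuration alone.
    """

    box_length: float
    positions: np.ndarray          # (S, 3), wrapped into [0, L)
    labels: np.ndarray             # (S,) site type labels
    mol_index: np.ndarray          # (S,) molecule id per site
    template_names: list[str]      # per molecule
    charges: np.ndarray            # (S,) e
    lj_eps: np.ndarray             # (S,) kJ/mol
    lj_sigma: np.ndarray           # (S,) A
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.positions %= self.box_length
        labels = np.asarray(self.labels)
        self.labels = labels
        # site-type bookkeeping used by the empirical-potential lookup
        self.type_labels = tuple(sorted(set(labels.tolist())))
        lut = {t: k for k, t in enumerate(self.type_labels)}
        self.type_index = np.array([lut[l] for l in labels.tolist()], dtype=np.intp)
        self._mol_slices: list[slice] = []
        for m in range(len(self.template_names)):
            idx = np.nonzero(self.mol_index == m)[0]
            self._mol_slices.append(slice(int(idx[0]), int(idx[-1]) + 1))

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_molecules(self) -> int:
        return len(self.template_names)

    @property
    def number_density(self) -> float:
        """Atom (site) number density, A^-3."""
        return self.n_sites / self.box_length ** 3

    def mol_slice(self, m: int) -> slice:
        return self._mol_slices[m]

    def molecules_of(self, template_name: str) -> np.ndarray:
        return np.array([m for m, t in enumerate(self.template_names)
                         if t == template_name], dtype=np.intp)

    def sites_of_label(self, label: str) -> np.ndarray:
        return np.nonzero(self.labels == label)[0]

    def copy(self) -> "Configuration":
        return Configuration(
            box_length=self.box_length,
            positions=self.positions.copy(),
            labels=self.labels.copy(),
            mol_index=self.mol_index.copy(),
            template_names=list(self.template_names),
            charges=self.charges.copy(),
            lj_eps=self.lj_eps.copy(),
            lj_sigma=self.lj_sigma.copy(),
            frame_index=self.frame_index,
        )


@dataclass(frozen=True)
class PotentialSet:
    """Evaluation conventions for the pairwise reference energy.

    With ``cutoff`` set, Lennard-Jones terms are truncated and shifted and
    Coulomb terms are force-shifted at the cutoff (both continuous there);
    with ``cutoff`` None the bare potentials are summed over all site
    pairs under minimum image.  No Ewald summation is attempted: the
    force-shifted truncation is adequate for structural Monte Carlo at
    the box sizes used here.
    """

    coulomb_k: float = K_COULOMB
    cutoff: float | None = 12.0

    def effective_cutoff(self, box_length: float) -> float | None:
        if self.cutoff is None:
            return None
        return min(self.cutoff, box_length / 2.0)


def minimum_image(delta: np.ndarray, box_length: float) -> np.ndarray:
    """Wrap displacement vectors into the central image of a cubic box."""
    return delta - box_length * np.round(delta / box_length)


def random_rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation via a normalised random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _box_length_from_density(
    templates: Mapping[str, MoleculeTemplate],
    counts: Mapping[str, int],
    mass_density: float | None,
    number_density: float | None,
) -> float:
    n_sites = sum(templates[t].n_sites * c for t, c in counts.items())
    if (mass_density is None) == (number_density is None):
        raise ValueError(
            "exactly one of mass_density (g/cm^3) or number_density "
            "(atoms/A^3) must be given")
    if number_density is not None:
        volume = n_sites / number_density
    else:
        mass_g = sum(templates[t].molar_mass * c for t, c in counts.items()) \
            / N_AVOGADRO
        volume = mass_g / mass_density * 1e24  # cm^3 -> A^3
    return volume ** (1.0 / 3.0)


def build_box(
    templates: Sequence[MoleculeTemplate] | Mapping[str, MoleculeTemplate],
    counts: Mapping[str, int],
    *,
    mass_density: float | None = None,
    number_density: float | None = None,
    seed: int | np.random.Generator = 0,
    min_distance: float = 1.5,
    max_tries: int = 2000,
) -> Configuration:
    """Randomly insert rigid molecules into a cubic box at the given density.

    ``mass_density`` is in g/cm^3, ``number_density`` in atoms/A^3 (give
    exactly one).  Insertion retries until every intermolecular site-site
    distance is at least ``min_distance``; persistent failure raises
    :class:`PackingError`.
    """
    if not isinstance(templates, Mapping):
        templates = {t.name: t for t in templates}
    for name in counts:
        if name not in templates:
            raise ValueError(f"no template named {name!r}")
        if counts[name] < 1:
            raise ValueError("molecule counts must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    box = _box_length_from_density(templates, counts, mass_density,
                                   number_density)
    placed: list[np.ndarray] = []
    labels: list[str] = []
    mol_index: list[int] = []
    template_names: list[str] = []
    charges: list[float] = []
    eps: list[float] = []
    sig: list[float] = []
    occupied = np.empty((0, 3))
    m = 0
    for name in counts:
        tpl = templates[name]
        local = tpl.coordinates()
        local -= local.mean(axis=0)
        for _ in range(counts[name]):
            for attempt in range(max_tries):
                rot = random_rotation_matrix(rng)
                centre = rng.uniform(0.0, box, size=3)
                coords = local @ rot.T + centre
                if occupied.size:
                    d = minimum_image(
                        occupied[None, :, :] - coords[:, None, :], box)
                    if np.min(np.linalg.norm(d, axis=-1)) < min_distance:
                        continue
                break
            else:
                raise PackingError(
                    f"could not place molecule {m} after {max_tries} tries "
                    f"(box {box:.2f} A, min distance {min_distance} A)")
            placed.append(coords)
            occupied = np.concatenate([occupied, coords]) if occupied.size \
                else coords.copy()
            labels.extend(s.label for s in tpl.sites)
            charges.extend(s.charge for s in tpl.sites)
            eps.extend(s.lj_epsilon for s in tpl.sites)
            sig.extend(s.lj_sigma for s in tpl.sites)
            mol_index.extend([m] * tpl.n_sites)
            template_names.append(name)
            m += 1
    return Configuration(
        box_length=box,
        positions=np.concatenate(placed),
        labels=np.array(labels),
        mol_index=np.array(mol_index, dtype=np.intp),
        template_names=template_names,
        charges=np.array(charges),
        lj_eps=np.array(eps),
        lj_sigma=np.array(sig),
    )


def _site_block_energy(
    pos_a: np.ndarray, q_a: np.ndarray, e_a: np.ndarray, s_a: np.ndarray,
    t_a: np.ndarray,
    pos_b: np.ndarray, q_b: np.ndarray, e_b: np.ndarray, s_b: np.ndarray,
    t_b: np.ndarray,
    box: float, potentials: PotentialSet, ep=None,
) -> float:
    """LJ + Coulomb (+ optional empirical-potential correction) between two
    disjoint site blocks under minimum image."""
    d = minimum_image(pos_b[None, :, :] - pos_a[:, None, :], box)
    r2 = np.einsum("ijk,ijk->ij", d, d)
    if np.any(r2 < 1e-12):
        raise SingularityError("coincident interaction sites (r = 0)")
    rc = potentials.effective_cutoff(box)
    if rc is not None:
        mask = r2 <= rc * rc
        if not mask.any():
            return 0.0
    else:
        mask = np.ones_like(r2, dtype=bool)
    r = np.sqrt(r2[mask])
    ii, jj = np.nonzero(mask)
    eps = np.sqrt(e_a[ii] * e_b[jj])
    energy = 0.0
    lj_sel = eps > 0.0
    if lj_sel.any():
        sg = 0.5 * (s_a[ii[lj_sel]] + s_b[jj[lj_sel]])
        x6 = (sg / r[lj_sel]) ** 6
        u_lj = 4.0 * eps[lj_sel] * (x6 * x6 - x6)
        if rc is not None:
            xc6 = (sg / rc) ** 6
            u_lj -= 4.0 * eps[lj_sel] * (xc6 * xc6 - xc6)
        energy += float(u_lj.sum())
    qq = q_a[ii] * q_b[jj]
    q_sel = qq != 0.0
    if q_sel.any():
        rq = r[q_sel]
        if rc is not None:
            # force-shifted truncation: V and dV/dr vanish at the cutoff
            u_c = potentials.coulomb_k * qq[q_sel] * (
                1.0 / rq + rq / rc ** 2 - 2.0 / rc)
        else:
            u_c = potentials.coulomb_k * qq[q_sel] / rq
        energy += float(u_c.sum())
    if ep is not None:
        energy += float(ep.lookup(t_a[ii], t_b[jj], r).sum())
    return energy


def pair_energy(
    config: Configuration, mol_a: int, mol_b: int,
    potentials: PotentialSet | None = None, ep=None,
) -> float:
    """Interaction energy (kJ/mol) between two molecules: the sum of their
    site-site Lennard-Jones and Coulomb terms under minimum image."""
    if mol_a == mol_b:
        raise ValueError("pair energy requires two distinct molecules")
    if mol_a > mol_b:  # canonical order: exact symmetry under exchange
        mol_a, mol_b = mol_b, mol_a
    if potentials is None:
        potentials = PotentialSet(cutoff=None)
    sa, sb = config.mol_slice(mol_a), config.mol_slice(mol_b)
    return _site_block_energy(
        config.positions[sa], config.charges[sa], config.lj_eps[sa],
        config.lj_sigma[sa], config.type_index[sa],
        config.positions[sb], config.charges[sb], config.lj_eps[sb],
        config.lj_sigma[sb], config.type_index[sb],
        config.box_length, potentials, ep)


def molecule_energy(
    config: Configuration, m: int, potentials: PotentialSet, ep=None,
    positions: np.ndarray | None = None,
) -> float:
    """Energy of molecule ``m`` with every other molecule in the box.

    ``positions`` optionally overrides the sites of ``m`` (a trial move)
    without touching the stored coordinates.
    """
    sl = config.mol_slice(m)
    pos_m = config.positions[sl] if positions is None else positions
    others = config.mol_index != m
    return _site_block_energy(
        pos_m, config.charges[sl], config.lj_eps[sl], config.lj_sigma[sl],
        config.type_index[sl],
        config.positions[others], config.charges[others],
        config.lj_eps[others], config.lj_sigma[others],
        config.type_index[others],
        config.box_length, potentials, ep)


def total_energy(config: Configuration, potentials: PotentialSet,
                 ep=None) -> float:
    """Total intermolecular energy: the sum of pair energies over unique
    molecule pairs (computed as half the sum of per-molecule energies)."""
    return 0.5 * sum(molecule_energy(config, m, potentials, ep)
                     for m in range(config.n_molecules))
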