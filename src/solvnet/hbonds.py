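"""Hydrogen-bond identification, classification and energetics.

Bonds are identified by distance criteria alone (the 30-degree angle
criterion belongs to the network-topology linkage definition, not to the
energetics routine): a donor hydrogen within the class's H...acceptor
cutoff, plus for water-water donation an O_W-O_W heavy-atom check.
Each hydrogen donates at most one bond, to its nearest eligible
acceptor.

Water molecules are partitioned into ammonia's first solvation shell
(FSS: O_W within 3.6 A of any N_A) and bulk; the donor's label
subclassifies water-water bonds.  Interaction energies are the full
molecule-molecule Lennard-Jones + Coulomb pair energies, and per-class
enthalpy histograms are summarised by least-squares Gaussian fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .model import Configuration, PotentialSet, minimum_image, pair_energy

__all__ = [
    "BOND_CLASSES",
    "HBondCriteria",
    "HBond",
    "EnthalpyDistribution",
    "identify_hbonds",
    "partition_water",
    "bond_energies",
    "enthalpy_distributions",
]

BOND_CLASSES = (
    "water->water(bulk)",
    "water->water(FSS)",
    "water->ammonia",
    "ammonia->water",
    "ammonia->ammonia",
)


@dataclass(frozen=True)
class HBondCriteria:
    """Distance cutoffs (A) defining each hydrogen-bond class.

    Defaults are the maxima of the first g(r) shells of the mixture:
    water-water requires O_W-O_W <= 3.3 with the H_W...O_W contact
    <= 2.4; water donates to ammonia inside H_W...N_A <= 2.43; ammonia
    donates to water inside H_A...O_W <= 2.49.  The ammonia-ammonia
    contact shows only a weak shoulder (~2.2 A); its cutoff default of
    2.4 A is a configurable choice, not a measured shell boundary.
    """

    oo_max: float = 3.3
    hw_ow_max: float = 2.4
    hw_na_max: float = 2.43
    ha_ow_max: float = 2.49
    ha_na_max: float = 2.4
    fss_cutoff: float = 3.6

    def __post_init__(self) -> None:
        for name in ("oo_max", "hw_ow_max", "hw_na_max", "ha_ow_max",
                     "ha_na_max", "fss_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class HBond:
    donor_mol: int
    acceptor_mol: int
    donor_site: int          # H site index in the configuration
    acceptor_site: int       # acceptor heavy-atom site index
    bond_class: str
    h_to_acceptor: float     # A
    energy: float | None = None  # kJ/mol, filled by bond_energies


@dataclass
class EnthalpyDistribution:
    bond_class: str
    bin_centers: np.ndarray
    counts: np.ndarray
    n_bonds: int
    mean: float | None = None     # Gaussian-fit mean, kJ/mol
    sd: float | None = None
    amplitude: float | None = None
    sample_mean: float | None = None
    low_count: bool = False


def partition_water(config: Configuration,
                    fss_cutoff: float = 3.6) -> dict[int, str]:
    """Label each water molecule 'FSS' if any ammonia nitrogen lies within
    ``fss_cutoff`` of its oxygen (minimum image), else 'bulk'."""
    ow = config.sites_of_label("O_W")
    na = config.sites_of_label("N_A")
    labels: dict[int, str] = {}
    if len(ow) == 0:
        return labels
    if len(na) == 0:
        return {int(config.mol_index[i]): "bulk" for i in ow}
    d = minimum_image(
        config.positions[na][None, :, :] - config.positions[ow][:, None, :],
        config.box_length)
    near = (np.linalg.norm(d, axis=-1) <= fss_cutoff).any(axis=1)
    for i, site in enumerate(ow):
        labels[int(config.mol_index[site])] = "FSS" if near[i] else "bulk"
    return labels


def _distances(config: Configuration, idx_a: np.ndarray,
               idx_b: np.ndarray) -> np.ndarray:
    d = minimum_image(
        config.positions[idx_b][None, :, :]
        - config.positions[idx_a][:, None, :],
        config.box_length)
    return np.linalg.norm(d, axis=-1)


def identify_hbonds(
    config: Configuration,
    criteria: HBondCriteria | None = None,
) -> list[HBond]:
    """All hydrogen bonds in a frame, classified by donor and acceptor
    species.

    Each hydrogen is assigned to at most one acceptor - the nearest
    heavy atom satisfying its class criteria - which prevents double
    counting and makes the bond set deterministic.
    """
    criteria = criteria or HBondCriteria()
    known = {"O_W", "H_W", "N_A", "H_A"}
    unknown = set(config.type_labels) - known
    if unknown:
        raise ValueError(f"unknown site labels {sorted(unknown)}")
    water_label = partition_water(config, criteria.fss_cutoff)
    bonds: list[HBond] = []

    def sweep(h_idx, acc_specs):
        """acc_specs: list of (acceptor indices, cutoff, class resolver)."""
        if len(h_idx) == 0:
            return
        candidates = []  # (distance, h_site, acc_site, resolver)
        for acc_idx, cutoff, resolver in acc_specs:
            if len(acc_idx) == 0:
                continue
            dist = _distances(config, h_idx, acc_idx)
            hh, aa = np.nonzero(dist <= cutoff)
            for k in range(len(hh)):
                h_site = int(h_idx[hh[k]])
                a_site = int(acc_idx[aa[k]])
                if config.mol_index[h_site] == config.mol_index[a_site]:
                    continue
                candidates.append((float(dist[hh[k], aa[k]]), h_site, a_site,
                                   resolver))
        # nearest acceptor wins, one bond per hydrogen
        candidates.sort(key=lambda c: (c[1], c[0]))
        taken: set[int] = set()
        for dist, h_site, a_site, resolver in candidates:
            if h_site in taken:
                continue
            bond = resolver(h_site, a_site, dist)
            if bond is not None:
                taken.add(h_site)
                bonds.append(bond)

    ow = config.sites_of_label("O_W")
    na = config.sites_of_label("N_A")
    hw = config.sites_of_label("H_W")
    ha = config.sites_of_label("H_A")
    mol_of = config.mol_index

    # O_W positions by molecule, for the heavy-atom check on water donation
    ow_of_mol = {int(mol_of[i]): int(i) for i in ow}

    def resolve_ww(h_site, a_site, dist):
        donor_mol = int(mol_of[h_site])
        d_oo = _distances(config,
                          np.array([ow_of_mol[donor_mol]]),
                          np.array([a_site]))[0, 0]
        if d_oo > criteria.oo_max:
            return None
        sub = water_label.get(donor_mol, "bulk")
        return HBond(donor_mol, int(mol_of[a_site]), h_site, a_site,
                     f"water->water({sub})", dist)

    def resolve_simple(bond_class):
        def resolve(h_site, a_site, dist):
            return HBond(int(mol_of[h_site]), int(mol_of[a_site]),
                         h_site, a_site, bond_class, dist)
        return resolve

    sweep(hw, [
        (ow, criteria.hw_ow_max, resolve_ww),
        (na, criteria.hw_na_max, resolve_simple("water->ammonia")),
    ])
    sweep(ha, [
        (ow, criteria.ha_ow_max, resolve_simple("ammonia->water")),
        (na, criteria.ha_na_max, resolve_simple("ammonia->ammonia")),
    ])
    return bonds


def bond_energies(
    config: Configuration,
    bonds: Sequence[HBond],
    potentials: PotentialSet | None = None,
) -> list[HBond]:
    """Fill in each bond's interaction energy: the full molecule-molecule
    Lennard-Jones + Coulomb pair energy of the bonded pair (bare
    potentials by default)."""
    if potentials is None:
        potentials = PotentialSet(cutoff=None)
    for bond in bonds:
        bond.energy = pair_energy(config, bond.donor_mol, bond.acceptor_mol,
                                  potentials)
    return list(bonds)


def _gaussian(x, amplitude, mean, sd):
    return amplitude * np.exp(-0.5 * ((x - mean) / sd) ** 2)


def fit_gaussian(bin_centers: np.ndarray,
                 counts: np.ndarray) -> tuple[float, float, float]:
    """Least-squares Gaussian fit to a histogram, initialised at the
    sample moments.  Returns (amplitude, mean, sd)."""
    total = counts.sum()
    mu0 = float(np.sum(bin_centers * counts) / total)
    sd0 = float(np.sqrt(np.sum((bin_centers - mu0) ** 2 * counts) / total))
    sd0 = max(sd0, 1e-6)
    popt, _ = curve_fit(
        _gaussian, bin_centers, counts,
        p0=[counts.max(), mu0, sd0], maxfev=10000)
    amplitude, mean, sd = popt
    return float(amplitude), float(mean), abs(float(sd))


def enthalpy_distributions(
    frames: Sequence[Configuration],
    criteria: HBondCriteria | None = None,
    potentials: PotentialSet | None = None,
    bin_width: float = 0.5,
    min_count: int = 50,
) -> dict[str, EnthalpyDistribution]:
    """Pooled per-class hydrogen-bond enthalpy histograms over an ensemble,
    with Gaussian fits.

    Classes with fewer than ``min_count`` bonds (or a degenerate,
    single-bin histogram) are flagged ``low_count`` and left unfitted;
    the fitted Gaussian mean is the reported class enthalpy.
    """
    criteria = criteria or HBondCriteria()
    pooled: dict[str, list[float]] = {c: [] for c in BOND_CLASSES}
    for frame in frames:
        bonds = bond_energies(frame, identify_hbonds(frame, criteria),
                              potentials)
        for b in bonds:
            pooled[b.bond_class].append(b.energy)
    out: dict[str, EnthalpyDistribution] = {}
    for cls in BOND_CLASSES:
        energies = np.array(pooled[cls])
        if len(energies) == 0:
            out[cls] = EnthalpyDistribution(
                cls, np.array([]), np.array([]), 0, low_count=True)
            continue
        lo = np.floor(energies.min() / bin_width) * bin_width
        hi = np.ceil(energies.max() / bin_width) * bin_width + bin_width
        edges = np.arange(lo, hi + bin_width / 2.0, bin_width)
        counts, _ = np.histogram(energies, bins=edges)
        centers = 0.5 * (edges[1:] + edges[:-1])
        dist = EnthalpyDistribution(
            cls, centers, counts, len(energies),
            sample_mean=float(energies.mean()))
        if len(energies) < min_count or np.count_nonzero(counts) < 3:
            dist.low_count = True
        else:
            try:
                amp, mean, sd = fit_gaussian(centers, counts)
                dist.amplitude, dist.mean, dist.sd = amp, mean, sd
            except RuntimeError:
                dist.low_count = True
        out[cls] = dist
    return out
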