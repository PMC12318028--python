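"""Composition, ionisation and isotope/scattering-length bookkeeping for
ammonia-water mixtures.

The mixture of interest is a 1 : 3.665 ammonia : water liquid (20.5 wt.%,
21.4 mol%).  This module carries the small pieces of arithmetic that anchor
the neutron-scattering forward model: mass/mole composition, molarity,
Ostwald's dilution law for the degree of base dissociation, the
null-scattering H:D fraction, per-site atomic fractions and the count of
distinct atom-pair correlations.

Units: molar masses in g/mol, mass density in g/cm^3, concentrations in
mol/L, coherent scattering lengths in fm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "MOLAR_MASS_AMMONIA",
    "MOLAR_MASS_WATER",
    "B_H",
    "B_D",
    "B_O",
    "B_N",
    "DEFAULT_SCATTERING_LENGTHS",
    "WATER_SITES",
    "AMMONIA_SITES",
    "MixtureSpec",
    "DissociationModel",
    "IsotopeScheme",
    "AtomTypeSet",
    "ostwald_alpha",
    "weight_percent",
    "mole_percent",
    "molarity",
    "null_h_fraction",
    "atom_fractions",
    "pair_count",
]

# Light-isotope molar masses; isotopic mass differences are ignored for
# composition arithmetic (the liquid is treated in light-isotope terms).
MOLAR_MASS_AMMONIA = 17.031  # g/mol
MOLAR_MASS_WATER = 18.015    # g/mol

# Coherent neutron scattering lengths, fm.  H and D are the contrast pair
# exploited by isotopic substitution; O and N from the standard
# Sears neutron-data tabulation.
B_H = -3.74
B_D = 6.67
B_O = 5.803
B_N = 9.36

DEFAULT_SCATTERING_LENGTHS: dict[str, float] = {
    "O_W": B_O,
    "H_W": B_H,
    "N_A": B_N,
    "H_A": B_H,
}

# Site counts per molecule, by site label.
WATER_SITES: dict[str, int] = {"O_W": 1, "H_W": 2}
AMMONIA_SITES: dict[str, int] = {"N_A": 1, "H_A": 3}

# Labels whose hydrogen is exchangeable and therefore carries the sample's
# H:D fraction (all hydrogens exchange in both water and ammonia).
EXCHANGEABLE_LABELS = frozenset({"H_W", "H_A"})


@dataclass(frozen=True)
class MixtureSpec:
    """Molar composition (and optionally mass density) of an ammonia-water
    mixture."""

    ammonia_moles: float
    water_moles: float
    molar_mass_ammonia: float = MOLAR_MASS_AMMONIA
    molar_mass_water: float = MOLAR_MASS_WATER
    mass_density: float | None = None  # g/cm^3

    def __post_init__(self) -> None:
        if self.ammonia_moles < 0 or self.water_moles < 0:
            raise ValueError("mole counts must be non-negative")
        if self.ammonia_moles == 0 and self.water_moles == 0:
            raise ValueError("mixture must contain at least one component")
        if self.molar_mass_ammonia <= 0 or self.molar_mass_water <= 0:
            raise ValueError("molar masses must be positive")
        if self.mass_density is not None and self.mass_density <= 0:
            raise ValueError("mass density must be positive")


@dataclass(frozen=True)
class DissociationModel:
    """Ostwald dilution-law description of a weak base.

    ``k_b`` is the base dissociation constant, ``c_0`` the added molar
    concentration, and ``alpha`` the resulting degree of dissociation.
    """

    k_b: float
    c_0: float
    alpha: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha", ostwald_alpha(self.k_b, self.c_0))


@dataclass(frozen=True)
class IsotopeScheme:
    """H:D composition of the exchangeable hydrogen sites of a sample.

    ``h_fraction`` is the protium fraction x_H; the effective coherent
    length is the linear mix b_eff = x_H*b_H + (1-x_H)*b_D.
    """

    h_fraction: float
    b_h: float = B_H
    b_d: float = B_D
    label: str = "custom"

    def __post_init__(self) -> None:
        if not 0.0 <= self.h_fraction <= 1.0:
            raise ValueError("h_fraction must lie in [0, 1]")

    @property
    def b_eff(self) -> float:
        return self.h_fraction * self.b_h + (1.0 - self.h_fraction) * self.b_d

    @classmethod
    def preset(cls, label: str, b_h: float = B_H, b_d: float = B_D) -> "IsotopeScheme":
        """Standard sample schemes: fully protiated ``H``, fully deuteriated
        ``D``, the 50:50 ``HD`` mix, and the ``null`` mix whose mean
        hydrogen scattering length vanishes."""
        fractions = {"H": 1.0, "D": 0.0, "HD": 0.5}
        if label in fractions:
            return cls(fractions[label], b_h, b_d, label)
        if label == "null":
            return cls(null_h_fraction(b_h, b_d), b_h, b_d, "null")
        raise ValueError(f"unknown isotope scheme label {label!r}")


@dataclass(frozen=True)
class AtomTypeSet:
    """Atomic fractions and scattering lengths of the distinct site types."""

    type_labels: tuple[str, ...]
    fractions: Mapping[str, float]
    lengths: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(self.fractions[t] for t in self.type_labels)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"atomic fractions sum to {total}, expected 1")

    @property
    def i(self) -> int:
        """Number of distinct atom types."""
        return len(self.type_labels)

    @property
    def n_pairs(self) -> int:
        """Number of unique atom-pair correlations, i(i+1)/2."""
        return pair_count(self.i)

    def pair_labels(self) -> list[tuple[str, str]]:
        labels = self.type_labels
        return [(labels[a], labels[b])
                for a in range(len(labels)) for b in range(a, len(labels))]


def ostwald_alpha(k_b: float, c_0: float) -> float:
    """Degree of dissociation of a weak base from Ostwald's dilution law.

    Solves ``alpha**2 * c_0 / (1 - alpha) = k_b`` for the root in (0, 1)
    via the closed-form quadratic, in a formulation stable for
    k_b << c_0 (the regime of aqueous ammonia).
    """
    if k_b <= 0 or c_0 <= 0:
        raise ValueError("k_b and c_0 must be positive")
    # alpha^2 c0 + alpha k_b - k_b = 0
    disc = math.sqrt(k_b * k_b + 4.0 * k_b * c_0)
    alpha = 2.0 * k_b / (k_b + disc)  # rationalised positive root
    return alpha


def weight_percent(spec: MixtureSpec) -> float:
    """Ammonia mass percentage of the mixture."""
    m_a = spec.ammonia_moles * spec.molar_mass_ammonia
    m_w = spec.water_moles * spec.molar_mass_water
    return 100.0 * m_a / (m_a + m_w)


def mole_percent(spec: MixtureSpec) -> float:
    """Ammonia mole percentage of the mixture."""
    return 100.0 * spec.ammonia_moles / (spec.ammonia_moles + spec.water_moles)


def molarity(spec: MixtureSpec) -> float:
    """Molar concentration of ammonia, mol/L, from the mass density."""
    if spec.mass_density is None:
        raise ValueError("mixture has no mass density set")
    w = weight_percent(spec) / 100.0
    return 1000.0 * spec.mass_density * w / spec.molar_mass_ammonia


def null_h_fraction(b_h: float = B_H, b_d: float = B_D) -> float:
    """Protium fraction x_H at which the mean coherent hydrogen scattering
    length x_H*b_H + (1-x_H)*b_D vanishes (the null-scattering sample)."""
    if b_h * b_d >= 0:
        raise ValueError(
            "b_H and b_D must have opposite signs for a null composition")
    return b_d / (b_d - b_h)


def atom_fractions(
    spec: MixtureSpec,
    site_scheme: Mapping[str, Mapping[str, int]] | None = None,
    lengths: Mapping[str, float] | None = None,
    isotope: IsotopeScheme | None = None,
) -> AtomTypeSet:
    """Per-site-type atomic fractions (and scattering lengths) of the mixture.

    ``site_scheme`` maps component name ('ammonia', 'water') to per-molecule
    site counts; defaults to H2O = 1 O_W + 2 H_W, NH3 = 1 N_A + 3 H_A.
    If ``isotope`` is given, exchangeable-hydrogen labels carry its
    effective scattering length b_eff instead of b_H.
    """
    if site_scheme is None:
        site_scheme = {"ammonia": AMMONIA_SITES, "water": WATER_SITES}
    moles = {"ammonia": spec.ammonia_moles, "water": spec.water_moles}
    counts: dict[str, float] = {}
    for component, sites in site_scheme.items():
        for label, per_mol in sites.items():
            if per_mol < 0:
                raise ValueError(f"negative site count for {label}")
            counts[label] = counts.get(label, 0.0) + per_mol * moles[component]
    total = sum(counts.values())
    fractions = {label: c / total for label, c in counts.items() if c > 0}
    labels = tuple(sorted(fractions))
    if lengths is None:
        lengths = DEFAULT_SCATTERING_LENGTHS
    b = {label: lengths.get(label, 0.0) for label in labels}
    if isotope is not None:
        for label in labels:
            if label in EXCHANGEABLE_LABELS:
                b[label] = isotope.b_eff
    return AtomTypeSet(type_labels=labels, fractions=fractions, lengths=b)


def pair_count(i: int) -> int:
    """Number N of distinct atom-pair correlations among i atom types."""
    if not isinstance(i, int) or i < 1:
        raise ValueError("i must be a positive integer")
    return i * (i + 1) // 2
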