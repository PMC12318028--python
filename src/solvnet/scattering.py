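"""Partial radial distribution functions, their Fourier transforms to
partial structure factors, and isotope-weighted total structure factors.

This is the forward model of a neutron diffraction with isotopic
substitution (NDIS) experiment: ensembles of periodic configurations
yield partial g_ab(r); each transforms to a partial structure factor

    S_ab(Q) = 1 + 4*pi*rho * int r^2 (g_ab(r) - 1) sin(Qr)/(Qr) dr,

and the measurable total structure factor is the weighted sum

    F(Q) = sum_{a, b>=a} (2 - delta_ab) c_a c_b b_a b_b (S_ab(Q) - 1),

with c the atomic fractions, b the coherent scattering lengths (fm) and
exchangeable-hydrogen b replaced by the sample's effective
b_eff = x_H*b_H + (1 - x_H)*b_D.  F(Q) is reported in fm^2 (bare
weighted sum; no self-scattering or normalisation convention applied).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .composition import EXCHANGEABLE_LABELS, AtomTypeSet, IsotopeScheme
from .model import Configuration, minimum_image

__all__ = [
    "RadialDistribution",
    "PartialStructureFactor",
    "TotalStructureFactor",
    "ScatteringGeometry",
    "compute_partial_gr",
    "gr_to_sq",
    "sq_to_gr",
    "fq_weights",
    "total_fq",
    "q_from_angle",
    "default_q_grid",
]


@dataclass
class RadialDistribution:
    """Tabulated partial g_ab(r) on uniform bins (bin centres in ``r``)."""

    pair_label: tuple[str, str]
    r: np.ndarray            # bin centres, A
    g: np.ndarray            # dimensionless
    rho: float               # total site number density, A^-3
    c_beta: float            # atomic fraction of the beta (neighbour) type
    n_frames: int = 1

    @property
    def bin_width(self) -> float:
        return float(self.r[1] - self.r[0])


@dataclass
class PartialStructureFactor:
    pair_label: tuple[str, str]
    q: np.ndarray            # A^-1
    s: np.ndarray            # dimensionless


@dataclass
class TotalStructureFactor:
    label: str               # isotope sample label
    q: np.ndarray            # A^-1
    f: np.ndarray            # fm^2
    weights: Mapping[tuple[str, str], float] = field(default_factory=dict)


@dataclass(frozen=True)
class ScatteringGeometry:
    """Elastic scattering geometry: 2*theta in degrees, wavelength in A."""

    two_theta: float
    wavelength: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.two_theta <= 180.0:
            raise ValueError("2*theta must lie in [0, 180] degrees")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")


def q_from_angle(geometry: ScatteringGeometry) -> float:
    """Momentum transfer Q = 4*pi*sin(theta)/lambda, A^-1."""
    theta = math.radians(geometry.two_theta / 2.0)
    return 4.0 * math.pi * math.sin(theta) / geometry.wavelength


def default_q_grid(q_min: float = 0.05, q_max: float = 30.0,
                   dq: float = 0.05) -> np.ndarray:
    return np.arange(q_min, q_max + 0.5 * dq, dq)


def compute_partial_gr(
    frames: Sequence[Configuration] | Configuration,
    pair_label: tuple[str, str],
    bin_width: float = 0.03,
    r_max: float | None = None,
    intermolecular_only: bool = True,
) -> RadialDistribution:
    """Histogram-estimate of the partial radial distribution function.

    Minimum-image site-site distances between the two labelled site types
    are binned and normalised by the ideal-shell count
    rho * c_beta * V_shell per central atom, averaged over frames.  By
    default only intermolecular pairs contribute (the covalent-bond
    peaks of rigid molecules are not part of the solution structure);
    the ideal count excludes the same-molecule partners accordingly, so
    g still tends to 1 at large r.  For a like pair each unordered pair
    contributes to both orderings.
    """
    if isinstance(frames, Configuration):
        frames = [frames]
    if not frames:
        raise ValueError("need at least one frame")
    alpha, beta = pair_label
    box = frames[0].box_length
    if r_max is None:
        r_max = box / 2.0
    if r_max > box / 2.0 + 1e-9:
        raise ValueError("r_max exceeds half the box length")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    edges = edges[edges <= r_max + 1e-12]
    counts = np.zeros(len(edges) - 1)
    n_alpha_total = 0
    rho_cb = None
    for cfg in frames:
        ia = cfg.sites_of_label(alpha)
        ib = cfg.sites_of_label(beta)
        if len(ia) == 0 or len(ib) == 0:
            raise ValueError(f"no sites for pair {pair_label}")
        d = minimum_image(
            cfg.positions[ib][None, :, :] - cfg.positions[ia][:, None, :],
            cfg.box_length)
        r = np.linalg.norm(d, axis=-1)
        if intermolecular_only:
            keep = cfg.mol_index[ia][:, None] != cfg.mol_index[ib][None, :]
        else:
            keep = ~(ia[:, None] == ib[None, :])  # self-pairs only
        counts += np.histogram(r[keep], bins=edges)[0]
        n_alpha_total += len(ia)
        # ideal count per central atom excludes the partners that can
        # never appear (self and, if requested, same-molecule sites)
        excluded = (len(ia) * len(ib) - int(keep.sum())) / len(ia)
        rho_cb = (len(ib) - excluded) / cfg.box_length ** 3
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = n_alpha_total * rho_cb * shell
    g = np.divide(counts, ideal, out=np.zeros_like(counts), where=ideal > 0)
    cfg0 = frames[0]
    # effective neighbour fraction: for a like pair the central atom
    # cannot be its own neighbour, so c_beta reflects (N_beta - 1)
    return RadialDistribution(
        pair_label=pair_label,
        r=0.5 * (edges[1:] + edges[:-1]),
        g=g,
        rho=cfg0.number_density,
        c_beta=rho_cb / cfg0.number_density,
        n_frames=len(frames),
    )


def _check_uniform(x: np.ndarray) -> None:
    dx = np.diff(x)
    if len(dx) and not np.allclose(dx, dx[0], rtol=1e-8, atol=1e-12):
        raise ValueError("grid must be uniform")


def gr_to_sq(
    rdf: RadialDistribution,
    rho: float | None = None,
    q_grid: np.ndarray | None = None,
    window: str = "none",
) -> PartialStructureFactor:
    """Fourier transform g(r) to the partial structure factor S(Q).

    Trapezoidal quadrature over the tabulated range; the optional Lorch
    window sin(pi r / r_max)/(pi r / r_max) damps truncation ripple.  No
    tail correction is applied beyond the tabulated r range.
    """
    _check_uniform(rdf.r)
    if rho is None:
        rho = rdf.rho
    if q_grid is None:
        q_grid = default_q_grid()
    r = rdf.r
    h = rdf.g - 1.0
    if window == "lorch":
        x = np.pi * r / r[-1]
        h = h * np.where(x > 0, np.sin(x) / np.maximum(x, 1e-300), 1.0)
    elif window != "none":
        raise ValueError(f"unknown window {window!r}")
    qr = np.outer(q_grid, r)
    kernel = np.where(qr > 0, np.sin(qr) / np.where(qr > 0, qr, 1.0), 1.0)
    integrand = r ** 2 * h * kernel
    s = 1.0 + 4.0 * np.pi * rho * np.trapezoid(integrand, r, axis=1)
    return PartialStructureFactor(pair_label=rdf.pair_label, q=q_grid, s=s)


def sq_to_gr(
    psf: PartialStructureFactor,
    rho: float,
    r_grid: np.ndarray,
) -> RadialDistribution:
    """Inverse transform S(Q) back to g(r) by trapezoidal quadrature:

        g(r) = 1 + 1/(2*pi^2*rho) int Q^2 (S(Q) - 1) sin(Qr)/(Qr) dQ.
    """
    _check_uniform(psf.q)
    q = psf.q
    h = psf.s - 1.0
    qr = np.outer(r_grid, q)
    kernel = np.where(qr > 0, np.sin(qr) / np.where(qr > 0, qr, 1.0), 1.0)
    integrand = q ** 2 * h * kernel
    g = 1.0 + np.trapezoid(integrand, q, axis=1) / (2.0 * np.pi ** 2 * rho)
    return RadialDistribution(
        pair_label=psf.pair_label, r=np.asarray(r_grid, dtype=float), g=g,
        rho=rho, c_beta=float("nan"))


def fq_weights(
    atom_set: AtomTypeSet,
    isotope: IsotopeScheme | None = None,
) -> dict[tuple[str, str], float]:
    """Per-pair weights (2 - delta_ab) c_a c_b b_a b_b, fm^2.

    Exchangeable-hydrogen site types carry the isotope scheme's effective
    scattering length b_eff in place of b_H.
    """
    b = dict(atom_set.lengths)
    if isotope is not None:
        for label in b:
            if label in EXCHANGEABLE_LABELS:
                b[label] = isotope.b_eff
    weights: dict[tuple[str, str], float] = {}
    for a, bb in atom_set.pair_labels():
        delta = 1.0 if a == bb else 0.0
        weights[(a, bb)] = ((2.0 - delta) * atom_set.fractions[a]
                            * atom_set.fractions[bb] * b[a] * b[bb])
    return weights


def total_fq(
    partials: Mapping[tuple[str, str], PartialStructureFactor],
    atom_set: AtomTypeSet,
    isotope: IsotopeScheme | None = None,
    label: str | None = None,
) -> TotalStructureFactor:
    """Isotope-weighted total structure factor F(Q) from all partials.

    Every unique pair of the atom-type set must be present (either key
    order accepted) on a common Q grid.
    """
    lookup: dict[frozenset | tuple, PartialStructureFactor] = {}
    for key, psf in partials.items():
        lookup[tuple(sorted(key))] = psf
    missing = [p for p in atom_set.pair_labels()
               if tuple(sorted(p)) not in lookup]
    if missing:
        raise ValueError(f"missing partial structure factors for {missing}")
    weights = fq_weights(atom_set, isotope)
    q = None
    f = None
    for pair, w in weights.items():
        psf = lookup[tuple(sorted(pair))]
        if q is None:
            q = psf.q
            f = np.zeros_like(q)
        elif len(psf.q) != len(q) or not np.allclose(psf.q, q):
            raise ValueError("partials are not on a common Q grid")
        f += w * (psf.s - 1.0)
    if label is None:
        label = isotope.label if isotope is not None else "unit"
    return TotalStructureFactor(label=label, q=q, f=f, weights=weights)
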