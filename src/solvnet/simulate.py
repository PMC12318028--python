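"""Metropolis Monte Carlo of rigid molecular liquids, with optional
empirical-potential (EP) refinement against a target total structure
factor.

The sampler proposes whole-molecule translations and rotations (and,
optionally, harmonically-restrained single-site jiggles) and accepts a
move of energy change dU with probability min(1, exp(-dU/kT)).  The EP
loop mimics empirical potential structure refinement: after each
sampling cycle the simulated F(Q) is compared with the target, the
misfit is Fourier-transformed to an r-space perturbation, and a damped,
amplitude-capped radial correction is added to the per-pair-type
potential tables before sampling continues.

The EP is represented as tabulated radial corrections with linear
interpolation (not the Poisson-function expansion of the published EPSR
engine) - simpler, and adequate at the box sizes used here.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import (
    Configuration,
    K_BOLTZMANN,
    MoleculeTemplate,
    PotentialSet,
    SingularityError,
    minimum_image,
    molecule_energy,
    total_energy,
)
from .scattering import (
    PartialStructureFactor,
    compute_partial_gr,
    gr_to_sq,
    sq_to_gr,
)

__all__ = [
    "EmpiricalPotential",
    "MCState",
    "MoveMix",
    "TrajectorySpec",
    "RefinementResult",
    "metropolis_accept",
    "metropolis_step",
    "run_sweeps",
    "run_simulation",
    "refine_empirical_potential",
]

logger = logging.getLogger("solvnet")


class EmpiricalPotential:
    """Additive per-pair-type radial energy corrections on a uniform r grid.

    Corrections vanish beyond the grid maximum and are clipped to
    ``amplitude_cap`` (kJ/mol) everywhere.
    """

    def __init__(self, type_labels: Sequence[str], r_max: float,
                 dr: float = 0.05, amplitude_cap: float = 2.0):
        self.type_labels = tuple(type_labels)
        self.r_grid = np.arange(0.0, r_max + dr / 2.0, dr)
        self.dr = dr
        self.amplitude_cap = amplitude_cap
        t = len(self.type_labels)
        self.tables = np.zeros((t, t, len(self.r_grid)))
        self.iteration = 0
        self._lut = {lab: i for i, lab in enumerate(self.type_labels)}

    def add_correction(self, pair: tuple[str, str],
                       delta_u: np.ndarray) -> None:
        """Add a correction (on the EP r grid) to both orderings of a pair,
        then clip the table to the amplitude cap."""
        a, b = self._lut[pair[0]], self._lut[pair[1]]
        cap = self.amplitude_cap
        self.tables[a, b] = np.clip(self.tables[a, b] + delta_u, -cap, cap)
        if a != b:
            self.tables[b, a] = self.tables[a, b]

    def lookup(self, ti: np.ndarray, tj: np.ndarray,
               r: np.ndarray) -> np.ndarray:
        """Linear-interpolated correction energies for site-type index
        arrays ``ti``, ``tj`` at separations ``r``; zero beyond the grid."""
        x = np.asarray(r) / self.dr
        i0 = np.floor(x).astype(np.intp)
        inside = i0 < len(self.r_grid) - 1
        i0c = np.clip(i0, 0, len(self.r_grid) - 2)
        frac = x - i0
        rows = self.tables[ti, tj]  # (n, nr)
        take = np.arange(len(i0c))
        u = rows[take, i0c] * (1.0 - frac) + rows[take, i0c + 1] * frac
        return np.where(inside, u, 0.0)

    def max_abs(self) -> float:
        return float(np.max(np.abs(self.tables))) if self.tables.size else 0.0


@dataclass
class MoveMix:
    """Move-type proposal probabilities and maximum displacements.

    Defaults follow common structural-MC practice: equal translation and
    rotation weight; jiggles (single-site displacements restrained
    harmonically to the template geometry) are off by default because the
    observables of interest here are intermolecular.
    """

    p_translate: float = 0.45
    p_rotate: float = 0.45
    p_jiggle: float = 0.10
    max_translation: float = 0.3    # A
    max_rotation_deg: float = 15.0
    max_jiggle: float = 0.05        # A
    jiggle_enabled: bool = False
    jiggle_spring: float = 2000.0   # kJ/(mol*A^2)

    def choose(self, rng: np.random.Generator) -> str:
        if self.jiggle_enabled:
            p = np.array([self.p_translate, self.p_rotate, self.p_jiggle])
        else:
            p = np.array([self.p_translate, self.p_rotate, 0.0])
        p = p / p.sum()
        return ["translate", "rotate", "jiggle"][int(rng.choice(3, p=p))]


@dataclass
class TrajectorySpec:
    """How many frames to save, how far apart (in sweeps), and how long to
    equilibrate first.  One sweep is one attempted move per molecule."""

    n_frames: int = 11
    frame_stride: int = 50
    equilibration_sweeps: int = 2000

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.frame_stride < 1:
            raise ValueError("n_frames and frame_stride must be >= 1")


class MCState:
    """Mutable Monte Carlo sampler state.

    Holds the configuration, the thermal factor kT = k_B*T, the running
    total energy (updated incrementally on accepted moves) and the seeded
    random generator.
    """

    def __init__(
        self,
        configuration: Configuration,
        temperature: float,
        potentials: PotentialSet | None = None,
        ep: EmpiricalPotential | None = None,
        seed: int | np.random.Generator = 0,
        templates: Mapping[str, MoleculeTemplate] | None = None,
    ):
        self.configuration = configuration
        self.temperature = float(temperature)
        self.kT = K_BOLTZMANN * self.temperature
        self.potentials = potentials or PotentialSet()
        self.ep = ep
        self.rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        self.templates = dict(templates) if templates else {}
        self.step_count = 0
        self.accepted_count = 0
        self.energy = total_energy(configuration, self.potentials, ep)

    @property
    def acceptance_rate(self) -> float:
        return self.accepted_count / self.step_count if self.step_count else 0.0

    def recompute_energy(self) -> float:
        self.energy = total_energy(self.configuration, self.potentials,
                                   self.ep)
        return self.energy


def metropolis_accept(delta_u: float, kT: float,
                      rng: np.random.Generator) -> bool:
    """The Metropolis criterion: downhill moves always accepted, uphill
    moves with probability exp(-dU/kT)."""
    if delta_u <= 0.0:
        return True
    return rng.random() < math.exp(-delta_u / kT)


def _intra_restraint(pos: np.ndarray, ref: np.ndarray, k: float) -> float:
    """Harmonic restraint on intramolecular site-site distances vs the
    template's."""
    if len(pos) < 2:
        return 0.0
    iu = np.triu_indices(len(pos), k=1)
    d = np.linalg.norm(pos[iu[0]] - pos[iu[1]], axis=1)
    d0 = np.linalg.norm(ref[iu[0]] - ref[iu[1]], axis=1)
    return 0.5 * k * float(np.sum((d - d0) ** 2))


def metropolis_step(
    state: MCState,
    move: str | None = None,
    moves: MoveMix | None = None,
    molecule: int | None = None,
) -> bool:
    """Attempt one Monte Carlo move on a random (or given) molecule.

    Returns True if the move was accepted.  A move that would place two
    sites on top of each other is auto-rejected with a warning.
    """
    moves = moves or MoveMix()
    cfg = state.configuration
    rng = state.rng
    if molecule is None:
        molecule = int(rng.integers(cfg.n_molecules))
    if move is None:
        move = moves.choose(rng)
    sl = cfg.mol_slice(molecule)
    # unwrap the molecule about its first site so rigid-body moves act on
    # a single periodic image
    stored = cfg.positions[sl]
    old = stored[0] + minimum_image(stored - stored[0], cfg.box_length)
    delta_intra = 0.0
    if move == "translate":
        new = old + rng.uniform(-moves.max_translation,
                                moves.max_translation, size=3)
    elif move == "rotate":
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = math.radians(rng.uniform(-moves.max_rotation_deg,
                                         moves.max_rotation_deg))
        c, s = math.cos(angle), math.sin(angle)
        ux, uy, uz = axis
        rot = np.array([
            [c + ux * ux * (1 - c), ux * uy * (1 - c) - uz * s,
             ux * uz * (1 - c) + uy * s],
            [uy * ux * (1 - c) + uz * s, c + uy * uy * (1 - c),
             uy * uz * (1 - c) - ux * s],
            [uz * ux * (1 - c) - uy * s, uz * uy * (1 - c) + ux * s,
             c + uz * uz * (1 - c)],
        ])
        centre = old.mean(axis=0)
        new = (old - centre) @ rot.T + centre
    elif move == "jiggle":
        tpl = state.templates.get(cfg.template_names[molecule])
        if tpl is None:
            raise ValueError("jiggle moves need the molecule templates")
        ref = tpl.coordinates()
        site = int(rng.integers(len(old)))
        new = old.copy()
        new[site] += rng.uniform(-moves.max_jiggle, moves.max_jiggle, size=3)
        delta_intra = (_intra_restraint(new, ref, moves.jiggle_spring)
                       - _intra_restraint(old, ref, moves.jiggle_spring))
    else:
        raise ValueError(f"unknown move type {move!r}")

    state.step_count += 1
    try:
        e_old = molecule_energy(cfg, molecule, state.potentials, state.ep)
        e_new = molecule_energy(cfg, molecule, state.potentials, state.ep,
                                positions=new)
    except SingularityError:
        warnings.warn("move rejected: coincident sites", stacklevel=2)
        return False
    delta_u = e_new - e_old + delta_intra
    if not np.isfinite(delta_u):
        warnings.warn("move rejected: non-finite energy change", stacklevel=2)
        return False
    if metropolis_accept(delta_u, state.kT, rng):
        cfg.positions[sl] = new % cfg.box_length
        state.energy += delta_u
        state.accepted_count += 1
        return True
    return False


def run_sweeps(state: MCState, n_sweeps: int,
               moves: MoveMix | None = None) -> None:
    """Run ``n_sweeps`` sweeps (one attempted move per molecule each)."""
    moves = moves or MoveMix()
    n_mol = state.configuration.n_molecules
    for _ in range(n_sweeps):
        for _ in range(n_mol):
            metropolis_step(state, moves=moves)
        if not np.isfinite(state.energy):
            raise RuntimeError(
                f"non-finite total energy after {state.step_count} moves "
                f"(T = {state.temperature} K)")


def run_simulation(
    state: MCState,
    spec: TrajectorySpec,
    moves: MoveMix | None = None,
) -> list[Configuration]:
    """Equilibrate, then return ``n_frames`` configurations saved
    ``frame_stride`` sweeps apart.  Deterministic for a given seed."""
    moves = moves or MoveMix()
    run_sweeps(state, spec.equilibration_sweeps, moves)
    frames: list[Configuration] = []
    for k in range(spec.n_frames):
        if k > 0:
            run_sweeps(state, spec.frame_stride, moves)
        frame = state.configuration.copy()
        frame.frame_index = k
        frames.append(frame)
    return frames


@dataclass
class RefinementResult:
    ep: EmpiricalPotential
    residuals: list[float]
    converged: bool
    frames: list[Configuration] = field(default_factory=list)


def _simulated_fq(
    frames: Sequence[Configuration],
    weights: Mapping[tuple[str, str], float],
    q_grid: np.ndarray,
    bin_width: float,
) -> tuple[np.ndarray, dict[tuple[str, str], PartialStructureFactor]]:
    f = np.zeros_like(q_grid)
    partials: dict[tuple[str, str], PartialStructureFactor] = {}
    for pair, w in weights.items():
        rdf = compute_partial_gr(frames, pair, bin_width=bin_width)
        psf = gr_to_sq(rdf, q_grid=q_grid, window="lorch")
        partials[pair] = psf
        f += w * (psf.s - 1.0)
    return f, partials


def refine_empirical_potential(
    state: MCState,
    target_q: np.ndarray,
    target_f: np.ndarray,
    weights: Mapping[tuple[str, str], float],
    n_cycles: int = 10,
    damping: float = 0.3,
    amplitude_cap: float = 2.0,
    sweeps_per_cycle: int = 100,
    frames_per_cycle: int = 10,
    frame_stride: int = 10,
    bin_width: float = 0.03,
    patience: int = 3,
) -> RefinementResult:
    """Iteratively refine an empirical potential against a target F(Q).

    Per cycle: sample an ensemble, form the simulated
    F(Q) = sum_p w_p (S_p(Q) - 1), take the misfit dF = target - simulated,
    distribute it over the pairs by the least-norm weighting
    dS_p = dF * w_p / sum_q w_q^2, invert each dS_p to an r-space
    perturbation dg_p, and add the damped, capped correction
    dU_p(r) = -damping * kT * dg_p(r) to the EP tables.  The summed
    squared misfit is recorded per cycle; if it grows over ``patience``
    consecutive cycles the refinement stops and reports failure.

    ``target_q`` should not extend below ~2*pi/box_length, the smallest
    wavevector the box supports.
    """
    target_q = np.asarray(target_q, dtype=float)
    target_f = np.asarray(target_f, dtype=float)
    box = state.configuration.box_length
    if target_q[0] < 2.0 * np.pi / box - 1e-9:
        raise ValueError("target Q grid extends below 2*pi/box_length")
    if state.ep is None:
        state.ep = EmpiricalPotential(
            state.configuration.type_labels, r_max=box / 2.0,
            amplitude_cap=amplitude_cap)
        state.recompute_energy()
    ep = state.ep
    w_norm = sum(w * w for w in weights.values())
    rho = state.configuration.number_density
    traj = TrajectorySpec(n_frames=frames_per_cycle,
                          frame_stride=frame_stride,
                          equilibration_sweeps=sweeps_per_cycle)
    residuals: list[float] = []
    frames: list[Configuration] = []
    worse = 0
    for cycle in range(n_cycles):
        frames = run_simulation(state, traj)
        f_sim, _ = _simulated_fq(frames, weights, target_q, bin_width)
        df = target_f - f_sim
        residual = float(np.sum(df * df))
        residuals.append(residual)
        logger.info("EP cycle %d: residual %.4g, max|EP| %.3g kJ/mol",
                    cycle, residual, ep.max_abs())
        if len(residuals) > 1 and residual > residuals[-2]:
            worse += 1
            if worse >= patience:
                logger.warning("EP refinement diverging; stopping")
                return RefinementResult(ep, residuals, False, frames)
        else:
            worse = 0
        for pair, w in weights.items():
            ds = df * w / w_norm
            psf = PartialStructureFactor(pair, target_q, 1.0 + ds)
            dg = sq_to_gr(psf, rho, ep.r_grid).g - 1.0
            ep.add_correction(pair, np.clip(
                -damping * state.kT * dg, -amplitude_cap, amplitude_cap))
        ep.iteration += 1
        state.recompute_energy()
    return RefinementResult(ep, residuals, True, frames)
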