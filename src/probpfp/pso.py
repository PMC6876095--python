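"""Particle-swarm training of the pair-HMM parameters.

Each particle's position is a (delta, epsilon, pi_M) vector.  Velocities
and positions follow the canonical update

    v' = w v + f1 r1 (p_best - x) + f2 r2 (g_best - x)
    x' = x + v'

with fresh r1, r2 ~ U[0, 1] per particle, per iteration, per component,
and absorbing walls at the search box (clamp + zero the clamped velocity
component).  Fitness of a position is the summed sum-of-pairs score of the
MEA pairwise alignments the resulting HMM posteriors induce on the family,
scored with BLOSUM62 and gap open -11 / extend -1.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .matrices import SubstitutionMatrix, blosum62, match_emissions
from .pairhmm import DEFAULT_BOUNDS, ParamVector, hmm_posterior, params_from_vector
from .pairwise import alignment_from_moves, mea_align
from .scoring import GapPenalties, sop_score
from .seqio import ProteinSequence

log = logging.getLogger(__name__)

#: Pairs used per fitness evaluation are capped on large families.
MAX_FITNESS_PAIRS = 10


@dataclass
class Particle:
    position: ParamVector
    velocity: np.ndarray
    best_position: ParamVector | None = None
    best_fitness: float = -np.inf


@dataclass(frozen=True)
class SwarmConfig:
    """Swarm size, iteration budget, and the canonical PSO coefficients."""

    n_particles: int = 10
    n_iterations: int = 30
    w: float = 0.729
    f1: float = 1.49445
    f2: float = 1.49445
    seed: int = 0
    bounds: np.ndarray = field(default_factory=lambda: DEFAULT_BOUNDS.copy())
    max_pairs: int = MAX_FITNESS_PAIRS

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("need at least one particle")
        if self.n_iterations < 0:
            raise ValueError("iteration count must be non-negative")
        if min(self.w, self.f1, self.f2) < 0:
            raise ValueError("w, f1, f2 must be non-negative")


def update_velocity(p: Particle, g: ParamVector, cfg: SwarmConfig,
                    r1, r2) -> np.ndarray:
    """Velocity update; r1, r2 may be scalars or per-component arrays."""
    x = p.position.theta
    pb = (p.best_position or p.position).theta
    return (cfg.w * p.velocity
            + cfg.f1 * np.asarray(r1) * (pb - x)
            + cfg.f2 * np.asarray(r2) * (g.theta - x))


def update_position(p: Particle, cfg: SwarmConfig) -> ParamVector:
    """Move by the current velocity, clamp to the box, and zero the
    velocity on any clamped component (absorbing walls)."""
    lo, hi = cfg.bounds[:, 0], cfg.bounds[:, 1]
    raw = p.position.theta + p.velocity
    clamped = np.clip(raw, lo, hi)
    p.velocity = np.where(raw == clamped, p.velocity, 0.0)
    return ParamVector(clamped, cfg.bounds)


def _select_pairs(n: int, max_pairs: int,
                  rng: np.random.Generator) -> list[tuple[int, int]]:
    pairs = list(itertools.combinations(range(n), 2))
    if n <= 5 or len(pairs) <= max_pairs:
        return pairs
    idx = rng.choice(len(pairs), size=max_pairs, replace=False)
    return [pairs[k] for k in sorted(idx)]


def fitness(v: ParamVector, family: list[ProteinSequence],
            matrix: SubstitutionMatrix | None = None,
            gaps: GapPenalties | None = None,
            pairs: list[tuple[int, int]] | None = None,
            emissions=None) -> float:
    """Summed SoP score of the MEA pairwise alignments induced by `v`."""
    if len(family) < 2:
        raise ValueError("fitness needs at least 2 sequences")
    matrix = matrix or blosum62()
    gaps = gaps or GapPenalties()
    if pairs is None:
        pairs = list(itertools.combinations(range(len(family)), 2))
    h = params_from_vector(v, emissions=emissions)
    total = 0.0
    for i, j in pairs:
        P = hmm_posterior(family[i], family[j], h)
        mea = mea_align(P)
        aln = alignment_from_moves(family[i], family[j], mea.moves)
        total += sop_score(aln, matrix, gaps)
    return total


def optimize(family: list[ProteinSequence],
             cfg: SwarmConfig | None = None,
             matrix: SubstitutionMatrix | None = None,
             gaps: GapPenalties | None = None,
             ) -> tuple[ParamVector, list[float]]:
    """Run the swarm and return the global-best vector and the per-iteration
    global-best fitness trace (length `n_iterations`).

    Draw order from the seeded generator: fitness-pair subsample, initial
    positions, initial velocities, then r1/r2 per iteration.  Positions are
    initialised uniformly in the box; velocities uniformly within +-10% of
    each component's span.  The initial positions are evaluated before the
    first move, so `n_iterations = 0` returns the best random start.
    """
    cfg = cfg or SwarmConfig()
    matrix = matrix or blosum62()
    gaps = gaps or GapPenalties()
    emissions = match_emissions(matrix.name if matrix.name == "BLOSUM62"
                                else "BLOSUM62")
    rng = np.random.default_rng(cfg.seed)
    pairs = _select_pairs(len(family), cfg.max_pairs, rng)
    if len(pairs) < len(family) * (len(family) - 1) // 2:
        log.info("fitness evaluated on %d subsampled pairs", len(pairs))

    lo, hi = cfg.bounds[:, 0], cfg.bounds[:, 1]
    span = hi - lo
    swarm: list[Particle] = []
    for _ in range(cfg.n_particles):
        pos = ParamVector(rng.uniform(lo, hi), cfg.bounds)
        vel = rng.uniform(-0.1 * span, 0.1 * span)
        swarm.append(Particle(position=pos, velocity=vel))

    def evaluate(p: Particle) -> None:
        f = fitness(p.position, family, matrix, gaps, pairs, emissions)
        if f > p.best_fitness:
            p.best_fitness = f
            p.best_position = p.position

    g_best: ParamVector | None = None
    g_fit = -np.inf
    for p in swarm:
        evaluate(p)
        if p.best_fitness > g_fit:
            g_fit = p.best_fitness
            g_best = p.best_position

    trace: list[float] = []
    for it in range(cfg.n_iterations):
        for p in swarm:
            r1 = rng.uniform(size=3)
            r2 = rng.uniform(size=3)
            p.velocity = update_velocity(p, g_best, cfg, r1, r2)
            p.position = update_position(p, cfg)
            evaluate(p)
            if p.best_fitness > g_fit:
                g_fit = p.best_fitness
                g_best = p.best_position
        trace.append(g_fit)
        log.info("PSO iteration %d/%d: best SoP %.3f", it + 1,
                 cfg.n_iterations, g_fit)
    return g_best, trace
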