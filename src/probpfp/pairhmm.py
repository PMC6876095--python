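"""Match posteriors from a three-state pair hidden Markov model.

The model has states M (emit a matched residue pair), X (emit a residue of
x against a gap) and Y (emit a residue of y against a gap).  Its free
parameters — the gap-open probability delta, the gap-extend probability
epsilon and the initial match probability pi_M — are the quantities the
particle-swarm trainer optimises; the emission tables are fixed,
derived from BLOSUM62 (see :mod:`probpfp.matrices`).

Topology: M -> (M, X, Y) with probabilities (1 - 2 delta, delta, delta);
X -> (X, M) with (epsilon, 1 - epsilon); Y symmetric.  Direct X <-> Y
transitions are forbidden, and there is no explicit begin/end state: the
initial distribution (pi_M, pi_X, pi_Y) with pi_X = pi_Y plays the begin
role and paths simply terminate once both sequences are emitted.

Forward/Backward over this lattice gives the match posterior

    P(x_i ~ y_j | x, y) = fM(i, j) * bM(i, j) / P(x, y).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._kernels import hmm_backward_kernel, hmm_forward_kernel
from .matrices import N_LETTERS, encode, match_emissions
from .seqio import ProteinSequence

log = logging.getLogger(__name__)

#: Default PSO search box for (delta, epsilon, pi_M): keeps every transition
#: row a strictly positive distribution with margin.
DEFAULT_BOUNDS = np.array([[1e-4, 0.3], [1e-4, 0.9], [0.1, 1 - 1e-4]])


@dataclass(frozen=True)
class HmmParams:
    """Pair-HMM parameter set: initial distribution, transitions, emissions."""

    pi: np.ndarray              # (3,) over (M, X, Y), pi_X == pi_Y
    delta: float                # gap-open transition M->X, M->Y
    epsilon: float              # gap-extend transition X->X, Y->Y
    emit_match: np.ndarray      # (21, 21) joint p(a, b), symmetric, sums to 1
    emit_single: np.ndarray     # (21,) background q(a), sums to 1

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        object.__setattr__(self, "pi", pi)
        if pi.shape != (3,) or np.any(pi <= 0) or np.any(pi >= 1):
            raise ValueError("pi must be 3 probabilities strictly inside (0,1)")
        if abs(pi.sum() - 1) > 1e-9 or abs(pi[1] - pi[2]) > 1e-9:
            raise ValueError("pi must sum to 1 with pi_X == pi_Y")
        if not (0 < self.delta < 0.5):
            raise ValueError("delta must lie in (0, 0.5)")
        if not (0 < self.epsilon < 1):
            raise ValueError("epsilon must lie in (0, 1)")
        p = np.asarray(self.emit_match, dtype=float)
        q = np.asarray(self.emit_single, dtype=float)
        if p.shape != (N_LETTERS, N_LETTERS) or q.shape != (N_LETTERS,):
            raise ValueError("emission table shapes are wrong")
        if abs(p.sum() - 1) > 1e-12 or abs(q.sum() - 1) > 1e-12:
            raise ValueError("emission tables must sum to 1")
        if not np.allclose(p, p.T, rtol=0, atol=1e-15):
            raise ValueError("match emissions must be symmetric")
        object.__setattr__(self, "emit_match", p)
        object.__setattr__(self, "emit_single", q)

    def transition_matrix(self) -> np.ndarray:
        """Row-stochastic transitions over (M, X, Y); X<->Y entries are 0."""
        d, e = self.delta, self.epsilon
        return np.array([
            [1 - 2 * d, d, d],
            [1 - e, e, 0.0],
            [1 - e, 0.0, e],
        ])


@dataclass(frozen=True)
class ParamVector:
    """A PSO position: theta = (delta, epsilon, pi_M) inside a box."""

    theta: np.ndarray
    bounds: np.ndarray = field(default_factory=lambda: DEFAULT_BOUNDS.copy())

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        bounds = np.asarray(self.bounds, dtype=float)
        if theta.shape != (3,) or bounds.shape != (3, 2):
            raise ValueError("theta must have 3 components with (3,2) bounds")
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "bounds", bounds)

    def clamped(self) -> "ParamVector":
        return ParamVector(
            np.clip(self.theta, self.bounds[:, 0], self.bounds[:, 1]),
            self.bounds,
        )


def default_params() -> HmmParams:
    """Untrained starting parameters (a generic protein setting)."""
    return params_from_vector(ParamVector(np.array([0.02, 0.8, 0.9])))


def params_from_vector(v: ParamVector,
                       emissions: tuple[np.ndarray, np.ndarray] | None = None,
                       ) -> HmmParams:
    """Deterministic embedding of a PSO position into a full parameter set.

    Out-of-bounds components are clamped to the box and logged, never
    raised — the swarm may propose boundary-violating positions.
    """
    theta = np.asarray(v.theta, dtype=float)
    lo, hi = v.bounds[:, 0], v.bounds[:, 1]
    if np.any(theta < lo) or np.any(theta > hi):
        log.warning("parameter vector %s outside bounds; clamped", theta)
        theta = np.clip(theta, lo, hi)
    delta, epsilon, pi_m = theta
    pi = np.array([pi_m, (1 - pi_m) / 2, (1 - pi_m) / 2])
    p, q = emissions if emissions is not None else match_emissions()
    return HmmParams(pi=pi, delta=float(delta), epsilon=float(epsilon),
                     emit_match=p, emit_single=q)


def _lattice_inputs(x: ProteinSequence, y: ProteinSequence, h: HmmParams):
    xi = encode(x.residues)
    yi = encode(y.residues)
    with np.errstate(divide="ignore"):
        Em = np.log(h.emit_match)[np.ix_(xi, yi)]
        Ex = np.log(h.emit_single[xi])
        Ey = np.log(h.emit_single[yi])
        lpi = np.log(h.pi)
        ltr = np.log(h.transition_matrix())
    return Em, Ex, Ey, lpi, ltr


def hmm_forward(x: ProteinSequence, y: ProteinSequence,
                h: HmmParams) -> tuple[tuple[np.ndarray, ...], float]:
    """Forward lattices (fM, fX, fY) and the total log-likelihood log P(x, y)."""
    Em, Ex, Ey, lpi, ltr = _lattice_inputs(x, y, h)
    fM, fX, fY = hmm_forward_kernel(Em, Ex, Ey, lpi, ltr)
    n, m = len(x), len(y)
    total = np.logaddexp(np.logaddexp(fM[n, m], fX[n, m]), fY[n, m])
    return (fM, fX, fY), float(total)


def hmm_backward(x: ProteinSequence, y: ProteinSequence,
                 h: HmmParams) -> tuple[tuple[np.ndarray, ...], float]:
    """Backward lattices and the total log-likelihood recomputed from them."""
    Em, Ex, Ey, lpi, ltr = _lattice_inputs(x, y, h)
    bM, bX, bY = hmm_backward_kernel(Em, Ex, Ey, ltr)
    total = lpi[0] + Em[0, 0] + bM[1, 1]
    if len(x) >= 1:
        start_x = lpi[1] + Ex[0] + bX[1, 0]
        total = np.logaddexp(total, start_x)
    if len(y) >= 1:
        start_y = lpi[2] + Ey[0] + bY[0, 1]
        total = np.logaddexp(total, start_y)
    return (bM, bX, bY), float(total)


def hmm_posterior(x: ProteinSequence, y: ProteinSequence,
                  h: HmmParams) -> np.ndarray:
    """Match posterior matrix P[i-1, j-1] = P(x_i ~ y_j | x, y), in [0, 1]."""
    (fM, _, _), total_f = hmm_forward(x, y, h)
    (bM, _, _), total_b = hmm_backward(x, y, h)
    if abs(total_f - total_b) > 1e-9 * max(1.0, abs(total_f)):
        log.warning("forward/backward totals disagree: %g vs %g",
                    total_f, total_b)
    P = np.exp(fM[1:, 1:] + bM[1:, 1:] - total_f)
    np.clip(P, 0.0, 1.0, out=P)
    return P
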