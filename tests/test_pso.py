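import numpy as np
import pytest

from probpfp.pairhmm import ParamVector
from probpfp.pso import (Particle, SwarmConfig, fitness, optimize,
                         update_position, update_velocity)
from probpfp.seqio import ProteinSequence


def _particle(x, v, bounds):
    p = Particle(position=ParamVector(np.array(x, float), bounds),
                 velocity=np.array(v, float))
    p.best_position = p.position
    return p


WIDE = np.array([[0.0, 1.0]] * 3)


class TestUpdates:
    def test_velocity_hand_value(self):
        cfg = SwarmConfig(w=0.7, f1=1.5, f2=1.5, bounds=WIDE)
        p = _particle([0.1] * 3, [0.01] * 3, WIDE)
        p.best_position = ParamVector(np.array([0.12] * 3), WIDE)
        g = ParamVector(np.array([0.2] * 3), WIDE)
        v = update_velocity(p, g, cfg, 0.5, 0.5)
        # 0.7*0.01 + 1.5*0.5*(0.12-0.1) + 1.5*0.5*(0.2-0.1)
        assert np.allclose(v, 0.097)

    def test_pure_inertia_when_all_positions_coincide(self):
        cfg = SwarmConfig(w=0.7, f1=1.5, f2=1.5, bounds=WIDE)
        p = _particle([0.1] * 3, [0.01] * 3, WIDE)
        g = ParamVector(np.array([0.1] * 3), WIDE)
        assert np.allclose(update_velocity(p, g, cfg, 0.3, 0.9), 0.007)

    def test_zero_coefficients_zero_velocity(self):
        cfg = SwarmConfig(w=0.0, f1=1.5, f2=1.5, bounds=WIDE)
        p = _particle([0.1] * 3, [0.01] * 3, WIDE)
        g = ParamVector(np.array([0.9] * 3), WIDE)
        assert np.allclose(update_velocity(p, g, cfg, 0.0, 0.0), 0.0)

    def test_position_hand_value(self):
        cfg = SwarmConfig(bounds=WIDE)
        p = _particle([0.1] * 3, [0.097] * 3, WIDE)
        assert np.allclose(update_position(p, cfg).theta, 0.197)

    def test_clamp_zeroes_velocity_at_walls(self):
        cfg = SwarmConfig(bounds=WIDE)
        p = _particle([1.0, 0.5, 0.5], [0.2, 0.1, -0.9], WIDE)
        new = update_position(p, cfg)
        assert np.allclose(new.theta, [1.0, 0.6, 0.0])
        assert p.velocity[0] == 0.0 and p.velocity[2] == 0.0
        assert p.velocity[1] == pytest.approx(0.1)

    def test_zero_velocity_is_identity(self):
        cfg = SwarmConfig(bounds=WIDE)
        p = _particle([0.3] * 3, [0.0] * 3, WIDE)
        assert np.allclose(update_position(p, cfg).theta, 0.3)

    def test_hand_iterated_trajectory(self):
        # three velocity/position updates with fixed r1 = r2 = 0.5,
        # recomputed here with plain arithmetic
        cfg = SwarmConfig(w=0.7, f1=1.5, f2=1.5, bounds=WIDE)
        g = ParamVector(np.array([0.8] * 3), WIDE)
        p = _particle([0.1] * 3, [0.05] * 3, WIDE)
        x, v, pb = 0.1, 0.05, 0.1
        for _ in range(3):
            v = 0.7 * v + 1.5 * 0.5 * (pb - x) + 1.5 * 0.5 * (0.8 - x)
            x = min(1.0, max(0.0, x + v))
            p.velocity = update_velocity(p, g, cfg, 0.5, 0.5)
            p.position = update_position(p, cfg)
            assert np.allclose(p.position.theta, x)
            assert np.allclose(p.velocity, v)


class TestFitness:
    def test_identical_sequences_score_diagonal(self):
        fam = [ProteinSequence("a", "ACDE"), ProteinSequence("b", "ACDE")]
        v = ParamVector(np.array([0.02, 0.2, 0.9]))
        assert fitness(v, fam) == pytest.approx(4 + 9 + 6 + 5)

    def test_invariant_to_family_order(self):
        fam = [ProteinSequence("a", "ACDE"), ProteinSequence("b", "ARNE"),
               ProteinSequence("c", "WCDE")]
        v = ParamVector(np.array([0.05, 0.3, 0.8]))
        assert fitness(v, fam) == pytest.approx(fitness(v, fam[::-1]))

    def test_needs_two_sequences(self):
        with pytest.raises(ValueError):
            fitness(ParamVector(np.array([0.02, 0.2, 0.9])),
                    [ProteinSequence("a", "ACDE")])


class TestOptimize:
    def _family(self, seed=5, n=4, length=30):
        from probpfp.simulate import generate_family
        return generate_family(n=n, length=length, p_sub=0.15,
                               p_indel=0.03, seed=seed).descendants

    def test_trace_monotone_and_sized(self):
        fam = self._family()
        cfg = SwarmConfig(n_particles=4, n_iterations=6, seed=11)
        best, trace = optimize(fam, cfg)
        assert len(trace) == 6
        assert all(a <= b for a, b in zip(trace, trace[1:]))
        lo, hi = cfg.bounds[:, 0], cfg.bounds[:, 1]
        assert np.all(best.theta >= lo) and np.all(best.theta <= hi)

    def test_same_seed_reproducible(self):
        fam = self._family()
        cfg = SwarmConfig(n_particles=3, n_iterations=4, seed=7)
        b1, t1 = optimize(fam, cfg)
        b2, t2 = optimize(fam, cfg)
        assert np.array_equal(b1.theta, b2.theta)
        assert t1 == t2

    def test_zero_iterations_returns_best_initial(self):
        fam = self._family()
        cfg = SwarmConfig(n_particles=5, n_iterations=0, seed=3)
        best, trace = optimize(fam, cfg)
        assert trace == []
        # recompute the initial positions with the same draw order
        rng = np.random.default_rng(3)
        lo, hi = cfg.bounds[:, 0], cfg.bounds[:, 1]
        starts = []
        for _ in range(5):
            starts.append(rng.uniform(lo, hi))
            rng.uniform(-0.1 * (hi - lo), 0.1 * (hi - lo))
        fits = [fitness(ParamVector(s, cfg.bounds), fam) for s in starts]
        assert np.array_equal(best.theta, starts[int(np.argmax(fits))])

    def test_single_particle_inertia_only_runs(self):
        fam = self._family(n=2, length=20)
        cfg = SwarmConfig(n_particles=1, n_iterations=3, w=1.0,
                          f1=0.0, f2=0.0, seed=2)
        best, trace = optimize(fam, cfg)
        assert len(trace) == 3
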