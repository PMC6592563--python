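"""Coupled three-state simulator: propensities, exact waiting times, dynamics."""

import numpy as np
import pytest
from scipy import integrate, optimize, stats

from tissuecorr import simulator, synthetic
from tissuecorr.errors import InvalidConfigError
from tissuecorr.network import sample_network
from tissuecorr.simulator import SimParams


@pytest.fixture(scope="module")
def params():
    return SimParams()


class TestPropensities:
    def test_initial_quiescent_state(self, params):
        """All copies off: only off->primed and low transcription can fire."""
        zeros = np.zeros(1)
        props = simulator.propensities(
            zeros, np.array([4.0]), zeros, zeros, zeros, t=0.0, params=params
        )
        assert props["off_primed"][0] == pytest.approx(params.R10 * 4)
        assert props["on_off"][0] == 0 and props["primed_on"][0] == 0
        assert props["mrna_death"][0] == 0
        assert props["mrna_birth"][0] == pytest.approx(
            params.alpha_norm * params.beta_L * 4
        )

    def test_isolated_cell_reduces_to_uncoupled_rates(self, params):
        state = (np.array([2.0]), np.array([1.0]), np.array([1.0]), np.array([5.0]))
        coupled = simulator.propensities(*state, np.zeros(1), 10.0, params)
        p0 = SimParams(delta=0.0, delta_b=0.0)
        uncoupled = simulator.propensities(*state, np.zeros(1), 10.0, p0)
        for key in coupled:
            assert coupled[key][0] == pytest.approx(uncoupled[key][0])

    def test_neighbour_on_genes_scale_gene_cycle_rates(self, params):
        """A neighbour with 2 on copies multiplies R1 by (1 + 2 delta)."""
        props = simulator.propensities(
            np.zeros(1), np.array([4.0]), np.zeros(1), np.zeros(1),
            np.array([2.0]), 0.0, params,
        )
        assert props["off_primed"][0] == pytest.approx(
            params.R10 * (1 + 2 * params.delta) * 4
        )

    def test_negative_counts_rejected(self, params):
        with pytest.raises(InvalidConfigError):
            simulator.propensities(
                np.array([-1.0]), np.zeros(1), np.zeros(1), np.zeros(1),
                np.zeros(1), 0.0, params,
            )


class TestNextEventTime:
    def test_constant_rate_closed_form(self):
        tau = simulator.next_event_time(0.0, np.exp(-1.0), c1=2.0, c2=0.0, decay_tau=12.0)
        assert tau == pytest.approx(0.5)

    def test_decaying_rate_matches_quadrature_oracle(self):
        """Root of logU + integral r(s) ds found by numeric quadrature."""
        for t, u, c1, c2 in [(0.0, 0.3, 0.5, 2.0), (5.0, 0.07, 1.5, 4.0),
                             (20.0, 0.6, 0.0, 3.0), (2.0, 0.12, 0.0, 5.0)]:
            target = -np.log(u)

            def deficit(tau):
                val, _ = integrate.quad(
                    lambda s: c1 + c2 * np.exp(-s / 12.0), t, t + tau
                )
                return val - target

            if deficit(500.0) < 0:
                continue  # unreachable target; covered elsewhere
            oracle = optimize.brentq(deficit, 1e-12, 500.0, xtol=1e-12)
            ours = simulator.next_event_time(t, u, c1, c2, 12.0)
            assert ours == pytest.approx(oracle, abs=1e-6)

    def test_pure_decay_can_never_fire(self):
        # remaining integral of c2 e^(-s/12) from t is bounded; tiny u exceeds it
        tau = simulator.next_event_time(30.0, 1e-12, c1=0.0, c2=0.1, decay_tau=12.0)
        assert np.isinf(tau)

    def test_u_near_one_gives_vanishing_wait(self):
        tau = simulator.next_event_time(0.0, 1 - 1e-12, c1=1.0, c2=1.0, decay_tau=12.0)
        assert tau < 1e-9

    def test_constant_rate_waits_are_exponential(self):
        rng = np.random.default_rng(77)
        rate = 2.0
        taus = np.array(
            [simulator.next_event_time(0.0, u, rate, 0.0, 12.0)
             for u in rng.random(10_000)]
        )
        p = stats.kstest(taus, "expon", args=(0, 1 / rate)).pvalue
        assert p > 0.01


class TestSimulate:
    def test_no_possible_events_gives_empty_log(self):
        p = SimParams(T1=np.inf, beta_L_cell=0.0, beta_H_cell=1.0, mu=0.0)
        traj = simulator.simulate(p, np.zeros((3, 3), bool), seed=1)
        assert traj.event_times.size == 0
        assert np.all(traj.mrna == 0)

    def test_gene_copy_conservation_on_grid(self):
        cfg = synthetic.SynthConfig(seed=3, n_cells=20, field_side=40.0)
        c, d = synthetic.generate_tissue(cfg)
        traj = simulator.simulate(SimParams(), sample_network(c, d), seed=3)
        total = traj.n_on + traj.n_off + traj.n_primed
        assert np.all(total == 4)
        assert np.all(traj.mrna >= 0)

    def test_event_times_strictly_increasing(self):
        cfg = synthetic.SynthConfig(seed=5, n_cells=10, field_side=30.0)
        c, d = synthetic.generate_tissue(cfg)
        traj = simulator.simulate(SimParams(), sample_network(c, d), seed=5)
        assert np.all(np.diff(traj.event_times) > 0)

    def test_stationary_mean_matches_birth_death_closed_form(self):
        """Coupling and decay off: long-run mean mRNA from renewal theory.

        p_on = T0/(T0+T1+T2); mean = copies*(bH*p_on + bL*(1-p_on))/mu.
        """
        p = SimParams(delta=0.0, delta_b=0.0, decay_adjustment=False, horizon=300.0)
        traj = simulator.simulate(p, np.zeros((10, 10), bool), seed=11)
        p_on = p.T0 / (p.T0 + p.T1 + p.T2)
        expected = 4 * (p.beta_H0 * p_on + p.beta_L * (1 - p_on)) / p.mu
        burn = traj.grid_times > 100.0  # past relaxation
        per_cell = traj.mrna[burn].mean(axis=0)
        se = per_cell.std(ddof=1) / np.sqrt(per_cell.size)
        assert abs(per_cell.mean() - expected) < 3 * se

    def test_uncoupled_cells_are_uncorrelated(self):
        """Coupling off, shared trend removed: cross-cell Pearson centres on 0.

        The decay adjustment imposes a common bell-shaped mean on every cell,
        which correlates even independent cells; with it off and the initial
        relaxation discarded, independence shows as near-zero mean r.
        """
        p = SimParams(delta=0.0, delta_b=0.0, decay_adjustment=False)
        cfg = synthetic.SynthConfig(seed=13, n_cells=30)
        c, d = synthetic.generate_tissue(cfg)
        traj = simulator.simulate(p, sample_network(c, d), seed=13)
        burn = traj.grid_times > 24.0
        corr = np.corrcoef(traj.mrna[burn].T)
        vals = corr[np.triu_indices(30, 1)]
        vals = vals[np.isfinite(vals)]
        assert abs(vals.mean()) < 0.05

    def test_decay_adjustment_produces_bell_shaped_ensemble_mean(self):
        cfg = synthetic.SynthConfig(seed=17)
        c, d = synthetic.generate_tissue(cfg)
        traj = simulator.simulate(SimParams(), sample_network(c, d), seed=17)
        mean = traj.mrna.mean(axis=1)
        peak = int(np.argmax(mean))
        assert mean[0] == 0.0
        assert 0 < peak < mean.size - 1
        assert mean[-1] < 0.7 * mean[peak]

    def test_alpha_norm_value(self, params):
        assert params.alpha_norm == pytest.approx(4.0 / (1.0 - np.exp(-4.0)), rel=1e-12)


class TestTranscriptionProfile:
    @pytest.mark.parametrize(
        "state, expected_cell_rate",
        [((0, 4, 0), 0.275), ((4, 0, 0), 4.25), ((1, 2, 1), 4.25 / 4 + 3 * 0.275 / 4)],
    )
    def test_state_substitution(self, params, state, expected_cell_rate):
        traj = simulator.SimTrajectory(
            event_times=np.empty(0), event_cells=np.empty(0, int),
            event_types=np.empty(0, int), grid_times=np.zeros(1),
            mrna=np.zeros((1, 1), int),
            n_on=np.full((1, 1), state[0]),
            n_off=np.full((1, 1), state[1]),
            n_primed=np.full((1, 1), state[2]),
            params=params,
        )
        beta = simulator.transcription_profile(traj)
        assert beta[0, 0] == pytest.approx(expected_cell_rate)


class TestSlopeExperiment:
    def test_returns_tidy_frame_with_all_levels_and_ranges(self):
        cfg = synthetic.SynthConfig(seed=2, n_cells=30, field_side=50.0,
                                    duration_hours=24.0)
        df = simulator.slope_experiment(
            SimParams(delta=0.5, delta_b=0.05, horizon=24.0),
            n_reps=2, seed=9, config=cfg,
        )
        assert len(df) == 8
        assert set(df.level) == {"mrna", "beta"}
        assert set(df.range) == {"all", "short"}
        assert np.isfinite(df.slope).all()

    def test_transcription_coupling_steepens_mrna_slopes_on_matched_seeds(self):
        """delta_b = delta/10 shifts mRNA-level slopes down vs delta_b = 0."""
        cfg = synthetic.SynthConfig(seed=2, n_cells=60, field_side=70.0)
        kw = dict(n_reps=6, seed=31, config=cfg)
        with_b = simulator.slope_experiment(SimParams(delta=0.5, delta_b=0.05), **kw)
        without = simulator.slope_experiment(SimParams(delta=0.5, delta_b=0.0), **kw)
        a = with_b[(with_b.level == "mrna") & (with_b.range == "all")].slope.to_numpy()
        b = without[(without.level == "mrna") & (without.range == "all")].slope.to_numpy()
        assert np.median(a) < np.median(b)
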