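"""End-to-end conditioning runs: trajectories, narratives, persistence."""

import math

import numpy as np
import pytest

from condlearn.experiments import (
    RunConfig,
    rescorla_wagner,
    run_acquisition,
    run_extinction,
    run_repeated_thorndike,
    run_thorndike,
    run_thorndike_phase2,
    threshold_crossing,
)
from condlearn.memory import LongTermStore
from condlearn.selection import PolicyConfig

W1 = "w_wm0_salivate"  # bell -> salivation weight
W2 = "w_wm1_salivate"  # food -> salivation weight


@pytest.fixture
def cfg():
    return RunConfig()


class TestAcquisition:
    def test_weight_follows_count_ratio_closed_form(self, cfg):
        result = run_acquisition(cfg)
        w1 = result.log.column(W1)
        for t, w in enumerate(w1, start=1):
            assert w == pytest.approx(math.log(1 + t), abs=1e-9)

    def test_both_weights_strictly_increase_with_shrinking_increments(self, cfg):
        result = run_acquisition(cfg)
        for col in (W1, W2):
            w = [0.0] + result.log.column(col)
            inc = [b - a for a, b in zip(w, w[1:])]
            assert all(d > 0 for d in inc)
            assert all(b < a for a, b in zip(inc, inc[1:]))

    def test_smaller_bias_fires_earlier(self, cfg):
        result = run_acquisition(cfg)
        u = result.log.column("u_cs")
        crossings = [threshold_crossing(u, b) for b in cfg.b_grid_acquisition]
        assert all(a <= b for a, b in zip(crossings, crossings[1:]))
        assert crossings[0] < math.inf  # b = 2.5 is reached within 50 trials

    def test_every_logged_weight_matches_its_counts(self, cfg):
        """Log-consistency audit: w == ln(nr/nbar) at the run's end."""
        result = run_acquisition(cfg)
        for edge in result.net.all_edges().values():
            assert abs(edge.w - math.log(edge.nr / edge.nbar)) < 1e-9


class TestExtinction:
    def test_requires_prior_learning(self, cfg):
        with pytest.raises(ValueError, match="prior learning"):
            run_extinction(cfg)

    def test_weight_follows_count_ratio_closed_form(self):
        cfg = RunConfig(extinction_init=(51, 1))
        result = run_extinction(cfg)
        w1 = result.log.column(W1)
        for t, w in enumerate(w1, start=1):
            assert w == pytest.approx(math.log(51 / (1 + t)), abs=1e-9)

    def test_weights_strictly_decrease(self):
        result = run_extinction(RunConfig(extinction_init=(51, 1)))
        w1 = [math.log(51)] + result.log.column(W1)
        assert all(b < a for a, b in zip(w1, w1[1:]))

    def test_bigger_bias_extinguishes_earlier(self):
        cfg = RunConfig(extinction_init=(51, 1))
        result = run_extinction(cfg)
        u = result.log.column("u_cs")
        crossings = [threshold_crossing(u, b, falling=True) for b in cfg.b_grid_extinction]
        assert all(a >= b for a, b in zip(crossings, crossings[1:]))

    def test_continues_from_acquisition_store(self, cfg):
        acq = run_acquisition(cfg)
        store = LongTermStore.from_state(acq.net, acq.state.chain_tallies)
        ext = run_extinction(cfg, store=store)
        assert ext.log.rows[0][W1] == pytest.approx(math.log(51 / 2), abs=1e-9)


class TestThorndike:
    def test_phase1_weights_only_decrease_and_choices_alternate(self, cfg):
        result = run_thorndike(cfg)
        phase1 = [r for r in result.log.rows if r["phase"] == "single-action"]
        assert len(phase1) == 30
        assert [r["sequence"] for r in phase1[:6]] == [
            "north", "east", "north", "east", "north", "east",
        ]
        assert all(not r["rewarded"] for r in phase1)
        for col in ("w_wm0_north", "w_wm0_east"):
            w = [0.0] + [r[col] for r in phase1]
            assert all(b <= a for a, b in zip(w, w[1:]))
        assert phase1[-1]["event"] == "grow:add-layer"

    def test_phase2_matches_the_trial_by_trial_narrative(self, cfg):
        """Trial 1 both-north, trial 2 wrong, right chain from trial 3 on."""
        result = run_thorndike(cfg)
        seqs = [r["sequence"] for r in result.log.rows if r["phase"] == "sequence"]
        assert seqs[0] == "north|north"
        assert seqs[1] != "north|east"
        assert all(s == "north|east" for s in seqs[2:])

    def test_phase2_entropy_stop_fires_before_budget(self, cfg):
        result = run_thorndike(cfg)
        assert result.log.meta["phase2_trials"] == 29
        last = [r for r in result.log.rows if r["phase"] == "sequence"][-1]
        assert last["event"] == "stop:entropy"
        assert last["se"] < 0.3

    def test_only_the_rewarded_chain_strengthens(self, cfg):
        result = run_thorndike(cfg)
        net = result.net
        assert net.input_weights[(0, 0)].w > 0  # wm -> north
        assert net.interlayer_weights[(0, 0, 1)].w > 0  # north -> east
        # east->north was tried once and failed; the never-tried edges kept
        # their naive statistics
        assert net.interlayer_weights[(0, 1, 0)].w < 0
        e = net.interlayer_weights[(0, 1, 1)]
        assert (e.nr, e.nbar, e.w) == (1, 1, 0.0)

    def test_weight_log_consistency_audit(self, cfg):
        result = run_thorndike(cfg)
        for edge in result.net.all_edges().values():
            assert abs(edge.w - math.log(edge.nr / edge.nbar)) < 1e-9

    def test_phase2_alone_runs_from_naive_two_layer_network(self, cfg):
        result = run_thorndike_phase2(cfg, stop_on_entropy=False)
        assert len(result.log) == 100
        ses = result.log.column("se")
        assert min(ses) <= 0.3
        assert ses[-1] == pytest.approx(
            -(0.02 * math.log(0.01) + 0.98 * math.log(0.98)), abs=1e-9
        )

    def test_random_ties_still_converge(self, cfg):
        """Entropy stop within 100 trials for nearly all seeds."""
        ok = 0
        for seed in range(50):
            cfg_s = RunConfig(policy=PolicyConfig(tie_break="random", seed=seed))
            result = run_thorndike_phase2(cfg_s, rng=np.random.default_rng(seed))
            last = result.log.rows[-1]
            ok += last["event"] == "stop:entropy"
        assert ok >= 48  # >= 95% of 50 seeds


class TestLawOfExercise:
    def test_practice_shortens_runs_deterministically(self, cfg, tmp_path):
        trials, _ = run_repeated_thorndike(cfg, 10, ltm_path=str(tmp_path / "ltm.json"))
        assert len(trials) == 10
        assert all(b <= a for a, b in zip(trials, trials[1:]))
        assert trials[1] < trials[0]  # experience genuinely speeds things up

    def test_fresh_store_each_run_gives_constant_times(self, cfg):
        times = []
        for _ in range(3):
            result = run_thorndike(cfg)
            times.append(result.log.meta["phase2_trials"])
        assert times == [times[0]] * 3

    def test_monotone_under_random_ties_across_seeds(self):
        ok = 0
        for seed in range(20):
            cfg = RunConfig(policy=PolicyConfig(tie_break="random", seed=seed))
            trials, _ = run_repeated_thorndike(cfg, 10, rng=np.random.default_rng(seed))
            ok += all(b <= a for a, b in zip(trials, trials[1:]))
        assert ok >= 18  # >= 90% of 20 seeds


class TestRescorlaWagnerBaseline:
    def test_one_step_from_zero(self):
        v = rescorla_wagner(1, alpha=0.1, lam=1.0, v0=0.0)
        assert v[-1] == pytest.approx(0.1)

    def test_geometric_decay_closed_form(self):
        v = rescorla_wagner(50, alpha=0.1, lam=0.0, v0=1.0)
        assert np.allclose(v, 0.9 ** np.arange(51))

    def test_converges_to_asymptote(self):
        v = rescorla_wagner(500, alpha=0.1, lam=1.0, v0=0.0)
        assert v[-1] == pytest.approx(1.0, abs=1e-9)

    def test_learning_rate_validated(self):
        with pytest.raises(ValueError):
            rescorla_wagner(10, alpha=0.0)


class TestUpdateModeSensitivity:
    @pytest.mark.parametrize("mode", ["raw", "asymptotic"])
    def test_alternate_modes_still_learn_the_right_chain(self, mode):
        cfg = RunConfig(update_mode=mode, mu=0.1)
        result = run_thorndike(cfg)
        seqs = [r["sequence"] for r in result.log.rows if r["phase"] == "sequence"]
        assert seqs[-1] == "north|east"
        assert result.net.interlayer_weights[(0, 0, 1)].w > 0
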