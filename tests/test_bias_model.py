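import math

import numpy as np
import pytest

from foragescan import bias_model as bm
from foragescan import synthetic_data as sd
from foragescan.org_metrics import mean_itd


def _ctx(coords, classes, class_a="A", **kw):
    return bm.ChoiceContext(np.asarray(coords, float), np.asarray(classes),
                            class_a, **kw)


# ---------------------------------------------------------------------------
# selection weights


def test_neutral_params_give_uniform_weights(rng):
    coords = rng.uniform(0, 1000, (6, 2))
    classes = np.array(list("AABBAB"))
    ctx = _ctx(coords, classes, prev_xy=np.array([0.0, 0.0]),
               prev_class="A", prev_heading=0.3)
    w = bm.selection_weights(ctx, bm.BiasParams())
    assert w == pytest.approx(np.full(6, 1 / 6))


def test_weights_sum_to_one_and_relabel_invariant(rng):
    coords = rng.uniform(0, 1000, (8, 2))
    classes = np.array(list("ABABABAB"))
    params = bm.BiasParams(p_a=0.7, p_s=0.3, rho_d=1.5, rho_theta=-0.8)
    ctx = _ctx(coords, classes, prev_xy=np.array([500.0, 500.0]),
               prev_class="B", prev_heading=-1.0)
    w = bm.selection_weights(ctx, params)
    assert w.sum() == pytest.approx(1.0)
    perm = rng.permutation(8)
    ctx2 = _ctx(coords[perm], classes[perm], prev_xy=np.array([500.0, 500.0]),
                prev_class="B", prev_heading=-1.0)
    w2 = bm.selection_weights(ctx2, params)
    assert w2 == pytest.approx(w[perm])


def test_strong_proximity_concentrates_on_nearest():
    coords = np.array([[10.0, 0.0], [500.0, 0.0], [900.0, 0.0]])
    ctx = _ctx(coords, ["A"] * 3, prev_xy=np.array([0.0, 0.0]),
               prev_class="A")
    w = bm.selection_weights(ctx, bm.BiasParams(rho_d=500.0))
    assert w[0] > 0.999


def test_class_and_stickiness_hand_normalization():
    """Two targets A/B after an A pick, spatial terms off:
    P(A) = .7*.6 / (.7*.6 + .3*.4)."""
    ctx = _ctx([[0, 0], [1, 1]], ["A", "B"], prev_xy=np.array([0.0, 0.0]),
               prev_class="A")
    w = bm.selection_weights(ctx, bm.BiasParams(p_a=0.7, p_s=0.6))
    assert w[0] == pytest.approx(0.42 / (0.42 + 0.12))


def test_first_pick_uses_class_weight_only():
    coords = np.array([[0.0, 0.0], [1000.0, 1000.0]])
    ctx = _ctx(coords, ["A", "B"])  # no history
    for rho in (0.0, 50.0):
        w = bm.selection_weights(ctx, bm.BiasParams(p_a=0.6, rho_d=rho,
                                                    rho_theta=3.0))
        assert w[0] == pytest.approx(0.6)


def test_direction_perseverance_prefers_straight_ahead():
    # previous motion heading east; candidate ahead vs behind
    coords = np.array([[100.0, 0.0], [-100.0, 0.0]])
    ctx = _ctx(coords, ["A", "A"], prev_xy=np.array([0.0, 0.0]),
               prev_class="A", prev_heading=0.0)
    w = bm.selection_weights(ctx, bm.BiasParams(rho_theta=2.0))
    assert w[0] > 0.9
    # negative rho_theta of same magnitude routes the bias laterally
    wl = bm.selection_weights(ctx, bm.BiasParams(rho_theta=-2.0))
    assert wl[0] == pytest.approx(0.5)  # ahead/behind symmetric under lateral mu


def test_bag_reduction_ignores_geometry(rng):
    """With spatial terms at zero the weights depend only on classes."""
    classes = np.array(list("ABBA"))
    params = bm.BiasParams(p_a=0.65, p_s=0.25)
    w1 = bm.selection_weights(_ctx(rng.uniform(0, 100, (4, 2)), classes,
                                   prev_xy=np.array([5.0, 5.0]),
                                   prev_class="B", prev_heading=1.0), params)
    w2 = bm.selection_weights(_ctx(rng.uniform(0, 100, (4, 2)), classes,
                                   prev_xy=np.array([90.0, 1.0]),
                                   prev_class="B", prev_heading=-2.0), params)
    assert w1 == pytest.approx(w2)


def test_empty_remaining_set_rejected():
    with pytest.raises(ValueError):
        _ctx(np.empty((0, 2)), [])


# ---------------------------------------------------------------------------
# simulation


def test_simulation_seeded_determinism(rng):
    disp = sd.gen_display(60, "feature", rng, n_target_classes=2)
    c1, k1 = bm.simulate_sequence(disp, bm.BiasParams(), 10, 77)
    c2, k2 = bm.simulate_sequence(disp, bm.BiasParams(), 10, 77)
    assert np.array_equal(c1, c2) and np.array_equal(k1, k2)


def test_too_many_picks_rejected(rng):
    disp = sd.gen_display(60, "feature", rng)
    with pytest.raises(ValueError):
        bm.simulate_sequence(disp, bm.BiasParams(), disp.n_targets + 1, rng)


def test_proximity_bias_reduces_mean_itd(rng):
    """rho_d > 0 shortens hops relative to the neutral model on the same
    display (Monte-Carlo)."""
    disp = sd.gen_display(100, "feature", rng)
    neutral, prox = [], []
    for i in range(300):
        c, _ = bm.simulate_sequence(disp, bm.BiasParams(), 10, 1000 + i)
        neutral.append(mean_itd(c))
        c, _ = bm.simulate_sequence(disp, bm.BiasParams(rho_d=4.0), 10,
                                    2000 + i)
        prox.append(mean_itd(c))
    assert np.mean(prox) < np.mean(neutral)


def test_stickiness_lengthens_runs(rng):
    """p_s = 0.95 produces longer same-class runs than p_s = 0.5."""
    disp = sd.gen_display(100, "feature", rng, n_target_classes=2)

    def mean_run_length(classes):
        runs, cur = [], 1
        for a, b in zip(classes, classes[1:]):
            if a == b:
                cur += 1
            else:
                runs.append(cur)
                cur = 1
        runs.append(cur)
        return np.mean(runs)

    sticky, neutral = [], []
    for i in range(200):
        _, k = bm.simulate_sequence(disp, bm.BiasParams(p_s=0.95), 15,
                                    3000 + i)
        sticky.append(mean_run_length(k))
        _, k = bm.simulate_sequence(disp, bm.BiasParams(p_s=0.5), 15,
                                    4000 + i)
        neutral.append(mean_run_length(k))
    assert np.mean(sticky) > np.mean(neutral) + 0.3


# ---------------------------------------------------------------------------
# likelihood


def _sim_trial_data(rng, params, n_trials=20, n_picks=10, **disp_kw):
    trials, sels = [], []
    for _ in range(n_trials):
        disp = sd.gen_display(100, "feature", rng, n_target_classes=2,
                              **disp_kw)
        c, k = bm.simulate_sequence(disp, params, n_picks, rng)
        s, ch = bm.steps_from_picks(c, k, disp)
        trials.append(s)
        sels.append(ch)
    return bm.compile_choice_data(trials, sels)


def test_single_remaining_target_contributes_zero(rng):
    disp = sd.gen_display(60, "feature", rng, target_fraction=0.2)
    n = disp.n_targets
    c, k = bm.simulate_sequence(disp, bm.BiasParams(), n, rng)
    steps, ch = bm.steps_from_picks(c, k, disp)
    data_last = bm.compile_choice_data([steps[-1:]], [ch[-1:]])
    assert bm.log_likelihood(data_last, bm.BiasParams(0.5, 0.5, 1.0, 1.0)) \
        == pytest.approx(0.0)


def test_neutral_likelihood_is_log_uniform(rng):
    disp = sd.gen_display(60, "feature", rng)
    n_t = disp.n_targets
    c, k = bm.simulate_sequence(disp, bm.BiasParams(), 5, rng)
    steps, ch = bm.steps_from_picks(c, k, disp)
    ll = bm.log_likelihood(bm.compile_choice_data([steps], [ch]),
                           bm.BiasParams())
    expected = -sum(math.log(n_t - i) for i in range(5))
    assert ll == pytest.approx(expected)


def test_generating_params_beat_perturbed_on_average(rng):
    gen = bm.BiasParams(p_a=0.7, p_s=0.7, rho_d=2.0, rho_theta=1.0)
    data = _sim_trial_data(rng, gen, n_trials=100, n_picks=10)
    ll_gen = bm.log_likelihood(data, gen)
    ll_far = bm.log_likelihood(data, bm.BiasParams(p_a=0.2, p_s=0.2,
                                                   rho_d=8.0,
                                                   rho_theta=-3.0))
    assert ll_gen > ll_far


def test_likelihood_rigid_motion_invariant(rng):
    """Rotating + translating display and picks jointly leaves the
    likelihood unchanged (relative distances and angles only)."""
    disp = sd.gen_display(60, "feature", rng, n_target_classes=2)
    c, k = bm.simulate_sequence(disp, bm.BiasParams(rho_d=2, rho_theta=1),
                                8, rng)
    th = 1.1
    R = np.array([[math.cos(th), -math.sin(th)],
                  [math.sin(th), math.cos(th)]])
    shift = np.array([321.0, -77.0])
    params = bm.BiasParams(p_a=0.6, p_s=0.7, rho_d=1.5, rho_theta=0.8)
    s1, ch1 = bm.steps_from_picks(c, k, disp)
    disp2 = (disp.xy[disp.is_target] @ R.T + shift,
             disp.classes[disp.is_target])
    s2, ch2 = bm.steps_from_picks(c @ R.T + shift, k, disp2)
    ll1 = bm.log_likelihood(bm.compile_choice_data([s1], [ch1]), params)
    ll2 = bm.log_likelihood(bm.compile_choice_data([s2], [ch2]), params)
    assert ll2 == pytest.approx(ll1, abs=1e-9)


def test_unmatched_pick_raises(rng):
    disp = sd.gen_display(60, "feature", rng)
    with pytest.raises(ValueError, match="remaining"):
        bm.steps_from_picks(np.array([[-500.0, -500.0]]), np.array(["green"]),
                            disp)


# ---------------------------------------------------------------------------
# fitting


def test_bag_fit_matches_frequency_estimator(rng):
    """Single-pick balanced bags: the ML p_a equals the closed-form A-pick
    frequency."""
    coords = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0],
                       [100.0, 100.0]])
    classes = np.array(["A", "A", "B", "B"])
    gen = bm.BiasParams(p_a=0.7)
    trials, sels = [], []
    n_a = 0
    for i in range(400):
        c, k = bm.simulate_sequence((coords, classes), gen, 1, 500 + i)
        s, ch = bm.steps_from_picks(c, k, (coords, classes))
        trials.append(s)
        sels.append(ch)
        n_a += int(k[0] == "A")
    data = bm.compile_choice_data(trials, sels)
    fit = bm.fit_bias(data, fix={"p_s": 0.5, "rho_d": 0.0, "rho_theta": 0.0})
    assert fit.params.p_a == pytest.approx(n_a / 400, abs=1e-4)


def test_rho_d_recovery_monotone(rng):
    """Mean recovered rho_d increases with the true value."""
    means = []
    for true in (0.0, 2.0, 4.0):
        ests = []
        for rep in range(5):
            data = _sim_trial_data(
                np.random.default_rng(9000 + rep), bm.BiasParams(rho_d=true),
                n_trials=40, n_picks=12)
            fit = bm.fit_bias(data, fix={"p_a": 0.5, "p_s": 0.5,
                                         "rho_theta": 0.0})
            ests.append(fit.params.rho_d)
        means.append(np.mean(ests))
    assert means[0] < means[1] < means[2]


def test_single_class_data_flags_unidentifiable(rng):
    disp = sd.gen_display(60, "feature", rng)  # one target class
    c, k = bm.simulate_sequence(disp, bm.BiasParams(rho_d=1.0), 8, rng)
    s, ch = bm.steps_from_picks(c, k, disp)
    fit = bm.fit_bias(bm.compile_choice_data([s], [ch]))
    assert "class_unidentifiable" in fit.flags
    assert fit.params.p_a == 0.5 and fit.params.p_s == 0.5


def test_fit_reports_se_and_convergence(rng):
    data = _sim_trial_data(rng, bm.BiasParams(p_a=0.6, rho_d=1.0),
                           n_trials=60, n_picks=10)
    fit = bm.fit_bias(data)
    assert fit.converged
    for name in ("p_a", "p_s", "rho_d", "rho_theta"):
        assert np.isfinite(fit.se[name]) and fit.se[name] > 0
    assert fit.loglik <= 0.0
    assert fit.params.abs_rho_theta == abs(fit.params.rho_theta)


def test_snapshot_steps_match_static_reconstruction(rng):
    """On a static display the snapshot route and the pick-matching route
    produce identical likelihoods."""
    disp = sd.gen_display(80, "feature", rng, n_target_classes=2)
    pol = sd.AgentPolicy(kind="bias_model",
                         bias=bm.BiasParams(rho_d=2.0), n_picks=10,
                         motion=False)
    tr, snaps = sd.run_agent(disp, pol, rng, return_snapshots=True)
    s1, ch1 = bm.steps_from_snapshots(snaps)
    coords = np.array([[p.x, p.y] for p in tr.picks])
    classes = np.array([p.item_class for p in tr.picks])
    s2, ch2 = bm.steps_from_picks(coords, classes, disp)
    params = bm.BiasParams(rho_d=1.0, rho_theta=0.5)
    ll1 = bm.log_likelihood(bm.compile_choice_data([s1], [ch1]), params)
    ll2 = bm.log_likelihood(bm.compile_choice_data([s2], [ch2]), params)
    assert ll1 == pytest.approx(ll2, abs=1e-9)
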