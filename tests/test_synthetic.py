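"""Agent simulator: trajectories, generative mechanics, recovery harness."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

import lockbox as lb
from lockbox.synthetic import Adaptation


def _flat_params(**kw):
    return lb.constant_agent("sim", n_episodes=kw.pop("n_episodes", 5), **kw)


class TestTargetingTrajectory:
    def test_full_jump_reaches_asymptote_immediately(self):
        traj = Adaptation(initial=0.2, asymptote=0.9, rate=0.3, jump=1.0)
        params = replace(
            lb.birdlike(), targeting={s: traj for s in lb.LOCKS}
        )
        assert lb.targeting_trajectory(params, "bar", 1) == 0.2
        for e in range(2, 8):
            assert lb.targeting_trajectory(params, "bar", e) == pytest.approx(0.9)

    def test_no_learning_limit_is_constant(self):
        traj = Adaptation(initial=0.3, asymptote=0.9, rate=0.0, jump=0.0)
        params = replace(lb.birdlike(), targeting={s: traj for s in lb.LOCKS})
        for e in range(1, 10):
            assert lb.targeting_trajectory(params, "wheel", e) == pytest.approx(0.3)

    def test_half_jump_then_flat(self):
        # p0=0.2, pinf=0.9, jump=0.5, rate=0 -> p2 = 0.55 and stays there
        traj = Adaptation(initial=0.2, asymptote=0.9, rate=0.0, jump=0.5)
        params = replace(lb.birdlike(), targeting={s: traj for s in lb.LOCKS})
        assert lb.targeting_trajectory(params, "door", 1) == 0.2
        for e in range(2, 6):
            assert lb.targeting_trajectory(params, "door", e) == pytest.approx(0.55)

    def test_regressed_episode_returns_naive_wheel_value(self):
        params = lb.birdlike()
        naive = params.targeting["wheel"].initial
        assert lb.targeting_trajectory(params, "wheel", 8, regressed=True) == naive
        assert lb.targeting_trajectory(params, "bar", 8, regressed=True) == \
            lb.targeting_trajectory(params, "bar", 8)


class TestSimulateSubject:
    def test_perfect_agent_three_contacts_per_episode(self):
        params = _flat_params(p=1.0, q=1.0, seed=5)
        sessions = lb.simulate_subject(params)
        recs = lb.decomposition_table(lb.segment_episodes(sessions))
        assert len(recs) == 5
        assert all(r.n_a == 3 and r.M == 1.0 and r.E == 3 for r in recs)

    def test_seed_determinism_byte_identical(self, tmp_path):
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        lb.write_event_log(lb.simulate_subject(lb.birdlike(seed=42, n_episodes=3)), a)
        lb.write_event_log(lb.simulate_subject(lb.birdlike(seed=42, n_episodes=3)), b)
        assert a.read_bytes() == b.read_bytes()

    def test_different_seeds_differ(self):
        s1 = lb.simulate_subject(lb.birdlike(seed=1, n_episodes=2))
        s2 = lb.simulate_subject(lb.birdlike(seed=2, n_episodes=2))
        assert s1 != s2

    def test_output_passes_pipeline_with_exact_episode_count(self):
        for seed in range(5):
            params = lb.birdlike(seed=seed, n_episodes=4)
            eps = lb.segment_episodes(lb.simulate_subject(params))
            assert len(eps) == 4
            assert all(ep.complete for ep in eps)

    def test_sessions_capped_and_solving_session_ends_at_door(self):
        params = lb.birdlike(seed=9, n_episodes=3)
        sessions = lb.simulate_subject(params)
        for sess in sessions:
            solved = any(
                ev.component == "door" and ev.opens_lock for ev in sess.events
            )
            if solved:
                assert sess.duration_s == sess.events[-1].time_s
            else:
                assert sess.duration_s == params.session_cap_s

    def test_stalling_params_raise(self):
        traj = {s: Adaptation(1e-6, 1e-6, 0.0, 0.0) for s in lb.LOCKS}
        params = replace(lb.birdlike(n_episodes=1), targeting=traj)
        with pytest.raises(lb.StallError):
            lb.simulate_subject(params)

    def test_old_strategy_bias_directs_early_mistargets_to_bar_and_door(self):
        # With full bias, every mistargeted contact before the first wheel
        # contact in episode 1 must land on bar or door (the old-box
        # strategy); after the first wheel contact the bias switches off.
        traj = {s: Adaptation(0.5, 0.5, 0.0, 0.0) for s in lb.LOCKS}
        params = replace(
            lb.birdlike(n_episodes=1, seed=3),
            targeting=traj,
            old_strategy_bias=1.0,
            regression_prob=0.0,
        )
        sessions = lb.simulate_subject(params)
        events = [ev for s in sessions for ev in s.events]
        seen_wheel = False
        for ev in events:
            if not seen_wheel and ev.component not in ("wheel",):
                assert ev.component in ("bar", "door")
            if ev.component == "wheel":
                seen_wheel = True

    def test_pooled_mistargeting_concentrates_at_reciprocal_p(self):
        # p=0.5 everywhere, q=1: expected M = 2 with binomial concentration
        params = _flat_params(p=0.5, q=1.0, n_episodes=400, seed=8)
        recs = lb.decomposition_table(lb.segment_episodes(lb.simulate_subject(params)))
        tot_a = sum(r.n_a for r in recs)
        tot_c = sum(r.n_c for r in recs)
        assert 1.9 <= tot_a / tot_c <= 2.1


class TestRecoveryReport:
    def test_perfect_agent_all_rows_pass(self):
        params = _flat_params(p=1.0, q=1.0, n_episodes=30, seed=2)
        res = lb.run_simulation(params)
        recs = lb.decomposition_table(lb.segment_episodes(res.sessions))
        report = lb.recovery_report(params, recs, truth=res.truth)
        assert report["passed"].all()
        m_row = report.set_index("quantity").loc["pooled_M"]
        assert m_row["estimate"] == 1.0 and m_row["truth"] == 1.0

    def test_effort_recovery_geometric_mean(self):
        # q=0.5 per lock, p=1: expected effort 3 * (1/0.5) = 6
        params = _flat_params(p=1.0, q=0.5, n_episodes=400, seed=4)
        res = lb.run_simulation(params)
        recs = lb.decomposition_table(lb.segment_episodes(res.sessions))
        report = lb.recovery_report(params, recs, truth=res.truth).set_index("quantity")
        row = report.loc["mean_E"]
        assert row["truth"] == pytest.approx(6.0)
        assert abs(row["estimate"] - 6.0) <= row["tolerance"]

    def test_engagement_recovery_exponential_mean(self):
        # lambda = 0.1/s constant: late-episode mean Delta ~ 10 s
        params = _flat_params(p=1.0, q=1.0, rate=0.1, n_episodes=400, seed=6)
        res = lb.run_simulation(params)
        recs = lb.decomposition_table(lb.segment_episodes(res.sessions))
        report = lb.recovery_report(params, recs, truth=res.truth).set_index("quantity")
        row = report.loc["delta_late_s"]
        assert row["truth"] == pytest.approx(10.0)
        assert abs(row["estimate"] - 10.0) <= row["tolerance"]

    def test_mismatched_subject_rejected(self):
        params = _flat_params(p=1.0, q=1.0, seed=2)
        recs = lb.decomposition_table(
            lb.segment_episodes(lb.simulate_subject(params))
        )
        other = replace(params, subject_id="someone_else")
        with pytest.raises(lb.ValidationError):
            lb.recovery_report(other, recs)


class TestConstraintShapes:
    """Distributional signatures of the behavioural constraints at the
    default preset (small-sample smoke versions; the full suite runs in the
    acceptance tests)."""

    def test_fast_and_slow_adaptation_and_nonmonotony(self):
        fast = slope_neg = nonmono = 0
        n = 20
        for seed in range(n):
            recs = lb.decomposition_table(
                lb.segment_episodes(lb.simulate_subject(lb.birdlike(seed=seed)))
            )
            T = [r.T_s for r in recs]
            M = [r.M for r in recs]
            fast += T[1] <= 0.5 * T[0]
            slope_neg += lb.fit_log_linear(recs).slope < 0
            nonmono += any(M[i + 1] > M[i] for i in range(1, len(M) - 1))
        assert fast >= n - 2
        assert slope_neg >= n - 2
        assert nonmono >= n / 2  # far above the rho/2 bound


class TestParamsYaml:
    def test_roundtrip(self, tmp_path):
        params = lb.birdlike(seed=13)
        path = tmp_path / "params.yaml"
        lb.save_agent_params(params, path)
        (loaded,) = lb.load_agent_params(path)
        assert loaded == params

    def test_multiple_subjects(self, tmp_path):
        ps = [lb.birdlike("a", seed=1), lb.birdlike("b", seed=2)]
        path = tmp_path / "params.yaml"
        lb.save_agent_params(ps, path)
        assert lb.load_agent_params(path) == ps

    def test_missing_field_names_it(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("subject_id: x\nn_episodes: 3\n", encoding="utf-8")
        with pytest.raises(lb.ValidationError, match="targeting"):
            lb.load_agent_params(path)
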