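"""Engine orchestration: trial composition, update policies, determinism."""

import math

import numpy as np
import pandas as pd
import pytest

from rwddm.engine import (
    CSUnit,
    ModelParams,
    ModelState,
    assign_credit_mixed_fi,
    combine_temporal_average,
    derive_seed,
    run_experiment,
    run_group,
    run_trial,
    select_compound_timer,
)
from rwddm.protocols import (
    GroupDesign,
    Phase,
    StimulusSpec,
    TrialSpec,
    build_design,
)


def _fi_trial(dur=5.0, label="CS"):
    return TrialSpec(
        (StimulusSpec(label, 0.0, dur),), "reinforced", dur, us_time=dur
    )


def _group(phases, params=None, n_reps=None):
    return GroupDesign(
        "g", tuple(phases), params or dict(m=0.0, sigma=0.3, alpha_t=0.1,
                                           alpha_V=0.1, H=5.0), n_reps or {}
    )


class TestNoiselessClosedForm:
    def test_three_trial_fi_matches_direct_recursion(self):
        """Noiseless engine run vs an independently coded recursion of the
        update rules (including the early-trial accumulation floor)."""
        params = dict(m=0.0, sigma=0.3, alpha_t=0.1, alpha_V=0.1, H=5.0)
        g = _group([Phase("p", ((_fi_trial(5.0), 3),))], params)
        tr = run_group(g, seed=0)

        # oracle: direct per-trial recursion in plain floats
        A, V = 1e-6, 0.0
        t_ms, sigma, alpha_t, alpha_V, H, theta, floor = (
            5000.0, 0.3, 0.1, 0.1, 5.0, 1.0, 0.01,
        )
        expected = []
        for _ in range(3):
            psi = A * t_ms
            x = math.exp(-((psi - theta) ** 2) / (2 * sigma**2))
            psi_eff = max(psi, floor * theta)
            lam = H * (A * 1000.0) / psi_eff
            V = V + alpha_V * (lam - V * x) * x
            A = A + alpha_t * A * (theta - psi_eff) / psi_eff
            expected.append((A, V))
        got = tr.units.sort_values("trial")[["A", "V"]].to_numpy()
        assert np.allclose(got, np.array(expected), rtol=1e-12)

    def test_first_trial_cr_is_zero_everywhere(self):
        g = _group([Phase("p", ((_fi_trial(5.0), 1),))])
        tr = run_group(g, seed=0)
        assert np.all(tr.cr[0] == 0.0)  # V starts at zero

    def test_converged_noiseless_extinction_leaves_slope_fixed(self):
        params = dict(m=0.0, sigma=0.3, alpha_t=0.1, alpha_V=0.1, H=5.0)
        ext = TrialSpec((StimulusSpec("CS", 0.0, 5.0),), "extinction", 5.0)
        g = _group(
            [Phase("acq", ((_fi_trial(5.0), 120),)),
             Phase("ext", ((ext, 30),))],
            params,
        )
        tr = run_group(g, seed=0, record="none")
        u = tr.units
        a_end_acq = u[u.phase == "acq"]["A"].iloc[-1]
        assert a_end_acq == pytest.approx(1 / 5000, rel=1e-5)
        # same 5-s marker in extinction: slope stays put, V decays
        assert np.allclose(u[u.phase == "ext"]["A"], a_end_acq, rtol=1e-9)
        v_ext = u[u.phase == "ext"]["V"].to_numpy()
        assert np.all(np.diff(v_ext) < 0) and v_ext[-1] < 0.1 * v_ext[0]


class TestDeterminismAndPhases:
    def test_same_seed_bit_identical(self):
        d = build_design("isi_effect", {"n_trials": 8})
        r1 = run_experiment(d, seed=5)
        r2 = run_experiment(d, seed=5)
        for gname in r1.groups:
            t1, t2 = r1[gname], r2[gname]
            pd.testing.assert_frame_equal(t1.units, t2.units)
            assert set(t1.cr) == set(t2.cr)
            for i in t1.cr:
                assert np.array_equal(t1.cr[i], t2.cr[i])

    def test_zero_trial_phase_is_identity(self):
        base = [Phase("a", ((_fi_trial(), 4),))]
        padded = [
            Phase("a", ((_fi_trial(), 4),)),
            Phase("empty", ((_fi_trial(), 0),)),
        ]
        t1 = run_group(_group(base), seed=2)
        t2 = run_group(_group(padded), seed=2)
        pd.testing.assert_frame_equal(
            t1.units, t2.units.drop(columns=[]), check_like=True
        )

    def test_trial_counts_per_phase_match_design(self):
        d = build_design("acquisition_extinction_reacquisition")
        tr = run_experiment(d, seed=1, record="none")["FI5"]
        counts = tr.trials.groupby("phase")["trial"].count()
        assert counts["acquisition"] == 80
        assert counts["extinction"] == 100
        assert counts["reacquisition"] == 80

    def test_record_rule_peak_only(self):
        d = build_design("temporal_averaging", {"n_trials": 4})
        tr = run_experiment(d, seed=1, record="peak")["FI10-20"]
        recorded = tr.trials.loc[list(tr.cr)]
        assert set(recorded.trial_type) == {"peak"}


class TestPeakTrialsAreProbes:
    def test_no_updates_on_peak_trials(self):
        peak = TrialSpec((StimulusSpec("CS", 0.0, 15.0),), "peak", 15.0)
        g = _group(
            [Phase("acq", ((_fi_trial(5.0), 10),)),
             Phase("probe", ((peak, 5),))]
        )
        tr = run_group(g, seed=0)
        assert not (tr.units.phase == "probe").any()
        probe_trials = tr.trials[tr.trials.phase == "probe"].index
        assert all(i in tr.cr for i in probe_trials)


class TestCompoundRules:
    def test_faster_timer_selection_and_tiebreak(self):
        fast = CSUnit("B", 0, A=2e-4)
        slow = CSUnit("A", 0, A=1e-4)
        assert select_compound_timer([fast, slow]) is fast
        tie = CSUnit("A", 0, A=2e-4)
        assert select_compound_timer([fast, tie]) is tie  # label order

    def test_credit_goes_to_max_activation(self):
        assert assign_credit_mixed_fi([None, None], [0.2, 0.9]) == 1
        assert assign_credit_mixed_fi([None, None], [0.9, 0.2]) == 0

    def test_temporal_average_equal_weighting(self):
        a, v = combine_temporal_average(0.1, 1.0, 0.05, 0.5)
        assert a == pytest.approx(0.075) and v == pytest.approx(0.75)

    def test_temporal_average_v_weighted(self):
        # V_low = 2 V_high -> combined A = (2/3) A_low + (1/3) A_high
        a, _ = combine_temporal_average(0.1, 2.0, 0.05, 1.0, "v_weighted")
        assert a == pytest.approx((2 / 3) * 0.1 + (1 / 3) * 0.05)

    def test_v_weighted_reduces_to_equal_for_equal_v(self):
        a1, v1 = combine_temporal_average(0.1, 0.7, 0.05, 0.7, "v_weighted")
        a2, v2 = combine_temporal_average(0.1, 0.7, 0.05, 0.7, "equal")
        assert a1 == pytest.approx(a2) and v1 == pytest.approx(v2)

    def test_faster_timer_policy_uses_single_cs_curve(self):
        """On a noiseless compound probe the CR must equal the chosen
        (faster) stimulus's own V·x curve, with no summation."""
        params = dict(
            m=0.0, sigma=0.3, alpha_t=0.2, alpha_V=0.1, H=5.0,
            compound_policy="faster_timer",
        )
        peak = TrialSpec(
            (StimulusSpec("A", 0.0, 20.0), StimulusSpec("B", 0.0, 20.0)),
            "peak",
            20.0,
        )
        g = _group(
            [
                Phase("acq", ((_fi_trial(5.0, "A"), 60), (_fi_trial(6.0, "B"), 60))),
                Phase("probe", ((peak, 1),)),
            ],
            params,
        )
        tr = run_group(g, seed=0)
        probe_idx = tr.trials[tr.trials.phase == "probe"].index[0]
        # A (5 s) has the larger slope; simulate its solo curve
        solo = TrialSpec((StimulusSpec("A", 0.0, 20.0),), "peak", 20.0)
        g2 = _group(
            [Phase("acq", ((_fi_trial(5.0, "A"), 60), (_fi_trial(6.0, "B"), 60))),
             Phase("probe", ((solo, 1),))],
            params,
        )
        tr2 = run_group(g2, seed=0)
        assert np.allclose(tr.cr[probe_idx], tr2.cr[probe_idx])


class TestErrors:
    def test_trial_shorter_than_dt_rejected(self):
        state = ModelState(ModelParams())
        bad = TrialSpec((StimulusSpec("A", 0.0, 0.001),), "extinction", 0.001)
        with pytest.raises(ValueError):
            run_trial(bad, state, np.random.default_rng(0))

    def test_unknown_group_selection(self):
        d = build_design("isi_effect", {"n_trials": 1})
        with pytest.raises(KeyError):
            run_experiment(d, 0, groups=["FI7"])

    def test_derived_seeds_below_2_31(self):
        assert all(0 <= derive_seed(2**20, i) < 2**31 for i in range(100))
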