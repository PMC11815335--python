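"""Error weights, movement models, autocorrelation weights and combination."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bayrsf.weights import (
    AutocorrWeights,
    MovementModel,
    autocorr_weights,
    build_error_weights,
    combine_weights,
    fit_movement_model,
)

T0 = pd.Timestamp("2021-06-01", tz="UTC")


def _track(seconds, xy):
    return pd.DataFrame(
        {
            "timestamp": T0 + pd.to_timedelta(seconds, unit="s"),
            "x": np.asarray(xy)[:, 0],
            "y": np.asarray(xy)[:, 1],
        }
    )


class TestErrorWeights:
    def test_inverse_mean_rescaling_hand_example(self):
        t = build_error_weights(
            pd.DataFrame({"n_sats": [4, 4, 9, 9], "error_m": [10, 10, 2, 2]}),
            quantile_cut=1.0,
        )
        assert t.weights == pytest.approx({4: 0.2, 9: 1.0})
        assert t.na_weight == pytest.approx(0.2)

    def test_quantile_truncation_drops_outliers(self):
        # one huge error at 9 sats would otherwise ruin the 9-sat mean
        errs = [10.0] * 10 + [2.0] * 9 + [1000.0]
        sats = [4] * 10 + [9] * 10
        t = build_error_weights(
            pd.DataFrame({"n_sats": sats, "error_m": errs}), quantile_cut=0.95
        )
        assert t.mean_error_m[9] == pytest.approx(2.0)
        assert t.weights == pytest.approx({4: 0.2, 9: 1.0})

    @given(st.lists(st.integers(4, 9), min_size=2, max_size=30, unique=True))
    @settings(max_examples=20, derandomize=True)
    def test_max_weight_exactly_one(self, counts):
        rng = np.random.default_rng(sum(counts))
        records = pd.DataFrame(
            {
                "n_sats": np.repeat(counts, 5),
                "error_m": rng.uniform(1, 100, size=5 * len(counts)),
            }
        )
        t = build_error_weights(records)
        assert max(t.weights.values()) == 1.0
        assert all(w > 0 for w in t.weights.values())
        assert t.na_weight == min(t.weights.values())

    def test_single_count_errors(self):
        with pytest.raises(ValueError):
            build_error_weights(pd.DataFrame({"n_sats": [4, 4], "error_m": [1, 2]}))

    def test_missing_count_lookup_gets_minimum(self):
        t = build_error_weights(
            pd.DataFrame({"n_sats": [4, 4, 9, 9], "error_m": [10, 10, 2, 2]}),
            quantile_cut=1.0,
        )
        np.testing.assert_allclose(t.weight_for([np.nan, 9, 4]), [0.2, 1.0, 0.2])


class TestMovementModel:
    def test_iid_data_selects_iid(self):
        """Independent positions at irregular times: IID wins in >= 90% of
        20 replicates."""
        wins = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            sec = np.sort(rng.uniform(0, 86400 * 10, 200))
            m = fit_movement_model(_track(sec, rng.normal(scale=500, size=(200, 2))))
            wins += m.family == "IID"
        assert wins >= 18

    def test_ou_recovery_within_factor_two(self):
        tau = 6 * 3600.0
        rng = np.random.default_rng(3)
        n = 500
        sec = np.cumsum(rng.exponential(1800.0, n))
        xy = np.zeros((n, 2))
        for i in range(1, n):
            r = np.exp(-(sec[i] - sec[i - 1]) / tau)
            xy[i] = r * xy[i - 1] + rng.normal(scale=np.sqrt(1 - r**2) * 300, size=2)
        m = fit_movement_model(_track(sec, xy))
        assert m.family in ("OU", "OUF")
        assert tau / 2 < m.tau_position < tau * 2

    def test_ou_likelihood_matches_exact_gp_oracle(self):
        """The sequential (Markov) OU likelihood equals a dense multivariate
        normal evaluation with the same profiled mean and variance."""
        from scipy.stats import multivariate_normal

        from bayrsf.weights import _ou_profile_loglik

        rng = np.random.default_rng(5)
        sec = np.sort(rng.uniform(0, 3600 * 24, 12))
        xy = rng.normal(scale=100, size=(12, 2))
        tau = 7200.0
        ll, mu, s2 = _ou_profile_loglik(np.log(tau), sec, xy)
        corr = np.exp(-np.abs(sec[:, None] - sec[None, :]) / tau)
        oracle = sum(
            multivariate_normal(np.full(12, mu[ax]), s2 * corr).logpdf(xy[:, ax])
            for ax in range(2)
        )
        assert ll == pytest.approx(oracle, rel=1e-9)

    def test_few_fixes_forces_iid(self):
        rng = np.random.default_rng(0)
        m = fit_movement_model(_track([0, 60, 120], rng.normal(size=(3, 2))))
        assert m.family == "IID"

    def test_ouf_timescale_ordering(self):
        m = MovementModel("OUF", 3600.0, 600.0, 1.0, (0, 0), 0.0, 0.0, 10)
        rho = m.rho(np.array([0.0, 600.0, 3600.0]))
        assert rho[0] == pytest.approx(1.0)
        assert np.all(np.diff(rho) < 0)


class TestAutocorrWeights:
    def test_iid_gives_unit_weights(self):
        rng = np.random.default_rng(1)
        tr = _track(np.arange(10) * 3600.0, rng.normal(size=(10, 2)))
        m = MovementModel("IID", None, None, 1.0, (0, 0), 0.0, 0.0, 10)
        ac = autocorr_weights(tr, m)
        np.testing.assert_allclose(ac.weights, 1.0)
        assert ac.n_eff == 10

    def test_identical_timestamps_split_weight(self):
        tr = _track([0.0, 0.0], [[0, 0], [1, 1]])
        for fam, tp in (("IID", None), ("OU", 3600.0)):
            m = MovementModel(fam, tp, None, 1.0, (0, 0), 0.0, 0.0, 2)
            ac = autocorr_weights(tr, m)
            np.testing.assert_allclose(ac.weights, 0.5)

    def test_three_equally_spaced_hand_example(self):
        """rho(dt)=0.5, rho(2dt)=0.25 -> w = (1/1.75, 1/2, 1/1.75)."""
        dt = 3600.0
        tau = dt / np.log(2.0)  # exp(-dt/tau) = 0.5
        m = MovementModel("OU", tau, None, 1.0, (0, 0), 0.0, 0.0, 3)
        ac = autocorr_weights(_track([0, dt, 2 * dt], np.zeros((3, 2))), m)
        np.testing.assert_allclose(ac.weights, [1 / 1.75, 0.5, 1 / 1.75])
        assert ac.n_eff == pytest.approx(2 / 1.75 + 0.5)

    def test_ou_small_tau_approaches_iid(self):
        sec = np.arange(20) * 3600.0
        tr = _track(sec, np.zeros((20, 2)))
        m = MovementModel("OU", 1e-6, None, 1.0, (0, 0), 0.0, 0.0, 20)
        ac = autocorr_weights(tr, m)
        np.testing.assert_allclose(ac.weights, 1.0, atol=1e-9)

    def test_neff_nonincreasing_with_duplicated_fix(self):
        m = MovementModel("OU", 3600.0, None, 1.0, (0, 0), 0.0, 0.0, 5)
        sec = [0.0, 3600.0, 7200.0]
        base = autocorr_weights(_track(sec, np.zeros((3, 2))), m).n_eff
        dup = autocorr_weights(_track(sec + [3600.0], np.zeros((4, 2))), m).n_eff
        # a coincident fix adds no information and drags down its neighbours
        assert dup <= base


def _design(n_use=5, n_abs=5, sats=9, ac=1.0, season="warm", ind="a"):
    rows = []
    for i in range(n_use):
        rows.append(
            {"individual_id": ind, "response": 1, "season": season,
             "n_sats": sats, "ac_weight": ac if np.ndim(ac) == 0 else ac[i]}
        )
    for _ in range(n_abs):
        rows.append(
            {"individual_id": ind, "response": 0, "season": season,
             "n_sats": np.nan, "ac_weight": np.nan}
        )
    return pd.DataFrame(rows)


def _table2_like():
    """Error table with na_weight 0.28 (4-sat) and weight 1 at 9 sats."""
    return build_error_weights(
        pd.DataFrame(
            {"n_sats": [4, 4, 9, 9], "error_m": [1 / 0.28, 1 / 0.28, 1.0, 1.0]}
        ),
        quantile_cut=1.0,
    )


class TestCombineWeights:
    def test_worked_example_five_gps_five_absences(self):
        """5 GPS fixes (9 sats, w=1) + 5 pseudo-absences with na weight 0.28:
        final weights 1.5625 / 0.4375 summing to the 10 rows."""
        out = combine_weights(_design(), _table2_like())
        gps = out.loc[out["response"] == 1, "weight"]
        pa = out.loc[out["response"] == 0, "weight"]
        np.testing.assert_allclose(gps, 1.5625, rtol=1e-9)
        np.testing.assert_allclose(pa, 0.4375, rtol=1e-9)
        assert out["weight"].sum() == pytest.approx(10.0, rel=1e-12)

    def test_zero_autocorr_weight_gives_zero_final_weight(self):
        out = combine_weights(
            _design(ac=np.array([0.0, 1, 1, 1, 1])), _table2_like()
        )
        w = out.loc[out["response"] == 1, "weight"].to_numpy()
        assert w[0] == 0.0
        assert (w[1:] > 0).all()

    def test_equal_error_weights_cancel(self):
        flat = build_error_weights(
            pd.DataFrame({"n_sats": [4, 4, 9, 9], "error_m": [2.0, 2.0, 2.0, 2.0]}),
            quantile_cut=1.0,
        )
        a = combine_weights(_design(sats=9), flat)
        b = combine_weights(_design(sats=4), flat)
        np.testing.assert_allclose(a["weight"], b["weight"])

    def test_missing_absences_is_hard_error(self):
        with pytest.raises(ValueError, match="pseudo-absences"):
            combine_weights(_design(n_abs=0), _table2_like())

    @given(
        st.integers(2, 30),
        st.integers(2, 30),
        st.integers(0, 1000),
    )
    @settings(max_examples=25, derandomize=True)
    def test_seasonal_sum_equals_row_count(self, n_use, n_abs, seed):
        rng = np.random.default_rng(seed)
        d = pd.concat(
            [
                _design(
                    n_use, n_abs, sats=int(rng.integers(4, 10)),
                    ac=rng.uniform(0.05, 1.0, n_use), ind=ind,
                )
                for ind in ("a", "b")
            ],
            ignore_index=True,
        )
        out = combine_weights(d, _table2_like())
        assert out["weight"].sum() == pytest.approx(len(out), rel=1e-9)

    def test_gps_and_absence_mass_equal_before_error_weighting(self):
        rng = np.random.default_rng(0)
        d = _design(n_use=7, n_abs=4, ac=rng.uniform(0.1, 1, 7))
        out = combine_weights(d, _table2_like())
        use_mass = out.loc[out["response"] == 1, "alloc_weight"].sum()
        abs_mass = out.loc[out["response"] == 0, "alloc_weight"].sum()
        assert use_mass == pytest.approx(abs_mass, rel=1e-12)
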