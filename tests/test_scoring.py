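"""Mediator scoring, transform, weight derivation and score summations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alscore import (
    ValidationError,
    WeightVector,
    acute_stress_score,
    allostatic_load_score,
    default_secondary_weights,
    fit_ordinal_weights,
    minmax_score,
    pseudo_log2,
    score_pipeline,
    secondary_mediator_score,
)

PRIMARY = ["cortisol", "epinephrine", "noradrenaline"]


def _frame(**cols):
    return pd.DataFrame(cols)


class TestMinMax:
    def test_hand_arithmetic(self):
        m = minmax_score(_frame(x=[2.0, 4.0, 8.0]))
        np.testing.assert_allclose(m.raw["x"], [0.0, 1 / 3, 1.0])
        assert m.minima["x"] == 2.0 and m.maxima["x"] == 8.0

    def test_endpoints_attained_per_biomarker(self, cohort63):
        from alscore import impute_qrilc

        values = impute_qrilc(cohort63, seed=0).values
        m = minmax_score(values)
        assert (m.raw.min(axis=0) == 0).all()
        assert (m.raw.max(axis=0) == 1).all()

    def test_degenerate_biomarker_named(self):
        with pytest.raises(ValidationError, match="flat"):
            minmax_score(_frame(flat=[3.0, 3.0, 3.0], ok=[1.0, 2.0, 3.0]))

    def test_missing_rejected(self):
        with pytest.raises(ValidationError):
            minmax_score(_frame(x=[1.0, np.nan, 3.0]))

    @given(
        values=st.lists(
            st.floats(min_value=-1e3, max_value=1e3), min_size=3, max_size=20
        ),
        scale=st.floats(min_value=1e-3, max_value=1e3),
        offset=st.floats(min_value=-1e3, max_value=1e3),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_affine_invariance(self, values, scale, offset):
        """Any positive affine rescaling of a biomarker's concentrations
        leaves its min-max scores unchanged."""
        arr = np.asarray(values)
        if np.ptp(arr) < 1e-6:
            return
        m1 = minmax_score(_frame(x=arr))
        m2 = minmax_score(_frame(x=scale * arr + offset))
        np.testing.assert_allclose(m1.raw["x"], m2.raw["x"], atol=1e-7)

    def test_permutation_equivariance(self):
        arr = np.array([3.0, 1.0, 7.0, 5.0])
        perm = [2, 0, 3, 1]
        m1 = minmax_score(_frame(x=arr))
        m2 = minmax_score(_frame(x=arr[perm]))
        np.testing.assert_allclose(m1.raw["x"].to_numpy()[perm], m2.raw["x"])


class TestPseudoLog2:
    @pytest.mark.parametrize(
        "x,expected", [(0.0, 0.0), (1.0, 1.0), (0.5, 0.5849625007211562)]
    )
    def test_values(self, x, expected):
        assert pseudo_log2(x) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_domain_enforced(self, bad):
        with pytest.raises(ValidationError):
            pseudo_log2(bad)

    def test_monotone_and_bounded(self):
        x = np.linspace(0, 1, 101)
        y = pseudo_log2(x)
        assert (np.diff(y) > 0).all()
        assert y.min() == 0.0 and y.max() == 1.0

    def test_dataframe_passthrough(self):
        df = _frame(a=[0.0, 0.5], b=[1.0, 0.25])
        out = pseudo_log2(df)
        assert isinstance(out, pd.DataFrame)
        assert list(out.columns) == ["a", "b"]


def _simulate_ordinal(beta, n=400, n_classes=3, seed=0):
    """Latent-logistic ordinal outcome from [0,1] scores — the generating
    model the proportional-odds fit should invert."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.uniform(0, 1, (n, len(beta))), columns=PRIMARY)
    latent = X.to_numpy() @ np.asarray(beta) + rng.logistic(size=n)
    cuts = np.quantile(latent, np.linspace(0, 1, n_classes + 1)[1:-1])
    y = pd.Series(np.searchsorted(cuts, latent).astype(float))
    return X, y


class TestOrdinalWeights:
    def test_weights_sum_to_one_nonnegative(self):
        X, y = _simulate_ordinal([6.0, 2.0, 0.0], seed=3)
        wv = fit_ordinal_weights(X, y, "three_class")
        assert sum(wv.weights.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(w >= 0 for w in wv.weights.values())
        assert wv.n_fitted == 400

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_parameter_recovery(self, seed):
        """Generating coefficients 6:2:0 on (cortisol, epinephrine,
        noradrenaline) are recovered as weight shares within 0.08."""
        X, y = _simulate_ordinal([6.0, 2.0, 0.0], seed=seed)
        wv = fit_ordinal_weights(X, y, "three_class")
        assert wv.weights["cortisol"] == pytest.approx(0.75, abs=0.08)
        assert wv.weights["epinephrine"] == pytest.approx(0.25, abs=0.08)
        assert wv.weights["noradrenaline"] == pytest.approx(0.0, abs=0.08)

    def test_single_signal_recovery(self):
        X, y = _simulate_ordinal([0.0, 6.0, 0.0], seed=9)
        wv = fit_ordinal_weights(X, y, "three_class")
        assert wv.weights["epinephrine"] > 0.9

    def test_two_class_scheme(self):
        X, y = _simulate_ordinal([4.0, 4.0, 0.0], n_classes=2, seed=5)
        wv = fit_ordinal_weights(X, y, "two_class")
        assert sum(wv.weights.values()) == pytest.approx(1.0, abs=1e-12)
        assert wv.scheme == "two_class"

    def test_missing_bp_excluded(self):
        X, y = _simulate_ordinal([6.0, 2.0, 0.0], seed=1)
        y.iloc[:50] = np.nan
        wv = fit_ordinal_weights(X, y, "three_class")
        assert wv.n_fitted == 350

    def test_too_few_participants_rejected(self):
        X, y = _simulate_ordinal([1.0, 1.0, 1.0], n=9, seed=0)
        with pytest.raises(ValidationError, match="at least 10"):
            fit_ordinal_weights(X, y, "three_class")

    def test_empty_class_rejected(self):
        X, y = _simulate_ordinal([1.0, 1.0, 1.0], n=40, n_classes=2, seed=0)
        with pytest.raises(ValidationError, match="class"):
            fit_ordinal_weights(X, y, "three_class")


class TestSummations:
    def _weights(self, w):
        return WeightVector(
            scheme="three_class",
            weights=dict(zip(PRIMARY, w)),
            coefficients=dict(zip(PRIMARY, w)),
            n_fitted=34,
            fit_converged=True,
        )

    def test_degenerate_weights_select_one_mediator(self):
        t = _frame(cortisol=[0.2, 0.4], epinephrine=[0.9, 0.1], noradrenaline=[0.5, 0.5])
        acute = acute_stress_score(t, self._weights([0.0, 1.0, 0.0]))
        np.testing.assert_allclose(acute, t["epinephrine"])

    def test_convex_combination_of_constant(self):
        t = _frame(cortisol=[0.5], epinephrine=[0.5], noradrenaline=[0.5])
        w = np.array([0.73, 0.22, 0.04])
        acute = acute_stress_score(t, self._weights(w / w.sum()))
        assert acute.iloc[0] == pytest.approx(0.5, abs=1e-12)

    def test_endpoints(self):
        w = self._weights([0.5, 0.3, 0.2])
        zeros = _frame(cortisol=[0.0], epinephrine=[0.0], noradrenaline=[0.0])
        ones = _frame(cortisol=[1.0], epinephrine=[1.0], noradrenaline=[1.0])
        assert acute_stress_score(zeros, w).iloc[0] == 0.0
        assert acute_stress_score(ones, w).iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_missing_mediator_column_rejected(self):
        t = _frame(cortisol=[0.5], epinephrine=[0.5])
        with pytest.raises(ValidationError, match="noradrenaline"):
            acute_stress_score(t, self._weights([0.3, 0.3, 0.4]))

    def test_secondary_score_cases(self, panel):
        sw = default_secondary_weights(panel)
        assert sw == {"fibrinogen": 0.25, "crp": 0.25, "hba1c": 0.25, "hdl": -0.25}
        cases = _frame(
            fibrinogen=[0.0, 1.0, 0.0],
            crp=[0.0, 1.0, 0.0],
            hba1c=[0.0, 1.0, 0.0],
            hdl=[0.0, 1.0, 1.0],
        )
        sec = secondary_mediator_score(cases, sw)
        np.testing.assert_allclose(sec, [0.0, 0.5, -0.25], atol=1e-12)

    def test_al_is_exact_sum(self):
        acute = pd.Series([0.0, 0.3, 1.0])
        sec = pd.Series([0.0, 0.4, 0.75])
        al = allostatic_load_score(acute, sec)
        np.testing.assert_array_equal(al.to_numpy(), (acute + sec).to_numpy())
        assert al.iloc[2] == 1.75  # within the construction's [.,2] bound


class TestPipelineProperties:
    def test_al_identity_and_bounds(self, cohort63):
        res = score_pipeline(cohort63, seed=21)
        s = res.scores
        np.testing.assert_array_equal(
            s["al_two"].to_numpy(), (s["acute_two"] + s["secondary"]).to_numpy()
        )
        np.testing.assert_array_equal(
            s["al_three"].to_numpy(), (s["acute_three"] + s["secondary"]).to_numpy()
        )
        for c in ("acute_two", "acute_three"):
            assert s[c].between(0, 1).all()
        assert s["secondary"].between(-0.25, 0.75).all()
        assert s["al_three"].between(-0.25, 2).all()

    def test_participant_permutation_permutes_scores(self, cohort63):
        from alscore import CohortTable

        perm = np.random.default_rng(0).permutation(len(cohort63))
        shuffled = CohortTable(
            cohort63.data.iloc[perm].reset_index(drop=True), cohort63.panel
        )
        r1 = score_pipeline(cohort63, seed=4)
        r2 = score_pipeline(shuffled, seed=4)
        a = r1.scores.set_index("participant_id")["secondary"]
        b = r2.scores.set_index("participant_id")["secondary"]
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())

    def test_hdl_increase_never_raises_al(self, cohort63):
        """HDL is protective: raising one participant's HDL (inside the
        cohort's min-max range) cannot raise their AL score."""
        from alscore import CohortTable

        res = score_pipeline(cohort63, seed=4)
        df = cohort63.data.copy()
        hdl = df["hdl"]
        # pick a participant strictly inside the range and nudge upward
        inner = hdl[(hdl > hdl.min()) & (hdl < hdl.quantile(0.8))].index[0]
        df.loc[inner, "hdl"] = hdl.quantile(0.9)
        bumped = score_pipeline(CohortTable(df, cohort63.panel), seed=4)
        pid = df.loc[inner, "participant_id"]
        before = res.scores.set_index("participant_id").loc[pid, "al_three"]
        after = bumped.scores.set_index("participant_id").loc[pid, "al_three"]
        assert after <= before
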