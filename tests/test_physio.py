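"""Physiology preprocessing, QC, and the two RSM-averaging regimes."""

import numpy as np
import pandas as pd
import pytest

from affectrsa import (
    build_physio_rsm_considering,
    build_physio_rsm_dismissing,
    preprocess_scr,
    qc_filter_startle,
    t_transform_startle,
)
from affectrsa.physio import ZeroVarianceError, collapse_repetitions, preprocess_table
from affectrsa.rsm import ModelSpec, build_model_rsm

from conftest import make_table


def simple_table(scr_by_participant, ratings_by_participant=None):
    """Trial table where arousal rating equals trial position unless given."""
    rows = []
    for p, values in enumerate(scr_by_participant):
        T = len(values)
        ratings = (ratings_by_participant[p] if ratings_by_participant
                   else list(range(1, T + 1)))
        for t, (v, r) in enumerate(zip(values, ratings), start=1):
            rows.append((f"sub-{p:02d}", t, f"stim-{t:02d}", 5, r, "neutral",
                         "low", np.nan, np.nan))
    df = make_table(rows)
    df["scr_log"] = np.concatenate([np.asarray(v, float) for v in scr_by_participant])
    return df


class TestTransforms:
    def test_log1p_closed_forms(self):
        out = preprocess_scr([0.0, np.e - 1, np.nan])
        assert out[0] == 0.0
        assert out[1] == pytest.approx(1.0, abs=1e-12)
        assert np.isnan(out[2])

    def test_log1p_rejects_negative(self):
        with pytest.raises(ValueError):
            preprocess_scr([-0.1])

    def test_t_transform_sd_ten_example(self):
        np.testing.assert_allclose(t_transform_startle([10, 20, 30]), [40, 50, 60])

    def test_t_transform_normalizes_to_mean50_sd10(self, rng):
        x = rng.gamma(2.0, 20.0, size=36)
        out = t_transform_startle(x)
        assert out.mean() == pytest.approx(50, abs=1e-9)
        assert out.std(ddof=1) == pytest.approx(10, abs=1e-9)

    def test_t_transform_with_missing_uses_present_trials(self):
        # mean 10, sample SD sqrt(50) over the two present values
        out = t_transform_startle([5.0, np.nan, 15.0])
        sd = np.sqrt(50.0)
        np.testing.assert_allclose(out[[0, 2]],
                                   [50 - 50 / sd, 50 + 50 / sd])
        assert np.isnan(out[1])

    def test_t_transform_degenerate_inputs(self):
        with pytest.raises(ZeroVarianceError):
            t_transform_startle([7.0, 7.0, 7.0])
        with pytest.raises(ZeroVarianceError):
            t_transform_startle([7.0, np.nan])


class TestStartleQc:
    def _table(self, n_missing, n_trials=36):
        vals = [np.nan] * n_missing + list(np.linspace(10, 50, n_trials - n_missing))
        rows = [("sub-01", t + 1, f"s{t}", 5, 5, "neutral", "low", 0.1, vals[t])
                for t in range(n_trials)]
        return make_table(rows)

    def test_over_half_nonresponses_excluded(self):
        filtered, report = qc_filter_startle(self._table(19))
        assert filtered.empty
        assert report.loc[0, "excluded"]
        assert report.loc[0, "nonresponse_frac"] == pytest.approx(19 / 36)

    def test_exactly_half_retained(self):
        # "more than 50%" is a strict inequality
        filtered, report = qc_filter_startle(self._table(18))
        assert not filtered.empty
        assert not report.loc[0, "excluded"]

    def test_zero_responses_count_as_nonresponses(self):
        table = self._table(10)
        table.loc[10:18, "startle_magnitude"] = 0.0  # 10 missing + 9 zeros = 19/36
        filtered, _ = qc_filter_startle(table)
        assert filtered.empty

    def test_no_missing_no_exclusions(self, fingerprint_table):
        clean = fingerprint_table.assign(
            startle_magnitude=fingerprint_table["startle_magnitude"].fillna(10.0))
        _, report = qc_filter_startle(clean)
        assert not report["excluded"].any()


def naive_dismissing(table, sort_dim="arousal"):
    """Sort / average across participants / NN — independent double loop."""
    per = []
    for _, grp in table.groupby("participant_id", sort=True):
        grp = grp.sort_values("trial_index").sort_values(
            f"{sort_dim}_rating", kind="stable")
        per.append(grp["scr_log"].to_numpy())
    mat = np.vstack(per)
    avg = np.array([np.nanmean(mat[:, k]) if np.any(~np.isnan(mat[:, k])) else np.nan
                    for k in range(mat.shape[1])])
    vmax = np.nanmax(avg)
    T = len(avg)
    out = np.empty((T, T))
    for i in range(T):
        for j in range(T):
            out[i, j] = vmax - abs(avg[i] - avg[j])
    return out


def naive_considering(table, sort_dim="arousal"):
    """Per-participant NN then cellwise mean — independent double loop."""
    mats = []
    for _, grp in table.groupby("participant_id", sort=True):
        grp = grp.sort_values("trial_index").sort_values(
            f"{sort_dim}_rating", kind="stable")
        v = grp["scr_log"].to_numpy()
        vmax = np.nanmax(v)
        T = len(v)
        m = np.empty((T, T))
        for i in range(T):
            for j in range(T):
                m[i, j] = (np.nan if np.isnan(v[i]) or np.isnan(v[j])
                           else vmax - abs(v[i] - v[j]))
        mats.append(m)
    stack = np.stack(mats)
    with np.errstate(invalid="ignore"):
        return np.nanmean(stack, axis=0)


class TestDismissingRegime:
    def test_identical_participants_reduce_to_single_rsm(self):
        vals = [0.1, 0.4, 0.9]
        table = simple_table([vals, vals, vals])
        r = build_physio_rsm_dismissing(table, "scr", "arousal")
        single = build_model_rsm(vals, ModelSpec(kind="NN", v_max=0.9, n_variables=3))
        np.testing.assert_allclose(r.values, single.values)

    def test_cancellation_yields_constant_rsm(self):
        # opposite rank-value profiles cancel: the regime's defining failure mode
        table = simple_table([[1, 2, 3], [3, 2, 1]])
        r = build_physio_rsm_dismissing(table, "scr", "arousal")
        assert np.allclose(r.values, r.values[0, 0])

    def test_matches_naive_oracle(self, rng):
        profiles = [rng.normal(0.5, 0.2, size=8) for _ in range(5)]
        ratings = [list(rng.integers(1, 10, size=8)) for _ in range(5)]
        table = simple_table(profiles, ratings)
        r = build_physio_rsm_dismissing(table, "scr", "arousal")
        np.testing.assert_allclose(r.values, naive_dismissing(table), rtol=1e-12)

    def test_unequal_trial_counts_error(self):
        table = simple_table([[1, 2, 3]])
        table2 = simple_table([[1, 2]])
        table2["participant_id"] = "sub-99"
        with pytest.raises(ValueError):
            build_physio_rsm_dismissing(pd.concat([table, table2]), "scr", "arousal")


class TestConsideringRegime:
    def test_single_participant_equals_own_rsm(self):
        table = simple_table([[0.1, 0.4, 0.9]])
        avg, individual, pids = build_physio_rsm_considering(table, "scr", "arousal")
        assert len(individual) == 1 and pids == ["sub-00"]
        np.testing.assert_allclose(avg.values, individual[0].values)

    def test_cancellation_fixture_not_constant(self):
        # individual structure survives averaging matrices instead of values
        table = simple_table([[1, 2, 3], [3, 2, 1]])
        avg, _, _ = build_physio_rsm_considering(table, "scr", "arousal")
        assert not np.allclose(avg.values, avg.values[0, 0])

    def test_matches_naive_oracle(self, rng):
        profiles = [rng.normal(0.5, 0.2, size=8) for _ in range(5)]
        ratings = [list(rng.integers(1, 10, size=8)) for _ in range(5)]
        table = simple_table(profiles, ratings)
        avg, _, _ = build_physio_rsm_considering(table, "scr", "arousal")
        np.testing.assert_allclose(avg.values, naive_considering(table), rtol=1e-12)

    def test_missing_trials_propagate_and_counts_track(self):
        profiles = [[0.1, 0.4, 0.9, 0.5], [0.2, np.nan, 0.7, 0.3], [0.3, 0.2, 0.1, 0.8]]
        table = simple_table(profiles)
        avg, individual, _ = build_physio_rsm_considering(table, "scr", "arousal")
        assert np.isnan(individual[1].values[1]).all()
        # cell count = N minus participants missing either trial
        assert avg.counts[1, 0] == 2 and avg.counts[2, 0] == 3

    def test_too_few_usable_trials_excluded_with_warning(self):
        profiles = [[0.1, 0.4, 0.9, 0.5], [0.2, np.nan, np.nan, 0.3]]
        table = simple_table(profiles)
        with pytest.warns(UserWarning, match="excluded"):
            _, individual, pids = build_physio_rsm_considering(table, "scr", "arousal")
        assert pids == ["sub-00"]


class TestRegimeContrast:
    def test_regimes_diverge_under_heteroskedasticity(self, populations_table):
        table, _ = preprocess_table(populations_table, "scr")
        dis = build_physio_rsm_dismissing(table, "scr", "arousal")
        con, _, _ = build_physio_rsm_considering(table, "scr", "arousal")
        frob = np.sqrt(np.nansum((dis.values - con.values) ** 2))
        assert frob > 0.1

    def test_regimes_coincide_for_noise_free_rating_locked_data(self):
        # identical ratings and a deterministic response per rating level
        ratings = [1, 3, 5, 7, 9, 9]
        values = [0.1 * r for r in ratings]
        table = simple_table([values] * 4, [ratings] * 4)
        dis = build_physio_rsm_dismissing(table, "scr", "arousal")
        con, _, _ = build_physio_rsm_considering(table, "scr", "arousal")
        np.testing.assert_allclose(dis.values, con.values, atol=1e-12)

    def test_participant_relabeling_invariance(self, rng):
        profiles = [list(rng.normal(0.5, 0.2, size=6)) for _ in range(4)]
        ratings = [list(rng.integers(1, 10, size=6)) for _ in range(4)]
        table = simple_table(profiles, ratings)
        relabeled = table.copy()
        mapping = {"sub-00": "z", "sub-01": "y", "sub-02": "x", "sub-03": "w"}
        relabeled["participant_id"] = relabeled["participant_id"].map(mapping)
        for builder in (build_physio_rsm_dismissing,):
            np.testing.assert_allclose(
                builder(table, "scr", "arousal").values,
                builder(relabeled, "scr", "arousal").values)
        a, _, _ = build_physio_rsm_considering(table, "scr", "arousal")
        b, _, _ = build_physio_rsm_considering(relabeled, "scr", "arousal")
        np.testing.assert_allclose(a.values, b.values)


class TestPreprocessTable:
    def test_scr_adds_log_column(self, populations_table):
        out, report = preprocess_table(populations_table, "scr")
        np.testing.assert_allclose(out["scr_log"],
                                   np.log1p(out["scr_amplitude"]))
        assert report.empty

    def test_startle_filters_and_t_transforms(self, populations_table):
        out, report = preprocess_table(populations_table, "startle")
        for _, grp in out.groupby("participant_id"):
            vals = grp["startle_t"].dropna()
            assert vals.mean() == pytest.approx(50, abs=1e-9)
            assert vals.std(ddof=1) == pytest.approx(10, abs=1e-9)
        assert set(report.columns) >= {"participant_id", "nonresponse_frac", "excluded"}


class TestRepetitionCollapse:
    def _repeated(self):
        rows = []
        for rep in range(2):
            for t in range(3):
                rows.append(("sub-01", rep * 3 + t + 1, f"stim-{t}", 4 + rep, 5,
                             "neutral", "low", 0.1 * (t + 1) + 0.2 * rep, 10.0))
        return make_table(rows)

    def test_mean_collapse_averages_repetitions(self):
        out = collapse_repetitions(self._repeated(), "mean")
        assert len(out) == 3
        first = out[out.stimulus_id == "stim-0"].iloc[0]
        assert first["scr_amplitude"] == pytest.approx((0.1 + 0.3) / 2)
        assert first["valence_rating"] == pytest.approx(4.5)

    def test_first_collapse_keeps_earliest(self):
        out = collapse_repetitions(self._repeated(), "first")
        assert len(out) == 3
        assert out[out.stimulus_id == "stim-0"].iloc[0]["scr_amplitude"] == pytest.approx(0.1)
        assert sorted(out["trial_index"]) == [1, 2, 3]
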