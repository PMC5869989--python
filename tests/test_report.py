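import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ramanbone as rb
from ramanbone import report
from ramanbone.data_model import ValidationError
from ramanbone.report import (
    METRICS,
    STARS_COARSE,
    STARS_FINE,
    compare_groups,
    fold_changes,
    radial_coordinates,
    star_label,
    summarize_spectra,
)


def metric_frame(groups):
    """Build a metrics table from {(bone, region, week): {metric: values}}."""
    rows = []
    for (bone, region, week), values in groups.items():
        n = len(next(iter(values.values())))
        for i in range(n):
            rows.append(
                dict(
                    bone=bone,
                    region=region,
                    week=week,
                    **{m: values[m][i] for m in METRICS},
                )
            )
    return pd.DataFrame(rows)


class TestFoldChanges:
    def test_baseline_week_is_exactly_one(self):
        rng = np.random.default_rng(0)
        table = metric_frame(
            {("femur", "diaphysis", 0): {m: rng.uniform(1, 2, 10) for m in METRICS}}
        )
        fc = fold_changes(table)
        assert (fc["fold_change"] == 1.0).all()
        assert (fc["sd"] == 0.0).all()

    def test_doubled_means_give_fold_change_two(self):
        base = {m: np.full(8, 2.0) for m in METRICS}
        high = {m: np.full(8, 4.0) for m in METRICS}
        table = metric_frame(
            {("femur", "diaphysis", 0): base, ("femur", "diaphysis", 4): high}
        )
        fc = fold_changes(table)
        wk4 = fc[fc["week"] == 4]
        assert np.allclose(wk4["fold_change"], 2.0)

    def test_missing_baseline_rejected(self):
        table = metric_frame(
            {("femur", "diaphysis", 4): {m: np.ones(5) for m in METRICS}}
        )
        with pytest.raises(ValidationError):
            fold_changes(table)

    def test_delta_method_sd_matches_closed_form(self):
        rng = np.random.default_rng(1)
        b = {m: rng.normal(10, 1, 20) for m in METRICS}
        g = {m: rng.normal(15, 2, 25) for m in METRICS}
        table = metric_frame(
            {("spine", "L1_L4", 0): b, ("spine", "L1_L4", 2): g}
        )
        fc = fold_changes(table).set_index(["week", "metric"])
        m = METRICS[0]
        mb, mg = b[m].mean(), g[m].mean()
        seb = b[m].std(ddof=1) / np.sqrt(20)
        seg = g[m].std(ddof=1) / np.sqrt(25)
        want = (mg / mb) * np.sqrt((seg / mg) ** 2 + (seb / mb) ** 2)
        assert fc.loc[(2, m), "sd"] == pytest.approx(want)

    def test_bootstrap_sd_agrees_with_delta(self):
        rng = np.random.default_rng(6)
        b = {m: rng.normal(10, 1, 30) for m in METRICS}
        g = {m: rng.normal(12, 1.5, 30) for m in METRICS}
        table = metric_frame({("femur", "diaphysis", 0): b, ("femur", "diaphysis", 2): g})
        delta = fold_changes(table).set_index(["week", "metric"])
        boot = fold_changes(table, sd_method="bootstrap", seed=1).set_index(["week", "metric"])
        for m in METRICS:
            assert boot.loc[(2, m), "sd"] == pytest.approx(delta.loc[(2, m), "sd"], rel=0.3)


class TestHolm:
    def test_holm_adjustment_matches_hand_computation(self):
        p = np.array([0.01, 0.04, 0.03, 0.005])
        np.testing.assert_allclose(report.holm_adjust(p), [0.03, 0.06, 0.06, 0.02])

    def test_holm_column_in_comparison_table(self):
        rng = np.random.default_rng(7)
        groups = {
            ("femur", "diaphysis", w): {m: rng.normal(10 + w, 1, 10) for m in METRICS}
            for w in (0, 2, 4)
        }
        table = report.compare_weeks_table(metric_frame(groups), holm=True)
        assert "p_holm" in table.columns
        assert (table["p_holm"] >= table["p"] - 1e-15).all()


class TestGroupComparison:
    def test_identical_groups_not_significant(self):
        a = np.array([1.0, 2.0, 3.0])
        c = compare_groups(a, a.copy())
        assert c.t == 0.0 and c.p == 1.0 and c.stars == "n.s."

    def test_zero_variance_equal_means_convention(self):
        c = compare_groups(np.ones(4), np.ones(5))
        assert (c.t, c.p, c.stars) == (0.0, 1.0, "n.s.")

    def test_large_separation_three_stars_fine_scale(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.0, 1.0, 10)
        b = rng.normal(5.0, 1.0, 10)  # 5-SD mean separation
        c = compare_groups(a, b, thresholds=STARS_FINE)
        assert c.p < 0.001 and c.stars == "***"
        # closed-form check of p at the computed t with 18 df
        want = 2.0 * stats.t.sf(abs(c.t), 18)
        assert c.p == pytest.approx(want, rel=1e-10)

    def test_star_thresholds_both_conventions(self):
        assert star_label(0.03, STARS_COARSE) == "*"
        assert star_label(0.03, STARS_FINE) == "*"
        assert star_label(0.004, STARS_COARSE) == "**"
        assert star_label(0.004, STARS_FINE) == "**"
        assert star_label(0.0005, STARS_FINE) == "***"
        assert star_label(0.2, STARS_FINE) == "n.s."

    def test_symmetric_up_to_sign(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 9)
        c1 = compare_groups(a, b)
        c2 = compare_groups(b, a)
        assert c1.t == pytest.approx(-c2.t)
        assert c1.p == pytest.approx(c2.p)

    def test_welch_option(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 5, 10)
        c = compare_groups(a, b, equal_var=False)
        t, p = stats.ttest_ind(a, b, equal_var=False)
        assert c.t == pytest.approx(t) and c.p == pytest.approx(p)

    def test_too_small_group_rejected(self):
        with pytest.raises(ValidationError):
            compare_groups(np.array([1.0]), np.array([1.0, 2.0]))


class TestRadial:
    def anchors(self):
        ang = np.deg2rad(report.RADIAL_ANCHORS)
        return np.column_stack([np.cos(ang), np.sin(ang)])

    def test_equal_normalized_values_map_to_origin(self):
        # two samples at opposite extremes: each normalizes to all-0 / all-1
        table = pd.DataFrame(
            [dict(zip(METRICS, [1.0, 1.0, 1.0, 1.0])), dict(zip(METRICS, [2.0, 2.0, 2.0, 2.0]))]
        )
        pts = radial_coordinates(table)
        # all-1 sample: equal weights -> centroid of anchors = origin
        assert pts.loc[1, ["x", "y"]].to_numpy() == pytest.approx([0.0, 0.0], abs=1e-12)
        # all-0 sample: zero total weight -> origin by convention
        assert pts.loc[0, ["x", "y"]].to_numpy() == pytest.approx([0.0, 0.0])

    def test_one_hot_sample_sits_on_its_anchor(self):
        rows = [dict(zip(METRICS, row)) for row in np.vstack([np.eye(4), np.zeros(4)])]
        pts = radial_coordinates(pd.DataFrame(rows))
        anchors = self.anchors()
        for i in range(4):
            assert pts.loc[i, ["x", "y"]].to_numpy() == pytest.approx(anchors[i], abs=1e-12)

    def test_hand_computed_two_sample_case(self):
        # sample with normalized values (1, 0, 0.5, 0.5):
        # point = (a0 + 0.5 a2 + 0.5 a3) / 2
        table = pd.DataFrame(
            [
                dict(zip(METRICS, [1.0, 0.0, 0.5, 0.5])),
                dict(zip(METRICS, [0.0, 1.0, 0.0, 1.0])),
            ]
        )
        # min-max over the two samples leaves values unchanged (0/1 per metric;
        # 0.5 stays 0.5 only if it is between min and max) -> build a third
        # row fixing min=0 and max=1 for every metric
        table = pd.concat(
            [table, pd.DataFrame([dict(zip(METRICS, [0.0, 0.0, 0.0, 0.0])),
                                  dict(zip(METRICS, [1.0, 1.0, 1.0, 1.0]))])],
            ignore_index=True,
        )
        pts = radial_coordinates(table)
        a = self.anchors()
        want = (a[0] + 0.5 * a[2] + 0.5 * a[3]) / 2.0
        assert pts.loc[0, ["x", "y"]].to_numpy() == pytest.approx(want, abs=1e-12)

    def test_points_inside_unit_disk_and_permutation_equivariant(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame(rng.uniform(0, 3, (30, 4)), columns=list(METRICS))
        pts = radial_coordinates(table)
        assert (pts["x"] ** 2 + pts["y"] ** 2 <= 1 + 1e-12).all()
        perm = rng.permutation(30)
        pts2 = radial_coordinates(table.iloc[perm].reset_index(drop=True))
        np.testing.assert_allclose(
            pts2[["x", "y"]].to_numpy(), pts[["x", "y"]].to_numpy()[perm]
        )

    def test_constant_metric_uses_half_convention(self):
        table = pd.DataFrame(
            {
                METRICS[0]: [1.0, 2.0],
                METRICS[1]: [5.0, 5.0],  # constant
                METRICS[2]: [0.0, 1.0],
                METRICS[3]: [0.0, 1.0],
            }
        )
        pts = radial_coordinates(table)
        assert np.isfinite(pts[["x", "y"]].to_numpy()).all()


class TestSummaries:
    def test_single_spectrum_group(self, tiny_set):
        s = summarize_spectra(tiny_set.select([0]), "week")
        np.testing.assert_array_equal(s["mean"], tiny_set.intensities[0])
        np.testing.assert_array_equal(s["sd"], 0.0)

    def test_identical_spectra_zero_sd(self, tiny_set):
        dup = tiny_set.with_intensities(
            np.vstack([tiny_set.intensities[0], tiny_set.intensities[0]])
        )
        dup.meta["week"] = 0
        dup.meta["bone"] = "femur"
        dup.meta["site"] = 1
        dup.meta["region"] = "distal_metaphysis"
        s = summarize_spectra(dup, "week")
        np.testing.assert_allclose(s["sd"], 0.0, atol=1e-12)

    def test_channelwise_sd_tracks_noise_model(self):
        # 100 week-0 femur spectra with ideal profile and zero baseline:
        # off-peak channelwise SD ~ noise_sd0
        import dataclasses
        from ramanbone import synth
        from ramanbone.data_model import SpectrumMeta

        # flat baseline at 30 keeps the zero-clip inactive off-peak, so the
        # channelwise SD should track sd0 + shot_scale * sqrt(30)
        cfg = rb.default_config(
            baseline_coef_ranges=((30.0, 30.0),) + ((0.0, 0.0),) * 5,
            baseline_floor=0.0,
            probe_background_scale=0.0,
            cosmic_ray_rate=0.0,
            ideal_profile=True,
        )
        meta = SpectrumMeta("s", "m", 0, "femur", 1, 1)
        rng = np.random.default_rng(0)
        X = np.array([synth.simulate_spectrum(cfg, meta, rng) for _ in range(100)])
        off_peak = cfg.axis < 880
        sd = X[:, off_peak].std(axis=0)
        want = cfg.noise_sd0 + cfg.shot_scale * np.sqrt(30.0)
        # the per-channel SD estimate itself carries ~7% sampling noise at
        # n=100, so check the ensemble rather than every single channel
        assert np.median(sd) == pytest.approx(want, rel=0.05)
        assert np.mean(np.abs(sd - want) < 0.2 * want) > 0.95

    def test_study_summary_shapes(self, small_study):
        sset, _, _, _ = small_study
        s = summarize_spectra(sset, ["bone", "week"])
        assert set(s.columns) == {"group", "wavenumber_cm1", "mean", "sd"}
        assert s.groupby("group").size().nunique() == 1


class TestDirectionalFoldChanges:
    def test_simulated_study_reproduces_generator_directions(self, small_metrics):
        fc = fold_changes(small_metrics).set_index(["bone", "region", "week", "metric"])

        def f(bone, region, week, metric):
            return fc.loc[(bone, region, week, metric), "fold_change"]

        for region in ("distal_metaphysis", "proximal_metaphysis"):
            m2m = [f("femur", region, w, "mineral_to_matrix") for w in (0, 2, 4, 5)]
            assert m2m == sorted(m2m)
            assert f("femur", region, 2, "phos_to_carb") < 1.0
            assert f("femur", region, 5, "phos_to_carb") > 1.0
            assert f("femur", region, 2, "crystallinity") < 1.0
            assert f("femur", region, 5, "crystallinity") > 1.0
            for w in (2, 4, 5):
                assert f("femur", region, w, "carb_to_matrix") > 1.0


class TestPlots:
    def test_figures_render_to_files(self, tmp_path, small_preprocessed, small_metrics):
        out, _ = small_preprocessed
        fc = fold_changes(small_metrics[small_metrics["bone"] == "femur"])
        report.plot_fold_changes(fc, tmp_path / "fc.png")
        pts = radial_coordinates(small_metrics.dropna(subset=list(METRICS)))
        report.plot_radial(pts, tmp_path / "radial.png")
        s = summarize_spectra(out.select(np.arange(0, len(out), 12)), "week")
        report.plot_mean_spectra(s, tmp_path / "mean.png")
        for name in ("fc.png", "radial.png", "mean.png"):
            assert (tmp_path / name).stat().st_size > 0
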