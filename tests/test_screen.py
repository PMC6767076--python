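"""Studentized residual / truncation-probability screening."""

import numpy as np
import pandas as pd
import pytest

from rrmeta import (
    MetaDataset,
    ScreenConfig,
    SimDesign,
    StudyTable,
    bin_and_tabulate,
    make_synthetic_collection,
    screen_collection,
    screen_meta_analysis,
    studentized_residuals,
    truncation_probability_hat,
)


class TestStudentizedResiduals:
    def test_identical_studies_give_zero_residuals(self):
        ds = MetaDataset(tuple(StudyTable(5, 50, 8, 50, str(j)) for j in range(4)))
        r, theta_m, tau2 = studentized_residuals(ds, "FEM")
        np.testing.assert_allclose(r, 0.0, atol=1e-12)
        assert tau2 == 0.0

    def test_two_equal_variance_studies_symmetric(self):
        ds = MetaDataset((StudyTable(5, 50, 10, 50, "a"), StudyTable(10, 50, 5, 50, "b")))
        r, _, _ = studentized_residuals(ds, "FEM")
        assert r[0] == pytest.approx(-r[1])

    def test_invariant_to_relabeling(self):
        studies = tuple(StudyTable(4 + j, 60, 9 - j, 55, str(j)) for j in range(5))
        ds = MetaDataset(studies)
        perm = (3, 1, 4, 0, 2)
        ds_perm = MetaDataset(tuple(studies[i] for i in perm))
        r, _, _ = studentized_residuals(ds, "REM")
        r_perm, _, _ = studentized_residuals(ds_perm, "REM")
        np.testing.assert_allclose(r_perm, r[list(perm)])

    def test_requires_two_studies(self):
        with pytest.raises(ValueError, match="K >= 2"):
            studentized_residuals(MetaDataset((StudyTable(1, 10, 2, 10),)), "FEM")

    def test_pooled_residuals_approximately_standard_normal(self):
        """On a benign synthetic collection the residuals have light skew."""
        designs = SimDesign(k=10, n=2000, theta=-0.5, pi_c=0.1, tau2=0.1,
                            option="point_mass", reps=1, seed=0)
        coll = make_synthetic_collection(400, designs, seed=101)
        rs = []
        for ds in coll:
            r, _, _ = studentized_residuals(ds, "REM")
            rs.append(r[np.isfinite(r)])
        pooled = np.concatenate(rs)
        from scipy.stats import skew

        assert abs(skew(pooled)) < 0.1
        assert np.std(pooled) == pytest.approx(1.0, abs=0.12)


class TestTruncationProbability:
    def test_published_complement_value(self):
        assert truncation_probability_hat(0.1, 0.0, 1.0) == pytest.approx(0.011, abs=5e-4)

    def test_zero_when_no_heterogeneity(self):
        assert truncation_probability_hat(0.4, 0.5, 0.0) == 0.0

    def test_vanishes_for_very_negative_effect(self):
        assert truncation_probability_hat(0.3, -40.0, 1.0) == pytest.approx(0.0)

    def test_limit_as_control_rate_approaches_one(self):
        from scipy.stats import norm

        theta, tau = 0.5, 1.0
        val = truncation_probability_hat(1.0 - 1e-12, theta, tau)
        assert val == pytest.approx(1 - norm.cdf(-theta / tau), abs=1e-6)

    def test_strictly_increasing_in_control_rate(self):
        ps = [truncation_probability_hat(p, 0.3, 0.8) for p in np.linspace(0.05, 0.95, 10)]
        assert all(a < b for a, b in zip(ps, ps[1:]))


class TestBinning:
    def _records(self, p_values, theta_m=0.2):
        n = len(p_values)
        return pd.DataFrame(
            {
                "ma_id": ["m"] * n, "study_id": [str(i) for i in range(n)],
                "theta_mj": np.zeros(n), "v_mj": np.ones(n),
                "theta_m": np.full(n, theta_m), "tau2_m": np.ones(n),
                "r_mj": np.linspace(-1, 1, n), "p_trunc": np.array(p_values),
                "bin": pd.cut(
                    np.array(p_values),
                    [0.0, 0.05, 0.15, 0.25, 0.35, 0.45, 0.55, 0.65, 0.75, 0.85, 1.01],
                    right=False,
                    labels=["<0.05", "[0.05-0.15)", "[0.15-0.25)", "[0.25-0.35)",
                            "[0.35-0.45)", "[0.45-0.55)", "[0.55-0.65)",
                            "[0.65-0.75)", "[0.75-0.85)", ">=0.85"],
                ).astype(str),
            }
        )

    def test_all_below_first_edge_single_cell(self):
        tab = bin_and_tabulate(self._records([0.01, 0.02, 0.04]))
        counts = tab["counts"]["total"]
        assert counts["<0.05"] == 3
        assert counts.drop("<0.05").sum() == 0

    def test_half_open_edges(self):
        tab = bin_and_tabulate(self._records([0.05, 0.1499, 0.15, 0.85]))
        counts = tab["counts"]["total"]
        assert counts["[0.05-0.15)"] == 2
        assert counts["[0.15-0.25)"] == 1
        assert counts[">=0.85"] == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no screen records"):
            bin_and_tabulate(pd.DataFrame())


class TestScreenPipeline:
    def test_arm_size_and_k_filters(self):
        tiny = MetaDataset(
            (StudyTable(1, 3, 2, 3, "a"), StudyTable(5, 50, 8, 50, "b"),
             StudyTable(6, 50, 7, 50, "c")),
            ma_id="m1",
        )
        rec = screen_meta_analysis(tiny, ScreenConfig(min_k=3, min_arm_size=5))
        assert rec.empty  # only 2 studies survive the arm filter

    def test_tau2_zero_filtered_when_required(self):
        homog = MetaDataset(
            tuple(StudyTable(10, 100, 10, 100, str(j)) for j in range(5)), ma_id="m")
        assert screen_meta_analysis(homog, ScreenConfig()).empty
        rec = screen_meta_analysis(homog, ScreenConfig(require_positive_tau2=False))
        assert len(rec) == 5
        assert (rec.p_trunc == 0).all()  # tau-hat = 0 -> probability defined as 0

    def test_heavy_truncation_shifts_residuals_down_across_bins(self):
        """Residual medians drift negative as the truncation probability grows."""
        design = SimDesign(k=10, n=400, theta=1.0, pi_c=0.3, tau2=1.0,
                           option="point_mass", reps=1, seed=0)
        coll = make_synthetic_collection(300, design, seed=55)
        records = screen_collection(coll, ScreenConfig())
        assert not records.empty
        med = records.groupby("bin", observed=True)["r_mj"].median()
        low = med.get("<0.05", np.nan)
        high_bins = [b for b in med.index if b not in ("<0.05", "[0.05-0.15)")]
        assert np.nanmean([med[b] for b in high_bins]) < low

    def test_collection_determinism(self):
        d = SimDesign(k=5, n=100, theta=0.0, pi_c=0.1, tau2=0.1,
                      option="truncation", reps=1, seed=0)
        a = make_synthetic_collection(5, d, seed=9)
        b = make_synthetic_collection(5, d, seed=9)
        for x, y in zip(a, b):
            assert [(s.y_c, s.y_t) for s in x] == [(s.y_c, s.y_t) for s in y]
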