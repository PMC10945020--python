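"""Central-composite design recovery, quadratic fit, ANOVA identities."""

import itertools

import numpy as np
import pytest

from hsiatp.rsm import (
    DEFAULT_FACTORS,
    REFERENCE_CODED_COEFFICIENTS,
    anova,
    build_design,
    fit_quadratic,
    load_packaged_design,
    model_matrix,
    pareto_effects,
    predict,
    surface_grid,
    term_names,
)
from hsiatp.synthetic_data import generate_ccd_responses


class TestBuildDesign:
    def setup_method(self):
        self.table = load_packaged_design()
        self.design = build_design(self.table)

    def test_structure_16_cube_10_axial_6_centre(self):
        levels = np.abs(self.design.coded).max(axis=1)
        assert (levels == 1).sum() == 16
        assert (levels == 2).sum() == 10
        assert (levels == 0).sum() == 6

    def test_known_runs_coded_correctly(self):
        runs = dict(zip(self.design.run_ids, self.design.coded))
        assert runs[24].tolist() == [2, 0, 0, 0, 0]
        assert runs[7].tolist() == [-1, 1, -1, 1, 1]
        centre_runs = [r for r, c in runs.items() if np.all(c == 0)]
        assert sorted(centre_runs) == [1, 6, 11, 26, 28, 29]

    def test_rounded_settings_snap_to_canonical_levels(self):
        # the orange-extract +1 level is printed variously as 0.41/0.42/0.43
        eps = self.table["orange_extract"].to_numpy()
        coded_eps = self.design.coded[:, 4]
        assert set(np.round(eps[coded_eps == 1], 2)) >= {0.41, 0.42, 0.43}

    def test_off_design_run_rejected(self):
        bad = self.table.copy()
        bad.loc[0, "soy_lecithin"] = 3.9  # half-way between levels
        with pytest.raises(ValueError, match="soy_lecithin"):
            build_design(bad)

    def test_coded_uncoded_roundtrip(self):
        natural = self.design.uncoded()
        again = build_design(
            self.table.assign(
                **{f.name: natural[:, i] for i, f in enumerate(DEFAULT_FACTORS)}
            )
        )
        assert np.array_equal(again.coded, self.design.coded)


class TestFitQuadratic:
    def setup_method(self):
        self.design = build_design(load_packaged_design())
        self.model = fit_quadratic(self.design)

    def test_reproduces_published_coefficients(self):
        assert self.model.coefficients[0] == pytest.approx(-5.539, abs=0.02)
        idx = term_names().index("alpha*epsilon")
        assert self.model.coefficients[idx] == pytest.approx(0.948, abs=0.02)
        assert self.model.se[idx] == pytest.approx(0.338, abs=0.01)
        assert self.model.p_values[idx] == pytest.approx(0.017, abs=0.005)

    def test_residual_degrees_of_freedom(self):
        assert self.model.df_resid == 11

    def test_coded_and_uncoded_predictions_identical(self):
        natural = self.design.uncoded()
        coded_pred = predict(self.model, self.design.coded, coded=True)
        natural_pred = predict(self.model, natural, coded=False)
        assert np.max(np.abs(coded_pred - natural_pred)) < 1e-10

    def test_noise_free_synthetic_coefficients_recovered_exactly(self):
        truth = REFERENCE_CODED_COEFFICIENTS
        y = generate_ccd_responses(self.design, truth, 0.0, seed=0)
        import dataclasses

        refit = fit_quadratic(dataclasses.replace(self.design, response=y))
        assert np.max(np.abs(refit.coefficients - truth)) < 1e-10
        assert refit.degenerate

    def test_rank_deficient_design_rejected(self):
        import dataclasses

        broken = dataclasses.replace(
            self.design, coded=np.zeros_like(self.design.coded)
        )
        with pytest.raises(ValueError, match="rank"):
            fit_quadratic(broken)


class TestAnova:
    def setup_method(self):
        self.design = build_design(load_packaged_design())
        self.model = fit_quadratic(self.design)
        self.table = anova(self.model).set_index("term")

    def test_published_sums_of_squares(self):
        assert self.table.loc["Total", "seq_ss"] == pytest.approx(68.8873, abs=0.2)
        assert self.table.loc["Error", "seq_ss"] == pytest.approx(20.1332, abs=0.15)
        assert self.table.loc["Pure Error", "seq_ss"] == pytest.approx(6.3843, abs=0.05)
        assert self.table.loc["alpha*epsilon", "seq_ss"] == pytest.approx(14.3758, abs=0.1)
        assert self.table.loc["alpha*epsilon", "contribution_pct"] == pytest.approx(
            20.87, abs=0.3
        )

    def test_ss_and_df_additivity(self):
        terms = self.table.drop(index=["Error", "Lack-of-fit", "Pure Error", "Total"])
        assert terms["seq_ss"].sum() + self.table.loc["Error", "seq_ss"] == pytest.approx(
            self.table.loc["Total", "seq_ss"], abs=1e-8
        )
        assert terms["df"].sum() + self.table.loc["Error", "df"] == 31
        assert (
            self.table.loc["Lack-of-fit", "seq_ss"] + self.table.loc["Pure Error", "seq_ss"]
            == pytest.approx(self.table.loc["Error", "seq_ss"], abs=1e-10)
        )
        assert self.table.loc["Lack-of-fit", "df"] == 6
        assert self.table.loc["Pure Error", "df"] == 5

    def test_contributions_sum_to_hundred(self):
        rows = self.table.drop(index=["Lack-of-fit", "Pure Error", "Total"])
        assert rows["contribution_pct"].sum() == pytest.approx(100.0, abs=1e-8)

    def test_lack_of_fit_insignificant(self):
        assert self.table.loc["Lack-of-fit", "p"] > 0.05

    def test_sequential_equals_adjusted_for_orthogonal_terms(self):
        """Linear and interaction columns are orthogonal to the rest of this
        CCD, so their type-I and type-III sums of squares coincide."""
        syms = [f.symbol for f in DEFAULT_FACTORS]
        orth = syms + [f"{a}*{b}" for a, b in itertools.combinations(syms, 2)]
        for t in orth:
            assert self.table.loc[t, "seq_ss"] == pytest.approx(
                self.table.loc[t, "adj_ss"], abs=1e-8
            )


class TestPredictAndGrid:
    def setup_method(self):
        self.model = fit_quadratic(build_design(load_packaged_design()))

    def test_centre_prediction(self):
        assert predict(self.model, [0, 0, 0, 0, 0])[0] == pytest.approx(-5.54, abs=0.05)
        assert predict(self.model, [0, 0, 0, 0, 0])[0] == self.model.coefficients[0]

    def test_axial_and_cube_run_predictions(self):
        assert predict(self.model, [2, 0, 0, 0, 0])[0] == pytest.approx(-4.84, abs=0.05)
        assert predict(self.model, [-1, 1, -1, 1, 1])[0] == pytest.approx(-9.33, abs=0.05)

    def test_random_points_match_polynomial_oracle(self, rng):
        pts = rng.uniform(-2, 2, size=(100, 5))
        got = predict(self.model, pts)
        beta = self.model.coefficients
        for pt, val in zip(pts, got):
            expected = beta[0]
            expected += sum(beta[1 + i] * pt[i] for i in range(5))
            expected += sum(beta[6 + i] * pt[i] ** 2 for i in range(5))
            for k, (i, j) in enumerate(itertools.combinations(range(5), 2)):
                expected += beta[11 + k] * pt[i] * pt[j]
            assert val == pytest.approx(expected, abs=1e-10)

    def test_extrapolation_warns(self):
        with pytest.warns(UserWarning, match="coded design region"):
            predict(self.model, [3, 0, 0, 0, 0])

    def test_grid_corners_and_centre(self):
        grid = surface_grid(self.model, (0, 4), n_grid=5)
        corner = grid.iloc[0]
        assert corner["atp_predicted"] == pytest.approx(
            predict(self.model, [-2, 0, 0, 0, -2])[0]
        )
        centre = grid[(grid["soy_lecithin_coded"] == 0) & (grid["orange_extract_coded"] == 0)]
        assert centre["atp_predicted"].iloc[0] == pytest.approx(-5.54, abs=0.05)

    def test_grid_symmetric_in_pair_ordering(self):
        a = surface_grid(self.model, (0, 4), n_grid=9)["atp_predicted"].to_numpy()
        b = surface_grid(self.model, (4, 0), n_grid=9)["atp_predicted"].to_numpy()
        assert np.allclose(np.sort(a), np.sort(b))

    def test_duplicate_factor_pair_rejected(self):
        with pytest.raises(ValueError):
            surface_grid(self.model, (2, 2))


class TestParetoEffects:
    def setup_method(self):
        self.design = build_design(load_packaged_design())
        self.model = fit_quadratic(self.design)

    def test_lecithin_orange_interaction_ranks_first(self):
        ranking = pareto_effects(self.model)
        assert ranking.iloc[0]["term"] == "alpha*epsilon"
        assert bool(ranking.iloc[0]["significant"])

    def test_ranking_matches_coef_over_se_oracle(self):
        ranking = pareto_effects(self.model)
        t_oracle = np.abs(self.model.coefficients[1:]) / self.model.se[1:]
        assert np.allclose(ranking["abs_t"].to_numpy(), np.sort(t_oracle)[::-1])

    def test_degenerate_noise_free_fit_flagged(self):
        import dataclasses

        y = model_matrix(self.design.coded) @ REFERENCE_CODED_COEFFICIENTS
        refit = fit_quadratic(dataclasses.replace(self.design, response=y))
        ranking = pareto_effects(refit)
        assert ranking.attrs["degenerate"]
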