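"""Hydrophobicity design generation, quadratic surface fit, enumeration."""

import itertools

import numpy as np
import pandas as pd
import pytest

import pepmaps as pm
from pepmaps.design import TERM_NAMES, expand_quadratic
from pepmaps.simulate import gen_design_responses

BETA_TRUE = np.array([70.0, 3.0, 8.0, -2.0, -5.0, -35.0, -4.0, 1.5, -1.0, 2.5])


class TestGenerateDesign:
    def test_fifteen_unique_points(self, design_15):
        assert len(design_15) == 15
        assert len(design_15.drop_duplicates()) == 15

    def test_coordinate_sums_vanish(self, design_15):
        np.testing.assert_allclose(design_15.sum(), 0.0, atol=1e-12)

    def test_eight_factorial_corners(self, design_15):
        corners = (design_15.abs() == 1.0).all(axis=1)
        assert corners.sum() == 8

    def test_six_face_centers_one_center(self, design_15):
        nonzero = (design_15 != 0).sum(axis=1)
        assert (nonzero == 1).sum() == 6
        assert (nonzero == 0).sum() == 1

    def test_symmetric_under_axis_sign_flips(self, design_15):
        pts = {tuple(p) for p in design_15.to_numpy()}
        for flips in itertools.product((1, -1), repeat=3):
            flipped = {tuple(np.array(p) * flips) for p in pts}
            assert flipped == pts

    def test_expanded_matrix_is_well_conditioned(self, design_15):
        Z = expand_quadratic(design_15.to_numpy())
        assert np.linalg.cond(Z) < 1e3


class TestAssignResidues:
    def test_high_level_picks_most_hydrophobic(self, scale):
        assert pm.assign_residues((1, 1, 1), scale, {"I", "F", "W"}) == "WWW"

    def test_mid_level_prefers_proline_over_alanine(self, scale):
        # |v3(P) - 0| = 0.059 beats |v3(A) - 0| = 0.194
        assert pm.assign_residues((0, 0, 0), scale, {"A", "P"}) == "PPP"

    def test_empty_pool_rejected(self, scale):
        with pytest.raises(ValueError, match="pool"):
            pm.assign_residues((0, 0, 0), scale, set())

    def test_pool_is_case_insensitive_and_deduplicated(self, scale):
        assert pm.assign_residues((1, 1, 1), scale, ["w", "W", "i"]) == "WWW"

    def test_exact_level_match_wins(self, scale):
        level = scale.v3("K")
        assert pm.assign_residues((level,) * 3, scale, {"R", "K", "A"}) == "KKK"


class TestFitQuadratic:
    def test_noiseless_beta_recovery(self, design_15):
        responses = gen_design_responses(design_15, BETA_TRUE, 0.0, seed=0)
        model = pm.fit_quadratic(design_15, responses["response_pct"])
        np.testing.assert_allclose(model.beta, BETA_TRUE, atol=1e-8)

    def test_corners_only_design_is_rank_deficient(self, design_15):
        corners = design_15[(design_15.abs() == 1.0).all(axis=1)]
        with pytest.raises(ValueError, match="rank-deficient"):
            pm.fit_quadratic(corners, np.arange(len(corners), dtype=float))

    def test_length_mismatch_rejected(self, design_15):
        with pytest.raises(ValueError, match="length"):
            pm.fit_quadratic(design_15, np.zeros(7))

    def test_position2_signal_yields_b2_b5_significance(self, design_15):
        """Responses driven only by the middle position's hydrophobicity
        (linear + quadratic) flag y and y^2 at alpha = 0.05 in at least
        90% of low-noise replicates, while each null term is flagged at
        no more than its nominal false-positive rate (which multiplicity
        makes unavoidable in a fraction of replicates)."""
        beta = np.array([60.0, 0, 10.0, 0, 0, -30.0, 0, 0, 0, 0])
        hits = 0
        null_flags = 0
        n_rep = 20
        null_terms = set(TERM_NAMES) - {"b0", "y", "y^2"}
        for rep in range(n_rep):
            responses = gen_design_responses(design_15, beta, 1.0, seed=rep)
            model = pm.fit_quadratic(design_15, responses["response_pct"])
            flagged = set(model.significant_terms())
            if {"y", "y^2"} <= flagged:
                hits += 1
            null_flags += len(flagged & null_terms)
        assert hits >= 0.9 * n_rep
        assert null_flags / (n_rep * len(null_terms)) <= 0.15


@pytest.fixture(scope="module")
def model(design_15):
    responses = gen_design_responses(design_15, BETA_TRUE, 0.0, seed=0)
    return pm.fit_quadratic(design_15, responses["response_pct"])


@pytest.fixture(scope="module")
def pro2_model():
    """Surface maximized when position 2 sits at proline's v3 level."""
    beta = np.array([80.0, 0, 0, 0, 0, -60.0, 0, 0, 0, 0])
    # peak of -60 (y - 0.0599)^2 expanded: add the linear term 2*60*0.0599
    beta[2] = 2 * 60.0 * 0.0599
    return pm.QuadraticModel(
        beta=beta, p_values=np.ones(10), residuals=np.empty(0),
        fitted=np.empty(0), points=np.empty((0, 3)),
    )


class TestPredict:
    def test_center_point_predicts_intercept(self, model):
        raw, _ = pm.predict_percent_inhibition(model, levels=(0.0, 0.0, 0.0))
        assert raw == pytest.approx(model.beta[0])

    def test_constant_model_predicts_constant(self):
        flat = pm.QuadraticModel(
            beta=np.r_[50.0, np.zeros(9)], p_values=np.ones(10),
            residuals=np.empty(0), fitted=np.empty(0), points=np.empty((0, 3)),
        )
        raw, clipped = pm.predict_percent_inhibition(flat, levels=(0.7, -0.3, 1.0))
        assert raw == clipped == 50.0

    def test_out_of_range_predictions_are_clipped_not_lost(self):
        hot = pm.QuadraticModel(
            beta=np.r_[132.0, np.zeros(9)], p_values=np.ones(10),
            residuals=np.empty(0), fitted=np.empty(0), points=np.empty((0, 3)),
        )
        raw, clipped = pm.predict_percent_inhibition(hot, levels=(0, 0, 0))
        assert raw == pytest.approx(132.0)
        assert clipped == 100.0

    def test_non_tripeptide_rejected(self, model, scale):
        with pytest.raises(ValueError, match="tripeptide"):
            pm.predict_percent_inhibition(model, peptide="IPIW", scale=scale)


class TestEnumerate:
    def test_fixed_position2_space_is_400(self, pro2_model, scale):
        table = pm.enumerate_and_rank(pro2_model, scale, position2="P")
        assert len(table) == 400
        assert table["peptide"].str[1].eq("P").all()
        assert table["peptide"].is_unique

    def test_free_space_is_8000_unique(self, pro2_model, scale):
        table = pm.enumerate_and_rank(pro2_model, scale)
        assert len(table) == 8000
        assert table["peptide"].is_unique

    def test_proline_dominates_top_candidates(self, pro2_model, scale):
        """Brute-force check: a surface penalizing |y - v3(P)| puts P at
        position 2 throughout the top of the free ranking."""
        table = pm.enumerate_and_rank(pro2_model, scale)
        assert table.head(20)["peptide"].str[1].eq("P").all()

    def test_ranking_is_sorted_with_alphabetical_ties(self, pro2_model, scale):
        table = pm.enumerate_and_rank(pro2_model, scale, position2="P")
        pct = table["predicted_pct"].to_numpy()
        assert np.all(np.diff(pct) <= 1e-12)
        assert list(table["rank"]) == list(range(1, 401))

    def test_threshold_bounds_enforced(self, pro2_model, scale):
        with pytest.raises(ValueError, match="threshold"):
            pm.enumerate_and_rank(pro2_model, scale, threshold=120.0)


class TestEndToEnd:
    def test_design_to_enumeration_recovers_optimum(self, design_15, scale):
        """Simulate the full loop: design, assign residues, measure with 5%
        noise, fit, enumerate; the model's prediction at the true optimum
        stays within one noise SD of that optimum's true response in >= 90%
        of replicates."""
        pool = {"I", "F", "R", "K", "A", "P"}
        truth_model = pm.QuadraticModel(
            beta=BETA_TRUE, p_values=np.ones(10), residuals=np.empty(0),
            fitted=np.empty(0), points=np.empty((0, 3)),
        )
        best = pm.enumerate_and_rank(truth_model, scale).iloc[0]
        x_star = np.array([[best.x, best.y, best.z]])
        truth = float(np.clip(expand_quadratic(x_star)[0] @ BETA_TRUE, 0, 100))
        ok = 0
        n_rep = 20
        for rep in range(n_rep):
            responses = gen_design_responses(design_15, BETA_TRUE, 5.0, seed=rep)
            responses["peptide"] = [
                pm.assign_residues(tuple(p), scale, pool)
                for p in design_15.to_numpy()
            ]
            model = pm.fit_quadratic(design_15, responses["response_pct"])
            pred = float(np.clip(expand_quadratic(x_star)[0] @ model.beta, 0, 100))
            if abs(pred - truth) <= 5.0:
                ok += 1
        assert ok >= 0.9 * n_rep
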