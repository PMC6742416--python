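"""Per-sample fine-mapping: cohort scoring, ranking, correlations, and
region reports."""

import numpy as np
import pandas as pd
import pytest

from gram import finemap
from gram.io import GramModelBundle
from gram.simulate import simulate_cohort


@pytest.fixture(scope="module")
def cohort(small_config):
    return simulate_cohort(small_config, n_variants=12, n_samples=10, seed=2)


@pytest.fixture(scope="module")
def cohort_input(cohort):
    return finemap.CohortInput(
        region="chr6:1000-2000",
        genotypes=cohort.genotypes,
        expression=cohort.expression,
        eqtl_targets=cohort.eqtl_targets,
        target_expression=cohort.target_expression,
    )


def null_bundle_like(bundle):
    return GramModelBundle(
        step1_model=bundle.step1_model,
        step2_binding_model=bundle.step2_binding_model,
        step2_expression_model=bundle.step2_expression_model,
        b_u=0.0, b_s1=0.0, b_s2=0.0, b0=0.0, lambda_=1.0,
        tf_ids=bundle.tf_ids,
    )


class TestScoreCohort:
    def test_identical_expression_gives_identical_columns(self, cohort, cohort_input,
                                                          small_bundle):
        expr = dict(cohort.expression)
        s0 = list(expr)[0]
        clone = finemap.CohortInput(
            region="r",
            genotypes=cohort.genotypes,
            expression={s: expr[s0] for s in cohort.genotypes.index},
            eqtl_targets=cohort.eqtl_targets,
            target_expression=cohort.target_expression,
        )
        mat = finemap.score_cohort(clone, small_bundle, cohort.bsm)
        first = mat.iloc[:, 0]
        assert all(np.array_equal(first, mat.iloc[:, j]) for j in range(mat.shape[1]))

    def test_null_coefficients_give_half_everywhere(self, cohort_input, cohort,
                                                    small_bundle):
        mat = finemap.score_cohort(cohort_input, null_bundle_like(small_bundle), cohort.bsm)
        assert np.allclose(mat.to_numpy(float), 0.5)

    def test_carriers_only_masks_noncarriers_and_agrees_elsewhere(
        self, cohort_input, cohort, small_bundle
    ):
        full = finemap.score_cohort(cohort_input, small_bundle, cohort.bsm)
        carriers = finemap.score_cohort(
            cohort_input, small_bundle, cohort.bsm, mode="carriers_only"
        )
        dosage = cohort.genotypes.T  # variants x samples
        masked = carriers.isna()
        assert masked.equals((dosage == 0).loc[carriers.index, carriers.columns])
        both = carriers.notna()
        assert np.array_equal(full.to_numpy()[both.to_numpy()],
                              carriers.to_numpy()[both.to_numpy()])

    def test_unknown_variant_rejected(self, cohort_input, small_bundle, small_dataset):
        with pytest.raises(ValueError, match="lacks variants"):
            finemap.score_cohort(cohort_input, small_bundle, small_dataset.bsm)


class TestRankVariants:
    def test_constant_matrix_ranked_by_id(self):
        mat = pd.DataFrame(0.5, index=["b", "a", "c"], columns=["s1", "s2"])
        ranking, mean = finemap.rank_variants(mat)
        assert ranking == ["a", "b", "c"]
        assert np.allclose(mean, 0.5)

    def test_single_sample_ranks_by_that_column(self):
        mat = pd.DataFrame({"s1": [0.2, 0.9, 0.5]}, index=["a", "b", "c"])
        ranking, _ = finemap.rank_variants(mat)
        assert ranking == ["b", "c", "a"]

    def test_agrees_with_brute_force_sort(self, rng):
        mat = pd.DataFrame(
            rng.random((8, 5)), index=[f"v{i}" for i in range(8)],
            columns=[f"s{j}" for j in range(5)],
        )
        ranking, mean = finemap.rank_variants(mat)
        brute = sorted(mat.index, key=lambda v: (-mat.loc[v].mean(), v))
        assert ranking == brute


class TestCorrelations:
    def test_exactly_linear_scores_give_r_one(self):
        expr = pd.DataFrame({"G": [1.0, 2.0, 3.0, 4.0]}, index=list("wxyz"))
        mat = pd.DataFrame([[0.1, 0.2, 0.3, 0.4]], index=["v"], columns=list("wxyz"))
        out = finemap.correlate_scores_expression(mat, expr, {"v": "G"})
        assert out.r.iloc[0] == pytest.approx(1.0)
        assert out.p_value.iloc[0] < 0.05

    def test_constant_series_reported_missing(self):
        expr = pd.DataFrame({"G": [2.0, 2.0, 2.0, 2.0]}, index=list("wxyz"))
        mat = pd.DataFrame([[0.1, 0.2, 0.3, 0.4]], index=["v"], columns=list("wxyz"))
        out = finemap.correlate_scores_expression(mat, expr, {"v": "G"})
        assert np.isnan(out.r.iloc[0])
        assert out.reason.iloc[0] == "constant series"

    def test_too_few_pairs_reported_missing(self):
        expr = pd.DataFrame({"G": [1.0, 2.0, 3.0]}, index=list("wxy"))
        mat = pd.DataFrame([[0.1, np.nan, np.nan]], index=["v"], columns=list("wxy"))
        out = finemap.correlate_scores_expression(mat, expr, {"v": "G"})
        assert "fewer than 3" in out.reason.iloc[0]

    def test_hand_computed_five_point_table(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        expr = pd.DataFrame({"G": y}, index=list("abcde"))
        mat = pd.DataFrame([x], index=["v"], columns=list("abcde"))
        out = finemap.correlate_scores_expression(mat, expr, {"v": "G"})
        # textbook formula
        r_hand = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert out.r.iloc[0] == pytest.approx(r_hand)


class TestRegionReport:
    def test_two_regions_two_reports(self, tmp_path, cohort, cohort_input, small_bundle):
        res = finemap.finemap_region(cohort_input, small_bundle, cohort.bsm)
        res2 = finemap.FineMapResult(
            region="chr1:5-6", score_matrix=res.score_matrix,
            mean_score=res.mean_score, ranking=res.ranking,
            correlations=res.correlations,
        )
        paths = finemap.render_region_report(
            {res.region: res, res2.region: res2}, tmp_path, plot=True
        )
        assert sum(p.suffix == ".png" for p in paths) == 2
        assert sum(p.name.endswith(".scores.tsv") for p in paths) == 2
        long = pd.read_csv([p for p in paths if p.name.endswith(".scores.tsv")][0], sep="\t")
        assert len(long) == res.score_matrix.size  # variants x samples long form

    def test_summary_contains_ranks_and_correlations(self, tmp_path, cohort,
                                                     cohort_input, small_bundle):
        res = finemap.finemap_region(cohort_input, small_bundle, cohort.bsm)
        paths = finemap.render_region_report(res, tmp_path, plot=False)
        summary = pd.read_csv(
            [p for p in paths if p.name.endswith(".summary.tsv")][0], sep="\t"
        )
        assert list(summary["rank"]) == list(range(1, len(summary) + 1))
        assert {"mean_score", "r", "p_value"} <= set(summary.columns)
        assert summary.variant_id.iloc[0] == res.ranking[0]

    def test_empty_region_writes_header_only_no_plot(self, tmp_path):
        empty = finemap.FineMapResult(
            region="empty", score_matrix=pd.DataFrame(columns=["s1"]),
            mean_score=pd.Series(dtype=float), ranking=[],
            correlations=pd.DataFrame(
                columns=["variant_id", "target_gene", "r", "p_value", "reason"]
            ),
        )
        empty.score_matrix.index.name = "variant_id"
        paths = finemap.render_region_report(empty, tmp_path, plot=True)
        assert not any(p.suffix == ".png" for p in paths)
        long = pd.read_csv([p for p in paths if p.name.endswith(".scores.tsv")][0], sep="\t")
        assert len(long) == 0

    def test_sample_mismatch_rejected(self, cohort):
        with pytest.raises(ValueError, match="expression"):
            finemap.CohortInput(
                region="r", genotypes=cohort.genotypes, expression={},
                eqtl_targets=cohort.eqtl_targets,
                target_expression=cohort.target_expression,
            )
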