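import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from segstab.bayes import MCMCConfig, PosteriorSummary
from segstab.classify import (
    classifications_to_frame,
    classify_genotype,
    classify_interval,
    count_classes,
    render_report,
)
from segstab.datasets import PUBLISHED_GRAND_MEAN, published_posterior_intervals
from segstab.errors import InputError


def summary_from_row(row) -> PosteriorSummary:
    """Posterior summary reconstructed from a published-intervals table row."""
    table = pd.DataFrame(
        {
            "beta0": {"mean": row["b0_mean"], "sd": float("nan"),
                      "lower": row["b0_lower"], "upper": row["b0_upper"]},
            "beta1": {"mean": row["b1_mean"], "sd": float("nan"),
                      "lower": row["b1_lower"], "upper": row["b1_upper"]},
            "beta12": {"mean": row["b12_mean"], "sd": float("nan"),
                       "lower": row["b12_lower"], "upper": row["b12_upper"]},
            "sigma2_d": {"mean": row["s2d_mean"], "sd": float("nan"),
                         "lower": row["s2d_lower"], "upper": row["s2d_upper"]},
        }
    ).T
    return PosteriorSummary(
        genotype=row["genotype"], table=table, r_squared=row["r2"]
    )


class TestClassifyInterval:
    @pytest.mark.parametrize(
        "lower, upper, expected",
        [(0.54, 0.88, "below"), (0.81, 1.17, "contains"), (1.46, 1.80, "above")],
    )
    def test_published_examples(self, lower, upper, expected):
        assert classify_interval(lower, upper, 1.0) == expected

    def test_closed_endpoints_count_as_contains(self):
        assert classify_interval(0.42, 1.00, 1.0) == "contains"
        assert classify_interval(1.00, 1.30, 1.0) == "contains"

    def test_invalid_interval(self):
        with pytest.raises(InputError):
            classify_interval(2.0, 1.0, 1.0)

    @given(
        lower=st.floats(-10, 10, allow_nan=False),
        width=st.floats(0, 10, allow_nan=False),
        ref=st.floats(-10, 10, allow_nan=False),
    )
    @settings(max_examples=200, derandomize=True)
    def test_reflection_antisymmetry(self, lower, width, ref):
        upper = lower + width
        direct = classify_interval(lower, upper, ref)
        mirrored = classify_interval(-upper, -lower, -ref)
        swap = {"below": "above", "above": "below", "contains": "contains"}
        assert mirrored == swap[direct]


class TestPublishedCounts:
    """The printed credible intervals reproduce the published narrative counts."""

    @pytest.mark.parametrize("prior_set, equal_count", [("M1", 14), ("M2", 11)])
    def test_beta1_equal_one_counts(self, prior_set, equal_count):
        rows = published_posterior_intervals(prior_set)
        cls = [
            classify_genotype(summary_from_row(row), PUBLISHED_GRAND_MEAN)
            for _, row in rows.iterrows()
        ]
        counts = count_classes(cls)
        assert counts["beta1"]["equal_one"] == equal_count
        assert sum(counts["beta1"].values()) == 25

    def test_published_recommendations(self):
        rows = published_posterior_intervals("M2").set_index("genotype")
        low_input = classify_genotype(
            summary_from_row(rows.loc["P4285HX"].to_dict() | {"genotype": "P4285HX"}),
            PUBLISHED_GRAND_MEAN,
        )
        assert low_input.beta1_class == "below_one"
        assert low_input.high_mean
        assert low_input.recommendation == "unfavorable_adapted"

        high_input = classify_genotype(
            summary_from_row(rows.loc["30A68HX"].to_dict() | {"genotype": "30A68HX"}),
            PUBLISHED_GRAND_MEAN,
        )
        assert high_input.beta1_class == "equal_one"
        assert high_input.response_class == "above_one"
        assert high_input.recommendation == "improvement_responsive"

    def test_no_published_genotype_is_stable(self):
        for prior_set in ("M1", "M2"):
            rows = published_posterior_intervals(prior_set)
            cls = [
                classify_genotype(summary_from_row(row), PUBLISHED_GRAND_MEAN)
                for _, row in rows.iterrows()
            ]
            assert all(c.stability_class == "nonzero" for c in cls)


class TestClassifyGenotype:
    def test_low_mean_blocks_general_recommendation(self):
        summary = PosteriorSummary(
            genotype="X",
            table=pd.DataFrame(
                {
                    "beta0": {"mean": 8000.0, "sd": 1.0, "lower": 7900.0, "upper": 8100.0},
                    "beta1": {"mean": 1.0, "sd": 0.1, "lower": 0.9, "upper": 1.1},
                    "beta12": {"mean": 1.0, "sd": 0.1, "lower": 0.9, "upper": 1.1},
                    "sigma2_d": {"mean": 0.0, "sd": 1.0, "lower": -1.0, "upper": 1.0},
                }
            ).T,
            r_squared=90.0,
        )
        cls = classify_genotype(summary, grand_mean=8500.0)
        assert not cls.high_mean
        assert cls.recommendation == "none"
        assert cls.stability_class == "zero"

    def test_missing_interval_rejected(self):
        summary = PosteriorSummary(
            genotype="X",
            table=pd.DataFrame(
                {"beta0": {"mean": 1.0, "sd": 1.0, "lower": 0.0, "upper": 2.0}}
            ).T,
            r_squared=50.0,
        )
        with pytest.raises(InputError):
            classify_genotype(summary, grand_mean=0.0)


class TestCountsAndReport:
    def test_counts_sum_to_total(self):
        rows = published_posterior_intervals()
        cls = [
            classify_genotype(summary_from_row(row), PUBLISHED_GRAND_MEAN)
            for _, row in rows.iterrows()
        ]
        counts = count_classes(cls)
        assert sum(counts["beta1"].values()) == 50
        assert sum(counts["response"].values()) == 50

    def test_empty_list_rejected(self):
        with pytest.raises(InputError):
            count_classes([])
        with pytest.raises(InputError):
            render_report([], [])

    def test_report_renders_deterministically(self):
        rows = published_posterior_intervals("M2")
        summaries = [summary_from_row(row) for _, row in rows.iterrows()]
        cls = [classify_genotype(s, PUBLISHED_GRAND_MEAN) for s in summaries]
        r1 = render_report(summaries, cls)
        r2 = render_report(summaries, cls)
        assert r1 == r2
        for geno in rows["genotype"]:
            assert geno in r1

    def test_report_rejects_mismatched_sets(self):
        rows = published_posterior_intervals("M2")
        summaries = [summary_from_row(row) for _, row in rows.iterrows()]
        cls = [classify_genotype(s, PUBLISHED_GRAND_MEAN) for s in summaries[:-1]]
        with pytest.raises(InputError):
            render_report(summaries, cls)
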