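"""Adaptability/stability verdicts and recommendation labels.

A genotype's credible intervals are tested against reference values:

* beta1 (slope in unfavorable environments) against 1;
* beta1 + beta2 (slope in favorable environments) against 1;
* the stability parameter sigma2_d against 0;

with closed-interval containment (an endpoint exactly at the reference counts
as "contains").  Together with whether R^2 exceeds a threshold (default 80%)
and whether the posterior mean intercept exceeds the trial grand mean, these
yield a recommendation:

* ``unfavorable_adapted`` — slope below 1 in poor environments and high mean
  yield: suited to low-input farming;
* ``improvement_responsive`` — average response in poor environments, slope
  above 1 in favorable ones, high mean yield: suited to high-input farming;
* ``general`` — average response in both regimes with high mean yield;
* ``none`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .anova import AnovaTable
from .bayes import PosteriorSummary
from .errors import InputError

__all__ = [
    "GenotypeClassification",
    "classify_interval",
    "classify_genotype",
    "count_classes",
    "render_report",
]


@dataclass(frozen=True)
class GenotypeClassification:
    genotype: str
    beta1_class: str        # below_one | equal_one | above_one
    response_class: str     # beta1+beta2 vs 1
    stability_class: str    # zero | nonzero
    high_r2: bool
    high_mean: bool
    recommendation: str     # unfavorable_adapted | improvement_responsive | general | none


def classify_interval(lower: float, upper: float, reference: float) -> str:
    """Position of a closed interval relative to a reference value."""
    if lower > upper:
        raise InputError(f"invalid interval: lower {lower} > upper {upper}")
    if upper < reference:
        return "below"
    if lower > reference:
        return "above"
    return "contains"


_VS_ONE = {"below": "below_one", "contains": "equal_one", "above": "above_one"}


def classify_genotype(
    summary: PosteriorSummary,
    grand_mean: float,
    r2_threshold: float = 80.0,
) -> GenotypeClassification:
    """Verdicts for one genotype from its posterior summary."""
    for param in ("beta1", "beta12"):
        if param not in summary.table.index:
            raise InputError(f"summary lacks an interval for {param}")
    b1 = classify_interval(*summary.interval("beta1"), 1.0)
    b12 = classify_interval(*summary.interval("beta12"), 1.0)
    if "sigma2_d" in summary.table.index:
        s2d = classify_interval(*summary.interval("sigma2_d"), 0.0)
        stability = "zero" if s2d == "contains" else "nonzero"
    else:
        stability = "nonzero"
    high_r2 = summary.r_squared > r2_threshold
    high_mean = summary.mean("beta0") > grand_mean

    beta1_class, response_class = _VS_ONE[b1], _VS_ONE[b12]
    if beta1_class == "below_one" and high_mean:
        rec = "unfavorable_adapted"
    elif beta1_class == "equal_one" and response_class == "above_one" and high_mean:
        rec = "improvement_responsive"
    elif beta1_class == "equal_one" and response_class == "equal_one" and high_mean:
        rec = "general"
    else:
        rec = "none"
    return GenotypeClassification(
        genotype=summary.genotype,
        beta1_class=beta1_class,
        response_class=response_class,
        stability_class=stability,
        high_r2=high_r2,
        high_mean=high_mean,
        recommendation=rec,
    )


def count_classes(classifications: Iterable[GenotypeClassification]) -> dict:
    """Counts of beta1 and response classes; each family sums to len(list)."""
    cls = list(classifications)
    if not cls:
        raise InputError("empty classification list")
    counts: dict = {"beta1": {}, "response": {}, "recommendation": {}}
    for c in cls:
        counts["beta1"][c.beta1_class] = counts["beta1"].get(c.beta1_class, 0) + 1
        counts["response"][c.response_class] = (
            counts["response"].get(c.response_class, 0) + 1
        )
        counts["recommendation"][c.recommendation] = (
            counts["recommendation"].get(c.recommendation, 0) + 1
        )
    return counts


def classifications_to_frame(
    classifications: Iterable[GenotypeClassification],
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genotype": c.genotype,
                "beta1_class": c.beta1_class,
                "response_class": c.response_class,
                "stability_class": c.stability_class,
                "high_r2": c.high_r2,
                "high_mean": c.high_mean,
                "recommendation": c.recommendation,
            }
            for c in classifications
        ]
    )


def render_report(
    summaries: list[PosteriorSummary],
    classifications: list[GenotypeClassification],
    anova: AnovaTable | None = None,
    dic_deltas: pd.Series | None = None,
) -> str:
    """Deterministic aligned-text report, genotypes ordered by posterior
    mean intercept, descending."""
    if not classifications:
        raise InputError("empty classification list")
    cls_by_geno = {c.genotype: c for c in classifications}
    sum_by_geno = {s.genotype: s for s in summaries}
    if set(cls_by_geno) != set(sum_by_geno):
        raise InputError("summaries and classifications cover different genotypes")

    order = sorted(summaries, key=lambda s: -s.mean("beta0"))
    lines = []
    if anova is not None:
        lines += ["Joint analysis of variance", anova.render(), ""]
    header = (
        f"{'Genotype':<12}{'b0':>10}{'b1 [95% CI]':>22}{'b1+b2 [95% CI]':>22}"
        f"{'s2_d':>14}{'R2%':>7}  {'Recommendation'}"
    )
    lines += ["Posterior summaries and classification", header]
    for s in order:
        c = cls_by_geno[s.genotype]
        b1l, b1u = s.interval("beta1")
        b12l, b12u = s.interval("beta12")
        s2d = (
            f"{s.mean('sigma2_d'):>14.0f}"
            if "sigma2_d" in s.table.index
            else f"{'':>14}"
        )
        b1_txt = f"{s.mean('beta1'):.2f} ({b1l:.2f},{b1u:.2f})"
        b12_txt = f"{s.mean('beta12'):.2f} ({b12l:.2f},{b12u:.2f})"
        lines.append(
            f"{s.genotype:<12}{s.mean('beta0'):>10.2f}{b1_txt:>22}{b12_txt:>22}"
            f"{s2d}{s.r_squared:>7.1f}  {c.recommendation}"
        )
    counts = count_classes(classifications)
    lines += [
        "",
        "Class counts (slope in unfavorable environments vs 1): "
        + ", ".join(f"{k}={v}" for k, v in sorted(counts["beta1"].items())),
        "Class counts (slope in favorable environments vs 1): "
        + ", ".join(f"{k}={v}" for k, v in sorted(counts["response"].items())),
    ]
    if dic_deltas is not None:
        lines += ["", "DIC(vague) - DIC(informative) per genotype:"]
        for geno in dic_deltas.index:
            lines.append(f"{geno:<12}{dic_deltas[geno]:>10.2f}")
    return "\n".join(lines) + "\n"
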