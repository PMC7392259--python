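"""End-to-end orchestration: data -> ANOVA -> index -> OLS -> Bayes -> report.

``run_pipeline`` executes the full adaptability/stability analysis and
writes one CSV per stage into the output directory:

    anova.csv, index.csv, ols.csv, summary_m1.csv / summary_m2.csv,
    diagnostics_m1.csv / diagnostics_m2.csv, dic.csv, classification.csv,
    report.txt, run_config.json

The whole run is deterministic given the top-level seed: each genotype chain
gets a seed derived from (base seed, prior mode, genotype position), so M1
and M2 runs on the same data differ only in their prior specifications.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd

from . import bayes, classify, diagnostics
from .anova import AnovaTable, joint_anova, residual_mean_square
from .bayes import MCMCConfig, PosteriorSummary, summaries_to_frame
from .errors import InputError, SegstabError
from .segmented import elicit_hyperparameters, fit_genotype_ols, fits_to_frame
from .trial_data import (
    TrialTable,
    compute_environment_index,
    genotype_environment_means,
    read_trials,
)

logger = logging.getLogger("segstab")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "analyze_table"]

_MODE_OFFSET = {"m1": 0, "m2": 1}


def chain_seed(base_seed: int, mode: str, genotype_pos: int) -> int:
    """Deterministic per-chain seed below 2**31."""
    return (base_seed * 100003 + _MODE_OFFSET[mode] * 50021 + genotype_pos) % (2**31)


@dataclass(frozen=True)
class PipelineConfig:
    input_path: str | Path | None = None
    input_format: str = "csv"
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    prior_mode: str = "both"      # m1 | m2 | both
    strength: float = 1.0          # informative-prior scaling
    prior_shape: float = 1.0
    r2_threshold: float = 80.0
    ci_level: float = 0.95
    outdir: str | Path = "segstab_out"
    seed: int = 0
    # variance of the vague coefficient priors (M1); must dwarf the squared
    # scale of the intercept (kg/ha), hence the large default
    m1_coef_var: float = 1e10

    def __post_init__(self) -> None:
        if self.prior_mode not in ("m1", "m2", "both"):
            raise InputError("prior_mode must be 'm1', 'm2' or 'both'")
        if not (0 < self.ci_level < 1):
            raise InputError("ci_level must be in (0, 1)")


@dataclass
class PipelineResult:
    anova: AnovaTable
    index: "pd.Series"
    summaries: dict[str, list[PosteriorSummary]]
    classifications: dict[str, list]
    dic: pd.DataFrame | None
    outdir: Path


def analyze_table(
    table: TrialTable, config: PipelineConfig
) -> PipelineResult:
    """Run every analysis stage on an in-memory table (no file output)."""
    anova = joint_anova(table)
    msr = residual_mean_square(anova)
    r = anova.r
    index = compute_environment_index(table)
    means = genotype_environment_means(table)

    fits = [
        fit_genotype_ols(means.loc[g], index, genotype=g) for g in means.index
    ]
    fit_by_geno = {f.genotype: f for f in fits}

    modes = ["m1", "m2"] if config.prior_mode == "both" else [config.prior_mode]
    mcmc = replace(config.mcmc, seed=config.seed)
    summaries: dict[str, list[PosteriorSummary]] = {}
    samples: dict[str, dict] = {}
    for mode in modes:
        mode_summaries = []
        mode_samples = {}
        for pos, g in enumerate(means.index):
            if mode == "m1":
                prior = bayes.minimally_informative_priors(config.m1_coef_var)
            else:
                prior = elicit_hyperparameters(
                    fit_by_geno[g], strength=config.strength,
                    prior_shape=config.prior_shape,
                )
            cfg = replace(mcmc, seed=chain_seed(config.seed, mode, pos))
            sample = bayes.gibbs_sample(means.loc[g], index, prior, cfg, genotype=g)
            sample = bayes.attach_stability(sample, msr, r)
            mode_samples[g] = sample
            mode_summaries.append(
                bayes.summarize_posterior(sample, means.loc[g], index,
                                          ci_level=config.ci_level)
            )
        summaries[mode] = mode_summaries
        samples[mode] = mode_samples

    classifications = {
        mode: [
            classify.classify_genotype(s, anova.grand_mean,
                                       r2_threshold=config.r2_threshold)
            for s in summaries[mode]
        ]
        for mode in modes
    }

    dic_frame = None
    diag_frames = {}
    for mode in modes:
        diag_rows = []
        for g, sample in samples[mode].items():
            rep = diagnostics.diagnose_sample(sample)
            if not rep.all_pass:
                logger.warning(
                    "Geweke check failed for genotype %s (%s)", g, mode
                )
            tab = rep.table.reset_index(names="parameter")
            tab.insert(0, "genotype", g)
            diag_rows.append(tab)
        diag_frames[mode] = pd.concat(diag_rows, ignore_index=True)
    if set(modes) == {"m1", "m2"}:
        means_map = {g: means.loc[g] for g in means.index}
        rows = []
        for g in means.index:
            d1 = diagnostics.compute_dic(samples["m1"][g], means_map[g], index)
            d2 = diagnostics.compute_dic(samples["m2"][g], means_map[g], index)
            rows.append(
                {
                    "genotype": g,
                    "dic_m1": d1.dic, "p_d_m1": d1.p_d,
                    "dic_m2": d2.dic, "p_d_m2": d2.p_d,
                    "delta_dic": diagnostics.compare_priors(d1, d2),
                }
            )
        dic_frame = pd.DataFrame(rows)

    result = PipelineResult(
        anova=anova, index=index.index, summaries=summaries,
        classifications=classifications, dic=dic_frame,
        outdir=Path(config.outdir),
    )
    result._diag_frames = diag_frames  # type: ignore[attr-defined]
    result._env_index = index  # type: ignore[attr-defined]
    result._fits = fits  # type: ignore[attr-defined]
    return result


def run_pipeline(config: PipelineConfig, table: TrialTable | None = None) -> PipelineResult:
    """Full pipeline with file outputs; returns the in-memory results too."""
    if table is None:
        if config.input_path is None:
            raise InputError("either a table or config.input_path is required")
        table = read_trials(config.input_path, format=config.input_format)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        result = analyze_table(table, config)
    except SegstabError:
        raise

    result.anova.to_csv(outdir / "anova.csv")
    result._env_index.to_csv(outdir / "index.csv")  # type: ignore[attr-defined]
    fits_to_frame(result._fits).to_csv(outdir / "ols.csv", index=False,  # type: ignore[attr-defined]
                                       float_format="%.6f")
    for mode, summ in result.summaries.items():
        summaries_to_frame(summ).to_csv(
            outdir / f"summary_{mode}.csv", index=False, float_format="%.6f"
        )
        result._diag_frames[mode].to_csv(  # type: ignore[attr-defined]
            outdir / f"diagnostics_{mode}.csv", index=False, float_format="%.6f"
        )
        classify.classifications_to_frame(result.classifications[mode]).to_csv(
            outdir / f"classification_{mode}.csv", index=False
        )
    if result.dic is not None:
        result.dic.to_csv(outdir / "dic.csv", index=False, float_format="%.6f")

    report_mode = "m2" if "m2" in result.summaries else "m1"
    # the headline classification (informative priors when available)
    classify.classifications_to_frame(result.classifications[report_mode]).to_csv(
        outdir / "classification.csv", index=False
    )
    dic_deltas = (
        result.dic.set_index("genotype")["delta_dic"] if result.dic is not None
        else None
    )
    report = classify.render_report(
        result.summaries[report_mode],
        result.classifications[report_mode],
        anova=result.anova,
        dic_deltas=dic_deltas,
    )
    (outdir / "report.txt").write_text(report)

    cfg_dump = asdict(config)
    cfg_dump["input_path"] = str(cfg_dump["input_path"])
    cfg_dump["outdir"] = str(cfg_dump["outdir"])
    (outdir / "run_config.json").write_text(json.dumps(cfg_dump, indent=2))
    return result
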