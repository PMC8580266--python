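"""High-level fit: standardize, sample, back-transform, summarize.

This is the glue the CLI and the evaluation harness share.  The sampling
always happens on the standardized scale (unless disabled), and all reported
numbers are on the original scale of the data, back-transformed draw by
draw.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import pandas as pd

from . import data_model
from .diagnostics import convergence_warnings, results_table
from .gibbs import ChainSet, McmcSettings, posterior_summary, run_mcmc
from .model_build import (
    AnalysisSpec,
    ImputationSpec,
    PriorConfig,
    StandardizationRecord,
    build_joint_model,
    standardize_dataset,
    unstandardize_draws,
)


@dataclass
class FitResult:
    chains: ChainSet                       # reporting (original) scale
    chains_std: ChainSet                   # sampling scale
    record: StandardizationRecord | None
    summaries: list                        # PosteriorSummary per monitored parameter
    warnings: list
    n_outcome_dropped: int
    runtime_s: float
    settings: McmcSettings

    def summary_table(self, coefficients_only: bool = True) -> pd.DataFrame:
        rows = self.summaries
        if coefficients_only:
            rows = [
                s for s in rows if s.name == "alpha0" or s.name.startswith("beta_")
            ]
        return results_table(rows)

    def summary(self, name: str):
        for s in self.summaries:
            if s.name == name:
                return s
        raise KeyError(name)


def fit_model(
    ds: data_model.MultilevelDataset,
    analysis_spec: AnalysisSpec,
    imputation_spec: ImputationSpec | str | None = "auto",
    settings: McmcSettings | None = None,
    priors: PriorConfig | None = None,
    standardize: bool = True,
    fixed_residual_sd: float | None = None,
    fixed_intercept_sd: float | None = None,
) -> FitResult:
    """Fit the joint (or analysis-only) model end to end.

    ``imputation_spec="auto"`` derives the default imputation spec from the
    missingness pattern (falling back to the analysis-only model when
    nothing is missing); ``None`` always fits the analysis model alone.
    """
    t0 = time.perf_counter()
    settings = settings or McmcSettings()
    ds2, n_dropped = data_model.drop_missing_outcome(ds, analysis_spec.outcome)

    if imputation_spec == "auto":
        ispec = ImputationSpec.auto(ds2, analysis_spec)
        if not ispec.targets:
            ispec = None
    else:
        ispec = imputation_spec

    record = None
    if standardize:
        ds_fit, record = standardize_dataset(ds2, analysis_spec, ispec)
        if fixed_residual_sd is not None:
            _, s_y = record.mean_sd(analysis_spec.outcome)
            fixed_residual_sd = fixed_residual_sd / s_y
    else:
        ds_fit = ds2

    model = build_joint_model(
        ds_fit,
        analysis_spec,
        ispec,
        priors=priors,
        fixed_residual_sd=fixed_residual_sd,
        fixed_intercept_sd=fixed_intercept_sd,
    )
    chains_std = run_mcmc(model, settings)
    if record is not None:
        chains = unstandardize_draws(chains_std, record, analysis_spec)
    else:
        chains = chains_std
    summaries = [posterior_summary(chains, p) for p in chains.param_names]
    warn = convergence_warnings(summaries)
    return FitResult(
        chains=chains,
        chains_std=chains_std,
        record=record,
        summaries=summaries,
        warnings=warn,
        n_outcome_dropped=n_dropped,
        runtime_s=time.perf_counter() - t0,
        settings=settings,
    )
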