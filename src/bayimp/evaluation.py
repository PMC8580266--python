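"""Scenario-based evaluation: systematic drops, comparator fits, Rubin pooling.

The harness mirrors a standard validation design for imputation methods:
starting from complete data, whole variables are blanked in randomly chosen
clusters (systematic missingness by plan), the method under test is run on
each mutilated copy, and results are pooled over scenarios with Rubin's
rules and compared against the gold standard (the same hierarchical analysis
model fitted to the complete data) and against a naive analysis that simply
discards every cluster with a systematically missing covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import MultilevelDataset, missingness_report
from .fitting import FitResult, fit_model
from .gibbs import McmcSettings
from .model_build import AnalysisSpec, ImputationSpec, PriorConfig


@dataclass
class DropPlan:
    """Which (cluster label, variable) pairs to blank entirely."""

    pairs: list[tuple]
    scenario_id: int = 0
    seed: int = 0

    def __post_init__(self):
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate (cluster, variable) pairs in drop plan")


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of m estimates with within-variances.

    Qbar = mean estimate, W = mean within variance, B = between variance
    (sample variance of the estimates), T = W + (1 + 1/m) B, SE = sqrt(T),
    and a normal-theory 95% interval Qbar +- 1.96 SE.
    """

    m: int
    qbar: float
    within: float
    between: float
    total: float
    se: float
    low: float
    high: float


def rubin_pool(estimates, variances) -> PooledEstimate:
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if est.shape != var.shape or est.ndim != 1:
        raise ValueError("estimates and variances must be equal-length vectors")
    m = est.size
    if m < 2:
        raise ValueError("Rubin pooling needs m >= 2 analyses")
    if np.any(var < 0):
        raise ValueError("variances must be >= 0")
    qbar = float(est.mean())
    W = float(var.mean())
    B = float(est.var(ddof=1))
    T = W + (1.0 + 1.0 / m) * B
    assert T >= W
    se = float(np.sqrt(T))
    return PooledEstimate(
        m=m, qbar=qbar, within=W, between=B, total=T, se=se,
        low=qbar - 1.96 * se, high=qbar + 1.96 * se,
    )


def make_scenarios(
    ds: MultilevelDataset,
    n_scenarios: int,
    continuous_var: str,
    binary_var: str,
    seed: int = 0,
    pattern: tuple[int, int, int] = (1, 1, 3),
) -> list[DropPlan]:
    """Randomize which clusters lose which variable, ``n_scenarios`` times.

    ``pattern`` = (clusters losing only the continuous variable, clusters
    losing only the binary variable, clusters losing both); the default
    blanks 5 of the clusters per scenario.  Scenarios are sampled without
    replacement within a scenario and made mutually distinct when possible.
    """
    n_cont, n_bin, n_both = pattern
    n_affected = n_cont + n_bin + n_both
    J = ds.n_clusters
    if n_affected > J:
        raise ValueError(
            f"pattern affects {n_affected} clusters but only {J} exist"
        )
    for v in (continuous_var, binary_var):
        if v not in ds.variables:
            raise ValueError(f"unknown variable {v!r}")
    rng = np.random.default_rng(int(seed) % (2**31))
    labels = list(ds.cluster_labels)
    plans: list[DropPlan] = []
    seen = set()
    attempts = 0
    while len(plans) < n_scenarios:
        chosen = rng.choice(J, size=n_affected, replace=False)
        cont_only = chosen[:n_cont]
        bin_only = chosen[n_cont: n_cont + n_bin]
        both = chosen[n_cont + n_bin:]
        pairs = []
        for c in np.concatenate([cont_only, both]):
            pairs.append((labels[c], continuous_var))
        for c in np.concatenate([bin_only, both]):
            pairs.append((labels[c], binary_var))
        key = frozenset(pairs)
        attempts += 1
        if key in seen and attempts < 50 * n_scenarios:
            continue
        seen.add(key)
        plans.append(DropPlan(pairs=pairs, scenario_id=len(plans), seed=int(seed)))
    return plans


def apply_drop(ds: MultilevelDataset, plan: DropPlan) -> MultilevelDataset:
    """Blank every cell of each (cluster, variable) pair; the input is untouched."""
    out = ds.copy()
    label_to_code = {lab: i for i, lab in enumerate(ds.cluster_labels)}
    for label, var in plan.pairs:
        if var not in ds.variables:
            raise ValueError(f"unknown variable {var!r} in drop plan")
        if label not in label_to_code:
            raise ValueError(f"unknown cluster {label!r} in drop plan")
        rows = out.rows_of_cluster(label_to_code[label])
        col = out.values[var].to_numpy(dtype=float)
        col[rows] = np.nan
        out.values[var] = col
        out.mask[var] = ~np.isnan(col)
    out.check_invariants()
    return out


def naive_subset(ds: MultilevelDataset, covariates=None) -> MultilevelDataset:
    """Drop every cluster in which any analysis covariate is systematically
    missing; clusters with only sporadic missingness are kept."""
    report = missingness_report(ds)
    bad = report.clusters_with_systematic(covariates)
    if not bad:
        return ds.copy()
    keep_labels = [lab for lab in ds.cluster_labels if lab not in bad]
    if not keep_labels:
        raise ValueError("naive subset would remove every cluster")
    label_to_code = {lab: i for i, lab in enumerate(ds.cluster_labels)}
    keep_rows = np.isin(ds.cluster_codes, [label_to_code[l] for l in keep_labels])
    out = ds.copy()
    out.values = ds.values.loc[keep_rows].reset_index(drop=True)
    out.mask = ds.mask.loc[keep_rows].reset_index(drop=True)
    old_codes = ds.cluster_codes[keep_rows]
    remap = {label_to_code[l]: i for i, l in enumerate(keep_labels)}
    out.cluster_codes = np.asarray([remap[c] for c in old_codes], dtype=np.int64)
    out.cluster_labels = keep_labels
    out.check_invariants()
    return out


# ---------------------------------------------------------------------------


COMPARISON_COLUMNS = ["method", "variable", "estimate", "SE", "low", "high", "m"]


@dataclass
class ComparisonResult:
    table: pd.DataFrame                      # tidy method x variable summary
    per_scenario: pd.DataFrame               # scenario-level estimates and SEs
    plans: list[DropPlan]
    failures: list[dict] = field(default_factory=list)


def _coef_rows(fit: FitResult) -> list:
    return [s for s in fit.summaries if s.name == "alpha0" or s.name.startswith("beta_")]


def run_comparison(
    ds_complete: MultilevelDataset,
    analysis_spec: AnalysisSpec,
    n_scenarios: int,
    settings: McmcSettings,
    seed: int,
    continuous_drop: str,
    binary_drop: str,
    pattern: tuple[int, int, int] = (1, 1, 3),
    imputation_spec: ImputationSpec | None = None,
    priors: PriorConfig | None = None,
) -> ComparisonResult:
    """Gold standard vs naive vs joint imputation-analysis over scenarios.

    The gold standard fits the hierarchical analysis model once on the
    complete data.  For each drop scenario the naive analysis removes the
    affected clusters, while the joint model imputes the blanked variables
    within the analysis; both are pooled over scenarios with Rubin's rules
    using each scenario's posterior mean and squared posterior SE.  A
    scenario that fails is recorded, never silently dropped.
    """
    plans = make_scenarios(
        ds_complete, n_scenarios, continuous_drop, binary_drop,
        seed=seed, pattern=pattern,
    )
    records, rows, failures = [], [], []

    def scen_settings(idx):
        s = McmcSettings(
            burn_in=settings.burn_in, updates=settings.updates,
            n_chains=settings.n_chains, thin=settings.thin,
            seed=(settings.seed + 7919 * (idx + 1)) % (2**31),
        )
        return s

    gold = fit_model(
        ds_complete, analysis_spec, imputation_spec="auto",
        settings=settings, priors=priors,
    )
    for s in _coef_rows(gold):
        rows.append(
            {
                "method": "gold_standard", "variable": s.name,
                "estimate": s.estimate, "SE": s.se,
                "low": s.cri_low, "high": s.cri_high, "m": 1,
            }
        )

    for plan in plans:
        dropped = apply_drop(ds_complete, plan)
        for method in ("naive", "joint"):
            try:
                if method == "naive":
                    sub = naive_subset(dropped, covariates=analysis_spec.covariate_names)
                    fit = fit_model(
                        sub, analysis_spec, imputation_spec="auto",
                        settings=scen_settings(plan.scenario_id), priors=priors,
                    )
                else:
                    ispec = imputation_spec or ImputationSpec.auto(dropped, analysis_spec)
                    fit = fit_model(
                        dropped, analysis_spec, imputation_spec=ispec,
                        settings=scen_settings(plan.scenario_id), priors=priors,
                    )
            except Exception as exc:  # noqa: BLE001 - reported, not swallowed
                failures.append(
                    {"scenario": plan.scenario_id, "method": method, "error": str(exc)}
                )
                continue
            for s in _coef_rows(fit):
                records.append(
                    {
                        "scenario": plan.scenario_id, "method": method,
                        "variable": s.name, "estimate": s.estimate, "SE": s.se,
                        "rhat": s.rhat,
                    }
                )
    per_scenario = pd.DataFrame.from_records(records)

    for method in ("naive", "joint"):
        sub = per_scenario[per_scenario["method"] == method]
        for var, grp in sub.groupby("variable", sort=False):
            pooled = rubin_pool(grp["estimate"].to_numpy(), grp["SE"].to_numpy() ** 2)
            rows.append(
                {
                    "method": method, "variable": var,
                    "estimate": pooled.qbar, "SE": pooled.se,
                    "low": pooled.low, "high": pooled.high, "m": pooled.m,
                }
            )
    table = pd.DataFrame(rows, columns=COMPARISON_COLUMNS)
    return ComparisonResult(
        table=table, per_scenario=per_scenario, plans=plans, failures=failures
    )


def pool_external(table: pd.DataFrame) -> pd.DataFrame:
    """Rubin-pool an external method's per-scenario results.

    Adapter for comparing other imputation methods on equal footing: the
    input needs columns (scenario, variable, estimate, SE); the output has
    one pooled row per variable in the tidy comparison layout.
    """
    need = {"scenario", "variable", "estimate", "SE"}
    if not need.issubset(table.columns):
        raise ValueError(f"adapter table must have columns {sorted(need)}")
    rows = []
    for var, grp in table.groupby("variable", sort=False):
        pooled = rubin_pool(grp["estimate"].to_numpy(), grp["SE"].to_numpy() ** 2)
        rows.append(
            {
                "method": "external", "variable": var, "estimate": pooled.qbar,
                "SE": pooled.se, "low": pooled.low, "high": pooled.high,
                "m": pooled.m,
            }
        )
    return pd.DataFrame(rows, columns=COMPARISON_COLUMNS)
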