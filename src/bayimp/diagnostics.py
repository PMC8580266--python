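"""Convergence diagnostics, warning rules, results table and CODA export.

Two diagnostics drive the user-facing recommendations: the split-chain
Gelman-Rubin statistic (R-hat), with a suggestion to increase the burn-in
period when R-hat > 1.1, and the batch-means Monte-Carlo error ("simulation
error"), with a suggestion to increase the number of updates when it exceeds
5% of a parameter's posterior SD.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd


@dataclass
class PosteriorSummary:
    """Posterior estimate, SE, 95% CrI, MCMC error and R-hat for one parameter."""

    name: str
    estimate: float
    median: float
    se: float
    cri_low: float
    cri_high: float
    mcse: float
    rhat: float
    rhat_degenerate: bool = False

    def __post_init__(self):
        if not (self.cri_low <= self.median <= self.cri_high):
            raise ValueError(
                f"{self.name}: credible interval does not bracket the median"
            )
        if self.mcse < 0:
            raise ValueError(f"{self.name}: negative Monte-Carlo error")


class Rhat(NamedTuple):
    value: float
    degenerate: bool


def gelman_rubin(draws) -> Rhat:
    """Split-chain potential scale reduction factor.

    Each chain is halved; with m half-chains of length n', W the mean
    within-half-chain variance and B = n' * Var(half-chain means),

        R-hat = sqrt(((n'-1)/n' * W + B/n') / W).

    If every draw is identical (W = 0) the statistic is degenerate and is
    reported as 1 with a flag.
    """
    arr = np.atleast_2d(np.asarray(draws, dtype=float))
    n = arr.shape[1]
    if n < 4:
        raise ValueError("need at least 4 draws per chain")
    half = n // 2
    halves = []
    for row in arr:
        halves.append(row[:half])
        halves.append(row[half: 2 * half])
    halves = np.asarray(halves)
    nprime = half
    within = halves.var(axis=1, ddof=1)
    W = float(within.mean())
    if W == 0.0:
        return Rhat(1.0, True)
    B_over_n = float(halves.mean(axis=1).var(ddof=1))
    rhat = np.sqrt(((nprime - 1) / nprime * W + B_over_n) / W)
    return Rhat(float(rhat), False)


def mcmc_error(draws) -> float:
    """Batch-means Monte-Carlo standard error of the posterior mean.

    The pooled draws are split into floor(sqrt(n)) equal batches (the
    remainder at the end is dropped) and the error is the SD of the batch
    means divided by sqrt(number of batches).
    """
    x = np.asarray(draws, dtype=float).reshape(-1)
    n = x.size
    if n < 100:
        raise ValueError("need at least 100 draws")
    n_batches = int(np.sqrt(n))
    size = n // n_batches
    means = x[: n_batches * size].reshape(n_batches, size).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))


def convergence_warnings(
    summaries,
    rhat_threshold: float = 1.1,
    mcse_fraction: float = 0.05,
) -> list[dict]:
    """Emit the tool's recommendations from per-parameter summaries.

    For each parameter: "increase number of updates" when the MCMC error
    exceeds ``mcse_fraction`` of its SE, and "increase burn-in period" when
    R-hat exceeds ``rhat_threshold``.
    """
    warnings = []
    for s in summaries:
        if s.mcse > mcse_fraction * s.se:
            warnings.append(
                {
                    "parameter": s.name,
                    "kind": "increase_updates",
                    "message": (
                        f"MCMC error of {s.name} is "
                        f"{100 * s.mcse / s.se if s.se > 0 else float('inf'):.1f}% "
                        f"of its standard error (> {100 * mcse_fraction:.0f}%): "
                        "increase number of updates"
                    ),
                }
            )
        if s.rhat > rhat_threshold:
            warnings.append(
                {
                    "parameter": s.name,
                    "kind": "increase_burn_in",
                    "message": (
                        f"R-hat of {s.name} is {s.rhat:.3f} "
                        f"(> {rhat_threshold}): increase burn-in period"
                    ),
                }
            )
    return warnings


RESULTS_COLUMNS = [
    "variable",
    "estimate",
    "SE",
    "CrI 2.5%",
    "CrI 97.5%",
    "MCMC error",
    "R-hat",
]


def results_table(summaries, path=None) -> pd.DataFrame:
    """One row per analysis-model coefficient; optionally written as CSV."""
    rows = [
        {
            "variable": s.name,
            "estimate": s.estimate,
            "SE": s.se,
            "CrI 2.5%": s.cri_low,
            "CrI 97.5%": s.cri_high,
            "MCMC error": s.mcse,
            "R-hat": s.rhat,
        }
        for s in summaries
    ]
    table = pd.DataFrame(rows, columns=RESULTS_COLUMNS)
    if path is not None:
        table.to_csv(path, index=False)
    return table


def warnings_json(warnings, path) -> None:
    with open(path, "w") as fh:
        json.dump(warnings, fh, indent=2)


# ---------------------------------------------------------------------------
# CODA export (BUGS dialect)


def export_coda(chains, out_dir, stem: str = "coda") -> list[str]:
    """Write BUGS-style CODA files: one index plus one file per chain.

    The index has one line per monitored parameter, ``name first_row
    last_row``; each chain file has one ``iteration value`` line per draw,
    parameter blocks contiguous and in monitored order.  Values are printed
    with full precision so a round trip reproduces the draws exactly.
    """
    os.makedirs(out_dir, exist_ok=True)
    names = chains.param_names
    n_draws = chains.iterations.size
    index_path = os.path.join(out_dir, f"{stem}Index.txt")
    with open(index_path, "w") as fh:
        for i, name in enumerate(names):
            fh.write(f"{name} {i * n_draws + 1} {(i + 1) * n_draws}\n")
    paths = [index_path]
    n_chains = chains.n_chains
    for c in range(n_chains):
        p = os.path.join(out_dir, f"{stem}{c + 1}.txt")
        with open(p, "w") as fh:
            for name in names:
                col = chains.draws[name][c]
                for it, val in zip(chains.iterations, col):
                    fh.write(f"{it} {float(val)!r}\n")
        paths.append(p)
    return paths


def read_coda(out_dir, stem: str = "coda"):
    """Parse CODA files written by :func:`export_coda`.

    Returns ``(param_names, iterations, draws)`` with ``draws`` mapping each
    parameter to an (n_chains, n_draws) array, bit-identical to the export.
    """
    index_path = os.path.join(out_dir, f"{stem}Index.txt")
    names, bounds = [], []
    with open(index_path) as fh:
        for line in fh:
            name, first, last = line.split()
            names.append(name)
            bounds.append((int(first), int(last)))
    chain_paths = []
    c = 1
    while os.path.exists(os.path.join(out_dir, f"{stem}{c}.txt")):
        chain_paths.append(os.path.join(out_dir, f"{stem}{c}.txt"))
        c += 1
    if not chain_paths:
        raise FileNotFoundError(f"no chain files for stem {stem!r} in {out_dir}")
    all_iters, all_vals = [], []
    for p in chain_paths:
        iters, vals = [], []
        with open(p) as fh:
            for line in fh:
                it, val = line.split()
                iters.append(int(it))
                vals.append(float(val))
        all_iters.append(iters)
        all_vals.append(vals)
    draws = {}
    for name, (first, last) in zip(names, bounds):
        block = slice(first - 1, last)
        draws[name] = np.asarray([vals[block] for vals in all_vals])
    n_draws = bounds[0][1] - bounds[0][0] + 1
    iterations = np.asarray(all_iters[0][: n_draws], dtype=int)
    return names, iterations, draws


def trace_data(chains) -> pd.DataFrame:
    """Tidy (parameter, chain, iteration, value) table for trace/density plots."""
    rec = []
    for name in chains.param_names:
        arr = chains.draws[name]
        for c in range(arr.shape[0]):
            rec.append(
                pd.DataFrame(
                    {
                        "parameter": name,
                        "chain": c + 1,
                        "iteration": chains.iterations,
                        "value": arr[c],
                    }
                )
            )
    return pd.concat(rec, ignore_index=True)
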