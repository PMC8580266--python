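"""Multilevel tabular data with an explicit observed/missing mask.

The package analyses a single rectangular table of individual-level records
pooled over clusters (studies, centres).  Each variable is typed continuous
or binary, and each cell is either observed or missing.  Missingness of a
variable within a cluster is classified as

* ``systematic`` -- the variable was never measured in that cluster,
* ``sporadic``   -- measured, but absent for some individuals,
* ``complete``   -- fully observed in that cluster.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default missing-value tokens, matched case-insensitively after stripping
DEFAULT_NA_TOKENS = ("", "na", "nan")

CONTINUOUS = "continuous"
BINARY = "binary"


class FormatError(ValueError):
    """Malformed input table (ragged rows, unparseable cells)."""


class ValidationError(ValueError):
    """Input violates a declared variable role or invariant."""


@dataclass
class MultilevelDataset:
    """Clustered individual-level records with a per-cell observed mask.

    Before :func:`assign_roles` the dataset is "untyped": ``raw`` holds the
    cell text and ``values``/``cluster_codes`` are unset.  After roles are
    assigned, ``values`` is an n x p float matrix (NaN at missing cells),
    ``mask`` the matching boolean observed matrix, and rows carry a stable
    0-based cluster code (labels sorted).
    """

    raw: pd.DataFrame | None = None
    values: pd.DataFrame | None = None
    mask: pd.DataFrame | None = None
    var_types: dict[str, str] = field(default_factory=dict)
    cluster_var: str | None = None
    cluster_labels: list | None = None
    cluster_codes: np.ndarray | None = None

    # -- basic properties -------------------------------------------------

    @property
    def typed(self) -> bool:
        return self.values is not None

    @property
    def n_rows(self) -> int:
        frame = self.values if self.typed else self.raw
        return 0 if frame is None else len(frame)

    @property
    def n_clusters(self) -> int:
        if self.cluster_labels is None:
            raise ValidationError("roles not assigned yet")
        return len(self.cluster_labels)

    @property
    def variables(self) -> list[str]:
        if not self.typed:
            raise ValidationError("roles not assigned yet")
        return list(self.values.columns)

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.cluster_codes, minlength=self.n_clusters)

    def rows_of_cluster(self, code: int) -> np.ndarray:
        return np.flatnonzero(self.cluster_codes == code)

    def check_invariants(self) -> None:
        if not self.typed:
            return
        if self.n_clusters < 2:
            raise ValidationError("at least 2 clusters are required")
        vals = self.values.to_numpy()
        msk = self.mask.to_numpy()
        if not np.array_equal(msk, ~np.isnan(vals)):
            raise ValidationError("observed mask inconsistent with NaN pattern")
        for name, vtype in self.var_types.items():
            if vtype == BINARY:
                col = self.values[name].to_numpy()
                obs = col[~np.isnan(col)]
                bad = np.unique(obs[(obs != 0.0) & (obs != 1.0)])
                if bad.size:
                    raise ValidationError(
                        f"binary variable {name!r} has observed values outside "
                        f"{{0,1}}: {bad.tolist()}"
                    )

    # -- construction helpers ---------------------------------------------

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MultilevelDataset":
        """Wrap an in-memory table (NaN marks missing) as an untyped dataset."""
        return cls(raw=frame.copy())

    def copy(self) -> "MultilevelDataset":
        return replace(
            self,
            raw=None if self.raw is None else self.raw.copy(),
            values=None if self.values is None else self.values.copy(),
            mask=None if self.mask is None else self.mask.copy(),
            var_types=dict(self.var_types),
            cluster_labels=None if self.cluster_labels is None else list(self.cluster_labels),
            cluster_codes=None if self.cluster_codes is None else self.cluster_codes.copy(),
        )


@dataclass
class MissingnessReport:
    """Per-(variable, cluster) missing counts and status.

    ``table`` has one row per (variable, cluster label) with columns
    ``variable, cluster, n_missing, n_total, status``; ``overall`` maps each
    variable to ``systematic-anywhere``, ``sporadic-only`` or ``complete``.
    """

    table: pd.DataFrame
    overall: dict[str, str]

    def status(self, variable: str, cluster) -> str:
        sub = self.table[
            (self.table["variable"] == variable) & (self.table["cluster"] == cluster)
        ]
        if sub.empty:
            raise KeyError((variable, cluster))
        return sub["status"].iloc[0]

    def systematic_pairs(self) -> list[tuple[str, object]]:
        sub = self.table[self.table["status"] == "systematic"]
        return list(zip(sub["variable"], sub["cluster"]))

    def clusters_with_systematic(self, variables=None) -> set:
        sub = self.table[self.table["status"] == "systematic"]
        if variables is not None:
            sub = sub[sub["variable"].isin(list(variables))]
        return set(sub["cluster"])


# ---------------------------------------------------------------------------


def read_table(
    path,
    na_tokens=DEFAULT_NA_TOKENS,
    delimiter: str = ",",
) -> MultilevelDataset:
    """Read a delimited text table (header row required) into an untyped dataset.

    Cells whose stripped, lower-cased text is in ``na_tokens`` are masked as
    missing.  Ragged rows raise :class:`FormatError` naming the offending
    1-based row number (the header is row 1).
    """
    tokens = {t.strip().lower() for t in na_tokens}
    try:
        with open(path, newline="") as fh:
            reader = csv.reader(fh, delimiter=delimiter)
            rows = list(reader)
    except OSError as exc:
        raise OSError(f"cannot read {path}: {exc}") from exc
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = [h.strip() for h in rows[0]]
    ncol = len(header)
    if len(set(header)) != ncol:
        raise FormatError(f"{path}: duplicate column names in header")
    data = []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != ncol:
            raise FormatError(
                f"{path}: row {i} has {len(row)} fields, expected {ncol}"
            )
        data.append(
            [None if cell.strip().lower() in tokens else cell.strip() for cell in row]
        )
    frame = pd.DataFrame(data, columns=header, dtype=object)
    return MultilevelDataset(raw=frame)


def assign_roles(
    ds: MultilevelDataset,
    cluster_var: str,
    types: dict[str, str],
) -> MultilevelDataset:
    """Type the columns and index the clusters.

    ``types`` maps every non-cluster column to ``"continuous"`` or
    ``"binary"``.  Binary columns must contain only {0, 1} among observed
    values.  Cluster labels are mapped to stable 0-based codes in sorted
    label order; rows with a missing cluster identifier are rejected.
    """
    frame = ds.raw
    if frame is None:
        raise ValidationError("dataset has no raw table")
    if cluster_var not in frame.columns:
        raise ValidationError(f"cluster variable {cluster_var!r} not in header")
    other = [c for c in frame.columns if c != cluster_var]
    missing_types = sorted(set(other) - set(types))
    if missing_types:
        raise ValidationError(f"no type declared for columns: {missing_types}")
    extra = sorted(set(types) - set(other))
    if extra:
        raise ValidationError(f"types declared for unknown columns: {extra}")
    bad_types = {v: t for v, t in types.items() if t not in (CONTINUOUS, BINARY)}
    if bad_types:
        raise ValidationError(f"unknown variable types: {bad_types}")

    cl_raw = frame[cluster_var]
    missing_cl = cl_raw.isna()
    if missing_cl.any():
        rows = (np.flatnonzero(missing_cl.to_numpy()) + 2).tolist()
        raise ValidationError(
            f"missing cluster identifier in data rows {rows[:10]}"
            + (" ..." if len(rows) > 10 else "")
        )

    # stable label order: numeric if all labels parse as numbers, else lexical
    labels = pd.unique(cl_raw)
    try:
        order = np.argsort([float(l) for l in labels])
    except (TypeError, ValueError):
        order = np.argsort([str(l) for l in labels])
    labels = [labels[i] for i in order]
    code_of = {lab: i for i, lab in enumerate(labels)}
    codes = cl_raw.map(code_of).to_numpy(dtype=np.int64)

    values = {}
    for name in other:
        col = frame[name]
        try:
            num = pd.to_numeric(col, errors="raise")
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"column {name!r} is not numeric: {exc}") from exc
        values[name] = num.astype(float)
    values = pd.DataFrame(values, index=frame.index)
    mask = values.notna()

    out = MultilevelDataset(
        raw=None,
        values=values,
        mask=mask,
        var_types={v: types[v] for v in other},
        cluster_var=cluster_var,
        cluster_labels=labels,
        cluster_codes=codes,
    )
    out.check_invariants()
    return out


def missingness_report(ds: MultilevelDataset) -> MissingnessReport:
    """Count missing cells per (variable, cluster) and classify the pattern."""
    if not ds.typed:
        raise ValidationError("assign_roles must be called first")
    records = []
    overall: dict[str, str] = {}
    mask = ds.mask.to_numpy()
    for vi, name in enumerate(ds.variables):
        any_systematic = False
        any_missing = False
        for code, label in enumerate(ds.cluster_labels):
            rows = ds.rows_of_cluster(code)
            n_total = rows.size
            n_missing = int((~mask[rows, vi]).sum())
            if n_missing == 0:
                status = "complete"
            elif n_missing == n_total:
                status = "systematic"
                any_systematic = True
            else:
                status = "sporadic"
            any_missing = any_missing or n_missing > 0
            records.append(
                {
                    "variable": name,
                    "cluster": label,
                    "n_missing": n_missing,
                    "n_total": n_total,
                    "status": status,
                }
            )
        if any_systematic:
            overall[name] = "systematic-anywhere"
        elif any_missing:
            overall[name] = "sporadic-only"
        else:
            overall[name] = "complete"
    return MissingnessReport(table=pd.DataFrame.from_records(records), overall=overall)


def drop_missing_outcome(
    ds: MultilevelDataset, outcome: str
) -> tuple[MultilevelDataset, int]:
    """Drop rows whose outcome value is missing; the outcome is never imputed.

    Returns the filtered dataset and the number of rows removed (also logged).
    """
    if outcome not in ds.variables:
        raise ValidationError(f"unknown outcome variable {outcome!r}")
    keep = ds.mask[outcome].to_numpy()
    n_dropped = int((~keep).sum())
    if n_dropped == 0:
        return ds, 0
    logger.info("excluding %d rows with a missing outcome value", n_dropped)
    out = replace(
        ds.copy(),
        values=ds.values.loc[keep].reset_index(drop=True),
        mask=ds.mask.loc[keep].reset_index(drop=True),
        cluster_codes=ds.cluster_codes[keep],
    )
    out.check_invariants()
    return out, n_dropped
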