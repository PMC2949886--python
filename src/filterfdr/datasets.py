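"""Expression-matrix container and tab-delimited I/O.

The central object is :class:`ExpressionDataset`: an m-feature by n-sample
matrix of (already log-transformed, pre-processed) expression values together
with a two-level group label per sample.  Every filter statistic, test
statistic and downstream procedure in this package consumes this object.

No normalisation or imputation is performed here: values are taken as-is, and
missing entries are an input error, because every per-feature statistic in the
package assumes a complete sample vector.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "read_expression_matrix",
    "read_phenotype_file",
    "write_expression_matrix",
    "write_results_table",
]

GROUP_LEVELS = ("A", "B")


class InputError(ValueError):
    """Raised when an input file or label assignment violates a precondition."""


@dataclass
class ExpressionDataset:
    """Feature x sample expression matrix with a two-group design.

    Parameters
    ----------
    values : ndarray, shape (m, n)
        Expression values, features in rows.  Assumed pre-processed
        (e.g. log-scale); no transformation is applied.
    feature_ids : sequence of str, length m
    sample_ids : sequence of str, length n
    group : sequence of {"A", "B"}, length n
        Group membership per sample; both groups must be non-empty.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    group: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InputError("values must be a 2-d (feature x sample) matrix")
        m, n = self.values.shape
        if m < 1:
            raise InputError("dataset must contain at least one feature")
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.feature_ids) != m:
            raise InputError(f"{len(self.feature_ids)} feature ids for {m} rows")
        if len(self.sample_ids) != n:
            raise InputError(f"{len(self.sample_ids)} sample ids for {n} columns")
        dupes = pd.Index(self.feature_ids)[pd.Index(self.feature_ids).duplicated()]
        if len(dupes):
            raise InputError(f"duplicate feature id(s): {sorted(set(dupes))}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise InputError(
                "missing/non-finite value at feature "
                f"{self.feature_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )
        self.group = np.asarray(self.group)
        if self.group.shape != (n,):
            raise InputError("group must assign exactly one label per sample")
        bad_levels = set(self.group.tolist()) - set(GROUP_LEVELS)
        if bad_levels:
            raise InputError(f"group labels must be 'A'/'B', got {sorted(bad_levels)}")
        if self.nX == 0 or self.nY == 0:
            raise InputError("both groups must be non-empty")

    # -- derived quantities -------------------------------------------------

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    @property
    def mask_a(self) -> np.ndarray:
        return self.group == "A"

    @property
    def mask_b(self) -> np.ndarray:
        return self.group == "B"

    @property
    def nX(self) -> int:
        """Size of group A."""
        return int(np.count_nonzero(self.mask_a))

    @property
    def nY(self) -> int:
        """Size of group B."""
        return int(np.count_nonzero(self.mask_b))

    def group_values(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y): the (m, nX) and (m, nY) sub-matrices per group."""
        return self.values[:, self.mask_a], self.values[:, self.mask_b]

    def with_group(self, group: np.ndarray) -> "ExpressionDataset":
        """Copy of the dataset with a new label vector (values shared)."""
        return ExpressionDataset(self.values, self.feature_ids, self.sample_ids, group)


def read_phenotype_file(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column (sample_id, group) tab-delimited phenotype file."""
    pheno = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if pheno.shape[1] < 2:
        raise InputError(f"phenotype file {path} needs two columns (sample, group)")
    return dict(zip(pheno.iloc[:, 0], pheno.iloc[:, 1]))


def read_expression_matrix(
    path: str | os.PathLike,
    group_spec: dict[str, str] | str | os.PathLike | None = None,
) -> ExpressionDataset:
    """Read a tab-delimited expression matrix into an :class:`ExpressionDataset`.

    The file layout is: first row sample ids, first column feature ids.  Group
    labels come either from ``group_spec`` (a mapping sample_id -> "A"/"B", or
    the path of a two-column phenotype TSV) or from an embedded second row
    whose feature-id cell is ``group``.  An explicit ``group_spec`` wins over
    the embedded row when both are present.

    Row and column order are preserved from the file.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    embedded: dict[str, str] | None = None
    if len(df.index) and str(df.index[0]).lower() == "group":
        embedded = {str(s): str(g) for s, g in df.iloc[0].items()}
        df = df.iloc[1:]

    if group_spec is None:
        mapping = embedded
    elif isinstance(group_spec, dict):
        mapping = {str(k): str(v) for k, v in group_spec.items()}
    else:
        mapping = read_phenotype_file(group_spec)
    if mapping is None:
        raise InputError("no group labels: supply group_spec or an embedded 'group' row")

    missing = [s for s in df.columns.astype(str) if s not in mapping]
    if missing:
        raise InputError(f"sample(s) without a group label: {missing}")

    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise InputError(f"non-numeric entry in expression matrix: {exc}") from exc
    group = np.array([mapping[str(s)] for s in df.columns])
    return ExpressionDataset(
        values=values,
        feature_ids=df.index.astype(str).tolist(),
        sample_ids=df.columns.astype(str).tolist(),
        group=group,
    )


def write_expression_matrix(dataset: ExpressionDataset, path: str | os.PathLike) -> None:
    """Write a dataset with an embedded ``group`` row, round-trippable by
    :func:`read_expression_matrix` at full float precision."""
    with open(path, "w") as fh:
        fh.write("feature_id\t" + "\t".join(dataset.sample_ids) + "\n")
        fh.write("group\t" + "\t".join(dataset.group.tolist()) + "\n")
        for fid, row in zip(dataset.feature_ids, dataset.values):
            fh.write(fid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def write_results_table(rows: list[dict] | pd.DataFrame, path: str | os.PathLike) -> None:
    """Write per-feature result records as a tab-delimited table.

    All records must share a common field set; floats are rendered with 12
    significant digits so p-values round-trip well beyond reporting precision.
    An empty record list yields a header-only file (a canonical header is used
    when no records carry one).
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        if len(rows) == 0:
            df = pd.DataFrame(
                columns=["feature_id", "filter_statistic", "statistic", "pvalue",
                         "adjusted", "rejected"]
            )
        else:
            fields = set(rows[0])
            for r in rows[1:]:
                if set(r) != fields:
                    raise InputError("result records do not share a common field set")
            df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
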