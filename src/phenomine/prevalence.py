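"""Feature-prevalence tables and condition clustering by prevalence profile.

A prevalence record states, for one (feature, condition) pair, the
percentage of individuals in a literature cohort showing the feature —
conditions being "aging" itself plus comparison diseases. Records pivot to
a conditions x features matrix (missing cells stay missing and are handled
by pairwise-complete similarity, never imputed), which is clustered with
uncentered similarity and average linkage to place aging among the
comparison diseases.

For continuous physiological quantities a prevalence must first be derived
from a 2-standard-deviation abnormality rule: the percentage of elderly
values falling outside the young mean +/- 2 SD band (two-sided by default;
direction-specific features can use a one-sided band).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster import SupportedDendrogram, bootstrap_support

__all__ = [
    "PrevalenceRecord",
    "PrevalenceMatrix",
    "load_prevalence",
    "to_matrix",
    "abnormality_prevalence",
    "condition_clustering",
]


@dataclass(frozen=True)
class PrevalenceRecord:
    feature: str
    condition: str
    prevalence: float  # percent, [0, 100]
    cohort_size: int
    source: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.prevalence <= 100.0):
            raise ValueError(
                f"prevalence {self.prevalence} for {self.feature!r}/"
                f"{self.condition!r} outside [0, 100]"
            )
        if self.cohort_size < 1:
            raise ValueError(f"cohort_size must be >= 1 for {self.feature!r}")


@dataclass
class PrevalenceMatrix:
    """Conditions x features percentage matrix; NaN marks missing entries."""

    table: pd.DataFrame
    total_cohort_size: int
    merged_cohort_sizes: dict[str, int] = field(default_factory=dict)

    @property
    def conditions(self) -> list[str]:
        return list(self.table.index)

    @property
    def features(self) -> list[str]:
        return list(self.table.columns)


def load_prevalence(path: str | Path) -> list[PrevalenceRecord]:
    """Read prevalence records from TSV.

    Columns (header required): ``feature``, ``condition``, ``prevalence``
    (percent), ``cohort_size``, optional ``source``. Out-of-range values are
    load errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"feature", "condition", "prevalence", "cohort_size"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                PrevalenceRecord(
                    feature=row["feature"].strip(),
                    condition=row["condition"].strip(),
                    prevalence=float(row["prevalence"]),
                    cohort_size=int(row["cohort_size"]),
                    source=row.get("source", "").strip() if "source" in df.columns else "",
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {i + 2}: {exc}") from exc
    return records


def to_matrix(
    records: Sequence[PrevalenceRecord],
    merge_map: Mapping[str, str] | None = None,
) -> PrevalenceMatrix:
    """Pivot records to a conditions x features matrix, applying merges.

    ``merge_map`` renames raw features to combined ones (features
    reflecting the same process are reported under one label; their cohort
    sizes are summed in ``merged_cohort_sizes``). The combined prevalence
    must be supplied by the input — records that merge to the same
    (condition, feature) cell with *different* prevalences are an error, as
    no pooling formula is invented here.
    """
    merge_map = dict(merge_map or {})
    cell: dict[tuple[str, str], float] = {}
    merged_sizes: dict[str, int] = {}
    total = 0
    for r in records:
        feature = merge_map.get(r.feature, r.feature)
        key = (r.condition, feature)
        if key in cell and cell[key] != r.prevalence:
            raise ValueError(
                f"conflicting prevalences for {key}: {cell[key]} vs "
                f"{r.prevalence}; provide a single combined value"
            )
        cell[key] = r.prevalence
        merged_sizes[feature] = merged_sizes.get(feature, 0) + r.cohort_size
        total += r.cohort_size
    conditions = sorted({c for c, _ in cell})
    features = sorted({f for _, f in cell})
    table = pd.DataFrame(np.nan, index=conditions, columns=features)
    for (c, f), v in cell.items():
        table.loc[c, f] = v
    return PrevalenceMatrix(table, total, merged_sizes)


def abnormality_prevalence(
    young_mean: float,
    young_sd: float,
    elderly_values: Sequence[float],
    two_sided: bool = True,
    direction: str = "above",
) -> float:
    """Percentage of elderly values more than 2 SD from the young mean.

    Two-sided by default (outside ``young_mean +/- 2 * young_sd``); with
    ``two_sided=False`` only the ``direction`` ("above"/"below") tail
    counts. Invariant under affine rescaling of all inputs together.
    """
    if young_sd <= 0:
        raise ValueError("young_sd must be positive")
    values = np.asarray(list(elderly_values), dtype=float)
    if values.size == 0:
        raise ValueError("elderly sample is empty")
    lo, hi = young_mean - 2 * young_sd, young_mean + 2 * young_sd
    if two_sided:
        abnormal = (values < lo) | (values > hi)
    elif direction == "above":
        abnormal = values > hi
    elif direction == "below":
        abnormal = values < lo
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return 100.0 * float(abnormal.mean())


def condition_clustering(
    matrix: PrevalenceMatrix,
    n_boot: int = 100,
    seed: int = 0,
    compute_au: bool = True,
) -> SupportedDendrogram:
    """Cluster conditions by prevalence profile (uncentered, average
    linkage) with bootstrap support over the feature columns.

    Missing entries are handled by pairwise-complete similarity.
    """
    if len(matrix.conditions) < 2:
        raise ValueError("need at least two conditions to cluster")
    X = matrix.table.to_numpy(dtype=float)
    return bootstrap_support(
        X,
        matrix.conditions,
        metric="uncentered",
        n_boot=n_boot,
        seed=seed,
        compute_au=compute_au,
        pairwise_complete=True,
    )
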