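"""Per-individual trait matrices, environmental tables, and trait variability.

The central container is :class:`TraitMatrix`: a numeric matrix of
``n_individuals x n_traits`` with a water-body (group) label per row.
Trait variability is summarised by the coefficient of variation
(CV = sample standard deviation / mean), computed per trait within each
group; groups are then compared by their mean CV over traits, which is
the quantity the tight-vs-loose network contrast is built on.

Missing values are carried as NaN and handled pairwise downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DomainError,
    FormatError,
    InsufficientDataError,
    UndefinedCVError,
)

logger = logging.getLogger(__name__)

#: The 18 functional traits measured on each individual: plant height,
#: stem branch, internode counts/length/diameter, relative stem length,
#: leaf number/thickness/length/width/area, relative leaf area, dry
#: plant/stem/leaf weight, stem:leaf weight ratio, and stem/leaf dry
#: mass fractions.
DEFAULT_TRAITS: tuple[str, ...] = (
    "H", "SB", "NN", "NL", "ND", "RSL", "LN", "LT", "LL",
    "LW", "LA", "RLA", "DPW", "DSW", "DLW", "SLR", "SMF", "LMF",
)


@dataclass
class TraitMatrix:
    """Individuals x traits with a group (water body) label per row.

    Parameters
    ----------
    values
        Float matrix, shape ``(n_individuals, n_traits)``; NaN marks
        missing measurements.
    trait_names
        Unique, non-empty trait column names.
    group
        Water-body label for every row.
    site
        Optional finer-grained site label per row.
    """

    values: np.ndarray
    trait_names: list[str]
    group: np.ndarray
    site: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.group = np.asarray(self.group, dtype=object)
        if self.values.ndim != 2:
            raise FormatError("trait values must be a 2-D matrix")
        if len(self.trait_names) != self.values.shape[1]:
            raise FormatError(
                f"{len(self.trait_names)} trait names for "
                f"{self.values.shape[1]} columns"
            )
        if len(self.trait_names) == 0:
            raise FormatError("trait matrix has zero trait columns")
        if len(set(self.trait_names)) != len(self.trait_names):
            raise FormatError("trait names must be unique")
        if len(self.group) != self.values.shape[0]:
            raise FormatError("group labels must match the number of rows")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    @property
    def groups(self) -> list:
        """Group labels in order of first appearance."""
        return list(pd.unique(self.group))

    def subset(self, group) -> "TraitMatrix":
        """Rows belonging to one water body."""
        mask = self.group == group
        if not mask.any():
            raise ConfigurationError(f"unknown group {group!r}")
        return TraitMatrix(
            values=self.values[mask],
            trait_names=list(self.trait_names),
            group=self.group[mask],
            site=None if self.site is None else self.site[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.trait_names)
        df.insert(0, "group", self.group)
        if self.site is not None:
            df.insert(1, "site", self.site)
        return df


@dataclass
class EnvTable:
    """One row of environmental variables per water body."""

    data: pd.DataFrame  # index = group label, columns = variables

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dupes = list(self.data.index[self.data.index.duplicated()])
            raise FormatError(f"duplicate group rows in environmental table: {dupes}")

    @property
    def groups(self) -> list:
        return list(self.data.index)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class CVTable:
    """Per-trait, per-group coefficients of variation.

    ``per_group`` is tidy (trait, group, cv) with NaN where the CV is
    undefined; ``group_mean_cv`` averages defined trait CVs within each
    group and is the group-level variability score.
    """

    per_group: pd.DataFrame
    group_mean_cv: pd.Series
    pooled: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def ranking(self, mode: str = "mean_of_groups") -> pd.Series:
        """Traits ordered from most to least variable.

        ``mean_of_groups`` averages each trait's per-group CVs;
        ``pooled`` ranks by the CV over all individuals together.
        """
        if mode == "mean_of_groups":
            scores = (
                self.per_group.groupby("trait", sort=False)["cv"].mean()
            )
        elif mode == "pooled":
            scores = self.pooled
        else:
            raise ConfigurationError(f"unknown ranking mode {mode!r}")
        return scores.sort_values(ascending=False)


def read_trait_matrix(
    path: str | Path,
    group_column: str,
    trait_columns: Sequence[str] | None = None,
    site_column: str | None = None,
    missing_tokens: Sequence[str] = ("NA", ""),
    sep: str | None = None,
) -> TraitMatrix:
    """Read a delimited per-individual trait table.

    Any cell matching ``missing_tokens`` (or otherwise non-numeric)
    becomes NaN. By default every numeric column other than the group
    and site columns is treated as a trait. Row order is preserved.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                     na_values=list(missing_tokens), keep_default_na=True,
                     skipinitialspace=True)
    if group_column not in df.columns:
        raise ConfigurationError(
            f"group column {group_column!r} not found in {path.name}; "
            f"columns are {list(df.columns)}"
        )
    reserved = {group_column}
    if site_column is not None:
        if site_column not in df.columns:
            raise ConfigurationError(f"site column {site_column!r} not found")
        reserved.add(site_column)
    if trait_columns is None:
        candidates = [c for c in df.columns if c not in reserved]
        numeric = df[candidates].apply(pd.to_numeric, errors="coerce")
        # keep columns with at least one parseable number
        trait_columns = [c for c in candidates if numeric[c].notna().any()]
    else:
        missing = [c for c in trait_columns if c not in df.columns]
        if missing:
            raise ConfigurationError(f"trait columns not found: {missing}")
    if len(trait_columns) == 0:
        raise FormatError(f"no trait columns found in {path.name}")
    values = (
        df[list(trait_columns)].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    )
    return TraitMatrix(
        values=values,
        trait_names=list(trait_columns),
        group=df[group_column].to_numpy(object),
        site=None if site_column is None else df[site_column].to_numpy(object),
    )


def read_env_table(
    path: str | Path, group_column: str = "group", sep: str | None = None
) -> EnvTable:
    """Read a one-row-per-water-body environmental table."""
    path = Path(path)
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if group_column not in df.columns:
        raise ConfigurationError(
            f"group column {group_column!r} not found in {path.name}"
        )
    df = df.set_index(group_column)
    df = df.apply(pd.to_numeric, errors="coerce")
    return EnvTable(data=df)


def coefficient_of_variation(x: Sequence[float] | np.ndarray) -> float:
    """Sample CV: standard deviation (n-1 denominator) over the mean.

    Dimensionless; missing values are dropped first. Raises
    :class:`UndefinedCVError` for a zero mean and
    :class:`InsufficientDataError` with fewer than two observations.
    """
    arr = np.asarray(x, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise InsufficientDataError(
            f"CV needs at least 2 observations, got {arr.size}"
        )
    mean = arr.mean()
    if mean == 0.0:
        raise UndefinedCVError("CV undefined: mean is zero")
    return float(arr.std(ddof=1) / mean)


def cv_table(tm: TraitMatrix) -> CVTable:
    """Per-group, per-trait CVs plus group mean CVs and pooled CVs.

    Undefined CVs (zero mean or <2 observations) are recorded as NaN,
    excluded from group means, and warned about rather than silently
    zeroed.
    """
    rows = []
    for g in tm.groups:
        sub = tm.subset(g)
        for j, trait in enumerate(tm.trait_names):
            try:
                cv = coefficient_of_variation(sub.values[:, j])
            except (UndefinedCVError, InsufficientDataError) as exc:
                warnings.warn(
                    f"CV undefined for trait {trait!r} in group {g!r}: {exc}",
                    stacklevel=2,
                )
                cv = np.nan
            rows.append({"trait": trait, "group": g, "cv": cv})
    per_group = pd.DataFrame(rows)
    group_mean = per_group.groupby("group", sort=False)["cv"].mean()
    group_mean.name = "mean_cv"

    pooled = {}
    for j, trait in enumerate(tm.trait_names):
        try:
            pooled[trait] = coefficient_of_variation(tm.values[:, j])
        except (UndefinedCVError, InsufficientDataError):
            pooled[trait] = np.nan
    return CVTable(
        per_group=per_group,
        group_mean_cv=group_mean,
        pooled=pd.Series(pooled, name="cv"),
    )


def light_extinction_coefficient(I0: float, Id: float, d: float) -> float:
    """Exponential light attenuation rate K = (1/d) ln(I0/Id), per metre.

    ``I0`` is photosynthetically active radiation at the surface, ``Id``
    at depth ``d`` (m). All arguments must be strictly positive.
    """
    if I0 <= 0 or Id <= 0 or d <= 0:
        raise DomainError(
            f"light extinction needs positive I0, Id, d; got {I0}, {Id}, {d}"
        )
    return float(np.log(I0 / Id) / d)


def write_cv_tables(cvt: CVTable, out_dir: str | Path, prefix: str = "cv") -> None:
    """Write the tidy per-group CV table and the group-level summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cvt.per_group.to_csv(out_dir / f"{prefix}_per_group.csv", index=False)
    cvt.group_mean_cv.rename_axis("group").reset_index().to_csv(
        out_dir / f"{prefix}_group_summary.csv", index=False
    )
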