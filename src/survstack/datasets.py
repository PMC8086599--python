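"""Survival dataset container, delimited-text I/O, splitting and feature tiers.

The universal input everywhere in this package is a :class:`SurvivalDataset`:
a numeric covariate matrix (missing cells are NaN), a non-negative follow-up
time per patient and a 0/1 event indicator (1 = the event, e.g. death, was
observed before the end of follow-up; 0 = censored).  Categorical covariates
must be pre-encoded numerically; binary covariates are 0/1.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalDataset",
    "FeatureSet",
    "survival_y",
    "load_dataset",
    "write_dataset",
    "split_train_test",
    "make_feature_sets",
]

#: sentinel strings that parse to a missing covariate cell
NA_STRINGS = ("", "NA")


def survival_y(times: np.ndarray, events: np.ndarray) -> np.ndarray:
    """Pack times and event indicators into the structured array used as ``y``.

    The layout (boolean field ``event``, float field ``time``) is the
    scikit-survival convention, so the result can be fed directly to
    scikit-survival estimators and metrics as well as to this package's own.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    y = np.empty(len(times), dtype=[("event", "?"), ("time", "<f8")])
    y["event"] = events.astype(bool)
    y["time"] = times
    return y


@dataclass
class SurvivalDataset:
    """Patient-level right-censored survival data.

    Parameters
    ----------
    covariates : ndarray of shape (n_patients, n_covariates)
        Numeric covariate matrix; missing entries are ``NaN``.
    times : ndarray of shape (n_patients,)
        Non-negative follow-up times (months).
    events : ndarray of shape (n_patients,)
        Event indicators in {0, 1}; 1 means the event was observed.
    covariate_names : sequence of str
        Unique column identifiers, one per covariate.
    group_labels : sequence, optional
        Per-patient category (e.g. cohort) used for stratified evaluation.
    """

    covariates: np.ndarray
    times: np.ndarray
    events: np.ndarray
    covariate_names: list[str] = field(default_factory=list)
    group_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events)
        self.covariate_names = list(self.covariate_names)
        n = len(self.times)
        if self.covariates.shape[0] != n or len(self.events) != n:
            raise ValueError(
                f"inconsistent lengths: {self.covariates.shape[0]} covariate rows, "
                f"{n} times, {len(self.events)} events"
            )
        if np.any(~np.isfinite(self.times)) or np.any(self.times < 0):
            raise ValueError("times must be finite and >= 0")
        ev = np.asarray(self.events, dtype=float)
        if np.any(np.isnan(ev)) or not np.isin(ev, (0.0, 1.0)).all():
            bad = np.flatnonzero(~np.isin(ev, (0.0, 1.0)))[:1]
            raise ValueError(f"event indicators must be exactly 0 or 1 (first bad row: {bad})")
        self.events = ev.astype(int)
        if len(self.covariate_names) != self.covariates.shape[1]:
            raise ValueError("covariate_names must match the number of covariate columns")
        if len(set(self.covariate_names)) != len(self.covariate_names):
            raise ValueError("covariate_names must be unique")
        if self.group_labels is not None:
            self.group_labels = np.asarray(self.group_labels)
            if len(self.group_labels) != n:
                raise ValueError("group_labels length mismatch")

    @property
    def n_patients(self) -> int:
        return len(self.times)

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]

    @property
    def y(self) -> np.ndarray:
        """Structured (event, time) array — scikit-survival's ``y`` convention."""
        return survival_y(self.times, self.events)

    def column(self, name: str) -> np.ndarray:
        return self.covariates[:, self.covariate_names.index(name)]

    def subset(self, index: np.ndarray) -> "SurvivalDataset":
        """Row subset (copy) by integer or boolean index."""
        index = np.asarray(index)
        return SurvivalDataset(
            covariates=self.covariates[index].copy(),
            times=self.times[index].copy(),
            events=self.events[index].copy(),
            covariate_names=list(self.covariate_names),
            group_labels=None if self.group_labels is None else self.group_labels[index].copy(),
        )

    def select(self, names: Sequence[str]) -> "SurvivalDataset":
        """Column subset (copy) in the given order."""
        idx = [self.covariate_names.index(n) for n in names]
        return dataclasses.replace(
            self,
            covariates=self.covariates[:, idx].copy(),
            covariate_names=list(names),
        )

    def matrix(self, feature_set: "FeatureSet | None" = None) -> np.ndarray:
        if feature_set is None:
            return self.covariates
        idx = [self.covariate_names.index(n) for n in feature_set.covariate_names]
        return self.covariates[:, idx]

    def to_frame(self, time_column: str = "time", event_column: str = "event") -> pd.DataFrame:
        df = pd.DataFrame(self.covariates, columns=self.covariate_names)
        df.insert(0, event_column, self.events)
        df.insert(0, time_column, self.times)
        if self.group_labels is not None:
            df["group"] = self.group_labels
        return df


@dataclass(frozen=True)
class FeatureSet:
    """A named, ordered subset of a dataset's covariates (an availability tier)."""

    name: str
    covariate_names: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.covariate_names)


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def load_dataset(
    path: str | Path,
    time_column: str = "time",
    event_column: str = "event",
    group_column: str | None = None,
    delimiter: str | None = None,
) -> SurvivalDataset:
    """Read a delimited text file with a header row into a :class:`SurvivalDataset`.

    Every column other than the time, event and (optional) group column becomes
    a covariate.  Empty cells and the string ``NA`` parse to missing; any other
    non-numeric covariate cell raises a parse error naming the row.
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in (time_column, event_column):
        if col not in df.columns:
            raise ValueError(f"required column {col!r} not found in {path.name}")
    if group_column is not None and group_column not in df.columns:
        raise ValueError(f"group column {group_column!r} not found in {path.name}")

    def _required_numeric(col: str) -> np.ndarray:
        raw = df[col].str.strip()
        vals = pd.to_numeric(raw, errors="coerce")
        bad = vals.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"column {col!r}, row {row}: cannot parse {raw.iloc[row]!r} (missing not allowed)")
        return vals.to_numpy(dtype=float)

    times = _required_numeric(time_column)
    if (times < 0).any():
        row = int(np.flatnonzero(times < 0)[0])
        raise ValueError(f"negative time at row {row}: {times[row]}")
    events = _required_numeric(event_column)
    if not np.isin(events, (0.0, 1.0)).all():
        row = int(np.flatnonzero(~np.isin(events, (0.0, 1.0)))[0])
        raise ValueError(f"event value outside {{0,1}} at row {row}: {events[row]}")

    drop = {time_column, event_column} | ({group_column} if group_column else set())
    cov_names = [c for c in df.columns if c not in drop]
    cols = []
    for col in cov_names:
        raw = df[col].str.strip()
        is_na = raw.isin(NA_STRINGS)
        vals = pd.to_numeric(raw.where(~is_na), errors="coerce")
        bad = vals.isna() & ~is_na
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"covariate {col!r}, row {row}: cannot parse {raw.iloc[row]!r}")
        cols.append(vals.to_numpy(dtype=float))
    covariates = np.column_stack(cols) if cols else np.empty((len(df), 0))
    groups = df[group_column].to_numpy() if group_column else None
    return SurvivalDataset(covariates, times, events, cov_names, groups)


def write_dataset(
    ds: SurvivalDataset,
    path: str | Path,
    time_column: str = "time",
    event_column: str = "event",
    delimiter: str | None = None,
) -> None:
    """Write a dataset back to delimited text; missing cells become empty fields."""
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    df = pd.DataFrame(ds.covariates, columns=ds.covariate_names)
    df.insert(0, event_column, ds.events)
    df.insert(0, time_column, ds.times)
    if ds.group_labels is not None:
        df["group"] = ds.group_labels
    df.to_csv(path, sep=sep, index=False, na_rep="")


def split_train_test(
    ds: SurvivalDataset, test_fraction: float, seed: int
) -> tuple[SurvivalDataset, SurvivalDataset]:
    """Random disjoint train/test partition by simple random sampling of patients.

    The train set gets ``round(n * (1 - test_fraction))`` patients and the
    test set the remainder.  The same seed always yields the same split.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    n = ds.n_patients
    if n < 2:
        raise ValueError("need at least 2 patients to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(n * (1.0 - test_fraction)))
    n_train = min(max(n_train, 1), n - 1)
    return ds.subset(np.sort(perm[:n_train])), ds.subset(np.sort(perm[n_train:]))


def make_feature_sets(
    ds: SurvivalDataset,
    base_names: Sequence[str],
    availability_thresholds: Sequence[float] = (),
) -> list[FeatureSet]:
    """Build nested availability tiers of covariates.

    Tier 0 is exactly ``base_names`` (authoritative even if fully missing).
    Each subsequent tier adds every covariate whose non-missing fraction is at
    least the corresponding threshold; thresholds must be descending, so the
    tiers are nested by construction — mirroring feature panels defined by
    "covariates present in at least X% of patients".
    """
    unknown = [n for n in base_names if n not in ds.covariate_names]
    if unknown:
        raise ValueError(f"unknown base covariate(s): {unknown}")
    thresholds = list(availability_thresholds)
    if any(not 0.0 < t <= 1.0 for t in thresholds):
        raise ValueError("availability thresholds must lie in (0, 1]")
    if any(a <= b for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("availability thresholds must be strictly descending")
    avail = 1.0 - np.mean(np.isnan(ds.covariates), axis=0)
    tiers: list[FeatureSet] = []
    current = list(base_names)
    tiers.append(FeatureSet(name=f"tier{len(current)}", covariate_names=tuple(current)))
    for thr in thresholds:
        extra = [
            name
            for name, a in zip(ds.covariate_names, avail)
            if a >= thr and name not in current
        ]
        current = current + extra
        tiers.append(FeatureSet(name=f"tier{len(current)}", covariate_names=tuple(current)))
    return tiers
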