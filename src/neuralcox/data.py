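"""Right-censored survival data container and CSV I/O.

A record is a covariate vector ``x``, an observed time ``Z`` (the event
time if the event was observed, otherwise the censoring time), an event
indicator ``E`` in {0, 1}, and optionally an integer treatment label.
The reserved CSV column names are ``time``, ``event`` and ``treatment``;
every other column is treated as a covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RESERVED_COLUMNS = ("time", "event", "treatment")


@dataclass
class SurvivalDataset:
    """Tabular right-censored survival data.

    Attributes
    ----------
    covariates : (n, d) float array
    time : (n,) float array of observed times Z >= 0
    event : (n,) int array, 1 = event observed, 0 = right-censored
    treatment : optional (n,) int array of group labels in {0, ..., k-1}
    feature_names : d column names for the covariates
    """

    covariates: np.ndarray
    time: np.ndarray
    event: np.ndarray
    treatment: np.ndarray | None = None
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if self.treatment is not None:
            self.treatment = np.asarray(self.treatment)
        if not self.feature_names:
            self.feature_names = [f"x{i}" for i in range(self.covariates.shape[1])]
        self._validate()
        self.event = self.event.astype(np.int64)
        if self.treatment is not None:
            self.treatment = self.treatment.astype(np.int64)

    def _validate(self) -> None:
        n = self.covariates.shape[0]
        if len(self.feature_names) != self.covariates.shape[1]:
            raise ValueError(
                f"{len(self.feature_names)} feature names for "
                f"{self.covariates.shape[1]} covariate columns"
            )
        for name, arr in (("time", self.time), ("event", self.event)):
            if arr.shape != (n,):
                raise ValueError(f"column '{name}' has {arr.shape[0]} rows, expected {n}")
        if self.treatment is not None and self.treatment.shape != (n,):
            raise ValueError(f"column 'treatment' has {self.treatment.shape[0]} rows, expected {n}")
        bad = np.flatnonzero(~np.isfinite(self.time) | (self.time < 0))
        if bad.size:
            raise ValueError(f"column 'time' has a negative or non-finite value at row {bad[0]}")
        ev = np.asarray(self.event, dtype=float)
        bad = np.flatnonzero(~np.isin(ev, (0.0, 1.0)))
        if bad.size:
            raise ValueError(
                f"column 'event' must be 0 or 1; found {self.event[bad[0]]!r} at row {bad[0]}"
            )
        if self.treatment is not None:
            tr = np.asarray(self.treatment, dtype=float)
            bad = np.flatnonzero((tr < 0) | (tr != np.round(tr)))
            if bad.size:
                raise ValueError(
                    f"column 'treatment' must hold non-negative integer labels; "
                    f"found {self.treatment[bad[0]]!r} at row {bad[0]}"
                )

    @property
    def n(self) -> int:
        return self.covariates.shape[0]

    @property
    def d(self) -> int:
        return self.covariates.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, idx: np.ndarray) -> "SurvivalDataset":
        """Row-subset (boolean mask or integer indices)."""
        idx = np.asarray(idx)
        return SurvivalDataset(
            covariates=self.covariates[idx],
            time=self.time[idx],
            event=self.event[idx],
            treatment=None if self.treatment is None else self.treatment[idx],
            feature_names=list(self.feature_names),
        )

    def with_treatment_covariate(self) -> "SurvivalDataset":
        """Return a copy with the treatment label appended as the last covariate.

        Models that take treatment as an input (for the recommender function)
        are trained on this representation; the appended column keeps the
        reserved name ``treatment``.
        """
        if self.treatment is None:
            raise ValueError("dataset has no treatment column")
        return SurvivalDataset(
            covariates=np.column_stack([self.covariates, self.treatment.astype(float)]),
            time=self.time,
            event=self.event,
            treatment=self.treatment,
            feature_names=list(self.feature_names) + ["treatment"],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.covariates, columns=self.feature_names)
        df["time"] = self.time
        df["event"] = self.event
        if self.treatment is not None:
            df["treatment"] = self.treatment
        return df

    def __eq__(self, other: object) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, SurvivalDataset):
            return NotImplemented
        same_treat = (self.treatment is None) == (other.treatment is None) and (
            self.treatment is None or np.array_equal(self.treatment, other.treatment)
        )
        return (
            np.array_equal(self.covariates, other.covariates)
            and np.array_equal(self.time, other.time)
            and np.array_equal(self.event, other.event)
            and same_treat
            and self.feature_names == other.feature_names
        )


def from_frame(df: pd.DataFrame) -> SurvivalDataset:
    """Build a dataset from a DataFrame using the reserved column names."""
    for required in ("time", "event"):
        if required not in df.columns:
            raise ValueError(f"missing required column '{required}'")
    feat_cols = [c for c in df.columns if c not in RESERVED_COLUMNS]
    return SurvivalDataset(
        covariates=df[feat_cols].to_numpy(dtype=float),
        time=df["time"].to_numpy(dtype=float),
        event=df["event"].to_numpy(),
        treatment=df["treatment"].to_numpy() if "treatment" in df.columns else None,
        feature_names=feat_cols,
    )


def read_csv(path) -> SurvivalDataset:
    """Read a survival dataset from a comma-separated file with a header row."""
    return from_frame(pd.read_csv(path, float_precision="round_trip"))


def write_csv(dataset: SurvivalDataset, path) -> None:
    """Write a dataset so that ``read_csv`` round-trips it exactly.

    Uses repr-precision floats; covariate column order is preserved.
    """
    dataset.to_frame().to_csv(path, index=False, float_format="%.17g")
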