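"""Long-format longitudinal data containers, CSV I/O and validation.

The central container is :class:`LongitudinalDataset`: a subject-indexed,
irregularly sampled collection of response profiles with a group label per
subject and optional numeric covariates.  Time is measured in hours since an
alignment event (e.g. sleep onset in ambulatory blood-pressure monitoring);
the response is assumed to already be on the analysis scale (e.g. log mmHg).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LongitudinalDataset",
    "CurveTable",
    "SchemaError",
    "ValidationError",
    "read_long_csv",
    "write_long_csv",
    "summarize",
]


class SchemaError(ValueError):
    """A required column is missing or cannot be interpreted."""


class ValidationError(ValueError):
    """The data violate a dataset invariant (duplicates, non-finite values...)."""


@dataclass
class LongitudinalDataset:
    """Long-format longitudinal data: one row per (subject, time) observation.

    Parameters
    ----------
    frame
        DataFrame with at least columns ``subject``, ``group``, ``time``,
        ``response`` plus one numeric column per covariate.
    covariates
        Names of covariate columns within ``frame`` (may be empty).
    group_levels
        Group labels in reference order (first level is the reference unless
        a model spec overrides it).  Defaults to first-appearance order.
    """

    frame: pd.DataFrame
    covariates: tuple[str, ...] = ()
    group_levels: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        required = ["subject", "group", "time", "response", *self.covariates]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        df = self.frame.loc[:, required].copy()
        df["subject"] = df["subject"].astype(str)
        df["group"] = df["group"].astype(str)
        for col in ("time", "response", *self.covariates):
            try:
                df[col] = pd.to_numeric(df[col], errors="raise")
            except (ValueError, TypeError) as exc:
                bad = pd.to_numeric(self.frame[col], errors="coerce")
                rows = list(self.frame.index[bad.isna() & self.frame[col].notna()][:5])
                raise SchemaError(f"non-numeric values in column {col!r} at rows {rows}") from exc
        df = df.sort_values(["subject", "time"], kind="mergesort").reset_index(drop=True)
        if self.group_levels is None:
            seen = self.frame["group"].astype(str)
            self.group_levels = tuple(dict.fromkeys(seen))
        self.frame = df
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        df = self.frame
        for col in ("time", "response"):
            if not np.isfinite(df[col].to_numpy(float)).all():
                raise ValidationError(f"non-finite values in column {col!r}")
        for col in self.covariates:
            vals = df[col].to_numpy(float)
            if np.isnan(vals).any():
                raise ValidationError(f"missing covariate values in column {col!r}")
        dup = df.duplicated(subset=["subject", "time"], keep=False)
        if dup.any():
            offenders = df.loc[dup, ["subject", "time"]].drop_duplicates()
            pairs = [(r.subject, float(r.time)) for r in offenders.itertuples()][:10]
            raise ValidationError(f"duplicated (subject, time) pairs: {pairs}")
        n_groups = df.groupby("subject", sort=False)["group"].nunique()
        multi = n_groups[n_groups > 1]
        if len(multi):
            raise ValidationError(f"subjects mapped to multiple groups: {list(multi.index)}")
        unknown = set(df["group"]) - set(self.group_levels)
        if unknown:
            raise ValidationError(f"group labels outside declared levels: {sorted(unknown)}")

    # -- accessors --------------------------------------------------------
    @property
    def subjects(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.frame["subject"]))

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_obs(self) -> int:
        return len(self.frame)

    def subject_group(self) -> pd.Series:
        """Group label per subject (index: subject id)."""
        return self.frame.groupby("subject", sort=False)["group"].first()

    def times(self) -> np.ndarray:
        return self.frame["time"].to_numpy(float)

    def response(self) -> np.ndarray:
        return self.frame["response"].to_numpy(float)

    def covariate_matrix(self) -> np.ndarray:
        if not self.covariates:
            return np.empty((self.n_obs, 0))
        return self.frame.loc[:, list(self.covariates)].to_numpy(float)

    def __eq__(self, other: object) -> bool:  # field-for-field equality
        if not isinstance(other, LongitudinalDataset):
            return NotImplemented
        return (
            self.covariates == other.covariates
            and self.group_levels == other.group_levels
            and self.frame.shape == other.frame.shape
            and all(
                self.frame[c].equals(other.frame[c])
                if self.frame[c].dtype == object
                else np.allclose(self.frame[c], other.frame[c], rtol=0, atol=0)
                for c in self.frame.columns
            )
        )


@dataclass
class CurveTable:
    """Curve estimates on a grid of equally spaced time points.

    Columns beyond ``grid``: one estimate per group or contrast, with
    optional ``sd``, ``lower``, ``upper``.
    """

    grid: np.ndarray
    label: str
    estimate: np.ndarray
    sd: np.ndarray | None = None
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, float)
        self.estimate = np.asarray(self.estimate, float)
        if np.any(np.diff(self.grid) <= 0):
            raise ValidationError("grid must be strictly increasing")
        if self.lower is not None and self.upper is not None:
            if np.any(self.lower > self.estimate + 1e-12) or np.any(
                self.estimate > self.upper + 1e-12
            ):
                raise ValidationError("bands must bracket the estimate")

    def to_frame(self) -> pd.DataFrame:
        out = {"time": self.grid, "label": self.label, "estimate": self.estimate}
        for name in ("sd", "lower", "upper"):
            val = getattr(self, name)
            if val is not None:
                out[name] = np.asarray(val, float)
        return pd.DataFrame(out)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


_DEFAULT_MAP = {
    "subject": "subject",
    "group": "group",
    "time": "time",
    "response": "response",
}


def read_long_csv(
    path,
    column_map: dict[str, str] | None = None,
    covariates: tuple[str, ...] = (),
    group_levels: tuple[str, ...] | None = None,
) -> LongitudinalDataset:
    """Read a long-format CSV into a :class:`LongitudinalDataset`.

    ``column_map`` maps canonical roles (``subject``, ``group``, ``time``,
    ``response``) to the file's column names; covariate columns are used
    under their own names.
    """
    cmap = dict(_DEFAULT_MAP)
    if column_map:
        cmap.update(column_map)
    # round_trip parsing keeps write_long_csv -> read_long_csv bit-exact
    raw = pd.read_csv(path, float_precision="round_trip")
    missing = [v for v in cmap.values() if v not in raw.columns]
    missing += [c for c in covariates if c not in raw.columns]
    if missing:
        raise SchemaError(f"columns not found in {path}: {missing}")
    frame = raw.rename(columns={v: k for k, v in cmap.items()})
    return LongitudinalDataset(frame, covariates=covariates, group_levels=group_levels)


def write_long_csv(dataset: LongitudinalDataset, path) -> None:
    dataset.frame.to_csv(path, index=False)


def summarize(dataset: LongitudinalDataset) -> dict:
    """Per-group subject counts, per-subject observation counts and time range."""
    per_subject = dataset.frame.groupby("subject", sort=False).size()
    groups = dataset.subject_group()
    return {
        "n_subjects": dataset.n_subjects,
        "n_obs": dataset.n_obs,
        "group_sizes": {g: int((groups == g).sum()) for g in dataset.group_levels},
        "obs_per_subject": {s: int(per_subject[s]) for s in dataset.subjects},
        "time_range": (float(dataset.frame["time"].min()), float(dataset.frame["time"].max())),
    }
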