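"""Cohort container, feature schema, delimited-text I/O and multi-trial
feature intersection.

A cohort is a feature table plus right-censored follow-up: an observed time in
days (time of death or of last contact) and an event indicator (1 = death
observed, 0 = censored).  Features are typed as continuous, nominal or
ordinal; the schema records observed ranges and category levels so that
encoders and the clinical kernel can be fit once and reused.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import EmptyIntersectionError, SchemaError, ValidationError

CONTINUOUS = "continuous"
NOMINAL = "nominal"
ORDINAL = "ordinal"
_KINDS = (CONTINUOUS, NOMINAL, ORDINAL)


@dataclass(frozen=True)
class FeatureSpec:
    """Description of a single feature.

    For continuous features ``vmin``/``vmax`` hold the observed range (same
    units as the feature); for nominal/ordinal features ``levels`` is the
    ordered list of category levels (order is meaningful for ordinal).
    """

    name: str
    kind: str
    vmin: float | None = None
    vmax: float | None = None
    levels: tuple = ()

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise SchemaError(f"unknown feature kind {self.kind!r} for {self.name!r}")
        if self.kind == CONTINUOUS:
            if self.vmin is None or self.vmax is None or not (self.vmax >= self.vmin):
                raise SchemaError(
                    f"continuous feature {self.name!r} needs max >= min, "
                    f"got [{self.vmin}, {self.vmax}]"
                )
        else:
            if len(self.levels) < 1:
                raise SchemaError(f"{self.kind} feature {self.name!r} has no levels")


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered collection of :class:`FeatureSpec` with unique names."""

    features: tuple[FeatureSpec, ...]

    def __post_init__(self):
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            dupes = {n for n in names if names.count(n) > 1}
            raise SchemaError(f"duplicate feature names: {sorted(dupes)}")
        object.__setattr__(self, "features", tuple(self.features))

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def __len__(self):
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def __getitem__(self, name: str) -> FeatureSpec:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    @classmethod
    def infer(cls, frame: pd.DataFrame) -> "FeatureSchema":
        """Infer a schema from a feature table.

        Numeric columns become continuous (with their observed min/max);
        everything else becomes nominal with sorted unique values as levels.
        Missing cells are ignored during inference.
        """
        specs = []
        for name in frame.columns:
            col = frame[name]
            if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
                vals = col.dropna().astype(float)
                vmin = float(vals.min()) if len(vals) else 0.0
                vmax = float(vals.max()) if len(vals) else 0.0
                specs.append(FeatureSpec(name, CONTINUOUS, vmin=vmin, vmax=vmax))
            else:
                levels = tuple(sorted(col.dropna().astype(str).unique()))
                if not levels:
                    levels = ("missing",)
                specs.append(FeatureSpec(name, NOMINAL, levels=levels))
        return cls(tuple(specs))


@dataclass
class SurvivalCohort:
    """Right-censored survival cohort: features + (time, event).

    Invariants enforced at construction: strictly positive finite times,
    event indicator restricted to {0, 1, False, True}, and equal lengths of
    feature table, time and event vectors.
    """

    frame: pd.DataFrame
    time: np.ndarray
    event: np.ndarray
    schema: FeatureSchema = None
    name: str | None = None

    def __post_init__(self):
        self.frame = self.frame.reset_index(drop=True)
        self.time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event)
        if event.dtype != bool:
            uniq = set(np.unique(event).tolist())
            if not uniq <= {0, 1, 0.0, 1.0, False, True}:
                raise ValidationError(
                    f"event indicator must be 0/1 or False/True, found {sorted(uniq)!r}"
                )
            event = event.astype(int).astype(bool)
        self.event = event
        if not (len(self.frame) == len(self.time) == len(self.event)):
            raise ValidationError(
                f"length mismatch: {len(self.frame)} feature rows, "
                f"{len(self.time)} times, {len(self.event)} events"
            )
        bad = np.flatnonzero(~np.isfinite(self.time) | (self.time <= 0))
        if bad.size:
            raise ValidationError(
                "follow-up times must be strictly positive and finite; "
                f"offending rows (0-based): {bad.tolist()[:20]}"
            )
        if self.schema is None:
            self.schema = FeatureSchema.infer(self.frame)
        else:
            missing = [f.name for f in self.schema if f.name not in self.frame.columns]
            if missing:
                raise SchemaError(f"schema features absent from table: {missing}")
            self.frame = self.frame[self.schema.names]

    @property
    def n_samples(self) -> int:
        return len(self.frame)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_surv(self) -> np.ndarray:
        """Structured (event, time) array as used by scikit-survival."""
        from sksurv.util import Surv

        return Surv.from_arrays(self.event, self.time)

    def subset(self, idx) -> "SurvivalCohort":
        idx = np.asarray(idx)
        return SurvivalCohort(
            frame=self.frame.iloc[idx].reset_index(drop=True),
            time=self.time[idx],
            event=self.event[idx],
            schema=self.schema,
            name=self.name,
        )


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_cohort(path, time_col="time", event_col="event", schema=None, name=None):
    """Read a delimited-text cohort file (CSV, or TSV by extension).

    Missing cells are kept as missing (for later imputation), never dropped.
    """
    frame = pd.read_csv(path, sep=_sep_for(path))
    for col in (time_col, event_col):
        if col not in frame.columns:
            raise SchemaError(f"column {col!r} not found in {path}; have {list(frame.columns)}")
    time = frame[time_col].to_numpy(dtype=float)
    event = frame[event_col].to_numpy()
    feats = frame.drop(columns=[time_col, event_col])
    return SurvivalCohort(frame=feats, time=time, event=event, schema=schema, name=name)


def write_cohort(cohort: SurvivalCohort, path, time_col="time", event_col="event"):
    """Write a cohort back to delimited text (inverse of :func:`read_cohort`)."""
    out = cohort.frame.copy()
    out[time_col] = cohort.time
    out[event_col] = cohort.event.astype(int)
    out.to_csv(path, sep=_sep_for(path), index=False)
    return path


def _merge_specs(specs: list[FeatureSpec]) -> FeatureSpec:
    """Combine per-cohort specs of the same feature into one covering spec."""
    first = specs[0]
    if first.kind == CONTINUOUS:
        return replace(
            first,
            vmin=min(s.vmin for s in specs),
            vmax=max(s.vmax for s in specs),
        )
    levels = list(first.levels)
    for s in specs[1:]:
        for lv in s.levels:
            if lv not in levels:
                levels.append(lv)
    return replace(first, levels=tuple(levels))


def intersect_features(cohorts: list[SurvivalCohort]) -> list[SurvivalCohort]:
    """Restrict every cohort to the features shared by all of them.

    A feature is shared when the same name occurs with the same kind in every
    cohort; this mirrors how overlapping clinical trials with different case
    report forms are merged before pooled training.  Level lists / ranges of
    the returned (identical) schemas cover all input cohorts.
    """
    if not cohorts:
        raise ValidationError("need at least one cohort")
    if len(cohorts) == 1:
        return list(cohorts)
    keys = [{(f.name, f.kind) for f in c.schema} for c in cohorts]
    common = set.intersection(*keys)
    # keep the first cohort's feature order
    ordered = [f.name for f in cohorts[0].schema if (f.name, f.kind) in common]
    if not ordered:
        raise EmptyIntersectionError(
            "no feature (name, kind) is present in every cohort"
        )
    merged = tuple(
        _merge_specs([c.schema[name] for c in cohorts]) for name in ordered
    )
    schema = FeatureSchema(merged)
    return [
        SurvivalCohort(
            frame=c.frame[ordered].copy(),
            time=c.time,
            event=c.event,
            schema=schema,
            name=c.name,
        )
        for c in cohorts
    ]
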