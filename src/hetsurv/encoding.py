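"""Feature encoding: imputation, standardization and dummy coding.

Continuous features are imputed (median) and standardized to zero mean and
unit variance on the fitting data; nominal and ordinal features are imputed
(mode) and expanded into 0/1 indicator columns with the first schema level as
the dropped reference, which avoids collinearity for linear models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import CONTINUOUS, FeatureSchema, SurvivalCohort
from .exceptions import SchemaError, ValidationError


@dataclass
class DesignMatrix:
    """Numeric matrix (samples x encoded columns) with column provenance."""

    values: np.ndarray
    columns: list[str]
    provenance: dict  # encoded column name -> source feature name
    encoder: "CohortEncoder" = None

    @property
    def shape(self):
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.columns)


class CohortEncoder(BaseEstimator, TransformerMixin):
    """Fit-once, reuse-on-new-data encoder for mixed-type feature tables.

    Parameters
    ----------
    schema : FeatureSchema, optional
        If omitted, inferred from the fitting data.
    impute : {"median_mode", "none"}
        ``median_mode`` replaces missing continuous values by the training
        median and missing categorical values by the training mode before
        encoding; ``none`` requires complete data.
    """

    def __init__(self, schema: FeatureSchema = None, impute: str = "median_mode"):
        self.schema = schema
        self.impute = impute

    def fit(self, X: pd.DataFrame, y=None):
        if self.impute not in ("median_mode", "none"):
            raise ValidationError(f"unknown impute strategy {self.impute!r}")
        schema = self.schema if self.schema is not None else FeatureSchema.infer(X)
        self.schema_ = schema
        self.fill_ = {}
        self.mean_ = {}
        self.scale_ = {}
        self.columns_ = []
        self.provenance_ = {}
        for spec in schema:
            col = X[spec.name]
            if spec.kind == CONTINUOUS:
                vals = pd.to_numeric(col, errors="coerce")
                self._check_missing(vals, spec.name)
                fill = float(vals.median()) if vals.notna().any() else 0.0
                filled = vals.fillna(fill).to_numpy(dtype=float)
                mu = float(filled.mean())
                sd = float(filled.std(ddof=0))
                self.fill_[spec.name] = fill
                self.mean_[spec.name] = mu
                self.scale_[spec.name] = sd if sd > 0 else 1.0
                self.columns_.append(spec.name)
                self.provenance_[spec.name] = spec.name
            else:
                vals = col.astype("object")
                self._check_missing(vals, spec.name)
                nonmiss = vals.dropna().astype(str)
                fill = nonmiss.mode().iloc[0] if len(nonmiss) else spec.levels[0]
                self.fill_[spec.name] = str(fill)
                for level in spec.levels[1:]:  # first level = dropped reference
                    cname = f"{spec.name}={level}"
                    self.columns_.append(cname)
                    self.provenance_[cname] = spec.name
        self.n_features_in_ = len(schema)
        return self

    def _check_missing(self, vals, name):
        if self.impute == "none" and vals.isna().any():
            raise ValidationError(
                f"feature {name!r} contains missing values and impute='none'"
            )

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        cols = []
        for spec in self.schema_:
            if spec.name not in X.columns:
                raise SchemaError(f"feature {spec.name!r} missing from input")
            col = X[spec.name]
            if spec.kind == CONTINUOUS:
                vals = pd.to_numeric(col, errors="coerce")
                self._check_missing(vals, spec.name)
                v = vals.fillna(self.fill_[spec.name]).to_numpy(dtype=float)
                cols.append((v - self.mean_[spec.name]) / self.scale_[spec.name])
            else:
                vals = col.astype("object")
                self._check_missing(vals, spec.name)
                v = vals.fillna(self.fill_[spec.name]).astype(str)
                unseen = sorted(set(v.unique()) - set(map(str, spec.levels)))
                if unseen:
                    raise SchemaError(
                        f"feature {spec.name!r}: unseen level(s) {unseen} "
                        f"(known: {list(spec.levels)})"
                    )
                for level in spec.levels[1:]:
                    cols.append((v == str(level)).to_numpy(dtype=float))
        return np.column_stack(cols) if cols else np.empty((len(X), 0))

    def impute_frame(self, X: pd.DataFrame) -> pd.DataFrame:
        """Return the raw feature table with training fills applied, without
        standardization or dummy coding (used by the clinical kernel)."""
        out = {}
        for spec in self.schema_:
            col = X[spec.name]
            if spec.kind == CONTINUOUS:
                vals = pd.to_numeric(col, errors="coerce")
                self._check_missing(vals, spec.name)
                out[spec.name] = vals.fillna(self.fill_[spec.name]).astype(float)
            else:
                vals = col.astype("object")
                self._check_missing(vals, spec.name)
                out[spec.name] = vals.fillna(self.fill_[spec.name]).astype(str)
        return pd.DataFrame(out, index=X.index)

    def transform_design(self, X: pd.DataFrame) -> DesignMatrix:
        return DesignMatrix(
            values=self.transform(X),
            columns=list(self.columns_),
            provenance=dict(self.provenance_),
            encoder=self,
        )


def encode_features(cohort: SurvivalCohort, impute: str = "median_mode") -> DesignMatrix:
    """Encode a cohort's feature table; the fitted encoder rides along on the
    returned :class:`DesignMatrix` for reuse on new data."""
    enc = CohortEncoder(schema=cohort.schema, impute=impute).fit(cohort.frame)
    return enc.transform_design(cohort.frame)
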