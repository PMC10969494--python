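"""Tabular container for areal count data.

One record per areal unit: unit ID, count response (possibly missing),
population used as the log offset, and a covariate matrix with a missingness
mask.  Missing cells are encoded as NaN in memory and as empty fields on
disk.  Synthetic datasets additionally carry the pre-masking truth so
imputation accuracy and predictive calibration can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    pass


@dataclass
class AreaTable:
    ids: np.ndarray                      # unit identifiers, order matches graph
    y: np.ndarray                        # counts, float with NaN for missing
    population: np.ndarray               # N_i > 0, offset O_i = log N_i
    X: np.ndarray                        # N x K covariates, NaN for missing
    covariate_names: list[str] = field(default_factory=list)
    y_true: np.ndarray | None = None     # pre-masking truth (synthetic only)
    X_true: np.ndarray | None = None

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.y = np.asarray(self.y, dtype=float)
        self.population = np.asarray(self.population, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.size == 0:
            self.X = self.X.reshape(len(self.ids), 0)
        if not self.covariate_names:
            self.covariate_names = [f"x{k + 1}" for k in range(self.X.shape[1])]
        n = len(self.ids)
        if not (self.y.shape == (n,) and self.population.shape == (n,) and self.X.shape[0] == n):
            raise SchemaError("inconsistent row counts across columns")
        if len(self.covariate_names) != self.X.shape[1]:
            raise SchemaError("covariate_names length must match X columns")

    # -- shapes and masks ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def k(self) -> int:
        return self.X.shape[1]

    @property
    def missing_y(self) -> np.ndarray:
        return np.isnan(self.y)

    @property
    def observed_y(self) -> np.ndarray:
        return ~np.isnan(self.y)

    @property
    def missing_X(self) -> np.ndarray:
        return np.isnan(self.X)

    @property
    def offset(self) -> np.ndarray:
        return np.log(self.population)

    def validate(self) -> None:
        """Hard schema checks (raise); soft per-unit issues go through
        ``carmap.report.validate_schema``."""
        if len(set(map(str, self.ids))) != self.n:
            raise SchemaError("duplicate unit IDs")
        if np.isnan(self.population).any() or (self.population <= 0).any():
            raise SchemaError("population must be positive for every unit (it is the offset)")
        yo = self.y[self.observed_y]
        if ((yo < 0) | (yo != np.round(yo))).any():
            raise SchemaError("observed counts must be nonnegative integers")

    # -- pandas / disk round trip ------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"id": self.ids.astype(str), "count": self.y,
                           "population": self.population})
        for k, name in enumerate(self.covariate_names):
            df[name] = self.X[:, k]
        return df

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        id_col: str = "id",
        count_col: str = "count",
        population_col: str = "population",
        covariate_cols: list[str] | None = None,
    ) -> "AreaTable":
        for col in (id_col, count_col, population_col):
            if col not in df.columns:
                raise SchemaError(f"required column {col!r} not found")
        if covariate_cols is None:
            covariate_cols = [c for c in df.columns
                              if c not in (id_col, count_col, population_col)]
        else:
            missing = [c for c in covariate_cols if c not in df.columns]
            if missing:
                raise SchemaError(f"covariate column(s) not found: {missing}")
        X = df[covariate_cols].to_numpy(dtype=float) if covariate_cols else \
            np.empty((len(df), 0))
        return cls(
            ids=df[id_col].to_numpy(),
            y=pd.to_numeric(df[count_col], errors="raise").to_numpy(dtype=float),
            population=df[population_col].to_numpy(dtype=float),
            X=X,
            covariate_names=list(covariate_cols),
        )

    def write_csv(self, path, *, write_truth: bool = True) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.17g")
        if write_truth and (self.y_true is not None or self.X_true is not None):
            truth = pd.DataFrame({"id": self.ids.astype(str)})
            if self.y_true is not None:
                truth["count_true"] = self.y_true
            if self.X_true is not None:
                for k, name in enumerate(self.covariate_names):
                    truth[f"{name}_true"] = self.X_true[:, k]
            truth.to_csv(path.with_name(path.stem + "_truth" + path.suffix),
                         index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path, **kwargs) -> "AreaTable":
        df = pd.read_csv(path, dtype={kwargs.get("id_col", "id"): str},
                         float_precision="round_trip")
        table = cls.from_frame(df, **kwargs)
        truth_path = Path(path).with_name(Path(path).stem + "_truth" + Path(path).suffix)
        if truth_path.exists():
            tdf = pd.read_csv(truth_path)
            if "count_true" in tdf.columns:
                table.y_true = tdf["count_true"].to_numpy(dtype=float)
            xcols = [f"{n}_true" for n in table.covariate_names]
            if all(c in tdf.columns for c in xcols):
                table.X_true = tdf[xcols].to_numpy(dtype=float)
        return table
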