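"""Configuration-driven pipeline: data + adjacency in, tables out.

A run reads an areal data table and an adjacency source, validates the
schema, computes the data-summary panel (unit counts, missingness
percentages, mean/variance/overdispersion index, Moran's I with a
permutation p-value), fits every requested model variant, and writes per-
variant posterior-summary and fitted-count tables plus one cross-variant
comparison table.  Every output records the seed and a configuration hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import selection
from .data import AreaTable, SchemaError
from .graph import AdjacencyGraph, build_adjacency, morans_i
from .inference import FitConfig, ModelSpec, fit, posterior_summary, \
    predict_missing_responses
from .outcomes import overdispersion_index

log = logging.getLogger("carmap")


@dataclass
class RunConfig:
    data_path: str
    adjacency_path: str
    output_dir: str
    variants: list[ModelSpec]
    fit: FitConfig = field(default_factory=FitConfig)
    id_col: str = "id"
    count_col: str = "count"
    population_col: str = "population"
    covariate_cols: list[str] | None = None
    contiguity: str = "queen"
    morans_permutations: int = 9999
    seed: int = 0

    def __post_init__(self):
        if not self.variants:
            raise ValueError("at least one model variant is required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        variants = [ModelSpec(**v) for v in raw.pop("variants")]
        fit_cfg = FitConfig(**raw.pop("fit", {}))
        return cls(variants=variants, fit=fit_cfg, **raw)

    def digest(self) -> str:
        blob = json.dumps({
            "data": self.data_path, "adjacency": self.adjacency_path,
            "variants": [vars(v) for v in self.variants],
            "fit": vars(self.fit), "seed": self.seed,
        }, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class ValidationReport:
    n_total: int
    n_pass: int
    issues: pd.DataFrame  # columns: id, issue

    @property
    def ok(self) -> bool:
        return len(self.issues) == 0


def validate_schema(table: AreaTable, graph: AdjacencyGraph | None = None) -> ValidationReport:
    """Per-unit soft checks, reported with unit context.

    Flags: duplicate IDs (hard error), all-fields-missing units (exclusion
    candidates, like areal units with no data at all), nonpositive
    population, and units isolated in the adjacency graph (unsuitable for a
    spatial model).
    """
    ids = list(map(str, table.ids))
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise SchemaError(f"duplicate unit ID(s): {', '.join(dupes)}")
    rows = []
    no_data = np.isnan(table.y) & np.isnan(table.X).all(axis=1) if table.k \
        else np.isnan(table.y)
    for i in np.flatnonzero(no_data):
        rows.append({"id": ids[i], "issue": "no data (exclusion candidate)"})
    bad_pop = ~np.isfinite(table.population) | (table.population <= 0)
    for i in np.flatnonzero(bad_pop):
        rows.append({"id": ids[i], "issue": "nonpositive population"})
    if graph is not None:
        iso = np.flatnonzero(graph.M == 0)
        for i in iso:
            rows.append({"id": str(graph.node_ids[i]),
                         "issue": "isolated in adjacency graph"})
    issues = pd.DataFrame(rows, columns=["id", "issue"])
    return ValidationReport(n_total=table.n,
                            n_pass=table.n - issues["id"].nunique(),
                            issues=issues)


def data_summary(table: AreaTable, graph: AdjacencyGraph, *,
                 n_perm: int = 9999, seed: int = 0) -> dict:
    """The descriptive panel reported before any model fitting."""
    y_obs = table.y[table.observed_y]
    i_res = morans_i(np.where(table.observed_y, table.y, y_obs.mean()),
                     graph, n_perm=n_perm, seed=seed)
    out = {
        "n_units": int(table.n),
        "n_observed": int(table.observed_y.sum()),
        "n_missing_response": int(table.missing_y.sum()),
        "pct_missing_response": float(100.0 * table.missing_y.mean()),
        "mean_count": float(y_obs.mean()),
        "var_count": float(y_obs.var(ddof=1)),
        "sd_count": float(y_obs.std(ddof=1)),
        "overdispersion_index": float(overdispersion_index(table.y)),
        "morans_i": float(i_res.statistic),
        "morans_i_p": float(i_res.p_value),
        "pct_missing_covariates": {
            name: float(100.0 * np.isnan(table.X[:, k]).mean())
            for k, name in enumerate(table.covariate_names)
        },
    }
    return out


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns paths of the written artifacts."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s %(levelname)s %(message)s",
        datefmt="%Y-%m-%dT%H:%M:%S",
    )
    stamp = {"seed": config.seed, "config_hash": config.digest(),
             "started": datetime.now(timezone.utc).isoformat()}
    log.info("run %s seed=%d", stamp["config_hash"], config.seed)

    table = AreaTable.read_csv(
        config.data_path, id_col=config.id_col, count_col=config.count_col,
        population_col=config.population_col,
        covariate_cols=config.covariate_cols,
    )
    graph = build_adjacency(config.adjacency_path, allow_isolated=True) \
        if str(config.adjacency_path).endswith((".geojson", ".json")) else \
        build_adjacency(config.adjacency_path,
                        node_ids=list(table.ids), allow_isolated=True)

    report = validate_schema(table, graph)
    if not report.ok:
        report.issues.to_csv(out_dir / "validation_issues.csv", index=False)
    if (graph.M == 0).any() or (~np.isfinite(table.population)).any() \
            or (table.population <= 0).any():
        raise SchemaError(
            "pre-flight validation failed; see validation_issues.csv "
            f"({len(report.issues)} issue(s))"
        )

    summary = data_summary(table, graph, n_perm=config.morans_permutations,
                           seed=config.seed)
    summary.update(stamp)
    (out_dir / "data_summary.json").write_text(json.dumps(summary, indent=2))

    records, artifacts = [], {"data_summary": str(out_dir / "data_summary.json")}
    for v_idx, spec in enumerate(config.variants):
        tag = f"variant{v_idx}_{spec.family}_{'sp' if spec.spatial else 'nsp'}_{spec.imputation}"
        log.info("fitting %s", spec.label)
        cfg = FitConfig(**{**vars(config.fit), "seed": config.fit.seed + v_idx})
        samples = fit(table, graph, spec, cfg)
        summ = posterior_summary(samples)
        summ.insert(0, "model", spec.label)
        summ.to_csv(out_dir / f"{tag}_posterior_summary.csv", index=False)
        fitted = pd.DataFrame({
            "id": samples.data["ids"].astype(str),
            "observed": samples.data["y"],
            "fitted_mean": samples.fitted_mean,
        })
        if samples.data["miss_y_ids"].size:
            pred = predict_missing_responses(samples)
            fitted = fitted.merge(pred, on="id", how="left")
        fitted.to_csv(out_dir / f"{tag}_fitted_counts.csv", index=False)
        samples.convergence_table().to_csv(out_dir / f"{tag}_convergence.csv",
                                           index=False)
        records.append(selection.evaluate(samples))
        artifacts[tag] = str(out_dir / f"{tag}_posterior_summary.csv")

    if len(records) >= 2:
        comparison = selection.compare_models(records)
    else:
        comparison = pd.DataFrame([vars(records[0])])
    comparison.insert(0, "seed", config.seed)
    comparison.insert(1, "config_hash", stamp["config_hash"])
    comparison.to_csv(out_dir / "model_comparison.csv", index=False)
    artifacts["comparison"] = str(out_dir / "model_comparison.csv")
    log.info("run %s complete", stamp["config_hash"])
    return artifacts
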