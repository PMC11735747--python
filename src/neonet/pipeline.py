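"""End-to-end orchestration: cohort -> QC -> connectomes -> metrics -> statistics.

A run is driven by a :class:`RunConfig` (loadable from YAML) and writes
all outputs as delimited text into a run directory, together with a
JSON manifest recording the package version, a hash of the effective
configuration, the seed and per-stage counts.  Re-running with the same
configuration and seed reproduces the tables byte for byte.

Stages, in order: generate or ingest the cohort; quality filtering;
per-scan correlation matrices; proportional-threshold cost sweep with
global metrics at every cost and nodal metrics at the headline cost;
cross-sectional group statistics (cost-wise ANCOVA grid, term-equivalent
ANCOVA with Tukey post hocs, nodal F maps); developmental-trajectory
model selection (global and regional, separately for preterm and term
samples); and the longitudinal paired comparisons.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    PRETERM_GROUPS,
    TERM_EQUIVALENT_WINDOW,
    add_group_column,
    filter_quality,
    read_metadata,
    select_longitudinal_pairs,
    select_term_equivalent,
)
from .connectome import DEFAULT_COST_GRID, correlation_matrix, cost_sweep
from .graph_metrics import global_metric_table, nodal_metric_table
from .group_inference import (
    ancova_group_effect,
    costwise_group_tests,
    nodal_group_maps,
    tukey_hsd,
)
from .longitudinal import groupwise_longitudinal, longitudinal_table
from .synthetic import GeneratorConfig, write_cohort_dataset
from .trajectories import fit_all_forms, regional_trajectories, trajectory_table

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    mode: str = "synthetic"               # "synthetic" or "files"
    input_dir: str | None = None          # required for files mode
    output_dir: str = "neonet_run"
    seed: int = 0
    # synthetic-cohort sizes (ignored in files mode)
    n_term: int = 40
    n_preterm: int = 20
    n_longitudinal: int = 8
    timepoints: int = 2300
    # analysis settings
    cost_grid: tuple[float, ...] = DEFAULT_COST_GRID
    headline_cost: float = 0.30
    covariates: tuple[str, ...] = ("pma_scan", "sex", "mean_dvars")
    q_level: float = 0.05
    include_extreme_groups: bool = True   # keep groups 1 and 7 in the ANCOVA
    clustering_mode: str = "binary"
    weight_length_mapping: str = "inverse"
    rank_by: str = "signed"
    sex_covariate: bool = True
    regional_metrics: tuple[str, ...] = ("strength", "clustering", "local_efficiency")

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError("mode must be 'synthetic' or 'files'")
        if self.mode == "files" and not self.input_dir:
            raise ValueError("files mode requires input_dir")
        self.cost_grid = tuple(float(c) for c in self.cost_grid)
        if any(b <= a for a, b in zip(self.cost_grid, self.cost_grid[1:])):
            raise ValueError("cost_grid must be strictly increasing")
        if not any(np.isclose(self.headline_cost, self.cost_grid)):
            raise ValueError("headline_cost must be a member of cost_grid")
        if not (0 < self.q_level < 1):
            raise ValueError("q_level must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["cost_grid"] = list(self.cost_grid)
        d["covariates"] = list(self.covariates)
        d["regional_metrics"] = list(self.regional_metrics)
        return d

    def config_hash(self) -> str:
        canon = json.dumps(self.as_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def validate_inputs(input_dir, n_regions: int = 90) -> pd.DataFrame:
    """Report-only check of a files-mode input directory.

    Verifies that the metadata table parses, that every manifest entry
    exists with the expected column count and finite values, and that
    sessions and files match one-to-one.
    """
    input_dir = Path(input_dir)
    rows = []
    try:
        metadata = read_metadata(input_dir / "metadata.tsv")
        rows.append({"item": "metadata.tsv", "status": "ok",
                     "detail": f"{len(metadata)} scans"})
    except (OSError, ValueError) as err:
        return pd.DataFrame([{"item": "metadata.tsv", "status": "error", "detail": str(err)}])
    manifest = pd.read_csv(input_dir / "manifest.tsv", sep="\t")
    sessions = set(metadata["session_id"])
    listed = set(manifest["session_id"])
    for sid in sorted(sessions - listed):
        rows.append({"item": sid, "status": "orphan", "detail": "session has no file"})
    for sid in sorted(listed - sessions):
        rows.append({"item": sid, "status": "orphan", "detail": "file has no metadata row"})
    for rec in manifest.itertuples(index=False):
        path = input_dir / rec.path
        if not path.exists():
            rows.append({"item": rec.session_id, "status": "missing", "detail": str(path)})
            continue
        ts = pd.read_csv(path, sep="\t")
        if ts.shape[1] != n_regions:
            rows.append({"item": rec.session_id, "status": "bad_columns",
                         "detail": f"expected {n_regions} columns, found {ts.shape[1]}"})
        elif not np.isfinite(ts.to_numpy(float)).all():
            rows.append({"item": rec.session_id, "status": "nonfinite",
                         "detail": "non-finite values present"})
        else:
            rows.append({"item": rec.session_id, "status": "ok",
                         "detail": f"{ts.shape[0]} timepoints"})
    return pd.DataFrame(rows)


def _load_cohort(config: RunConfig, outdir: Path):
    """Stage 1: synthesise or ingest metadata plus per-scan time series."""
    if config.mode == "synthetic":
        gen = GeneratorConfig(
            n_term=config.n_term,
            n_preterm=config.n_preterm,
            n_longitudinal=config.n_longitudinal,
            timepoints=config.timepoints,
            seed=config.seed,
        )
        data_dir = outdir / "cohort"
        metadata = write_cohort_dataset(gen, data_dir)
    else:
        data_dir = Path(config.input_dir)
        metadata = read_metadata(data_dir / "metadata.tsv")
    manifest = pd.read_csv(data_dir / "manifest.tsv", sep="\t")
    files = dict(zip(manifest["session_id"], manifest["path"]))
    missing = [s for s in metadata["session_id"] if s not in files]
    if missing:
        raise FileNotFoundError(
            f"time-series file missing for session(s): {missing[:5]}"
        )
    return metadata, data_dir, files


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order; returns the run manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("neonet")
    root.addHandler(handler)
    stages: dict[str, dict] = {}
    try:
        config.to_yaml(outdir / "config.yaml")

        metadata, data_dir, files = _load_cohort(config, outdir)
        stages["cohort"] = {"scans": len(metadata),
                            "subjects": metadata["subject_id"].nunique()}

        kept, excluded = filter_quality(metadata)
        _write(excluded, outdir / "qc_excluded.tsv")
        stages["quality_filter"] = {"kept": len(kept), "excluded": len(excluded)}

        kept = add_group_column(kept)
        kept["group"] = kept["group"].astype(str)

        # stage 3-4: connectomes, sweep, metric tables
        graphs_by_cost: dict[float, list] = {c: [] for c in config.cost_grid}
        for rec in kept.itertuples(index=False):
            ts = pd.read_csv(data_dir / files[rec.session_id], sep="\t")
            conn = correlation_matrix(ts, session_id=rec.session_id)
            for g in cost_sweep(conn, config.cost_grid, rank_by=config.rank_by):
                graphs_by_cost[g.cost].append(g)
        all_graphs = [g for graphs in graphs_by_cost.values() for g in graphs]
        meta_cols = kept[["session_id", "subject_id", "ga_birth", "pma_scan", "sex",
                          "mean_dvars", "radiology_score", "group"]]
        global_table = global_metric_table(
            all_graphs, meta_cols, clustering_mode=config.clustering_mode,
            mapping=config.weight_length_mapping,
        ).sort_values(["cost", "session_id"], kind="mergesort", ignore_index=True)
        _write(global_table, outdir / "metrics_global.tsv")
        headline = min(config.cost_grid, key=lambda c: abs(c - config.headline_cost))
        nodal_table = nodal_metric_table(
            graphs_by_cost[headline], meta_cols,
            clustering_mode=config.clustering_mode,
            mapping=config.weight_length_mapping,
        ).sort_values(["session_id", "region"], kind="mergesort", ignore_index=True)
        _write(nodal_table, outdir / "metrics_nodal.tsv")
        stages["metrics"] = {"graphs": len(all_graphs), "headline_cost": headline}

        # stage 5: cross-sectional group statistics on the term-equivalent sample
        te_sessions = select_term_equivalent(kept, TERM_EQUIVALENT_WINDOW)["session_id"]
        te_table = global_table[global_table["session_id"].isin(te_sessions)].copy()
        if not config.include_extreme_groups:
            te_table = te_table[~te_table["group"].isin(["extremely_preterm", "postterm"])]
        costwise = costwise_group_tests(
            te_table, covariates=config.covariates, q=config.q_level
        )
        _write(costwise, outdir / "group_stats_costwise.tsv")

        te_headline = te_table[np.isclose(te_table["cost"], headline)]
        ancova_rows, tukey_rows = [], []
        for metric in ("strength", "clustering", "path_length", "global_efficiency"):
            res = ancova_group_effect(te_headline, metric, config.covariates)
            sex_terms = {f"{name}": (f, p) for name, f, p in res.covariate_terms}
            ancova_rows.append({
                "metric": metric, "df": res.factor_df, "df_resid": res.residual_df,
                "f_value": res.f_value, "p_value": res.p_value,
                "sex_f": sex_terms.get("sex", (np.nan, np.nan))[0],
                "sex_p": sex_terms.get("sex", (np.nan, np.nan))[1],
            })
            for cmp_ in tukey_hsd(res):
                tukey_rows.append({"metric": metric, "group_a": cmp_.group_a,
                                   "group_b": cmp_.group_b,
                                   "difference": cmp_.difference,
                                   "p_value": cmp_.p_value})
        _write(pd.DataFrame(ancova_rows), outdir / "group_stats_term_equivalent.tsv")
        _write(pd.DataFrame(tukey_rows), outdir / "group_stats_tukey.tsv")

        nodal_te = nodal_table[nodal_table["session_id"].isin(te_sessions)]
        map_rows = []
        for metric in config.regional_metrics:
            nm, p_star, f_thr = nodal_group_maps(
                nodal_te, metric, covariates=config.covariates, q=config.q_level
            )
            nm = nm.assign(metric=metric,
                           p_star=np.nan if p_star is None else p_star,
                           f_threshold=np.nan if f_thr is None else f_thr)
            map_rows.append(nm)
        _write(pd.concat(map_rows, ignore_index=True), outdir / "nodal_group_maps.tsv")
        stages["group_inference"] = {
            "term_equivalent_scans": len(te_sessions),
            "costwise_rejections": int(costwise["reject"].sum()),
        }

        # stage 6: developmental trajectories, preterm and term samples separately
        is_preterm = kept["group"].isin(PRETERM_GROUPS)
        samples = {
            "preterm": kept.loc[is_preterm, "session_id"],
            "term": kept.loc[~is_preterm, "session_id"],
        }
        traj_rows, regional_rows = [], []
        for sample, sessions in samples.items():
            gsub = global_table[
                np.isclose(global_table["cost"], headline)
                & global_table["session_id"].isin(sessions)
            ]
            for metric in ("strength", "clustering", "path_length", "global_efficiency"):
                try:
                    fits = fit_all_forms(gsub, metric, sex_covariate=config.sex_covariate)
                except ValueError as err:
                    logger.warning("trajectory fit skipped (%s/%s): %s",
                                   sample, metric, err)
                    continue
                tt = trajectory_table(fits).assign(sample=sample, metric=metric)
                traj_rows.append(tt)
            nsub = nodal_table[nodal_table["session_id"].isin(sessions)]
            if nsub["subject_id"].nunique() >= 10:
                reg = regional_trajectories(
                    nsub, metrics=config.regional_metrics,
                    sex_covariate=config.sex_covariate, q=config.q_level,
                ).assign(sample=sample)
                regional_rows.append(reg)
        traj_table = (
            pd.concat(traj_rows, ignore_index=True) if traj_rows
            else pd.DataFrame(columns=["form", "f_value", "p_value", "aic", "loglik",
                                       "k", "method", "best", "sample", "metric"])
        )
        _write(traj_table, outdir / "trajectories_global.tsv")
        if regional_rows:
            _write(pd.concat(regional_rows, ignore_index=True),
                   outdir / "trajectories_regional.tsv")
        stages["trajectories"] = {"tables": len(traj_rows)}

        # stage 7: longitudinal paired comparisons at the headline cost
        pairs = select_longitudinal_pairs(kept, TERM_EQUIVALENT_WINDOW)
        if len(pairs) > 0:
            headline_metrics = global_table[np.isclose(global_table["cost"], headline)]
            paired = attach_paired_metrics(pairs, headline_metrics)
            results = groupwise_longitudinal(paired)
            _write(longitudinal_table(results), outdir / "longitudinal.tsv")
            stages["longitudinal"] = {"pairs": len(pairs), "tests": len(results)}
        else:
            stages["longitudinal"] = {"pairs": 0, "tests": 0}

        manifest = {
            "package_version": __version__,
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "stages": stages,
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    except Exception as err:
        completed = list(stages)
        stage = "unknown" if not completed else f"after {completed[-1]}"
        raise RuntimeError(f"pipeline aborted ({stage}): {err}") from err
    finally:
        root.removeHandler(handler)
        handler.close()


def attach_paired_metrics(pairs: pd.DataFrame, metric_table: pd.DataFrame,
                          metrics=("strength", "clustering", "path_length",
                                   "global_efficiency")) -> pd.DataFrame:
    """Join metric values onto longitudinal pairs (one row per subject).

    ``metric_table`` must be at a single cost, keyed by session_id.
    """
    lookup = metric_table.set_index("session_id")
    out = pairs.copy()
    for metric in metrics:
        out[f"{metric}_first"] = out["session_id_first"].map(lookup[metric]).to_numpy()
        out[f"{metric}_second"] = out["session_id_second"].map(lookup[metric]).to_numpy()
    out["group"] = out["group"].astype(str)
    return out
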