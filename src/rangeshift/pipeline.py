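"""Config-driven orchestration of the full range-dynamics analysis.

Stages, in order: read inputs -> thin occurrences -> sampling-bias surface
-> variable screening -> bias-weighted background -> replicate model fits
-> thresholds -> per-period suitability projections -> binary maps, change
maps/tables and migration vectors per transition -> limiting factors.
Every artifact lands under the output directory and is hashed into a JSON
run manifest; a fixed master seed makes the whole run reproducible
byte-for-byte.  Each stage draws randomness from its own stream derived by
hashing the stage name with the master seed, so changing one stage's
workload does not perturb the others.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from . import dynamics, limiting, maxent, occurrences, screening
from .grids import ClimateStack, build_stack, read_grid, write_grid

__all__ = ["RunConfig", "RunManifest", "ConfigError", "StageError",
           "validate_config", "read_stack_dir", "run_pipeline", "stage_seed"]

log = logging.getLogger("rangeshift")


class ConfigError(ValueError):
    """Malformed or out-of-range run configuration."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    occurrences: str = ""
    periods: list[str] = field(default_factory=list)  # chronological order
    stack_dirs: dict[str, str] = field(default_factory=dict)
    training_period: str = "present"
    output_dir: str = "run_output"
    min_dist_km: float = 10.0
    bias_radius_km: float = 60.0
    corr_threshold: float = 0.85
    priority: list[str] = field(default_factory=list)
    beta: float = 1.0
    replicates: int = 10
    train_fraction: float = 0.75
    background_n: int = 10000
    threshold_rule: str = "mtss"  # or "10tp"
    block_km: float = 60.0
    seed: int = 0
    raster_format: str = "geotiff"

    def validate(self) -> "RunConfig":
        if not self.occurrences:
            raise ConfigError("occurrences path is required")
        if not self.periods:
            raise ConfigError("at least one period is required")
        if self.training_period not in self.periods:
            raise ConfigError(f"training_period {self.training_period!r} not in periods")
        missing = [p for p in self.periods if p not in self.stack_dirs]
        if missing:
            raise ConfigError(f"no stack_dir for period(s) {missing}")
        for name in ("min_dist_km", "bias_radius_km", "beta", "block_km"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0.0 < self.corr_threshold <= 1.0:
            raise ConfigError("corr_threshold must be in (0, 1]")
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigError("train_fraction must lie strictly between 0 and 1")
        if self.replicates < 1 or self.background_n < 1:
            raise ConfigError("replicates and background_n must be >= 1")
        if self.seed < 0:
            raise ConfigError("seed must be non-negative")
        if self.threshold_rule not in {"mtss", "10tp"}:
            raise ConfigError("threshold_rule must be 'mtss' or '10tp'")
        if self.raster_format not in {"geotiff", "ascii_grid"}:
            raise ConfigError("raster_format must be 'geotiff' or 'ascii_grid'")
        return self


_LIST_KEYS = {"periods", "priority"}
_INT_KEYS = {"replicates", "background_n", "seed"}
_FLOAT_KEYS = {"min_dist_km", "bias_radius_km", "corr_threshold", "beta",
               "train_fraction", "block_km"}
_STR_KEYS = {"occurrences", "training_period", "output_dir", "threshold_rule",
             "raster_format"}


def validate_config(text: str) -> RunConfig:
    """Parse a flat ``key = value`` config document into a checked RunConfig.

    ``periods`` and ``priority`` are comma-separated; per-period raster
    directories are given as ``stack_dir.<period> = <path>``.  Unknown keys
    are an error.
    """
    cfg = RunConfig()
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key.startswith("stack_dir."):
            cfg.stack_dirs[key[len("stack_dir."):]] = value
        elif key in _LIST_KEYS:
            setattr(cfg, key, [v.strip() for v in value.split(",") if v.strip()])
        elif key in _INT_KEYS:
            try:
                setattr(cfg, key, int(value))
            except ValueError:
                raise ConfigError(f"line {lineno}: {key} must be an integer") from None
        elif key in _FLOAT_KEYS:
            try:
                setattr(cfg, key, float(value))
            except ValueError:
                raise ConfigError(f"line {lineno}: {key} must be a number") from None
        elif key in _STR_KEYS:
            setattr(cfg, key, value)
        else:
            raise ConfigError(f"line {lineno}: unknown config key {key!r}")
    return cfg.validate()


def stage_seed(master_seed: int, stage: str) -> int:
    """Independent per-stage RNG seed (stable hash of stage name + master)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def read_stack_dir(path: str | Path, period_label: str) -> ClimateStack:
    """Read every raster in a directory as one period's stack (name = stem)."""
    path = Path(path)
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in {".tif", ".tiff", ".asc", ".txt"}
    )
    if not files:
        raise FileNotFoundError(f"no rasters in {path}")
    return build_stack({p.stem: read_grid(p) for p in files}, period_label)


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    stages: dict = field(default_factory=dict)  # stage -> {relpath: sha256} + counts
    eval_summary: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    change_tables: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    failed_stage: str | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(self.to_json())


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute every stage; returns (and writes) the run manifest.

    On a stage failure the manifest recording all finished stages is still
    written before the error is re-raised as :class:`StageError`.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = ".tif" if config.raster_format == "geotiff" else ".asc"
    cfg_dict = {f.name: getattr(config, f.name) for f in fields(config)}
    manifest = RunManifest(config=cfg_dict)

    def record(stage: str, outputs: dict[str, Path], **counts) -> None:
        entry = {"outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs.values()}}
        entry.update(counts)
        manifest.stages[stage] = entry
        log.info("stage %-12s %s", stage, " ".join(f"{k}={v}" for k, v in counts.items()))

    current = "read_inputs"
    try:
        occ = occurrences.read_occurrences(config.occurrences)
        stacks = {p: read_stack_dir(config.stack_dirs[p], p) for p in config.periods}
        training = stacks[config.training_period]
        record(current, {}, n_occurrences=len(occ), n_periods=len(stacks))

        current = "thin"
        thinned = occurrences.thin(occ, config.min_dist_km)
        p_thin = out / "occurrences_thinned.csv"
        occurrences.write_occurrences(thinned, p_thin)
        record(current, {"thinned": p_thin}, n_before=len(occ), n_after=len(thinned))

        current = "bias"
        bias = occurrences.bias_surface(thinned, training.template, config.bias_radius_km)
        p_bias = out / f"bias_surface{ext}"
        write_grid(bias, p_bias, config.raster_format)
        record(current, {"bias": p_bias})

        current = "screen"
        report = screening.correlation_matrix(training)
        kept = screening.prune_correlated(report, config.corr_threshold,
                                          config.priority or None)
        p_corr = out / "correlation_matrix.csv"
        report.to_csv(p_corr)
        p_kept = out / "selected_variables.txt"
        p_kept.write_text("\n".join(kept) + "\n")
        stacks = {p: s.subset(kept) for p, s in stacks.items()}
        training = stacks[config.training_period]
        record(current, {"correlation": p_corr, "selected": p_kept}, n_kept=len(kept))

        current = "background"
        background = occurrences.sample_background(
            bias, config.background_n, stage_seed(config.seed, current)
        )
        record(current, {}, n_background=len(background))

        current = "model"
        report_eval, model = maxent.replicate_runs(
            thinned, background, training,
            k=config.replicates, train_fraction=config.train_fraction,
            beta=config.beta, seed=stage_seed(config.seed, current),
        )
        p_eval = out / "evaluation.csv"
        report_eval.to_csv(p_eval)
        p_model = out / "model_lambdas.json"
        model.save(p_model)
        manifest.eval_summary = {
            "mean_train_auc": report_eval.mean_train_auc,
            "mean_test_auc": report_eval.mean_test_auc,
            "n_replicates": report_eval.n_replicates,
            "train_fraction": report_eval.train_fraction,
        }
        record(current, {"evaluation": p_eval, "model": p_model},
               mean_test_auc=round(report_eval.mean_test_auc, 4))

        current = "thresholds"
        names = model.features.var_names
        pres_scores = model.predict_values(
            training.values_at(thinned.xy[:, 0], thinned.xy[:, 1], names))
        bg_scores = model.predict_values(
            training.values_at(background.xy[:, 0], background.xy[:, 1], names))
        thr = dynamics.Thresholds(
            mtss=dynamics.mtss_threshold(pres_scores, bg_scores),
            ten_percent_tp=dynamics.ten_percent_tp_threshold(pres_scores),
        )
        manifest.thresholds = {"mtss": thr.mtss, "ten_percent_tp": thr.ten_percent_tp}
        p_thr = out / "thresholds.json"
        p_thr.write_text(json.dumps(manifest.thresholds, indent=1))
        record(current, {"thresholds": p_thr}, mtss=round(thr.mtss, 4),
               ten_percent_tp=round(thr.ten_percent_tp, 4))

        current = "project"
        t_used = thr.mtss if config.threshold_rule == "mtss" else thr.ten_percent_tp
        suitability = {}
        binaries = {}
        proj_paths = {}
        for p in config.periods:
            pred = maxent.predict_logistic(model, stacks[p], clamp=True)
            suitability[p] = pred
            binaries[p] = dynamics.binarize(pred, t_used, p)
            path = out / f"suitability_{p}{ext}"
            write_grid(pred, path, config.raster_format)
            proj_paths[p] = path
        record(current, proj_paths, threshold_used=round(t_used, 4))

        current = "dynamics"
        dyn_paths = {}
        presence_means = limiting.presence_variable_means(training, thinned)
        for early_p, late_p in zip(config.periods, config.periods[1:]):
            pair = f"{early_p}_to_{late_p}"
            cmap = dynamics.change_map(binaries[early_p], binaries[late_p])
            table = dynamics.change_table(cmap)
            manifest.change_tables[pair] = {
                "areas_km2": table.areas,
                "area_early_km2": table.area_early,
                "area_late_km2": table.area_late,
                "ratio_contraction": table.ratio_contraction,
                "ratio_no_change": table.ratio_no_change,
                "ratio_expansion": table.ratio_expansion,
            }
            p_table = out / f"change_table_{pair}.csv"
            table.to_csv(p_table)
            dyn_paths[f"table_{pair}"] = p_table
            cmap_grid = binaries[early_p].grid.like(cmap.classes.astype(float))
            p_cmap = out / f"change_map_{pair}{ext}"
            write_grid(cmap_grid, p_cmap, config.raster_format)
            dyn_paths[f"map_{pair}"] = p_cmap
            # an empty range (total collapse) has no centroid: record the
            # fact and emit empty vector tables instead of aborting
            p_overall = out / f"overall_vector_{pair}.csv"
            p_mv = out / f"migration_vectors_{pair}.csv"
            try:
                overall = dynamics.centroid_vector(binaries[early_p], binaries[late_p])
                overall.to_csv(p_overall)
                mv = dynamics.migration_vectors(
                    dynamics.block_centroids(binaries[early_p], config.block_km),
                    dynamics.block_centroids(binaries[late_p], config.block_km),
                    pair,
                )
                mv.to_csv(p_mv)
            except (dynamics.CentroidError, dynamics.MatchingError, ValueError) as exc:
                manifest.warnings.append(f"{pair}: no vectors ({exc})")
                empty = dynamics.VectorField([], pair)
                empty.to_csv(p_overall)
                empty.to_csv(p_mv)
            dyn_paths[f"overall_{pair}"] = p_overall
            dyn_paths[f"vectors_{pair}"] = p_mv
        record(current, dyn_paths, n_transitions=max(0, len(config.periods) - 1))

        current = "limits"
        lf_paths = {}
        for early_p, late_p in zip(config.periods, config.periods[1:]):
            pair = f"{early_p}_to_{late_p}"
            cmap = dynamics.change_map(binaries[early_p], binaries[late_p])
            lfmap = limiting.limiting_factor_map(model, stacks[late_p], presence_means)
            lf_grid = stacks[late_p].template.like(lfmap.factor_index.astype(float))
            p_lf = out / f"limiting_factor_{pair}{ext}"
            write_grid(lf_grid, p_lf, config.raster_format)
            lf_paths[f"map_{pair}"] = p_lf
            p_leg = out / f"limiting_factor_legend_{pair}.csv"
            lfmap.legend().to_csv(p_leg, index=False)
            lf_paths[f"legend_{pair}"] = p_leg
            shares = []
            for cls in ("contraction", "expansion"):
                fs_row = limiting.factor_shares(lfmap, cmap, cls)
                if fs_row.undefined:
                    manifest.warnings.append(f"{pair}: no {cls} cells, shares undefined")
                else:
                    shares.append(fs_row.shares.assign(class_label=cls, pair=pair))
            p_shares = out / f"factor_shares_{pair}.csv"
            if shares:
                pd.concat(shares, ignore_index=True).to_csv(p_shares, index=False)
            else:
                pd.DataFrame(
                    columns=["variable", "n_cells", "share_pct", "class_label", "pair"]
                ).to_csv(p_shares, index=False)
            lf_paths[f"shares_{pair}"] = p_shares
        record(current, lf_paths)
    except Exception as exc:
        manifest.failed_stage = current
        manifest.warnings.append(f"stage {current} failed: {exc}")
        manifest.save(out / "manifest.json")
        raise StageError(current, exc) from exc

    manifest.save(out / "manifest.json")
    return manifest
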