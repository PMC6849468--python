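"""End-to-end screening pipeline: inputs -> traits -> growth fits -> reports.

A single :class:`RunConfig` drives the whole method in one of three input
modes:

* ``synthetic`` — simulate a full pot study (varieties x N levels x
  replicates x imaging days) with known growth structure and coupled harvest
  traits;
* ``image_manifest`` — segment a directory of view images listed in a
  manifest CSV and extract the digital traits;
* ``trait_csv`` — start from an existing longitudinal trait table, or skip
  fitting entirely by supplying a table of split-line parameters.

Every run writes the same artifact set into an output directory (trait
table, fit table, window summary, recommended screening day, NUE/harvest
report, ANOVA and correlation reports, ranked tables, optional figures) plus
a machine-readable ``manifest.json``; identical config and seed give
byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .growth import (
    LinearPhaseWindow,
    common_linear_window,
    fit_variety_means,
    fits_from_table,
    recommend_screening_das,
)
from .imaging import SegmentationConfig, extract_trait_table
from .stats import (
    N_INPUT_G,
    correlation_matrix,
    nue_table,
    outlier_screen,
    rank_report,
    timecourse_correlation,
    two_way_anova,
)
from .synthetic import GrowthSpec, generate_growth_series

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "ConfigError",
    "StageError",
    "validate_config",
    "load_config",
    "generate_study",
    "run_pipeline",
]

MODES = ("synthetic", "image_manifest", "trait_csv")

DEFAULT_OBSERVATION_DAYS = (26.0, 30.0, 34.0, 38.0, 42.0, 46.0, 50.0, 54.0, 58.0, 62.0, 66.0, 70.0)


class ConfigError(ValueError):
    """Raised when a run configuration is invalid; carries all violations."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" + "\n".join(f"- {e}" for e in errors))


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one pipeline run."""

    mode: str = "synthetic"
    seed: int = 0
    image_manifest: str | None = None
    trait_csv: str | None = None
    fits_csv: str | None = None
    harvest_csv: str | None = None
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    per_pot_fits: bool = False
    grid_step: float = 0.1
    n_input_g: dict[str, float] = field(default_factory=lambda: dict(N_INPUT_G))
    n_varieties: int = 15
    n_replicates: int = 15
    observation_days: tuple[float, ...] = DEFAULT_OBSERVATION_DAYS
    k_extremes: int = 3
    figures: bool = True


_SCHEMA_KEYS = {
    "mode",
    "seed",
    "paths",
    "segmentation",
    "growth",
    "n_input_g",
    "study",
    "report",
}
_PATH_KEYS = {"image_manifest", "trait_csv", "fits_csv", "harvest_csv"}
_GROWTH_KEYS = {"per_pot_fits", "grid_step"}
_STUDY_KEYS = {"n_varieties", "n_replicates", "observation_days"}
_REPORT_KEYS = {"k_extremes", "figures"}
_SEG_KEYS = {f.name for f in dataclasses.fields(SegmentationConfig)}


def validate_config(raw: dict[str, Any]) -> RunConfig:
    """Validate a raw (YAML-loaded) config dict against the strict schema.

    Every violation is collected and reported at once; unknown keys are
    errors.  Returns the immutable :class:`RunConfig` on success.
    """
    errors: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a mapping"])

    unknown = set(raw) - _SCHEMA_KEYS
    errors += [f"unknown key {k!r}" for k in sorted(unknown)]

    mode = raw.get("mode", "synthetic")
    if mode not in MODES:
        errors.append(f"mode: must be one of {MODES}, got {mode!r}")

    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or isinstance(seed, bool):
        errors.append("seed: must be an integer")
        seed = 0

    paths = raw.get("paths", {}) or {}
    if not isinstance(paths, dict):
        errors.append("paths: must be a mapping")
        paths = {}
    errors += [f"paths: unknown key {k!r}" for k in sorted(set(paths) - _PATH_KEYS)]
    set_paths = {k: v for k, v in paths.items() if k in _PATH_KEYS and v is not None}

    mode_inputs = {"image_manifest": "image_manifest", "trait_csv": "trait_csv"}
    if mode == "synthetic" and set_paths:
        errors.append(
            f"paths: synthetic mode takes no input paths, got {sorted(set_paths)}"
        )
    if mode == "image_manifest" and "image_manifest" not in set_paths:
        errors.append("paths.image_manifest: required in image_manifest mode")
    if mode == "trait_csv" and not ({"trait_csv", "fits_csv"} & set(set_paths)):
        errors.append("paths: trait_csv mode needs trait_csv and/or fits_csv")
    if mode == "image_manifest" and ({"trait_csv", "fits_csv"} & set(set_paths)):
        errors.append("paths: image_manifest mode conflicts with trait/fits CSV inputs")
    for key, value in set_paths.items():
        if not Path(value).exists():
            errors.append(f"paths.{key}: file not found: {value}")

    seg_raw = raw.get("segmentation", {}) or {}
    errors += [
        f"segmentation: unknown key {k!r}" for k in sorted(set(seg_raw) - _SEG_KEYS)
    ]
    seg = SegmentationConfig()
    try:
        seg = SegmentationConfig(**{k: v for k, v in seg_raw.items() if k in _SEG_KEYS})
    except (TypeError, ValueError) as exc:
        errors.append(f"segmentation: {exc}")

    growth_raw = raw.get("growth", {}) or {}
    errors += [f"growth: unknown key {k!r}" for k in sorted(set(growth_raw) - _GROWTH_KEYS)]
    grid_step = growth_raw.get("grid_step", 0.1)
    if not (isinstance(grid_step, (int, float)) and grid_step > 0):
        errors.append("growth.grid_step: must be a positive number")
        grid_step = 0.1

    ninp = raw.get("n_input_g", dict(N_INPUT_G)) or {}
    for level, grams in ninp.items():
        if not (isinstance(grams, (int, float)) and grams > 0):
            errors.append(f"n_input_g.{level}: must be positive grams of N")

    study_raw = raw.get("study", {}) or {}
    errors += [f"study: unknown key {k!r}" for k in sorted(set(study_raw) - _STUDY_KEYS)]
    n_var = study_raw.get("n_varieties", 15)
    n_rep = study_raw.get("n_replicates", 15)
    for name, val in (("n_varieties", n_var), ("n_replicates", n_rep)):
        if not (isinstance(val, int) and val >= 1):
            errors.append(f"study.{name}: must be a positive integer")
    days = tuple(float(d) for d in study_raw.get("observation_days", DEFAULT_OBSERVATION_DAYS))
    if len(days) < 5 or any(b <= a for a, b in zip(days, days[1:])):
        errors.append("study.observation_days: need >= 5 strictly increasing days")

    report_raw = raw.get("report", {}) or {}
    errors += [f"report: unknown key {k!r}" for k in sorted(set(report_raw) - _REPORT_KEYS)]
    k_ext = report_raw.get("k_extremes", 3)
    if not (isinstance(k_ext, int) and k_ext >= 1):
        errors.append("report.k_extremes: must be a positive integer")
        k_ext = 3

    if errors:
        raise ConfigError(errors)
    return RunConfig(
        mode=mode,
        seed=seed,
        image_manifest=set_paths.get("image_manifest"),
        trait_csv=set_paths.get("trait_csv"),
        fits_csv=set_paths.get("fits_csv"),
        harvest_csv=set_paths.get("harvest_csv"),
        segmentation=seg,
        per_pot_fits=bool(growth_raw.get("per_pot_fits", False)),
        grid_step=float(grid_step),
        n_input_g={str(k): float(v) for k, v in ninp.items()},
        n_varieties=n_var,
        n_replicates=n_rep,
        observation_days=days,
        k_extremes=k_ext,
        figures=bool(report_raw.get("figures", True)),
    )


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


# ---------------------------------------------------------------------------
# synthetic study
# ---------------------------------------------------------------------------

def generate_study(
    seed: int,
    *,
    n_varieties: int = 15,
    n_replicates: int = 15,
    observation_days: tuple[float, ...] = DEFAULT_OBSERVATION_DAYS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full two-N-level pot screen with coupled growth and harvest.

    Each variety gets its own split-line growth structure per N level: at low
    N roughly two thirds of varieties start their linear phase before imaging
    begins (so the visible breakpoint is its *completion*, late, with a
    flatter second slope) while the rest commence it mid-window; at optimum N
    almost all varieties show a commencement breakpoint, growth being N-driven
    and steep.  Replicate pots vary around the variety trajectory with
    observation noise.  Harvest dry biomass per pot is proportional to final
    estimated biomass plus noise, grain yield is a noisy fraction of dry
    biomass, so vegetative performance genuinely predicts harvest — the
    association the screening method relies on.

    Returns ``(series, harvest)``: the longitudinal trait table
    (``pot_id, variety, n_level, das, eb_kpix, tva_kpix``) and the per-pot
    harvest table.
    """
    rng = np.random.default_rng(seed)
    days = tuple(float(d) for d in observation_days)
    lo, hi = days[0], days[-1]
    series_rows = []
    harvest_rows = []
    pot = 0
    for vi in range(n_varieties):
        variety = f"V{vi + 1:02d}"
        # low N: completion-type for ~2/3 of varieties
        completion_type = rng.random() < 2 / 3
        params = {}
        if completion_type:
            params["low"] = GrowthSpec(
                lag_slope=float(rng.uniform(8, 13)),
                linear_slope=float(rng.uniform(3, 6)),
                breakpoints=(float(rng.uniform(0.65, 0.92) * (hi - lo) + lo),),
                observation_days=days,
                baseline_kpix=float(rng.uniform(10, 30)),
            )
        else:
            params["low"] = GrowthSpec(
                lag_slope=float(rng.uniform(4, 7)),
                linear_slope=float(rng.uniform(9, 16)),
                breakpoints=(float(rng.uniform(0.25, 0.55) * (hi - lo) + lo),),
                observation_days=days,
                baseline_kpix=float(rng.uniform(10, 30)),
            )
        if rng.random() < 0.9:
            params["optimum"] = GrowthSpec(
                lag_slope=float(rng.uniform(15, 27)),
                linear_slope=float(rng.uniform(28, 57)),
                breakpoints=(float(rng.uniform(0.22, 0.6) * (hi - lo) + lo),),
                observation_days=days,
                baseline_kpix=float(rng.uniform(30, 80)),
            )
        else:
            params["optimum"] = GrowthSpec(
                lag_slope=float(rng.uniform(22, 28)),
                linear_slope=float(rng.uniform(12, 18)),
                breakpoints=(float(rng.uniform(0.7, 0.9) * (hi - lo) + lo),),
                observation_days=days,
                baseline_kpix=float(rng.uniform(30, 80)),
            )
        for n_level, spec in params.items():
            scale = 1.0 if n_level == "low" else 2.2
            for _ in range(n_replicates):
                pot += 1
                pot_id = f"P{pot:05d}"
                pot_spec = dataclasses.replace(
                    spec,
                    noise_sd=4.0 * scale,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                pot_gain = float(rng.normal(1.0, 0.08))  # pot-to-pot vigour
                ser = generate_growth_series(pot_spec)
                eb = np.maximum(ser["eb_kpix"].to_numpy() * pot_gain, 0.0)
                tva = np.maximum(
                    0.21 * eb + rng.normal(0.0, 2.0 * scale, size=len(eb)), 0.0
                )
                for d, e, t in zip(ser["das"], eb, tva):
                    series_rows.append(
                        {
                            "pot_id": pot_id,
                            "variety": variety,
                            "n_level": n_level,
                            "das": d,
                            "eb_kpix": e,
                            "tva_kpix": t,
                        }
                    )
                final_eb = eb[-1]
                dw = max(0.030 * final_eb + rng.normal(0.0, 0.12 * scale), 0.5)
                hi_frac = float(np.clip(rng.normal(0.48, 0.04), 0.2, 0.7))
                gy = hi_frac * dw
                harvest_rows.append(
                    {
                        "pot_id": pot_id,
                        "variety": variety,
                        "n_level": n_level,
                        "dw_g": dw,
                        "gy_g": gy,
                        "sn": max(rng.normal(4.2 if n_level == "low" else 15.4, 1.2), 1.0),
                        "gn": max(rng.normal(34.8 if n_level == "low" else 37.9, 3.5), 5.0),
                        "gw1000_g": max(rng.normal(41.4 if n_level == "low" else 44.3, 2.8), 20.0),
                        "shoot_n_pct": max(rng.normal(0.35 if n_level == "low" else 0.63, 0.05), 0.05),
                        "grain_n_pct": max(
                            rng.normal(2.1 if n_level == "low" else 2.7, 0.15) - 0.02 * (gy - 0.48 * dw),
                            0.5,
                        ),
                        "wsc_pct": max(rng.normal(5.0 if n_level == "low" else 8.8, 1.0), 0.5),
                    }
                )
    series = pd.DataFrame(series_rows)
    harvest = pd.DataFrame(harvest_rows)
    return series, harvest


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.10g"


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict[str, Any]:
    """Execute all stages and write the artifact set into ``out_dir``.

    Returns the run manifest (also written as ``manifest.json``).  A failing
    stage raises :class:`StageError` naming the stage; artifacts written
    before the failure are retained and listed in ``manifest.partial.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    timings: dict[str, float] = {}
    stage = "init"

    def _record(name: str, path: Path) -> None:
        artifacts[name] = path.name

    try:
        # ----- stage: traits ------------------------------------------------
        stage = "traits"
        t0 = time.perf_counter()
        series = None
        harvest = None
        if config.mode == "synthetic":
            series, harvest = generate_study(
                config.seed,
                n_varieties=config.n_varieties,
                n_replicates=config.n_replicates,
                observation_days=config.observation_days,
            )
        elif config.mode == "image_manifest":
            manifest_df = pd.read_csv(config.image_manifest)
            series, skipped = extract_trait_table(manifest_df, config.segmentation)
            if len(skipped):
                _write_csv(skipped, out / "skipped_images.csv")
                _record("skipped_images", out / "skipped_images.csv")
        else:  # trait_csv
            if config.trait_csv is not None:
                series = pd.read_csv(config.trait_csv)
        if config.harvest_csv is not None:
            harvest = pd.read_csv(config.harvest_csv)
        if series is not None:
            _write_csv(series, out / "trait_table.csv")
            _record("trait_table", out / "trait_table.csv")
        timings[stage] = time.perf_counter() - t0

        # ----- stage: growth fits ------------------------------------------
        stage = "fit"
        t0 = time.perf_counter()
        if config.fits_csv is not None:
            fits_table = pd.read_csv(config.fits_csv)
            fits = fits_from_table(fits_table)
            fits_table = fits_table.copy()
            fits_table["phase"] = [f.phase for f in fits]
        else:
            if series is None:
                raise ValueError("no trait series available to fit")
            fits_table = fit_variety_means(
                series, grid_step=config.grid_step, per_pot=config.per_pot_fits
            )
            fits = fits_from_table(fits_table)
        _write_csv(fits_table, out / "splitline_fits.csv")
        _record("splitline_fits", out / "splitline_fits.csv")
        timings[stage] = time.perf_counter() - t0

        # ----- stage: windows ----------------------------------------------
        stage = "window"
        t0 = time.perf_counter()
        observed = None
        if series is not None and "das" in series:
            observed = (float(series["das"].min()), float(series["das"].max()))
        window_rows = []
        recommendations = {}
        for n_level in sorted({f.n_level for f in fits}):
            level_fits = [f for f in fits if f.n_level == n_level]
            win = common_linear_window(
                level_fits, n_level=n_level, observed_range=observed
            )
            window_rows.append(
                {
                    "n_level": n_level,
                    "start_das": win.start_das,
                    "end_das": win.end_das,
                    "empty": win.empty,
                    "n_commencing": len(win.commencing_varieties),
                    "n_completing": len(win.completing_varieties),
                }
            )
            if not win.empty and observed is not None:
                days_in = [d for d in sorted(set(series["das"]))]
                try:
                    recommendations[n_level] = recommend_screening_das(win, days_in)
                except ValueError:
                    recommendations[n_level] = None
        windows = pd.DataFrame(window_rows)
        _write_csv(windows, out / "linear_phase_windows.csv")
        _record("linear_phase_windows", out / "linear_phase_windows.csv")
        if recommendations:
            rec = pd.DataFrame(
                [{"n_level": k, "screening_das": v} for k, v in sorted(recommendations.items())]
            )
            _write_csv(rec, out / "recommended_screening_das.csv")
            _record("recommended_screening_das", out / "recommended_screening_das.csv")
        timings[stage] = time.perf_counter() - t0

        # ----- stage: stats -------------------------------------------------
        stage = "stats"
        t0 = time.perf_counter()
        if harvest is not None:
            nue = nue_table(harvest, config.n_input_g)
            _write_csv(nue, out / "nue_harvest_report.csv")
            _record("nue_harvest_report", out / "nue_harvest_report.csv")

            anova_rows = []
            counts = harvest.groupby(["n_level", "variety"]).size()
            if (
                harvest["n_level"].nunique() >= 2
                and harvest["variety"].nunique() >= 2
                and counts.min() >= 2
                and counts.nunique() == 1
            ):
                for trait in ("dw_g", "gy_g", "nue_b", "nue_g"):
                    summary = two_way_anova(nue, trait)
                    for effect in summary.table.index:
                        if effect == "residual":
                            continue
                        anova_rows.append(
                            {
                                "trait": trait,
                                "effect": effect,
                                "sum_sq": summary.table.loc[effect, "sum_sq"],
                                "df": summary.table.loc[effect, "df"],
                                "F": summary.table.loc[effect, "F"],
                                "p": summary.table.loc[effect, "PR(>F)"],
                                "sed": summary.sed.get(effect, np.nan),
                                "lsd_p05": summary.lsd.get(effect, np.nan),
                                "cv_pct": summary.cv_pct,
                            }
                        )
            if anova_rows:
                _write_csv(pd.DataFrame(anova_rows), out / "anova_summary.csv")
                _record("anova_summary", out / "anova_summary.csv")

            ranked = rank_report(
                harvest, "dw_g", sorted(harvest["n_level"].unique())[0],
                k_extremes=config.k_extremes,
            )
            _write_csv(ranked, out / "variety_ranking.csv")
            _record("variety_ranking", out / "variety_ranking.csv")

        corr_report = None
        if harvest is not None and series is not None and {"pot_id", "das"} <= set(series.columns):
            snap_das = max(series["das"].unique())
            if recommendations:
                cand = [v for v in recommendations.values() if v is not None]
                if cand:
                    snap_das = cand[0]
            snap = series[series["das"] == snap_das]
            merged = snap.merge(harvest, on=["pot_id", "variety", "n_level"], how="inner")
            traits = [
                c for c in ("eb_kpix", "tva_kpix", "mb_g", "la_cm2", "dw_g", "gy_g")
                if c in merged.columns
            ]
            if len(traits) >= 2 and len(merged) >= 3:
                corr_report = correlation_matrix(merged, traits)
                _write_csv(
                    corr_report.r.reset_index(names="trait"), out / "trait_correlations.csv"
                )
                _record("trait_correlations", out / "trait_correlations.csv")

            tc = timecourse_correlation(series, harvest)
            _write_csv(tc, out / "timecourse_correlations.csv")
            _record("timecourse_correlations", out / "timecourse_correlations.csv")
        timings[stage] = time.perf_counter() - t0

        # ----- stage: figures ----------------------------------------------
        stage = "figures"
        t0 = time.perf_counter()
        if config.figures:
            from . import plots

            if series is not None and config.fits_csv is None and len(fits):
                p = plots.plot_growth_fits(series, fits, out / "growth_fits.png")
                _record("growth_fits_figure", p)
            if corr_report is not None:
                p = plots.plot_correlation_heatmap(
                    corr_report.r, out / "trait_correlations.png"
                )
                _record("trait_correlations_figure", p)
        timings[stage] = time.perf_counter() - t0

        # ----- manifest -----------------------------------------------------
        stage = "manifest"
        config_dict = dataclasses.asdict(config)
        config_dict["segmentation"] = dataclasses.asdict(config.segmentation)
        manifest = {
            "package": "wheatnue",
            "version": __version__,
            "seed": config.seed,
            "config": config_dict,
            "config_sha256": hashlib.sha256(
                json.dumps(config_dict, sort_keys=True, default=str).encode()
            ).hexdigest(),
            "artifacts": {
                name: {"file": fname, "sha256": _sha256(out / fname)}
                for name, fname in sorted(artifacts.items())
            },
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        logger.info("pipeline complete: %d artifacts in %s", len(artifacts), out)
        return manifest
    except Exception as exc:
        partial = {
            "failed_stage": stage,
            "error": str(exc),
            "artifacts": artifacts,
        }
        with open(out / "manifest.partial.json", "w") as fh:
            json.dump(partial, fh, indent=2, sort_keys=True)
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc
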