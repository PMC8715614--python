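"""End-to-end orchestration: simulate/load -> score -> moderate -> window -> synergy.

``run_full_analysis`` drives the whole pipeline from a ``RunConfig`` and
writes every artifact as CSV (atomically: temp file + rename), returning a
manifest of output paths.  Runs are deterministic given the seed; the run log
echoes the configuration so any artifact can be reproduced from it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import moderation, psychometrics, synergy, windows
from .moderation import DEFAULT_N_TESTS, build_results_table, intelligence_baseline
from .psychometrics import (SingleFactorModel, keyed_item_matrix,
                            load_item_specs, score_composite)
from .simulate import SimConfig, generate_population, make_config
from .synergy import fig3_table, synergy_fit
from .windows import WindowConfig, extreme_group_omega, run_window_analysis, summarize_meta

__all__ = ["RunConfig", "run_full_analysis", "validate_table"]

logger = logging.getLogger(__name__)

TEST_COLS = [f"test_{j}" for j in range(1, 13)]
ITEM_COLS = [f"item_{j}" for j in range(1, 19)]
REQUIRED_COLS = TEST_COLS + ITEM_COLS + ["gpa", "degree"]


@dataclass
class RunConfig:
    """One pipeline run: either simulate a table or analyze an existing CSV."""

    mode: str = "simulate"  # 'simulate' | 'analyze'
    input_path: str | None = None
    sim: SimConfig = field(default_factory=SimConfig)
    window: WindowConfig = field(default_factory=WindowConfig)
    outdir: str = "results"
    seed: int = 0
    alpha: float = 0.05
    bonferroni_m: int = DEFAULT_N_TESTS
    composite: str = "dependable"

    def validate(self) -> None:
        if self.mode not in ("simulate", "analyze"):
            raise ValueError("mode must be 'simulate' or 'analyze'")
        if self.mode == "analyze" and not self.input_path:
            raise ValueError("analyze mode requires input_path")
        if self.mode == "simulate" and self.input_path:
            raise ValueError("simulate mode takes no input_path")
        self.window.validate()


class SchemaError(ValueError):
    """Input table violates the respondent-table schema."""


def validate_table(data: pd.DataFrame, specs=None) -> None:
    """Check the respondent-table schema; raise SchemaError naming the cell."""
    if specs is None:
        specs = load_item_specs()
    missing = [c for c in REQUIRED_COLS if c not in data.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    for sp in specs:
        col = data[sp.column]
        bad = col.dropna()
        bad = bad[(bad < sp.scale_min) | (bad > sp.scale_max) | (bad % 1 != 0)]
        if len(bad):
            row = bad.index[0]
            raise SchemaError(
                f"{sp.column}: value {bad.iloc[0]!r} at row {row} outside "
                f"Likert range {sp.scale_min}..{sp.scale_max}"
            )
    deg = data["degree"].dropna()
    bad = deg[(deg < 0) | (deg > 6) | (deg % 1 != 0)]
    if len(bad):
        raise SchemaError(
            f"degree: value {bad.iloc[0]!r} at row {bad.index[0]} outside ordinal range 0..6"
        )


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, index=False)
    os.replace(tmp, path)


def _write_text(text: str, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run the full pipeline and write all artifacts; returns the manifest."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    specs = load_item_specs()
    manifest: dict[str, str] = {}
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / f"{name}.csv"
        _write_csv(df, path)
        written.append(path)
        manifest[name] = str(path)

    try:
        if cfg.mode == "simulate":
            sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
            data, truth = generate_population(sim, specs)
            emit("respondents", data)
            emit("latent_truth", truth)
        else:
            data = pd.read_csv(cfg.input_path)
            validate_table(data, specs)

        model = SingleFactorModel().fit(data[TEST_COLS])
        emit("factor_solution", model.solution_().to_frame())
        iq = model.transform(data[TEST_COLS])
        emit("intelligence_scores", pd.DataFrame({"id": data.get("id", data.index), "iq": iq}))

        base_rows = []
        for out in ("gpa", "degree"):
            b = intelligence_baseline(data[out], iq)
            base_rows.append({"outcome": out, **dataclasses.asdict(b)})
        emit("intelligence_baseline", pd.DataFrame(base_rows))

        table = build_results_table(
            data, specs, iq, alpha=cfg.alpha, n_tests=cfg.bonferroni_m
        )
        emit("results_table", table)

        items = keyed_item_matrix(data, specs, cfg.composite)
        composite = score_composite(data, specs, cfg.composite)
        win = run_window_analysis(
            iq, items, composite,
            {"gpa": data["gpa"].to_numpy(), "degree": data["degree"].to_numpy()},
            cfg.window,
        )
        emit("window_results", win)
        emit("window_summary_tidy", windows.tidy_window_summary(win))

        meta_rows = []
        for out in ("gpa", "degree"):
            mf = summarize_meta(win, out)
            meta_rows.append(
                {
                    "outcome": out,
                    "b_unadjusted": mf.unadjusted.coef_mean_iq,
                    "ci_lo_unadjusted": mf.unadjusted.ci_mean_iq[0],
                    "ci_hi_unadjusted": mf.unadjusted.ci_mean_iq[1],
                    "b_adjusted": mf.adjusted.coef_mean_iq,
                    "ci_lo_adjusted": mf.adjusted.ci_mean_iq[0],
                    "ci_hi_adjusted": mf.adjusted.ci_mean_iq[1],
                    "b_omega_on_iq": mf.omega_on_iq,
                    "b_slope_on_omega": mf.slope_on_omega,
                    "attenuation_pct": mf.attenuation_pct,
                    "cis_overlap": mf.cis_overlap,
                    "n_windows": mf.unadjusted.n_windows,
                }
            )
        emit("meta_fits", pd.DataFrame(meta_rows))

        try:
            olow, ohigh = extreme_group_omega(iq, items, min_n=cfg.window.min_n)
            emit(
                "extreme_group_omega",
                pd.DataFrame({"group": ["low", "high"], "omega": [olow, ohigh]}),
            )
        except (ValueError, RuntimeError) as exc:
            logger.warning("extreme-group omega skipped: %s", exc)

        syn_rows = []
        for out in ("gpa", "degree"):
            sf = synergy_fit(table, out, use_adjusted=True, label_alpha=cfg.alpha)
            syn_rows.append(
                {
                    "outcome": out,
                    "slope": sf.slope,
                    "intercept": sf.intercept,
                    "slope_se": sf.slope_se,
                    "p_slope": sf.p_slope,
                    "n_rows": sf.n_rows,
                    "label": sf.label,
                }
            )
            emit(f"synergy_scatter_{out}", fig3_table(table, sf))
        emit("synergy_fits", pd.DataFrame(syn_rows))

        log_lines = [
            "traitsynergy run log",
            f"mode: {cfg.mode}",
            f"seed: {cfg.seed}",
            f"alpha: {cfg.alpha}",
            f"bonferroni_m: {cfg.bonferroni_m}",
            f"composite: {cfg.composite}",
            "window config: " + json.dumps(dataclasses.asdict(cfg.window)),
        ]
        if cfg.mode == "simulate":
            log_lines.append("sim config: " + json.dumps(sim.to_dict()))
        else:
            log_lines.append(f"input: {cfg.input_path}")
        log_path = outdir / "run_log.txt"
        _write_text("\n".join(log_lines) + "\n", log_path)
        written.append(log_path)
        manifest["run_log"] = str(log_path)

        manifest_path = outdir / "manifest.json"
        _write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", manifest_path)
        manifest["manifest"] = str(manifest_path)
        return manifest
    except Exception:
        for path in written:
            try:
                path.unlink()
            except OSError:
                pass
        raise
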