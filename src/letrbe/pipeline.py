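"""End-to-end analysis pipeline: records in, tidy result tables out.

The pipeline reproduces the standard multi-LET knockout analysis flow on
either synthetic or user-supplied record tables:

1. per cell line x quality: LQ fit and MID (exponential interpolation);
2. RBE_MID against the X-ray reference, with the Mylar dose-axis
   correction applied when the test quality was assayed on Mylar;
3. SER of each knockout against wild-type at every quality;
4. RBE-LET line fits per cell line, and the fit of RBE-LET slope against
   X-ray MID;
5. focus kinetics: one-phase decay fit, 1 h induction, 24 h percent
   residual, and the residual-vs-LET line fit per cell line;
6. optionally, mechanistic-model survival predictions for every phenotype
   preset and a predicted-vs-observed MID comparison.

All randomness is controlled by a single mandatory seed in the config;
rerunning the same config writes byte-identical tables.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .foci import fit_one_phase_decay, induced_foci, percent_residual
from .induction import InductionParams
from .io import (
    clonogenic_to_dose_response,
    foci_records_to_timecourse,
    read_clonogenic_csv,
    read_foci_csv,
    write_clonogenic_csv,
    write_foci_csv,
)
from .qualities import QUALITY_PRESETS, NucleusGeometry
from .repair import KineticsParams, PHENOTYPE_PRESETS, predict_survival_curve
from .survival import (
    MIDResult,
    compute_mid,
    compute_rbe,
    compute_ser,
    fit_linear,
    fit_lq,
)
from .synthetic import default_truth, generate_clonogenic_dataset, generate_foci_dataset, truth_table

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": None,                  # mandatory: no hidden entropy
    "clonogenic": "synth",         # path to CSV, or "synth"
    "foci": "synth",               # path to CSV, or "synth"
    "output_dir": "results",
    "reference_quality": "xray",
    "wildtype_line": "wild_type",
    "mylar_factor": 1.22,          # <1 inverts the correction direction
    "mylar_correction": True,
    "model": {
        "enabled": False,
        "n_cells": 1000,
        "doses": None,             # per-quality dose grids; None = data grids
    },
}


def load_config(path) -> dict:
    """Load a YAML pipeline config, merged over the defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    config = {**DEFAULT_CONFIG, **user}
    config["model"] = {**DEFAULT_CONFIG["model"], **(user.get("model") or {})}
    return config


def _validate(config: dict) -> None:
    if config.get("seed") is None:
        raise ValueError("config must set an explicit integer seed")
    if config["reference_quality"] not in QUALITY_PRESETS:
        raise ValueError(f"unknown reference quality {config['reference_quality']!r}")


def _check_let_labels(df: pd.DataFrame, source: str, log: logging.Logger) -> None:
    """Quality labels present in preset registry must carry matching LETs."""
    for q, sub in df.groupby("quality"):
        if q in QUALITY_PRESETS:
            let = QUALITY_PRESETS[q].let
            if not np.allclose(sub["let"], let, rtol=1e-6):
                raise ValueError(
                    f"{source}: LET for quality {q!r} disagrees with preset "
                    f"({sorted(set(sub['let']))} vs {let})"
                )
        else:
            log.warning("%s: quality %r not in preset registry", source, q)


def run_pipeline(config: dict, log_stream=None) -> dict:
    """Run the full analysis; returns the result tables and writes CSVs.

    Returns a dict with keys ``lq``, ``mid``, ``rbe``, ``ser``, ``foci``,
    ``rbe_let``, ``residual_let`` and, when the mechanistic model is
    enabled, ``model_mid`` and ``pred_vs_obs``.
    """
    _validate(config)
    seed = int(config["seed"])
    outdir = Path(config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)

    log = logging.getLogger("letrbe.pipeline")
    log.setLevel(logging.INFO)
    log.handlers = []
    handler = logging.StreamHandler(log_stream or sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    file_handler = logging.FileHandler(outdir / "run.log", mode="w")
    file_handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(file_handler)

    log.info("letrbe %s; seed=%d", __version__, seed)
    log.info("config: %s", {k: v for k, v in config.items()})

    # ---- inputs -----------------------------------------------------------
    rng = np.random.default_rng(seed)
    if config["clonogenic"] == "synth" or config["foci"] == "synth":
        truth = default_truth()
        truth_table(truth).to_csv(outdir / "truth.csv", index=False)
    if config["clonogenic"] == "synth":
        clono = generate_clonogenic_dataset(truth, rng)
        write_clonogenic_csv(clono, outdir / "clonogenic.csv")
    else:
        clono = read_clonogenic_csv(config["clonogenic"])
    if config["foci"] == "synth":
        foci = generate_foci_dataset(truth, rng)
        write_foci_csv(foci, outdir / "foci.csv")
    else:
        foci = read_foci_csv(config["foci"])
    _check_let_labels(clono, "clonogenic", log)
    _check_let_labels(foci, "foci", log)
    log.info("clonogenic records: %d; foci records: %d", len(clono), len(foci))

    ref_q = config["reference_quality"]
    wt = config["wildtype_line"]
    factor = float(config["mylar_factor"]) if config.get("mylar_correction", True) else 1.0

    # ---- LQ fits and MIDs -------------------------------------------------
    dropped: list[str] = []
    lq_rows, mids, surfaces = [], {}, {}
    import warnings as _warnings

    for (line, q), sub in clono.groupby(["cell_line", "quality"], sort=True):
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            dr = clonogenic_to_dose_response(sub, dropped_log=dropped)
            fit = fit_lq(dr)
            mid = compute_mid(dr)
        mids[(line, q)] = mid
        surfaces[(line, q)] = sub["surface"].iloc[0]
        lq_rows.append({
            "cell_line": line, "quality": q, "let": QUALITY_PRESETS[q].let
            if q in QUALITY_PRESETS else float(sub["let"].iloc[0]),
            "alpha": fit.alpha, "beta": fit.beta,
            "alpha_se": fit.alpha_se, "beta_se": fit.beta_se,
            "converged": fit.converged, "mid": mid.mid,
            "mid_tail_fraction": mid.tail_fraction, "n_doses": len(dr),
        })
    for msg in dropped:
        log.info("dropped: %s", msg)
    lq_table = pd.DataFrame(lq_rows)
    mid_table = lq_table[["cell_line", "quality", "let", "mid", "mid_tail_fraction"]]

    # ---- RBE --------------------------------------------------------------
    rbe_rows = []
    for (line, q), mid in sorted(mids.items()):
        if q == ref_q or (line, ref_q) not in mids:
            continue
        ref = mids[(line, ref_q)]
        if surfaces[(line, q)] == "mylar":
            # reference plate doses scaled onto the Mylar axis
            ref = MIDResult(mid=ref.mid * factor, method=ref.method,
                            tail_fraction=ref.tail_fraction)
        rbe = compute_rbe(ref, mid)
        rbe_rows.append({
            "cell_line": line, "quality": q, "let": QUALITY_PRESETS[q].let
            if q in QUALITY_PRESETS else np.nan,
            "rbe_mid": rbe.value, "mid_reference": rbe.numerator_mid,
            "mid_test": rbe.denominator_mid,
            "mylar_corrected": surfaces[(line, q)] == "mylar",
        })
    rbe_table = pd.DataFrame(rbe_rows)

    # ---- SER --------------------------------------------------------------
    ser_rows = []
    for (line, q), mid in sorted(mids.items()):
        if line == wt or (wt, q) not in mids:
            continue
        ser = compute_ser(mids[(wt, q)], mid)
        ser_rows.append({
            "cell_line": line, "quality": q, "let": QUALITY_PRESETS[q].let
            if q in QUALITY_PRESETS else np.nan, "ser": ser.value,
        })
    ser_table = pd.DataFrame(ser_rows)

    # ---- RBE-LET fits ------------------------------------------------------
    rbe_let_rows = []
    if not rbe_table.empty:
        for line, sub in rbe_table.groupby("cell_line"):
            if len(sub) < 3:
                continue
            fit = fit_linear(sub["let"], sub["rbe_mid"])
            rbe_let_rows.append({
                "cell_line": line, "slope": fit.slope, "intercept": fit.intercept,
                "r_squared": fit.r_squared, "slope_se": fit.slope_se,
                "xray_mid": mids[(line, ref_q)].mid if (line, ref_q) in mids else np.nan,
            })
    rbe_let_table = pd.DataFrame(rbe_let_rows)
    if len(rbe_let_table) >= 3:
        slope_fit = fit_linear(rbe_let_table["xray_mid"], rbe_let_table["slope"])
        log.info("RBE-LET slope vs X-ray MID: slope=%.4f R^2=%.3f",
                 slope_fit.slope, slope_fit.r_squared)

    # ---- focus kinetics ----------------------------------------------------
    foci_rows = []
    for (line, q), sub in foci.groupby(["cell_line", "quality"], sort=True):
        tc = foci_records_to_timecourse(sub)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            fit = fit_one_phase_decay(tc)
            induction, ind_sem = induced_foci(tc)
            residual = percent_residual(tc)
        foci_rows.append({
            "cell_line": line, "quality": q, "let": QUALITY_PRESETS[q].let
            if q in QUALITY_PRESETS else float(sub["let"].iloc[0]),
            "y0": fit.y0, "plateau": fit.plateau, "k": fit.k,
            "converged": fit.converged, "induced_foci_1h": induction,
            "induced_sem": ind_sem, "percent_residual_24h": residual,
            "percent_repaired_24h": 100.0 - residual,
        })
    foci_table = pd.DataFrame(foci_rows)

    residual_let_rows = []
    if not foci_table.empty:
        for line, sub in foci_table.groupby("cell_line"):
            if len(sub) < 3:
                continue
            fit = fit_linear(sub["let"], sub["percent_residual_24h"])
            residual_let_rows.append({
                "cell_line": line, "slope": fit.slope,
                "intercept": fit.intercept, "r_squared": fit.r_squared,
            })
    residual_let_table = pd.DataFrame(residual_let_rows)

    results = {
        "lq": lq_table, "mid": mid_table, "rbe": rbe_table, "ser": ser_table,
        "rbe_let": rbe_let_table, "foci": foci_table,
        "residual_let": residual_let_table,
    }

    # ---- mechanistic model -------------------------------------------------
    if config["model"]["enabled"]:
        geom = NucleusGeometry()
        induction_params = InductionParams()
        kinetics = KineticsParams()
        n_cells = int(config["model"]["n_cells"])
        model_rows = []
        data_lines = {line for line, _ in mids}
        for label, phen in PHENOTYPE_PRESETS.items():
            for q, quality in QUALITY_PRESETS.items():
                grid = (config["model"]["doses"] or {}).get(q) if config["model"]["doses"] else None
                if grid is None:
                    grid = sorted(clono.loc[clono["quality"] == q, "dose"].unique()) \
                        if (clono["quality"] == q).any() else [0, 0.5, 1, 2, 4]
                curve = predict_survival_curve(
                    phen, quality, grid, n_cells,
                    geom=geom, induction=induction_params, kinetics=kinetics,
                    seed=seed,
                )
                with _warnings.catch_warnings():
                    _warnings.simplefilter("ignore")
                    mid = compute_mid(curve)
                model_rows.append({
                    "cell_line": label, "quality": q, "let": quality.let,
                    "mid_model": mid.mid,
                })
        model_table = pd.DataFrame(model_rows)
        results["model_mid"] = model_table

        merged = model_table.merge(
            mid_table, on=["cell_line", "quality"], how="inner",
            suffixes=("", "_obs"),
        )
        if len(merged) >= 3:
            fit = fit_linear(merged["mid"], merged["mid_model"])
            results["pred_vs_obs"] = pd.DataFrame([{
                "slope": fit.slope, "intercept": fit.intercept,
                "r_squared": fit.r_squared, "slope_se": fit.slope_se,
                "n_points": len(merged),
            }])
            log.info("predicted vs observed MID: slope=%.3f R^2=%.3f",
                     fit.slope, fit.r_squared)
        log.info("model lines without matching data: %s",
                 sorted(set(PHENOTYPE_PRESETS) - data_lines) or "none")

    # ---- outputs -----------------------------------------------------------
    for name, table in results.items():
        table.to_csv(outdir / f"{name}.csv", index=False)
        log.info("wrote %s.csv (%d rows)", name, len(table))
    log.removeHandler(file_handler)
    file_handler.close()
    return results
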