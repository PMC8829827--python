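"""Delimited-table and config I/O plus the end-to-end pipeline.

Tables are plain delimited text with a header row; column names carry the
reporting units (``g_G_per_cm``, ``D_app_1e5_cm2_s``, ``C_M_mM`` ...), and
reading converts them to the internal SI units.  The pipeline config is a
flat-per-section YAML mapping; every key is validated before any
computation, and unknown keys are an error.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import constants as const
from .competition import fit_Q
from .decay import GradientDecaySeries, PulseParams, calibrate_gradient, fit_replicates
from .exchange import entropy_of_release, fit_Db
from .lineshape import fit_Rb
from .quantify import IntegralRatioRecord, fit_ion_excess, na_total, percent_vs_prediction
from .release import ReleaseInputs, complex_fraction, released_ions

# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

#: column name -> conversion applied on read (reporting units -> internal SI)
_UNIT_RULES = {
    "g_G_per_cm": const.gradient_G_per_cm_to_T_per_m,
    "D_app_1e5_cm2_s": const.diffusion_report_to_SI,
    "se_D": const.diffusion_report_to_SI,
    "C_M_mM": const.concentration_mM_to_M,
    "KCl_mM": const.concentration_mM_to_M,
    "Na_total_mM": const.concentration_mM_to_M,
}

#: internal column names after unit conversion
_RENAME = {
    "g_G_per_cm": "g",                  # T/m
    "D_app_1e5_cm2_s": "D_app",         # m^2/s
    "C_M_mM": "C_M",                    # mol/L
    "KCl_mM": "KCl",                    # mol/L
    "Na_total_mM": "Na_total",          # mol/L
}

SCHEMAS = {
    "decay": ["g_G_per_cm", "integral", "replicate"],
    "quant": ["C_M_mM", "r_sample", "replicate"],
    "titration": ["C_M_mM", "D_app_1e5_cm2_s", "se_D"],
    "competition": ["KCl_mM", "D_app_1e5_cm2_s", "se_D"],
    "r2_titration": ["C_M_mM", "R2_app", "se_R2"],
    "spectrum": ["freq_hz", "intensity"],
}


def read_table(path, schema: str) -> pd.DataFrame:
    """Read a delimited table, validate the header, apply unit conversions.

    Numeric parse failures raise with the 1-based data row and column named.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    path = Path(path)
    import csv
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                         skipinitialspace=True)
    except (pd.errors.EmptyDataError, csv.Error):
        raise ValueError(f"{path}: empty or unparseable file") from None
    missing = [c for c in SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; "
                         f"expected header {SCHEMAS[schema]}")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    out = {}
    for col in SCHEMAS[schema]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna() & df[col].notna()]
        if len(bad):
            row = int(bad[0]) + 1
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[bad[0]]!r} in "
                f"column {col!r}, data row {row}")
        if col in _UNIT_RULES:
            vals = vals.map(_UNIT_RULES[col])
        out[_RENAME.get(col, col)] = vals.to_numpy(dtype=float)
    return pd.DataFrame(out)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

_GLOBAL_KEYS = {"seed", "na_buffer_mM", "predicted_Ncation", "out_dir"}
_SECTION_KEYS = {
    "decay": {"table", "delta_ms", "Delta_ms", "tau_ms", "TL_ms", "nucleus",
              "weighting", "D_reference_1e5"},
    "quantify": {"table", "r_buffer", "fix_intercept"},
    "exchange": {"table", "D_f_1e5", "a", "weighted", "n_boot"},
    "competition": {"table", "Na_total_mM", "T_capacity_mM", "D_f_1e5",
                    "D_b_1e5", "weighted", "n_boot"},
    "release": {"D_PD_1e5", "D_D_1e5", "D_f_1e5", "n_c", "p_complex",
                "P_total_mM", "DNA_total_mM", "Kd_mM",
                "se_D_PD_1e5", "se_D_D_1e5", "se_D_f_1e5"},
    "lineshape": {"table", "R_f", "a", "weighted", "n_boot"},
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    """Reject unknown keys anywhere in the config (typo protection)."""
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    for key, val in cfg.items():
        if key in _GLOBAL_KEYS:
            continue
        if key in _SECTION_KEYS:
            if not isinstance(val, dict):
                raise ValueError(f"config section {key!r} must be a mapping")
            unknown = set(val) - _SECTION_KEYS[key]
            if unknown:
                raise ValueError(
                    f"unknown key(s) {sorted(unknown)} in config section "
                    f"{key!r}; allowed: {sorted(_SECTION_KEYS[key])}")
        else:
            raise ValueError(
                f"unknown config key {key!r}; allowed sections: "
                f"{sorted(_SECTION_KEYS)}, global keys: {sorted(_GLOBAL_KEYS)}")


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

_STAGE_ORDER = ["decay", "quantify", "exchange", "competition", "release",
                "lineshape"]


def run_pipeline(config: dict, base_dir=".") -> dict:
    """Execute the configured stages in dependency order.

    Returns ``{"results": {...}, "log": [...]}``; measured parameters flow
    forward (quantify's ``a`` into exchange and lineshape; exchange's D_f/D_b
    into competition) unless overridden in the config.  Any stage failure
    raises with the stage name; completed stages' results are attached to
    the exception.
    """
    validate_config(config)
    base = Path(base_dir)
    na_buffer = float(config.get("na_buffer_mM", 20.0)) * 1e-3
    results: dict = {}
    log: list[str] = []
    log.append(f"na_buffer = {na_buffer * 1e3:.3f} mM")

    for stage in _STAGE_ORDER:
        if stage not in config:
            continue
        sec = config[stage]
        try:
            if stage == "decay":
                _stage_decay(sec, base, results, log)
            elif stage == "quantify":
                _stage_quantify(sec, base, na_buffer, results, log)
            elif stage == "exchange":
                _stage_exchange(sec, base, na_buffer, results, log)
            elif stage == "competition":
                _stage_competition(sec, base, results, log)
            elif stage == "release":
                _stage_release(sec, config, results, log)
            elif stage == "lineshape":
                _stage_lineshape(sec, base, na_buffer, results, log)
        except Exception as exc:
            exc.partial_results = results  # preserve completed stages
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return {"results": results, "log": log}


def _pulse_params(sec: dict) -> PulseParams:
    return PulseParams(
        delta=float(sec.get("delta_ms", 2.0)) * 1e-3,
        Delta=float(sec.get("Delta_ms", 20.0)) * 1e-3,
        tau=float(sec.get("tau_ms", 0.2)) * 1e-3,
        T_L=float(sec.get("TL_ms", 0.0)) * 1e-3,
        nucleus=sec.get("nucleus", "23Na"))


def _stage_decay(sec, base, results, log):
    df = read_table(base / sec["table"], "decay")
    params = _pulse_params(sec)
    series = [
        GradientDecaySeries(grp["g"].to_numpy(), grp["integral"].to_numpy(),
                            params, replicate=int(rep))
        for rep, grp in df.groupby("replicate")]
    mean_D, sem, fits = fit_replicates(series, sec.get("weighting", "none"))
    results["D_app"] = const.diffusion_SI_to_report(mean_D)
    results["se_D_app"] = (const.diffusion_SI_to_report(sem)
                           if np.isfinite(sem) else None)
    log.append(f"decay: D = {results['D_app']:.3f} x1e-5 cm2/s "
               f"(SEM over {len(series)} replicates, "
               f"least-squares, n = {fits[0].n_points})")
    if "D_reference_1e5" in sec:
        s = calibrate_gradient(series[0],
                               const.diffusion_report_to_SI(
                                   float(sec["D_reference_1e5"])))
        results["gradient_scale"] = s
        log.append(f"decay: gradient calibration scale s = {s:.6f}")


def _stage_quantify(sec, base, na_buffer, results, log):
    df = read_table(base / sec["table"], "quant")
    r_buffer = float(sec["r_buffer"])
    na = np.array([
        na_total(IntegralRatioRecord(r, r_buffer, C, na_buffer))
        for r, C in zip(df["r_sample"], df["C_M"])])
    fix = na_buffer if sec.get("fix_intercept", False) else None
    fit = fit_ion_excess(df["C_M"].to_numpy(), na, fix_intercept=fix,
                         Na_buffer=na_buffer)
    results["a"] = fit.a_
    results["se_a"] = fit.se_a_
    results["intercept_mM"] = fit.intercept_ * 1e3
    mode = "fixed intercept" if fix is not None else "free intercept"
    log.append(f"quantify: a = {fit.a_:.1f} +/- {fit.se_a_:.1f} ions per "
               f"macromolecule ({mode}, OLS, n = {fit.n_points_})")


def _stage_exchange(sec, base, na_buffer, results, log):
    df = read_table(base / sec["table"], "titration")
    D_f = const.diffusion_report_to_SI(float(sec["D_f_1e5"]))
    a = float(sec["a"]) if "a" in sec else results["a"]
    fit = fit_Db(df["C_M"].to_numpy(), df["D_app"].to_numpy(), D_f, a,
                 na_buffer, sigma=df["se_D"].to_numpy(),
                 weighted=bool(sec.get("weighted", False)),
                 n_boot=int(sec.get("n_boot", 0)))
    D_b = fit.estimate
    ent = entropy_of_release(D_b, D_f)
    results["D_f"] = const.diffusion_SI_to_report(D_f)
    results["D_b"] = const.diffusion_SI_to_report(D_b)
    results["se_D_b"] = const.diffusion_SI_to_report(fit.se)
    results["Db_over_Df"] = ent.ratio
    results["dS_release_eu"] = ent.dS_per_ion_eu
    log.append(f"exchange: D_b = {results['D_b']:.3f} +/- "
               f"{results['se_D_b']:.3f} x1e-5 cm2/s "
               f"({fit.method}, n = {fit.n_points}); "
               f"D_b/D_f = {ent.ratio:.2f}; "
               f"dS_release = {ent.dS_per_ion_eu:.2f} eu per ion")
    log.append("exchange: assumption - D_f measured on buffer, a from "
               "quantification; D_b is the only fitted parameter")


def _stage_competition(sec, base, results, log):
    df = read_table(base / sec["table"], "competition")
    Na_total = float(sec["Na_total_mM"]) * 1e-3
    T = float(sec["T_capacity_mM"]) * 1e-3
    D_f = (const.diffusion_report_to_SI(float(sec["D_f_1e5"]))
           if "D_f_1e5" in sec else const.diffusion_report_to_SI(results["D_f"]))
    D_b = (const.diffusion_report_to_SI(float(sec["D_b_1e5"]))
           if "D_b_1e5" in sec else const.diffusion_report_to_SI(results["D_b"]))
    fit = fit_Q(df["KCl"].to_numpy(), df["D_app"].to_numpy(), Na_total, T,
                D_f, D_b, sigma=df["se_D"].to_numpy(),
                weighted=bool(sec.get("weighted", False)),
                n_boot=int(sec.get("n_boot", 0)))
    results["Q"] = fit.estimate
    results["se_Q"] = fit.se
    log.append(f"competition: Q = {fit.estimate:.2f} +/- {fit.se:.2f} "
               f"({fit.method}, n = {fit.n_points})")
    log.append("competition: assumption - total atmosphere occupancy held "
               "fixed at n_c[DNA] for all KCl (n_c = a)")


def _stage_release(sec, config, results, log):
    if "p_complex" in sec:
        p_complex = float(sec["p_complex"])
    else:
        p_complex = complex_fraction(
            float(sec["P_total_mM"]) * 1e-3,
            float(sec["DNA_total_mM"]) * 1e-3,
            float(sec["Kd_mM"]) * 1e-3 if "Kd_mM" in sec else None)
    n_c = float(sec["n_c"]) if "n_c" in sec else results["a"]
    inputs = ReleaseInputs(
        D_PD=float(sec["D_PD_1e5"]), D_D=float(sec["D_D_1e5"]),
        D_f=float(sec["D_f_1e5"]), n_c=n_c, p_complex=p_complex,
        se_D_PD=float(sec.get("se_D_PD_1e5", 0.0)),
        se_D_D=float(sec.get("se_D_D_1e5", 0.0)),
        se_D_f=float(sec.get("se_D_f_1e5", 0.0)))
    n_R, se = released_ions(inputs)
    results["n_R"] = n_R
    results["se_n_R"] = se
    results["p_complex"] = p_complex
    log.append(f"release: n_R = {n_R:.1f} +/- {se:.1f} ions per complex "
               f"(p_complex = {p_complex:.3f}, first-order propagation)")
    log.append("release: assumption - equal Na_total in the two samples; "
               "protein carries no Na+ atmosphere")
    if "predicted_Ncation" in config and "a" in results:
        pct = percent_vs_prediction(results["a"],
                                    float(config["predicted_Ncation"]))
        results["percent_vs_prediction"] = pct
        log.append(f"release: measured a exceeds the electrostatic "
                   f"prediction by {pct:.0f}%")


def _stage_lineshape(sec, base, na_buffer, results, log):
    df = read_table(base / sec["table"], "r2_titration")
    a = float(sec["a"]) if "a" in sec else results["a"]
    fit = fit_Rb(df["C_M"].to_numpy(), df["R2_app"].to_numpy(),
                 float(sec["R_f"]), a, na_buffer,
                 sigma=df["se_R2"].to_numpy(),
                 weighted=bool(sec.get("weighted", False)),
                 n_boot=int(sec.get("n_boot", 0)))
    results["R_f"] = float(sec["R_f"])
    results["R_b"] = fit.estimate
    results["se_R_b"] = fit.se
    log.append(f"lineshape: R_b = {fit.estimate:.1f} +/- {fit.se:.1f} s^-1 "
               f"({fit.method}, n = {fit.n_points})")


def write_results(payload: dict, out_dir) -> None:
    """Write the machine-readable results file and the plain-text log.

    Output is deterministic (sorted keys, no timestamps): identical config
    and seed give byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "results.json", "w") as fh:
        json.dump(payload["results"], fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(payload["log"]) + "\n")
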