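"""Delimited-text and JSON I/O: occupancy traces, gating schemes, run
configuration, and the end-to-end reproduction report.

All files use comma separation, "." decimal, UTF-8 and Unix newlines; units
are seconds and molar throughout (micromolar appears only in rendered
reports).  Logging goes to standard error; results never do.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .calibrate import CalibrationResult, calibrate, default_targets
from .scheme import RATE_NAMES, GatingScheme, STATE_LABELS
from .simulate import OccupancyTrace

log = logging.getLogger(__name__)

TRACE_TIME_COL = "time_s"
TRACE_POPEN_COL = "p_open"
TRACE_OCC_COLS = tuple(f"occ_{label}" for label in STATE_LABELS)


class TraceFormatError(ValueError):
    pass


class ConfigError(ValueError):
    pass


def write_trace(trace: OccupancyTrace, path: str | Path, occupancies: bool = True) -> None:
    """Write a trace as CSV with columns time_s, p_open[, occ_R ... occ_AOD]."""
    data = {TRACE_TIME_COL: trace.time, TRACE_POPEN_COL: trace.p_open}
    if occupancies:
        for j, col in enumerate(TRACE_OCC_COLS):
            data[col] = trace.occupancy[:, j]
    pd.DataFrame(data).to_csv(path, index=False, lineterminator="\n")


def read_trace(path: str | Path) -> OccupancyTrace:
    """Read a trace CSV written by :func:`write_trace` (lossless round trip)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise TraceFormatError(f"{path}: empty trace file") from exc
    for col in (TRACE_TIME_COL, TRACE_POPEN_COL):
        if col not in df.columns:
            raise TraceFormatError(f"{path}: missing required column {col!r}")
    if len(df) == 0:
        raise TraceFormatError(f"{path}: trace has no samples")
    time = df[TRACE_TIME_COL].to_numpy(dtype=float)
    p_open = df[TRACE_POPEN_COL].to_numpy(dtype=float)
    if all(col in df.columns for col in TRACE_OCC_COLS):
        occupancy = df[list(TRACE_OCC_COLS)].to_numpy(dtype=float)
        ao = occupancy[:, STATE_LABELS.index("AO")]
        explicit = None if np.array_equal(ao, p_open) else p_open
        return OccupancyTrace(time=time, occupancy=occupancy, metadata={"source": str(path)},
                              _p_open=explicit)
    occupancy = np.zeros((len(time), 6))
    occupancy[:, STATE_LABELS.index("AO")] = p_open
    return OccupancyTrace(time=time, occupancy=occupancy,
                          metadata={"source": str(path), "occupancies": "p_open-only"})


def write_scheme(scheme: GatingScheme, path: str | Path) -> None:
    Path(path).write_text(json.dumps(scheme.rates(), indent=2, sort_keys=True) + "\n")


def read_scheme(path: str | Path) -> GatingScheme:
    """Read a gating scheme from JSON holding exactly the ten rate names."""
    raw = json.loads(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: scheme file must be a JSON object")
    unknown = set(raw) - set(RATE_NAMES)
    if unknown:
        raise ConfigError(f"{path}: unknown rate key(s) {sorted(unknown)}")
    missing = set(RATE_NAMES) - set(raw)
    if missing:
        raise ConfigError(f"{path}: missing rate key(s) {sorted(missing)}")
    return GatingScheme(**{k: float(v) for k, v in raw.items()})


@dataclass
class RunConfig:
    """Configuration of the one-command reproduction run."""

    scheme_path: str | None = None  # optional: skip calibration, use this WT scheme
    target_set: str = "default"
    n_starts: int = 32
    seed: int = 1
    out_dir: str = "results"

    _FIELD_TYPES = {
        "scheme_path": (str, type(None)),
        "target_set": str,
        "n_starts": int,
        "seed": int,
        "out_dir": str,
    }


def read_config(path: str | Path) -> RunConfig:
    """Load a JSON config with defaults; unknown keys and wrong types are errors."""
    raw = json.loads(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a JSON object")
    defaults = RunConfig()
    for key, value in raw.items():
        if key not in RunConfig._FIELD_TYPES:
            raise ConfigError(f"{path}: unknown config key {key!r}")
        expected = RunConfig._FIELD_TYPES[key]
        if not isinstance(value, expected) or isinstance(value, bool):
            raise ConfigError(f"{path}: config key {key!r} has wrong type {type(value).__name__}")
        setattr(defaults, key, value)
    return defaults


def write_config(config: RunConfig, path: str | Path) -> None:
    payload = {k: v for k, v in asdict(config).items()}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _report_payload(result: CalibrationResult) -> dict:
    stats = result.stats
    printed_wt = next(r for r in result.per_target
                      if r["genotype"] == "WT" and r["statistic"] == "ec50")
    printed_mut = next(r for r in result.per_target
                       if r["genotype"] == "W329A" and r["statistic"] == "ec50")
    fold_model = stats["W329A"]["ec50"] / stats["WT"]["ec50"]
    fold_printed = printed_mut["printed_mean"] / printed_wt["printed_mean"]
    return {
        "seed": result.seed,
        "loss": result.loss,
        "converged": result.converged,
        "winning_start": result.start_index,
        "n_evaluations": result.n_evaluations,
        "fitted_wt_rates": result.scheme.rates(),
        "targets": result.per_target,
        "genotype_stats": stats,
        "fold_change_ec50": {
            "model": fold_model,
            "printed": fold_printed,
            "model_ge_10": bool(fold_model >= 10.0),
            "printed_ge_10": bool(fold_printed >= 10.0),
        },
        "directional_checks": {
            "tau_order": bool(
                stats["W329A"]["weighted_tau"]
                < stats["WT"]["weighted_tau"] / 10.0
                < stats["WT"]["weighted_tau"]
                < stats["W280Q"]["weighted_tau"]
            ),
            "ec50_order": bool(
                stats["W280Q"]["ec50"] < stats["WT"]["ec50"] < stats["W329A"]["ec50"]
            ),
            "desensitization": bool(
                stats["W329A"]["desensitization_pct"] < 5.0
                and stats["WT"]["desensitization_pct"] > 30.0
            ),
        },
    }


def _render_report(payload: dict) -> str:
    lines = [
        "rho1 receptor model reproduction report",
        f"seed={payload['seed']}  loss={payload['loss']:.4g}  converged={payload['converged']}",
        "",
        f"{'genotype':<8} {'statistic':<14} {'printed':>12} {'model':>12} {'within 1 SEM':>13}",
    ]
    for row in payload["targets"]:
        unit_scale = 1e6 if row["statistic"] == "ec50" else 1.0
        unit = "uM" if row["statistic"] == "ec50" else "s"
        lines.append(
            f"{row['genotype']:<8} {row['statistic']:<14} "
            f"{row['printed_mean'] * unit_scale:>10.3g} {unit:<2}"
            f"{row['model_value'] * unit_scale:>10.3g} {unit:<2}"
            f"{str(row['within_tolerance']):>11}"
        )
    fc = payload["fold_change_ec50"]
    lines += [
        "",
        f"EC50 fold change W329A/WT: model {fc['model']:.2f}, printed {fc['printed']:.2f}",
        f"directional checks: {payload['directional_checks']}",
    ]
    return "\n".join(lines) + "\n"


def run_reproduction(config: RunConfig) -> dict:
    """Calibrate against the default targets and write the reproduction report.

    Returns the report payload; writes ``report.json`` and ``report.txt``
    under ``config.out_dir``.  Deterministic given the config (reports carry
    no timestamps).
    """
    if config.target_set != "default":
        raise ConfigError(f"unknown target set {config.target_set!r}")
    targets = default_targets()
    import importlib.metadata

    import scipy

    try:
        pkg_version = importlib.metadata.version("rho1kin")
    except importlib.metadata.PackageNotFoundError:  # pragma: no cover
        pkg_version = "unknown"
    log.info("reproduction: rho1kin %s, numpy %s, scipy %s",
             pkg_version, np.__version__, scipy.__version__)
    log.info("reproduction: calibrating (%d starts, seed %d)", config.n_starts, config.seed)
    if config.scheme_path is not None:
        wt = read_scheme(config.scheme_path)
        result = _result_from_scheme(wt, targets, config.seed)
    else:
        result = calibrate(targets, n_starts=config.n_starts, seed=config.seed)
    payload = _report_payload(result)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    (out / "report.txt").write_text(_render_report(payload))
    log.info("reproduction: report written to %s", out)
    return payload


def _result_from_scheme(wt: GatingScheme, targets, seed: int) -> CalibrationResult:
    """Evaluate a fixed WT scheme against targets without optimizing."""
    from .calibrate import model_summary_stats

    genotypes = sorted({t.genotype for t in targets})
    stats = {g: model_summary_stats(wt, g) for g in genotypes}
    per_target, loss, converged = [], 0.0, True
    for t in targets:
        value = stats[t.genotype][t.statistic]
        within = abs(value - t.printed_mean) <= t.tolerance
        converged &= within
        loss += (np.log(value) - np.log(t.printed_mean)) ** 2
        per_target.append({
            "genotype": t.genotype, "statistic": t.statistic,
            "printed_mean": t.printed_mean, "printed_sem": t.printed_sem,
            "tolerance": t.tolerance, "model_value": value,
            "within_tolerance": bool(within),
        })
    return CalibrationResult(scheme=wt, per_target=per_target, loss=float(loss),
                             n_evaluations=len(genotypes), converged=bool(converged),
                             seed=seed, start_index=-1, stats=stats)
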