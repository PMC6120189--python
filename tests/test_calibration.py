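"""Calibration targets, genotype summary statistics, and joint fitting."""

import numpy as np
import pytest

from rho1kin import (
    CalibrationTarget,
    apply_mutation,
    calibrate,
    default_targets,
    model_summary_stats,
    predefined_mutant_rules,
)
from rho1kin.calibrate import _heuristic_start, default_rate_bounds
from rho1kin.scheme import RATE_NAMES


def test_default_targets_are_the_six_printed_statistics():
    targets = default_targets()
    assert len(targets) == 6
    by = {(t.genotype, t.statistic): t for t in targets}
    assert by[("WT", "ec50")].printed_mean == pytest.approx(2.19e-6)
    assert by[("WT", "ec50")].printed_sem == pytest.approx(0.65e-6)
    assert by[("W280Q", "ec50")].printed_mean == pytest.approx(0.92e-6)
    assert by[("W329A", "ec50")].printed_mean == pytest.approx(25.76e-6)
    assert by[("WT", "weighted_tau")].printed_mean == pytest.approx(26.9)
    assert by[("W280Q", "weighted_tau")].printed_mean == pytest.approx(84.4)
    assert by[("W329A", "weighted_tau")].printed_mean == pytest.approx(0.86)
    assert by[("W329A", "weighted_tau")].printed_sem == pytest.approx(0.1)
    # default tolerance is one SEM
    assert all(t.tolerance == t.printed_sem for t in targets)


def test_target_validation():
    with pytest.raises(Exception):
        CalibrationTarget("WT", "ec50", 1e-6, 0.0)
    with pytest.raises(Exception):
        CalibrationTarget("XX", "ec50", 1e-6, 1e-7)


FAST = dict(crc_dt=0.05, deact_dt=0.05, max_fit_points=600)


def test_mutant_stats_equal_stats_of_explicitly_mutated_scheme(wt_like_scheme):
    via_rule = model_summary_stats(wt_like_scheme, "W329A", **FAST)
    mutated = apply_mutation(wt_like_scheme, predefined_mutant_rules()["W329A"])
    direct = model_summary_stats(mutated, "WT", **FAST)
    assert via_rule["ec50"] == pytest.approx(direct["ec50"], rel=1e-9)
    assert via_rule["weighted_tau"] == pytest.approx(direct["weighted_tau"], rel=1e-9)


def test_desensitization_free_genotype_has_zero_extent(binding_limited_scheme):
    stats = model_summary_stats(binding_limited_scheme, "W329A", **FAST)
    assert stats["desensitization_pct"] == pytest.approx(0.0, abs=0.5)


def test_w329a_ec50_is_tenfold_wt_in_binding_limit(binding_limited_scheme):
    # Kd = 1 uM so that even the 10x-shifted mutant curve saturates well
    # inside the standard 10 nM - 1 mM concentration grid
    scheme = binding_limited_scheme.with_rates(k_minus1=1.0)
    wt = model_summary_stats(scheme, "WT", **FAST)
    mut = model_summary_stats(scheme, "W329A", **FAST)
    assert mut["ec50"] / wt["ec50"] == pytest.approx(10.0, rel=0.10)


def test_tenfold_k_minus1_increases_model_ec50():
    rng = np.random.default_rng(17)
    for _ in range(3):
        rates = {
            "k1": 10 ** rng.uniform(5.5, 6.5),
            "k_minus1": 10 ** rng.uniform(-0.5, 1.0),
            "f1": 10 ** rng.uniform(0.5, 2.0),
            "f_minus1": 10 ** rng.uniform(0.5, 2.0),
            "beta": 10 ** rng.uniform(1.0, 2.5),
            "alpha": 10 ** rng.uniform(0.5, 2.0),
            "dAF_on": 0.0, "dAF_off": 1.0, "dAO_on": 0.0, "dAO_off": 1.0,
        }
        from rho1kin import GatingScheme

        base = GatingScheme(**rates)
        fast = base.with_rates(k_minus1=rates["k_minus1"] * 10.0)
        ec50_base = model_summary_stats(base, "WT", **FAST)["ec50"]
        ec50_fast = model_summary_stats(fast, "WT", **FAST)["ec50"]
        assert ec50_fast > ec50_base


def test_heuristic_start_lies_within_bounds():
    bounds = default_rate_bounds()
    x0 = _heuristic_start(default_targets(), bounds)
    lo = np.log([bounds[n][0] for n in RATE_NAMES])
    hi = np.log([bounds[n][1] for n in RATE_NAMES])
    assert np.all(x0 >= lo - 1e-12) and np.all(x0 <= hi + 1e-12)


def test_calibration_fixed_point_at_known_solution(wt_like_scheme):
    """Starting at a scheme whose own statistics are the targets, the
    optimizer stays put and the loss is essentially zero."""
    stats = {g: model_summary_stats(wt_like_scheme, g) for g in ("WT", "W280Q", "W329A")}
    targets = [
        CalibrationTarget(g, stat, stats[g][stat], 0.05 * stats[g][stat])
        for g in ("WT", "W280Q", "W329A")
        for stat in ("ec50", "weighted_tau")
    ]
    # inner-loop grids aligned with the reference grids so the start is an
    # exact zero of the objective
    result = calibrate(
        targets, n_starts=1, seed=1, initial_scheme=wt_like_scheme,
        screen_nfev=2, refine_nfev=3, fast_dt=0.01, fast_fit_points=2000,
    )
    assert result.loss <= 1e-6
    assert result.converged


def test_calibration_roundtrip_recovers_target_statistics(wt_like_scheme):
    """Targets generated from a known scheme are recovered within 5%."""
    stats = {g: model_summary_stats(wt_like_scheme, g) for g in ("WT", "W280Q", "W329A")}
    targets = [
        CalibrationTarget(g, stat, stats[g][stat], 0.05 * stats[g][stat])
        for g in ("WT", "W280Q", "W329A")
        for stat in ("ec50", "weighted_tau")
    ]
    result = calibrate(targets, n_starts=2, seed=4, screen_nfev=6, refine_nfev=25, n_refine=1)
    assert result.converged
    for row in result.per_target:
        assert row["model_value"] == pytest.approx(row["printed_mean"], rel=0.05)


def test_removing_a_target_does_not_increase_optimal_loss(wt_like_scheme):
    stats = {g: model_summary_stats(wt_like_scheme, g) for g in ("WT", "W329A")}
    targets = [
        CalibrationTarget(g, stat, stats[g][stat], 0.05 * stats[g][stat])
        for g in ("WT", "W329A")
        for stat in ("ec50", "weighted_tau")
    ]
    kw = dict(n_starts=1, seed=1, initial_scheme=wt_like_scheme,
              screen_nfev=2, refine_nfev=3, fast_dt=0.01)
    full = calibrate(targets, **kw)
    subset = calibrate(targets[:-1], **kw)
    assert subset.loss <= full.loss + 1e-9


def test_result_statistics_reproducible_from_fitted_scheme(wt_like_scheme):
    stats = {g: model_summary_stats(wt_like_scheme, g) for g in ("WT", "W329A")}
    targets = [
        CalibrationTarget(g, "ec50", stats[g]["ec50"], 0.05 * stats[g]["ec50"])
        for g in ("WT", "W329A")
    ]
    result = calibrate(targets, n_starts=1, seed=1, initial_scheme=wt_like_scheme,
                       screen_nfev=2, refine_nfev=3, fast_dt=0.01)
    for row in result.per_target:
        fresh = model_summary_stats(result.scheme, row["genotype"])
        assert fresh[row["statistic"]] == pytest.approx(row["model_value"], rel=1e-9)
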