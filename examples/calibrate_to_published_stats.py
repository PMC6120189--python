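"""Jointly calibrate the WT rate set against the six published rho1
summary statistics.

Estimates one wild-type rate vector such that, with mutants derived through
the fixed perturbation rules, the model reproduces the three GABA EC50s and
the three weighted deactivation time constants within one printed SEM each.

A single informed start is used here so the example runs in about two
minutes; the reference run uses 32 multi-starts (see scripts/acceptance.py).
"""

from rho1kin import calibrate, default_targets

result = calibrate(default_targets(), n_starts=1, seed=1)

print(f"loss {result.loss:.4g}   converged within 1 SEM: {result.converged}")
print()
print(f"{'genotype':<8} {'statistic':<13} {'printed':>10} {'model':>10} {'within':>7}")
for row in result.per_target:
    scale, unit = (1e6, "uM") if row["statistic"] == "ec50" else (1.0, "s")
    print(f"{row['genotype']:<8} {row['statistic']:<13} "
          f"{row['printed_mean'] * scale:>8.2f} {unit:<3}"
          f"{row['model_value'] * scale:>8.2f} {unit:<3}"
          f"{str(row['within_tolerance']):>5}")

print()
print("fitted WT rates:")
for name, value in result.scheme.rates().items():
    print(f"  {name:<9} {value:12.4g}")
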