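"""Fit Type-II allometric lines and test for a common slope between sexes.

On log-log axes the SMA slope is the allometric exponent: 3 means
isometry (mass grows like length cubed), above 3 means positive
allometry. The likelihood-ratio test asks whether females and males can
share one exponent.
"""

from allobci import common_slope_test, fit_line, generate_population, stratify

strata = stratify(generate_population(seed=1), "sex")

for stratum in strata:
    for variable in ("mass", "fat"):
        f = fit_line(
            stratum.column("svl"),
            stratum.column(variable),
            "SMA",
            x_transform="log",
            y_transform="log",
        )
        lo, hi = f.slope_ci
        print(
            f"{stratum.label:>6} {variable:<4} SMA slope {f.slope:.2f} "
            f"[95% CI {lo:.2f}-{hi:.2f}]  r2 {f.r2:.2f}  n {f.n}"
        )

for variable in ("mass", "fat"):
    groups = [(s.column("svl"), s.column(variable)) for s in strata]
    t = common_slope_test(groups, x_transform="log", y_transform="log")
    verdict = "different" if t.p <= 0.05 else "indistinguishable"
    print(
        f"common-slope LR test ({variable}): statistic {t.statistic:.2f}, "
        f"p = {t.p:.4f} -> sex slopes {verdict}"
    )

# Slopes above 3 indicate positive allometry: big snakes are
# disproportionately heavy, and disproportionately fat, for their length.
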