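"""Compute the 11 body condition indices and the fat-based condition measures.

Shows the rank agreement between the scaled mass index and the SMA
residual index (always exactly 1: the log of the SMI is an increasing
affine function of the SMA residual) and the size-independence of
residual fat.
"""

from allobci import compute_condition, generate_population, kendall_tau, stratify

stratum = stratify(generate_population(seed=1), "sex")[0]
table = compute_condition(stratum)

print(f"stratum {table.stratum}, n = {stratum.n}")
print(table.values.head(3).round(4).to_string())

v = table.values
print()
print("mean SMA residual    :", f"{v['SMAres'].mean():+.2e}  (centred by construction)")
print("mean residual fat    :", f"{v['residual_fat'].mean():+.2e}  (centred by construction)")
print("tau(SMI, SMAres)     :", kendall_tau(v["SMI"], v["SMAres"]).tau)
print(
    "tau(percent fat, SVL):",
    round(kendall_tau(v["percent_fat"], stratum.column("svl")).tau, 3),
    " (positive: percent fat conflates condition with size)",
)
print(
    "tau(residual fat, SVL):",
    round(kendall_tau(v["residual_fat"], stratum.column("svl")).tau, 3),
    " (slightly negative: SMA residuals carry corr -sqrt((1-r)/2) with x)",
)
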