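"""End-to-end body-condition-index verification.

:func:`run_verification` runs the full analysis on a set of morphometric
records: stratify by sex; test for common allometric slopes between
groups; fit the mass and fat allometries; compute the 11 BCIs and the
three true-condition measures; build the accuracy/bias matrices (Kendall
tau and OLS r² of every BCI against percent fat, scaled fat, residual fat
and SVL); the pairwise BCI tau matrix; the regression-assumption battery
for the four residual BCIs; and the Mann-Whitney size-bias test on the
most percent-fat-associated BCI per stratum. The result is a bundle of
tidy tables; :func:`write_report` serialises them to CSV plus a JSON and
plain-text summary.

Everything here is deterministic given the input records and options.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from . import __version__
from .allometry import common_slope_test, fit_line
from .condition import BCI_KEYS, MEASURE_KEYS, ConditionTable, compute_condition
from .data_model import MorphRecord, Stratum, stratify
from .diagnostics import (
    kendall_tau,
    mann_whitney,
    regression_assumptions,
    size_partition,
)

__all__ = ["VerificationOptions", "ValidationReport", "run_verification", "write_report"]


@dataclass(frozen=True)
class VerificationOptions:
    """Knobs for :func:`run_verification`.

    ``size_bias_bcis`` maps a stratum label to the BCI used in the
    size-bias test; by default each stratum uses its best percent-fat
    performer by OLS r². ``x0`` optionally overrides the SMI/scaled-fat
    reference length per stratum (default: stratum mean SVL).
    """

    common_slope: bool = True
    alpha: float = 0.05
    size_bias_window_cm: float = 25.0
    size_bias_bcis: dict[str, str] = field(default_factory=dict)
    x0: dict[str, float] = field(default_factory=dict)


@dataclass
class ValidationReport:
    """All verification outputs as tidy tables.

    ``accuracy_bias`` has one row per (stratum, bci, reference) with the
    Kendall tau, its p-value and the OLS r² of the BCI on the reference;
    references are the three true-condition measures plus SVL.
    ``bci_matrix`` maps stratum label to a symmetric 11x11 tau DataFrame.
    """

    allometry: pd.DataFrame
    common_slope: pd.DataFrame | None
    condition_vs_length: pd.DataFrame
    accuracy_bias: pd.DataFrame
    bci_matrix: dict[str, pd.DataFrame]
    assumptions: pd.DataFrame
    size_bias: pd.DataFrame
    condition_tables: dict[str, ConditionTable]
    provenance: dict


def _allometry_rows(stratum: Stratum, alpha: float) -> list[dict]:
    L = np.asarray(stratum.column("svl"), dtype=float)
    rows = []
    for variable, y in (("mass", "mass"), ("fat", "fat")):
        Y = np.asarray(stratum.column(y), dtype=float)
        f = fit_line(L, Y, "SMA", alpha=alpha, x_transform="log", y_transform="log")
        rows.append(
            {
                "stratum": stratum.label,
                "variable": variable,
                "method": "SMA",
                "slope": f.slope,
                "ci_lo": f.slope_ci[0],
                "ci_hi": f.slope_ci[1],
                "r2": f.r2,
                "n": f.n,
            }
        )
    return rows


def _condition_vs_length_rows(
    stratum: Stratum, table: ConditionTable
) -> list[dict]:
    # OLS of each true-condition measure on ln SVL: an ideal measure has
    # zero slope and zero r2 (no residual association with size).
    ln_l = np.log(np.asarray(stratum.column("svl"), dtype=float))
    rows = []
    for key in MEASURE_KEYS:
        res = _sps.linregress(ln_l, table.values[key].to_numpy())
        rows.append(
            {
                "stratum": stratum.label,
                "measure": key,
                "slope": float(res.slope),
                "p": float(res.pvalue),
                "r2": float(res.rvalue) ** 2,
            }
        )
    return rows


def _accuracy_bias_rows(stratum: Stratum, table: ConditionTable) -> list[dict]:
    svl = np.asarray(stratum.column("svl"), dtype=float)
    refs = {key: table.values[key].to_numpy() for key in MEASURE_KEYS}
    refs["svl"] = svl
    ln_refs = {**{k: v for k, v in refs.items()}, "svl": np.log(svl)}
    rows = []
    for bci in BCI_KEYS:
        v = table.values[bci].to_numpy()
        for ref_name, ref in refs.items():
            cr = kendall_tau(v, ref)
            # r2 from OLS of the BCI on the reference (ln SVL for size)
            lr = _sps.linregress(ln_refs[ref_name], v)
            rows.append(
                {
                    "stratum": stratum.label,
                    "bci": bci,
                    "reference": ref_name,
                    "tau": cr.tau,
                    "tau_p": cr.p,
                    "ols_r2": float(lr.rvalue) ** 2,
                }
            )
    return rows


def _bci_matrix(table: ConditionTable) -> pd.DataFrame:
    cols = {k: table.values[k].to_numpy() for k in BCI_KEYS}
    mat = pd.DataFrame(np.eye(len(BCI_KEYS)), index=list(BCI_KEYS), columns=list(BCI_KEYS))
    for i, a in enumerate(BCI_KEYS):
        for b in BCI_KEYS[i + 1 :]:
            tau = kendall_tau(cols[a], cols[b]).tau
            mat.loc[a, b] = mat.loc[b, a] = tau
    return mat


_REGRESSION_BCIS = (
    ("OLSres", "ols_logM_logL", True),
    ("MAres", "ma_logM_logL", True),
    ("SMAres", "sma_logM_logL", True),
    ("resM_L3", "sma_M_L3", False),
)


def _assumption_rows(stratum: Stratum, table: ConditionTable) -> list[dict]:
    L = np.asarray(stratum.column("svl"), dtype=float)
    M = np.asarray(stratum.column("mass"), dtype=float)
    rows = []
    for bci, fit_key, logscale in _REGRESSION_BCIS:
        x = np.log(L) if logscale else L**3
        y = np.log(M) if logscale else M
        resid = table.values[bci].to_numpy()
        rep = regression_assumptions(x, y, resid=resid, moment_tests="auto")
        row = {
            "stratum": stratum.label,
            "bci": bci,
            "reset_stat": rep.reset.statistic,
            "reset_p": rep.reset.p,
            "breusch_pagan_stat": rep.breusch_pagan.statistic,
            "breusch_pagan_p": rep.breusch_pagan.p,
            "shapiro_stat": rep.shapiro_wilk.statistic,
            "shapiro_p": rep.shapiro_wilk.p,
            "skew": rep.skewness,
            "excess_kurtosis": rep.excess_kurtosis,
            "dagostino_p": rep.dagostino_skew.p if rep.dagostino_skew else np.nan,
            "anscombe_glynn_p": (
                rep.anscombe_glynn_kurtosis.p if rep.anscombe_glynn_kurtosis else np.nan
            ),
        }
        rows.append(row)
    return rows


def _best_percent_fat_bci(accuracy: pd.DataFrame, stratum_label: str) -> str:
    sub = accuracy[
        (accuracy["stratum"] == stratum_label)
        & (accuracy["reference"] == "percent_fat")
    ]
    return str(sub.loc[sub["ols_r2"].idxmax(), "bci"])


def run_verification(
    records: Sequence[MorphRecord],
    options: VerificationOptions | None = None,
) -> ValidationReport:
    """Run the full BCI verification battery on a set of records.

    Raises a ``RuntimeError`` naming the failing stage and stratum if any
    stage fails.
    """
    opts = options or VerificationOptions()
    strata = stratify(records, "sex")

    stage = "common_slope"
    common = None
    try:
        if opts.common_slope and len(strata) >= 2:
            rows = []
            for variable in ("mass", "fat"):
                groups = [
                    (s.column("svl"), s.column(variable)) for s in strata
                ]
                t = common_slope_test(
                    groups, alpha=opts.alpha, x_transform="log", y_transform="log"
                )
                rows.append(
                    {
                        "key": "sex",
                        "variable": variable,
                        "statistic": t.statistic,
                        "df": t.df,
                        "p": t.p,
                        "common_slope": t.common_slope,
                        **{
                            f"slope_{s.label}": b
                            for s, b in zip(strata, t.group_slopes)
                        },
                    }
                )
            handled = [r for r in records if r.handling in ("fresh", "frozen")]
            if len({r.handling for r in handled}) == 2:
                hstrata = stratify(handled, "handling")
                if all(len(s) >= 3 for s in hstrata):
                    groups = [(s.column("svl"), s.column("fat")) for s in hstrata]
                    t = common_slope_test(
                        groups, alpha=opts.alpha, x_transform="log", y_transform="log"
                    )
                    rows.append(
                        {
                            "key": "handling",
                            "variable": "fat",
                            "statistic": t.statistic,
                            "df": t.df,
                            "p": t.p,
                            "common_slope": t.common_slope,
                            **{
                                f"slope_{s.label}": b
                                for s, b in zip(hstrata, t.group_slopes)
                            },
                        }
                    )
            common = pd.DataFrame(rows)

        stage = "allometry"
        allom_rows: list[dict] = []
        for s in strata:
            allom_rows += _allometry_rows(s, opts.alpha)

        stage = "condition"
        tables: dict[str, ConditionTable] = {}
        for s in strata:
            tables[s.label] = compute_condition(s, x0=opts.x0.get(s.label))

        stage = "condition_vs_length"
        cvl_rows: list[dict] = []
        for s in strata:
            cvl_rows += _condition_vs_length_rows(s, tables[s.label])

        stage = "accuracy_bias"
        acc_rows: list[dict] = []
        for s in strata:
            acc_rows += _accuracy_bias_rows(s, tables[s.label])
        accuracy = pd.DataFrame(acc_rows)

        stage = "bci_matrix"
        matrices = {s.label: _bci_matrix(tables[s.label]) for s in strata}

        stage = "assumptions"
        assum_rows: list[dict] = []
        for s in strata:
            assum_rows += _assumption_rows(s, tables[s.label])

        stage = "size_bias"
        sb_rows: list[dict] = []
        for s in strata:
            bci = opts.size_bias_bcis.get(
                s.label, _best_percent_fat_bci(accuracy, s.label)
            )
            low, high = size_partition(
                s, tables[s.label].values[bci].to_numpy(), opts.size_bias_window_cm
            )
            res = mann_whitney(low, high)
            sb_rows.append(
                {
                    "stratum": s.label,
                    "bci": bci,
                    "w": res.w,
                    "p": res.p,
                    "n_low": res.n1,
                    "n_high": res.n2,
                    "method": res.method,
                }
            )
    except Exception as exc:
        raise RuntimeError(f"verification stage {stage!r} failed: {exc}") from exc

    return ValidationReport(
        allometry=pd.DataFrame(allom_rows),
        common_slope=common,
        condition_vs_length=pd.DataFrame(cvl_rows),
        accuracy_bias=accuracy,
        bci_matrix=matrices,
        assumptions=pd.DataFrame(assum_rows),
        size_bias=pd.DataFrame(sb_rows),
        condition_tables=tables,
        provenance={
            "software": f"allobci {__version__}",
            "n_records": len(records),
            "strata": [s.label for s in strata],
            "options": {
                "common_slope": opts.common_slope,
                "alpha": opts.alpha,
                "size_bias_window_cm": opts.size_bias_window_cm,
                "size_bias_bcis": dict(opts.size_bias_bcis),
                "x0": dict(opts.x0),
            },
        },
    )


def _df_payload(df: pd.DataFrame) -> list[dict]:
    return json.loads(df.to_json(orient="records"))


def write_report(
    report: ValidationReport,
    out_dir: str | Path,
    formats: Sequence[str] = ("csv", "json", "txt"),
) -> list[Path]:
    """Serialise a report to ``out_dir``; returns the written paths.

    CSV output: one tidy file per table plus one BCI tau matrix per
    stratum; JSON output: a single machine-readable summary that
    re-parses to the same tables; TXT output: a short human summary. A
    ``manifest.json`` lists every file produced.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    tables: dict[str, pd.DataFrame] = {
        "allometry": report.allometry,
        "condition_vs_length": report.condition_vs_length,
        "accuracy_bias": report.accuracy_bias,
        "assumptions": report.assumptions,
        "size_bias": report.size_bias,
    }
    if report.common_slope is not None and len(report.common_slope):
        tables["common_slope"] = report.common_slope

    if "csv" in formats:
        for name, df in tables.items():
            p = out / f"{name}.csv"
            df.to_csv(p, index=False)
            written.append(p)
        for label, mat in report.bci_matrix.items():
            p = out / f"bci_matrix_{label}.csv"
            mat.to_csv(p)
            written.append(p)

    if "json" in formats:
        payload = {
            "provenance": report.provenance,
            "tables": {name: _df_payload(df) for name, df in tables.items()},
            "bci_matrix": {
                label: {
                    "index": list(mat.index),
                    "values": mat.to_numpy().tolist(),
                }
                for label, mat in report.bci_matrix.items()
            },
        }
        p = out / "summary.json"
        p.write_text(json.dumps(payload, indent=1, sort_keys=True))
        written.append(p)

    if "txt" in formats:
        lines = [f"BCI verification report ({report.provenance['software']})", ""]
        lines.append("Allometric (SMA) slopes:")
        for _, r in report.allometry.iterrows():
            lines.append(
                f"  {r['stratum']:>8} {r['variable']:<5} slope {r['slope']:6.3f} "
                f"[{r['ci_lo']:.3f}, {r['ci_hi']:.3f}]  r2 {r['r2']:.3f}  n {int(r['n'])}"
            )
        if "common_slope" in tables:
            lines.append("")
            lines.append("Common-slope tests:")
            for _, r in tables["common_slope"].iterrows():
                lines.append(
                    f"  {r['key']}/{r['variable']}: LR {r['statistic']:.2f} "
                    f"(df {int(r['df'])}), p = {r['p']:.4f}"
                )
        lines.append("")
        lines.append("Best BCI per stratum by Kendall tau:")
        for label in report.bci_matrix:
            sub = report.accuracy_bias[report.accuracy_bias["stratum"] == label]
            for ref in ("percent_fat", "scaled_fat", "residual_fat"):
                s2 = sub[sub["reference"] == ref]
                best = s2.loc[s2["tau"].idxmax()]
                lines.append(
                    f"  {label:>8} vs {ref:<12}: {best['bci']:<12} tau {best['tau']:.2f}"
                )
        lines.append("")
        lines.append("Size-bias (Mann-Whitney) tests:")
        for _, r in report.size_bias.iterrows():
            lines.append(
                f"  {r['stratum']:>8} {r['bci']:<12} W {r['w']:.1f} p {r['p']:.4f} "
                f"(n {int(r['n_low'])}/{int(r['n_high'])})"
            )
        p = out / "summary.txt"
        p.write_text("\n".join(lines) + "\n")
        written.append(p)

    manifest = out / "manifest.json"
    manifest.write_text(
        json.dumps({"files": [f.name for f in written]}, indent=1)
    )
    written.append(manifest)
    return written
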