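import json

import numpy as np
import pandas as pd
import pytest

from allobci import (
    MorphRecord,
    PopulationConfig,
    VerificationOptions,
    compute_bcis,
    generate_population,
    kendall_tau,
    run_verification,
    stratify,
    write_report,
)
from allobci.condition import BCI_KEYS


@pytest.fixture(scope="module")
def report(default_population):
    return run_verification(default_population)


def test_report_tables_fully_populated(report):
    assert len(report.allometry) == 4  # 2 strata x {mass, fat}
    assert len(report.condition_vs_length) == 6  # 2 strata x 3 measures
    assert len(report.accuracy_bias) == 2 * 11 * 4
    assert set(report.bci_matrix) == {"female", "male"}
    assert len(report.assumptions) == 8  # 2 strata x 4 regression BCIs
    assert len(report.size_bias) == 2
    assert report.accuracy_bias["tau_p"].between(0, 1).all()
    assert report.assumptions["reset_p"].between(0, 1).all()


def test_common_slope_detects_sex_difference(report):
    cs = report.common_slope.set_index("variable")
    assert cs.loc["fat", "p"] <= 0.05  # generating slopes 5.16 vs 4.37


def test_bci_matrix_symmetric_unit_diagonal(report):
    for mat in report.bci_matrix.values():
        assert list(mat.index) == list(BCI_KEYS)
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T)
        assert np.allclose(np.diag(mat.to_numpy()), 1.0)
        assert mat.loc["SMI", "SMAres"] == 1.0


def test_strongly_linked_trio(report):
    """The MA residual, SMA residual and scaled mass indices are
    near-interchangeable: SMI and SMAres are rank-identical, and the MA
    pairs stay very strongly correlated. (At log-log r2 = 0.96 and slope
    ~3.2 the population tau between MA and SMA residuals is ~0.95, so the
    MA pairs cannot reach the SMI/SMAres bound under Gaussian structure.)"""
    for mat in report.bci_matrix.values():
        assert mat.loc["SMI", "SMAres"] == 1.0
        assert mat.loc["MAres", "SMAres"] >= 0.90
        assert mat.loc["MAres", "SMI"] >= 0.90


def test_best_bci_structure_mirrors_allometric_expectations(report):
    """Against scaled fat the winner is a residual-family index; against
    percent fat the winner is a ratio index that tracks length even more
    strongly than it tracks percent fat."""
    acc = report.accuracy_bias
    ratio_indices = {"M/L", "M/L2", "M/L3", "M/prM", "logM/logL", "logM/logprM"}
    for stratum in ("female", "male"):
        sub = acc[acc["stratum"] == stratum]
        best_scaled = sub[sub["reference"] == "scaled_fat"].nlargest(1, "tau")
        assert best_scaled["bci"].item() in {"MAres", "SMAres", "SMI"}
        best_pf = sub[sub["reference"] == "percent_fat"].nlargest(1, "tau")
        bci = best_pf["bci"].item()
        assert bci in ratio_indices
        tau_svl = sub[(sub["bci"] == bci) & (sub["reference"] == "svl")]["tau"].item()
        assert tau_svl > best_pf["tau"].item()


def test_ols_residual_index_unbiased_on_fitting_stratum():
    """tau(OLSres, SVL) averages to ~0 across replicates: residual indices
    are size-independent by construction on the data they were fitted to."""
    taus = []
    for seed in range(200):
        pop = generate_population(
            PopulationConfig(female=None, seed=seed)  # males only, n = 134
        )
        stratum = stratify(pop, "sex")[0]
        v = compute_bcis(stratum).values
        taus.append(kendall_tau(v["OLSres"], stratum.column("svl")).tau)
    assert abs(float(np.mean(taus))) < 0.03


def test_single_stratum_without_common_slope(default_population):
    females = [r for r in default_population if r.sex == "female"]
    rep = run_verification(females, VerificationOptions(common_slope=False))
    assert rep.common_slope is None
    assert set(rep.bci_matrix) == {"female"}
    assert len(rep.size_bias) == 1


def test_verification_is_deterministic(default_population, tmp_path):
    r1 = run_verification(default_population)
    r2 = run_verification(default_population)
    write_report(r1, tmp_path / "a", formats=("json",))
    write_report(r2, tmp_path / "b", formats=("json",))
    assert (tmp_path / "a" / "summary.json").read_bytes() == (
        tmp_path / "b" / "summary.json"
    ).read_bytes()


def test_stage_errors_carry_context():
    # constant SVL: every fit is degenerate
    records = [
        MorphRecord(f"r{i}", "female", 200.0, 5000.0 + i, 300.0 + i) for i in range(5)
    ]
    with pytest.raises(RuntimeError, match="stage"):
        run_verification(records)


def test_written_report_files_and_manifest(report, tmp_path):
    files = write_report(report, tmp_path)
    names = {f.name for f in files}
    for expected in (
        "allometry.csv",
        "condition_vs_length.csv",
        "accuracy_bias.csv",
        "assumptions.csv",
        "size_bias.csv",
        "common_slope.csv",
        "bci_matrix_female.csv",
        "bci_matrix_male.csv",
        "summary.json",
        "summary.txt",
        "manifest.json",
    ):
        assert expected in names
    manifest = json.loads((tmp_path / "manifest.json").read_text())
    assert set(manifest["files"]) == names - {"manifest.json"}


def test_json_summary_round_trips_to_tables(report, tmp_path):
    write_report(report, tmp_path, formats=("json",))
    payload = json.loads((tmp_path / "summary.json").read_text())
    rebuilt = pd.DataFrame(payload["tables"]["accuracy_bias"])
    original = report.accuracy_bias.reset_index(drop=True)
    pd.testing.assert_frame_equal(
        rebuilt[original.columns], original, check_exact=False, rtol=1e-12
    )
    mats = payload["bci_matrix"]["female"]
    assert np.allclose(
        np.asarray(mats["values"]), report.bci_matrix["female"].to_numpy()
    )


def test_formats_subset_omits_files(report, tmp_path):
    files = write_report(report, tmp_path, formats=("txt",))
    names = {f.name for f in files}
    assert names == {"summary.txt", "manifest.json"}
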