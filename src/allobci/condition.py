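"""Body condition indices and fat-based measures of true condition.

Eleven length-mass body condition indices (BCIs) are computed per stratum
(sex), spanning the three families in common use:

* ratio indices — M/L, the Quételet index M/L², Fulton's index M/L³, the
  relative index M/prM, the log ratio index logM/logL and the log relative
  index logM/log(prM);
* regression indices — vertical residuals of log mass on log length under
  OLS, MA and SMA fits, and SMA residuals of raw mass on length cubed;
* the scaled mass index (SMI), which standardises each animal's mass to a
  reference length X₀ through the Thorpe-Lleonart (TL) allometric scaling
  model  Y* = Y · (X₀ / X)^b  with b the SMA slope of log mass on log
  length.

Alongside, three fat-based measures of "true" body condition: percent fat
(fat/mass), scaled fat (TL-scaled fat mass) and residual fat (SMA
residuals of log fat on log length). All fits and the reference length X₀
are stratum-local.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .allometry import AxisFit, fit_line, residuals
from .data_model import Stratum

__all__ = [
    "TLParams",
    "ConditionTable",
    "BCI_KEYS",
    "MEASURE_KEYS",
    "tl_scale",
    "compute_bcis",
    "compute_true_condition",
    "compute_condition",
]

#: Column keys of the 11 body condition indices, in presentation order.
BCI_KEYS = (
    "M/L",
    "M/L2",
    "M/L3",
    "M/prM",
    "logM/logL",
    "logM/logprM",
    "OLSres",
    "MAres",
    "SMAres",
    "resM_L3",
    "SMI",
)

#: Column keys of the three true-condition measures.
MEASURE_KEYS = ("percent_fat", "scaled_fat", "residual_fat")


@dataclass(frozen=True)
class TLParams:
    """Parameters of the TL scaling model ``y* = y * (x0 / x) ** b_sma``.

    ``x0`` is the reference length (cm) — by convention the arithmetic
    mean length of the study population, though the choice is arbitrary;
    ``b_sma`` is the SMA slope of log y on log x. ``source`` records which
    regression the slope came from.
    """

    x0: float
    b_sma: float
    source: str = "mass_on_svl"

    def __post_init__(self) -> None:
        if not self.x0 > 0:
            raise ValueError(f"reference length x0 must be positive, got {self.x0}")
        if not np.isfinite(self.b_sma):
            raise ValueError(f"b_sma must be finite, got {self.b_sma}")


def tl_scale(y, x, params: TLParams):
    """Scale ``y`` to the reference length via ``y * (x0 / x) ** b_sma``.

    Accepts scalars or arrays; both ``y`` and ``x`` must be strictly
    positive.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.any(y <= 0) or np.any(x <= 0):
        raise ValueError("TL scaling requires strictly positive y and x")
    out = y * (params.x0 / x) ** params.b_sma
    return float(out) if out.ndim == 0 else out


@dataclass
class ConditionTable:
    """Per-record index and measure values for one stratum.

    ``values`` has one row per record (indexed by record id, in stratum
    order) and one column per computed key. ``fits`` maps a description to
    the :class:`~allobci.allometry.AxisFit` used; ``tl_params`` maps
    ``"mass_on_svl"``/``"fat_on_svl"`` to the TL parameters used.
    """

    stratum: str
    values: pd.DataFrame
    fits: dict[str, AxisFit] = field(default_factory=dict)
    tl_params: dict[str, TLParams] = field(default_factory=dict)

    def tidy(self) -> pd.DataFrame:
        """Long-form view: one row per (stratum, record, key, value)."""
        long = self.values.reset_index(names="record").melt(
            id_vars="record", var_name="key", value_name="value"
        )
        long.insert(0, "stratum", self.stratum)
        return long

    def merge(self, other: "ConditionTable") -> "ConditionTable":
        """Combine index and measure columns computed for the same stratum."""
        if other.stratum != self.stratum:
            raise ValueError("cannot merge condition tables from different strata")
        return ConditionTable(
            stratum=self.stratum,
            values=pd.concat([self.values, other.values], axis=1),
            fits={**self.fits, **other.fits},
            tl_params={**self.tl_params, **other.tl_params},
        )


def _record_index(stratum: Stratum) -> pd.Index:
    return pd.Index([r.id for r in stratum.records], name="id")


def compute_bcis(stratum: Stratum, x0: float | None = None) -> ConditionTable:
    """Compute the 11 body condition indices for one stratum.

    Parameters
    ----------
    stratum : Stratum
        Records of one sex (or other homogeneous group); all regression
        fits are estimated within the stratum.
    x0 : float, optional
        Reference length for the SMI; defaults to the stratum's arithmetic
        mean SVL.

    Returns
    -------
    ConditionTable
        Index columns in :data:`BCI_KEYS` order.
    """
    L = np.asarray(stratum.column("svl"), dtype=float)
    M = np.asarray(stratum.column("mass"), dtype=float)

    fit_ols = fit_line(L, M, "OLS", x_transform="log", y_transform="log")
    fit_ma = fit_line(L, M, "MA", x_transform="log", y_transform="log")
    fit_sma = fit_line(L, M, "SMA", x_transform="log", y_transform="log")
    fit_cube = fit_line(L**3, M, "SMA")  # raw mass on raw length cubed

    ln_L = np.log(L)
    ln_M = np.log(M)
    prM = np.exp(fit_sma.predict(ln_L))  # no smearing correction; rank-neutral

    x0_val = float(np.mean(L)) if x0 is None else float(x0)
    tl_mass = TLParams(x0=x0_val, b_sma=fit_sma.slope, source="mass_on_svl")

    values = pd.DataFrame(
        {
            "M/L": M / L,
            "M/L2": M / L**2,
            "M/L3": M / L**3,
            "M/prM": M / prM,
            "logM/logL": ln_M / ln_L,
            "logM/logprM": ln_M / np.log(prM),
            "OLSres": residuals(fit_ols, L, M),
            "MAres": residuals(fit_ma, L, M),
            "SMAres": residuals(fit_sma, L, M),
            "resM_L3": residuals(fit_cube, L**3, M),
            "SMI": tl_scale(M, L, tl_mass),
        },
        index=_record_index(stratum),
    )
    return ConditionTable(
        stratum=stratum.label,
        values=values,
        fits={
            "ols_logM_logL": fit_ols,
            "ma_logM_logL": fit_ma,
            "sma_logM_logL": fit_sma,
            "sma_M_L3": fit_cube,
        },
        tl_params={"mass_on_svl": tl_mass},
    )


def compute_true_condition(stratum: Stratum, x0: float | None = None) -> ConditionTable:
    """Compute percent fat, scaled fat and residual fat for one stratum.

    Percent fat is fat mass over total mass; scaled fat applies the TL
    scaling model to fat mass with the SMA slope of log fat on log SVL;
    residual fat is the vertical SMA residual of log fat on log SVL (its
    stratum mean is exactly zero — the fitted line passes through the
    centroid).
    """
    L = np.asarray(stratum.column("svl"), dtype=float)
    M = np.asarray(stratum.column("mass"), dtype=float)
    F = np.asarray(stratum.column("fat"), dtype=float)

    fit_fat = fit_line(L, F, "SMA", x_transform="log", y_transform="log")
    x0_val = float(np.mean(L)) if x0 is None else float(x0)
    tl_fat = TLParams(x0=x0_val, b_sma=fit_fat.slope, source="fat_on_svl")

    values = pd.DataFrame(
        {
            "percent_fat": F / M,
            "scaled_fat": tl_scale(F, L, tl_fat),
            "residual_fat": residuals(fit_fat, L, F),
        },
        index=_record_index(stratum),
    )
    return ConditionTable(
        stratum=stratum.label,
        values=values,
        fits={"sma_logF_logL": fit_fat},
        tl_params={"fat_on_svl": tl_fat},
    )


def compute_condition(stratum: Stratum, x0: float | None = None) -> ConditionTable:
    """All 11 BCIs plus the three true-condition measures in one table."""
    return compute_bcis(stratum, x0).merge(compute_true_condition(stratum, x0))
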