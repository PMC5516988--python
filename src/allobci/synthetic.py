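"""Synthetic morphometric populations with controlled allometric structure.

Emulates a cross-sectional sample of a large snake whose mass and fat
scale as power laws of length with sex-specific exponents — the regime
where body-condition-index behaviour is hardest to get right. Defaults
reproduce the study conditions for invasive Burmese pythons: 114 females
and 134 males; SMA slopes of log mass on log SVL of 3.21 (F) and 3.04 (M)
at r² = 0.96; SMA slopes of log fat on log SVL of 5.16 (F) and 4.37 (M)
at r² = 0.85 (F) / 0.81 (M); mean SVL 235 cm (F) / 214 cm (M) with ranges
contained in 70-482 cm (F) / 76-347 cm (M).

The construction is parameterised *directly* by the SMA slope ``b`` and
correlation ``rho``: with ``ln L ~ Normal(mu, s²)`` and

    ln Y = alpha + rho * b * (ln L - mu) + eps,   sd(eps) = b * s * sqrt(1 - rho²),

the ratio sd(ln Y)/sd(ln L) — i.e. the population SMA slope — is exactly
``b`` and corr(ln Y, ln L) is exactly ``rho``. Residuals are Gaussian by
default; an optional skew-normal shape parameter mimics the left-skewed
fat residuals real pythons show.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .data_model import MorphRecord

__all__ = [
    "SexConfig",
    "PopulationConfig",
    "FEMALE_DEFAULTS",
    "MALE_DEFAULTS",
    "generate_population",
    "generate_fixture",
    "FIXTURE_NAMES",
]


@dataclass(frozen=True)
class SexConfig:
    """Generating parameters for one sex.

    ``mass_slope``/``fat_slope`` are the target SMA slopes of log mass /
    log fat on log SVL; ``mass_corr``/``fat_corr`` the target log-log
    Pearson correlations (so the achieved r² is the square). Intercepts
    ``alpha`` are the mean of ln mass / ln fat at the mean log-SVL.
    ``resid_skew`` is a skew-normal shape parameter for the residuals
    (0 = Gaussian; negative = left skew).
    """

    n: int
    log_svl_mean: float
    log_svl_sd: float
    mass_slope: float
    mass_corr: float
    mass_alpha: float
    fat_slope: float
    fat_corr: float
    fat_alpha: float
    resid_skew: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("need n >= 3 per sex")
        if not (self.mass_slope > 0 and self.fat_slope > 0):
            raise ValueError("slopes must be positive")
        for name in ("mass_corr", "fat_corr"):
            rho = getattr(self, name)
            if not (0 < rho <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {rho}")
        if not self.log_svl_sd > 0:
            raise ValueError("log_svl_sd must be positive")


def _alpha_for_mean(target_mean: float, slope: float, log_svl_sd: float) -> float:
    # lognormal mean correction: E[Y] = exp(alpha + sd(lnY)^2 / 2)
    return math.log(target_mean) - (slope * log_svl_sd) ** 2 / 2


_F_S = 0.33  # log-SVL sd, females: ln(482/70) ~ 6 sd
_M_S = 0.25  # log-SVL sd, males:   ln(347/76) ~ 6 sd

FEMALE_DEFAULTS = SexConfig(
    n=114,
    log_svl_mean=math.log(235) - _F_S**2 / 2,
    log_svl_sd=_F_S,
    mass_slope=3.21,
    mass_corr=math.sqrt(0.96),
    mass_alpha=_alpha_for_mean(11_852, 3.21, _F_S),
    fat_slope=5.16,
    fat_corr=math.sqrt(0.85),
    fat_alpha=_alpha_for_mean(1_226, 5.16, _F_S),
)

MALE_DEFAULTS = SexConfig(
    n=134,
    log_svl_mean=math.log(214) - _M_S**2 / 2,
    log_svl_sd=_M_S,
    mass_slope=3.04,
    mass_corr=math.sqrt(0.96),
    mass_alpha=_alpha_for_mean(7_683, 3.04, _M_S),
    fat_slope=4.37,
    fat_corr=math.sqrt(0.81),
    fat_alpha=_alpha_for_mean(571, 4.37, _M_S),
)


@dataclass(frozen=True)
class PopulationConfig:
    """A two-sex population; either sex block may be ``None`` to skip it.

    ``resid_cross_corr`` correlates the mass and fat log-residuals given
    length. Fat bodies are part of total mass, so an unusually fat animal
    is also unusually heavy for its length; a cross-correlation of 0.75
    (via the Gaussian rank-correlation relation rho = sin(pi*tau/2))
    reproduces the tau of ~0.55 observed between residual-family
    condition indices and residual fat in real pythons. Set 0 for
    conditionally independent mass and fat residuals.
    """

    female: SexConfig | None = FEMALE_DEFAULTS
    male: SexConfig | None = MALE_DEFAULTS
    resid_cross_corr: float = 0.75
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.female is None and self.male is None:
            raise ValueError("at least one sex block is required")
        if not (-1 <= self.resid_cross_corr <= 1):
            raise ValueError("resid_cross_corr must lie in [-1, 1]")


def _standard_residual(rng: np.random.Generator, n: int, skew: float) -> np.ndarray:
    """Zero-mean unit-sd residual draws, optionally skew-normal."""
    if skew == 0.0:
        return rng.standard_normal(n)
    z = stats.skewnorm.rvs(skew, size=n, random_state=rng)
    delta = skew / math.sqrt(1 + skew * skew)
    mu = delta * math.sqrt(2 / math.pi)
    sd = math.sqrt(1 - mu * mu)
    return (z - mu) / sd


_MAX_ROUNDS = 1000


def _generate_sex(
    rng: np.random.Generator, sex: str, cfg: SexConfig, rho_mf: float
) -> list[MorphRecord]:
    sd_em = cfg.mass_slope * cfg.log_svl_sd * math.sqrt(1 - cfg.mass_corr**2)
    sd_ef = cfg.fat_slope * cfg.log_svl_sd * math.sqrt(1 - cfg.fat_corr**2)

    def draw(m: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        ln_l = cfg.log_svl_mean + cfg.log_svl_sd * rng.standard_normal(m)
        e1 = _standard_residual(rng, m, cfg.resid_skew)
        e2 = _standard_residual(rng, m, cfg.resid_skew)
        e_m = sd_em * e1
        e_f = sd_ef * (rho_mf * e1 + math.sqrt(1 - rho_mf**2) * e2)
        ln_m = cfg.mass_alpha + cfg.mass_corr * cfg.mass_slope * (ln_l - cfg.log_svl_mean) + e_m
        ln_f = cfg.fat_alpha + cfg.fat_corr * cfg.fat_slope * (ln_l - cfg.log_svl_mean) + e_f
        return np.exp(ln_l), np.exp(ln_m), np.exp(ln_f)

    svl, mass, fat = draw(cfg.n)
    drawn, kept = cfg.n, int(np.sum(fat < mass))
    rounds = 0
    # resample rows violating fat < mass so the marginal structure stays intact
    while True:
        bad = ~(fat < mass)
        if not bad.any():
            break
        rounds += 1
        if rounds > _MAX_ROUNDS or (drawn > 100 * cfg.n and kept < drawn / 100):
            raise RuntimeError(
                f"infeasible config for {sex}: fat < mass rejection rate "
                f"{1 - kept / drawn:.3f} after {drawn} draws"
            )
        m = int(bad.sum())
        s2, m2, f2 = draw(m)
        svl[bad], mass[bad], fat[bad] = s2, m2, f2
        drawn += m
        kept = cfg.n - int(np.sum(~(fat < mass)))

    prefix = sex[0].upper()
    return [
        MorphRecord(
            id=f"{prefix}{i + 1:03d}",
            sex=sex,
            svl=float(svl[i]),
            mass=float(mass[i]),
            fat=float(fat[i]),
        )
        for i in range(cfg.n)
    ]


def generate_population(
    config: PopulationConfig | None = None, seed: int | None = None
) -> list[MorphRecord]:
    """Draw one synthetic population; deterministic under a fixed seed.

    ``seed`` overrides ``config.seed`` when given. Records come out
    females first, then males, each in draw order.
    """
    cfg = config or PopulationConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    records: list[MorphRecord] = []
    if cfg.female is not None:
        records += _generate_sex(rng, "female", cfg.female, cfg.resid_cross_corr)
    if cfg.male is not None:
        records += _generate_sex(rng, "male", cfg.male, cfg.resid_cross_corr)
    return records


FIXTURE_NAMES = ("perfect-power-law", "tiny-mixed-sex", "tie-heavy")


def generate_fixture(name: str) -> list[MorphRecord]:
    """Small deterministic datasets for tests and examples.

    * ``perfect-power-law`` — 10 females on exact power laws
      mass = 9e-4 * L**3, fat = 1.7e-9 * L**5 (log-log r² = 1).
    * ``tiny-mixed-sex`` — 4 females + 4 males with plausible values.
    * ``tie-heavy`` — 10 females with duplicated masses and lengths,
      exercising tie handling in rank statistics.
    """
    if name == "perfect-power-law":
        svls = np.geomspace(80.0, 300.0, 10)
        return [
            MorphRecord(
                id=f"P{i + 1:02d}",
                sex="female",
                svl=float(L),
                mass=float(9e-4 * L**3),
                fat=float(1.7e-9 * L**5),
            )
            for i, L in enumerate(svls)
        ]
    if name == "tiny-mixed-sex":
        rows = [
            ("F01", "female", 120.0, 1500.0, 90.0),
            ("F02", "female", 180.0, 5200.0, 420.0),
            ("F03", "female", 240.0, 13500.0, 1300.0),
            ("F04", "female", 300.0, 27000.0, 3100.0),
            ("M01", "male", 110.0, 1200.0, 70.0),
            ("M02", "male", 160.0, 3600.0, 230.0),
            ("M03", "male", 210.0, 7800.0, 560.0),
            ("M04", "male", 260.0, 14500.0, 1100.0),
        ]
        return [MorphRecord(i, s, l, m, f) for i, s, l, m, f in rows]
    if name == "tie-heavy":
        rows = [
            ("T01", 100.0, 1000.0, 60.0),
            ("T02", 100.0, 1000.0, 80.0),
            ("T03", 120.0, 1000.0, 95.0),
            ("T04", 120.0, 1800.0, 95.0),
            ("T05", 140.0, 2600.0, 150.0),
            ("T06", 140.0, 2600.0, 150.0),
            ("T07", 160.0, 4100.0, 260.0),
            ("T08", 160.0, 3900.0, 260.0),
            ("T09", 180.0, 5900.0, 410.0),
            ("T10", 180.0, 5900.0, 330.0),
        ]
        return [MorphRecord(i, "female", l, m, f) for i, l, m, f in rows]
    raise ValueError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
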