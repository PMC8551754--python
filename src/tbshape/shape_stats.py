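"""Distribution-shape descriptors for a set of temperature readings.

For any reading set the pipeline reports the KDE modal temperature, the
10th/90th empirical quantiles, skewness with a bootstrap left/right
classification, and Hartigan's dip statistic with a Monte-Carlo p-value
for bimodality. All statistics are order-invariant (set semantics).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats as sps

from tbshape._dip import dip_sorted
from tbshape.errors import InsufficientDataError, ValidationError

LEFT = "left"
RIGHT = "right"
SYMMETRIC = "symmetric"

#: Below this many readings only mode/quantiles/skew are reported;
#: dip test and skew classification are flagged missing.
MIN_FULL_REPORT_N = 30

BIMODAL_ALPHA = 0.05


@dataclass(frozen=True)
class StatsConfig:
    """Settings shared by all shape reports of one run."""

    n_mc: int = 999
    n_boot: int = 1000
    seed: int = 0
    skew_method: str = "moment"
    grid_step_c: float = 0.01
    bandwidth_rule: str = "silverman"
    # report quantile levels; fields keep their q10/q90 names regardless
    q_low: float = 0.10
    q_high: float = 0.90

    def __post_init__(self) -> None:
        if self.n_mc < 100:
            raise ValidationError("n_mc must be >= 100")
        if self.n_boot < 100:
            raise ValidationError("n_boot must be >= 100")
        if self.skew_method not in ("moment", "quantile"):
            raise ValidationError("skew_method must be 'moment' or 'quantile'")
        if self.grid_step_c <= 0:
            raise ValidationError("grid_step_c must be > 0")
        if not 0.0 < self.q_low < self.q_high < 1.0:
            raise ValidationError("need 0 < q_low < q_high < 1")


@dataclass(frozen=True)
class ShapeStats:
    """Shape descriptors of one reading set; None marks a field that the
    reading count was too small to support."""

    n: int
    mode_c: float
    q10_c: float
    q90_c: float
    skew: float | None
    skew_class: str | None
    dip_stat: float | None
    dip_p: float | None
    bimodal: bool | None

    def to_dict(self) -> dict:
        return asdict(self)


def _as_values(values) -> np.ndarray:
    # sorted canonical form: all shape statistics have set semantics, and
    # sorting makes order-invariance exact (incl. seeded resampling)
    v = np.sort(np.asarray(values, dtype=float).ravel())
    if v.size == 0:
        raise ValidationError("empty reading set")
    if not np.all(np.isfinite(v)):
        raise ValidationError("non-finite values in reading set")
    return v


def kde_mode(
    values,
    bandwidth_rule: str = "silverman",
    grid_step_c: float = 0.01,
) -> float:
    """Modal temperature: argmax of a Gaussian KDE on a regular grid.

    The grid spans min−1 to max+1 °C at ``grid_step_c`` resolution; ties
    break toward the lowest temperature. A single reading (or an
    all-equal set) is its own mode.
    """
    v = _as_values(values)
    vmin, vmax = float(v.min()), float(v.max())
    if v.size == 1 or vmin == vmax:
        return vmin
    kde = sps.gaussian_kde(v, bw_method=bandwidth_rule)
    grid = np.arange(vmin - 1.0, vmax + 1.0 + grid_step_c / 2, grid_step_c)
    dens = kde(grid)
    return float(grid[int(np.argmax(dens))])  # argmax: first max = lowest temp


def empirical_quantile(values, p: float) -> float:
    """Sample quantile with linear interpolation between order statistics."""
    if not 0.0 < p < 1.0:
        raise ValidationError(f"quantile level must be in (0, 1), got {p}")
    v = _as_values(values)
    return float(np.quantile(v, p, method="linear"))


def skewness(values, method: str = "moment") -> float:
    """Dimensionless skewness of a reading set.

    ``moment``: adjusted Fisher–Pearson standardized third moment.
    ``quantile``: Bowley-type (q90 + q10 − 2·median) / (q90 − q10).
    """
    v = _as_values(values)
    if v.size < 3:
        raise InsufficientDataError(f"skewness needs >= 3 readings, got {v.size}")
    if np.std(v) == 0:
        raise ValidationError("skewness undefined for zero-variance readings")
    if method == "moment":
        return float(sps.skew(v, bias=False))
    if method == "quantile":
        q10, q50, q90 = np.quantile(v, [0.10, 0.50, 0.90], method="linear")
        if q90 == q10:
            raise ValidationError("quantile skewness undefined: q10 == q90")
        return float((q90 + q10 - 2.0 * q50) / (q90 - q10))
    raise ValidationError(f"unknown skewness method {method!r}")


def classify_skew(values, n_boot: int = 1000, seed: int = 0) -> str:
    """Classify a distribution as left / right / symmetric.

    Uses the bootstrap 95 % percentile interval of the moment skewness:
    right (left) if the whole interval lies above (below) zero,
    symmetric otherwise. Deterministic given ``seed``.
    """
    v = _as_values(values)
    n = v.size
    if n < 30:
        raise InsufficientDataError(
            f"skew classification needs >= 30 readings, got {n}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boots = sps.skew(v[idx], axis=1, bias=False)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    if lo > 0:
        return RIGHT
    if hi < 0:
        return LEFT
    return SYMMETRIC


def dip_statistic(values) -> float:
    """Hartigan's dip: max distance between the ECDF and the nearest
    unimodal CDF. Affine-invariant; always in [1/(2n), 0.25]."""
    v = _as_values(values)
    if v.size < 4:
        raise InsufficientDataError(f"dip needs >= 4 readings, got {v.size}")
    return dip_sorted(np.sort(v))


def dip_test(values, n_mc: int = 999, seed: int = 0) -> tuple[float, float]:
    """Dip statistic plus Monte-Carlo p-value against the uniform null.

    p = (1 + #{null dips >= observed}) / (n_mc + 1), so p is never zero.
    The uniform(0, 1) null is the calibration distribution of the
    published test.
    """
    v = _as_values(values)
    if v.size < 4:
        raise InsufficientDataError(f"dip test needs >= 4 readings, got {v.size}")
    if n_mc < 100:
        raise ValidationError("n_mc must be >= 100")
    obs = dip_sorted(np.sort(v))
    rng = np.random.default_rng(seed)
    n = v.size
    count = 0
    for _ in range(n_mc):
        null = np.sort(rng.random(n))
        if dip_sorted(null) >= obs:
            count += 1
    p = (1.0 + count) / (n_mc + 1.0)
    return obs, p


def shape_report(values, config: StatsConfig | None = None) -> ShapeStats:
    """Assemble all shape descriptors for one reading set.

    Sets with fewer than 30 readings get a partial report: mode and
    quantiles (and skewness when defined) are present, dip test and skew
    classification are None.
    """
    cfg = config or StatsConfig()
    v = _as_values(values)
    n = int(v.size)
    mode = kde_mode(v, bandwidth_rule=cfg.bandwidth_rule, grid_step_c=cfg.grid_step_c)
    q10 = empirical_quantile(v, cfg.q_low)
    q90 = empirical_quantile(v, cfg.q_high)
    skew = skew_class = dip_stat = dip_p = bimodal = None
    if n >= 3 and np.std(v) > 0:
        skew = skewness(v, method=cfg.skew_method)
    if n >= MIN_FULL_REPORT_N:
        seeds = np.random.SeedSequence(cfg.seed).generate_state(2)
        if np.std(v) > 0:
            skew_class = classify_skew(v, n_boot=cfg.n_boot, seed=int(seeds[0]))
        dip_stat, dip_p = dip_test(v, n_mc=cfg.n_mc, seed=int(seeds[1]))
        bimodal = bool(dip_p < BIMODAL_ALPHA)
    return ShapeStats(
        n=n, mode_c=mode, q10_c=q10, q90_c=q90, skew=skew,
        skew_class=skew_class, dip_stat=dip_stat, dip_p=dip_p, bimodal=bimodal,
    )
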