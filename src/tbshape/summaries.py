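"""Per-individual and cross-individual (panel) summaries.

An individual summary holds the shape statistics of the active, resting
and overall distributions plus the daily amplitude (active mode minus
resting mode). The panel summary aggregates per-individual modes and
amplitudes — KDE mode, mean, sample sd, min–max range — and tallies
shape-class counts, mirroring a cross-species comparison table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from tbshape.errors import ValidationError
from tbshape.phase_partition import PhasePartition, phase_subsets
from tbshape.shape_stats import (
    LEFT,
    RIGHT,
    ShapeStats,
    StatsConfig,
    kde_mode,
    shape_report,
)
from tbshape.trace_io import TbTrace

_STAT_FIELDS = (
    "n", "mode_c", "q10_c", "q90_c", "skew", "skew_class",
    "dip_stat", "dip_p", "bimodal",
)


@dataclass(frozen=True)
class IndividualSummary:
    """Shape statistics for one individual's trace."""

    species: str
    individual_id: str
    active: ShapeStats
    rest: ShapeStats
    overall: ShapeStats
    amplitude_c: float  # active.mode_c - rest.mode_c

    def to_flat_dict(self) -> dict:
        row: dict = {"species": self.species, "individual_id": self.individual_id}
        for phase in ("active", "rest", "overall"):
            stats: ShapeStats = getattr(self, phase)
            for f in _STAT_FIELDS:
                row[f"{phase}_{f}"] = getattr(stats, f)
        row["amplitude_c"] = self.amplitude_c
        return row

    @classmethod
    def from_flat_dict(cls, row: dict) -> "IndividualSummary":
        def _clean(v, kind):
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return None
            if kind == "int":
                return int(v)
            if kind == "float":
                return float(v)
            if kind == "bool":
                return bool(v) if not isinstance(v, str) else v == "True"
            return str(v)

        kinds = {
            "n": "int", "mode_c": "float", "q10_c": "float", "q90_c": "float",
            "skew": "float", "skew_class": "str", "dip_stat": "float",
            "dip_p": "float", "bimodal": "bool",
        }
        parts = {}
        for phase in ("active", "rest", "overall"):
            kw = {f: _clean(row[f"{phase}_{f}"], kinds[f]) for f in _STAT_FIELDS}
            parts[phase] = ShapeStats(**kw)
        return cls(
            species=str(row["species"]),
            individual_id=str(row["individual_id"]),
            active=parts["active"],
            rest=parts["rest"],
            overall=parts["overall"],
            amplitude_c=float(row["amplitude_c"]),
        )


@dataclass(frozen=True)
class MetricSummary:
    """Cross-individual summary of one scalar metric."""

    mode_c: float
    mean_c: float
    sd_c: float
    range_c: tuple[float, float]


@dataclass(frozen=True)
class PanelSummary:
    """Cross-individual statistics over a panel of individual summaries."""

    n_individuals: int
    active_mode: MetricSummary
    rest_mode: MetricSummary
    amplitude: MetricSummary
    n_right_skewed_overall: int
    n_left_skewed_overall: int
    n_bimodal_overall: int
    n_right_skewed_active: int

    def to_dict(self) -> dict:
        def _metric(m: MetricSummary) -> dict:
            return {
                "mode_c": m.mode_c,
                "mean_c": m.mean_c,
                "sd_c": m.sd_c,
                "range_c": list(m.range_c),
            }

        return {
            "n_individuals": self.n_individuals,
            "active_mode": _metric(self.active_mode),
            "rest_mode": _metric(self.rest_mode),
            "amplitude": _metric(self.amplitude),
            "n_right_skewed_overall": self.n_right_skewed_overall,
            "n_left_skewed_overall": self.n_left_skewed_overall,
            "n_bimodal_overall": self.n_bimodal_overall,
            "n_right_skewed_active": self.n_right_skewed_active,
        }


def summarize_individual(
    trace: TbTrace,
    partition: PhasePartition,
    stats_config: StatsConfig | None = None,
) -> IndividualSummary:
    """Shape stats for the active, rest and overall reading sets.

    The overall set keeps transitional readings — they belong to the
    marginal distribution even though neither phase claims them.
    Undersized subsets yield partial ShapeStats rather than an error.
    """
    active_v, rest_v, overall_v = phase_subsets(trace, partition)
    cfg = stats_config or StatsConfig()
    reports = {}
    for name, vals in (("active", active_v), ("rest", rest_v), ("overall", overall_v)):
        if vals.size == 0:
            reports[name] = ShapeStats(
                n=0, mode_c=float("nan"), q10_c=float("nan"), q90_c=float("nan"),
                skew=None, skew_class=None, dip_stat=None, dip_p=None, bimodal=None,
            )
        else:
            reports[name] = shape_report(vals, cfg)
    amplitude = reports["active"].mode_c - reports["rest"].mode_c
    return IndividualSummary(
        species=trace.species,
        individual_id=trace.individual_id,
        active=reports["active"],
        rest=reports["rest"],
        overall=reports["overall"],
        amplitude_c=float(amplitude),
    )


def _metric_summary(values: np.ndarray, grid_step_c: float) -> MetricSummary:
    return MetricSummary(
        mode_c=kde_mode(values, grid_step_c=grid_step_c),
        mean_c=float(np.mean(values)),
        sd_c=float(np.std(values, ddof=1)),
        range_c=(float(np.min(values)), float(np.max(values))),
    )


def summarize_panel(
    summaries: list[IndividualSummary],
    stats_config: StatsConfig | None = None,
    average_within_species: bool = False,
) -> PanelSummary:
    """Aggregate individual summaries into panel statistics.

    The cross-individual "mode" uses the same KDE mode estimator as
    within-trace modes. ``average_within_species`` collapses multiple
    individuals of one species to their per-species mean metric values
    before aggregating (shape-class counts are still tallied per
    individual's overall/active flags of the collapsed representative —
    the first individual of each species).
    """
    cfg = stats_config or StatsConfig()
    usable = [
        s for s in summaries
        if np.isfinite(s.active.mode_c) and np.isfinite(s.rest.mode_c)
    ]
    if len(usable) < 2:
        raise ValidationError(
            f"panel summary needs >= 2 summaries with complete modes, "
            f"got {len(usable)}"
        )
    if average_within_species:
        by_species: dict[str, list[IndividualSummary]] = {}
        for s in usable:
            by_species.setdefault(s.species, []).append(s)
        active_modes = np.array(
            [np.mean([s.active.mode_c for s in grp]) for grp in by_species.values()]
        )
        rest_modes = np.array(
            [np.mean([s.rest.mode_c for s in grp]) for grp in by_species.values()]
        )
        amplitudes = np.array(
            [np.mean([s.amplitude_c for s in grp]) for grp in by_species.values()]
        )
        flag_carriers = [grp[0] for grp in by_species.values()]
    else:
        active_modes = np.array([s.active.mode_c for s in usable])
        rest_modes = np.array([s.rest.mode_c for s in usable])
        amplitudes = np.array([s.amplitude_c for s in usable])
        flag_carriers = usable

    return PanelSummary(
        n_individuals=len(flag_carriers),
        active_mode=_metric_summary(active_modes, cfg.grid_step_c),
        rest_mode=_metric_summary(rest_modes, cfg.grid_step_c),
        amplitude=_metric_summary(amplitudes, cfg.grid_step_c),
        n_right_skewed_overall=sum(
            1 for s in flag_carriers if s.overall.skew_class == RIGHT
        ),
        n_left_skewed_overall=sum(
            1 for s in flag_carriers if s.overall.skew_class == LEFT
        ),
        n_bimodal_overall=sum(
            1 for s in flag_carriers if s.overall.bimodal is True
        ),
        n_right_skewed_active=sum(
            1 for s in flag_carriers if s.active.skew_class == RIGHT
        ),
    )
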