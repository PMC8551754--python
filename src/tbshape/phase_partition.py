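"""Classify readings as ACTIVE / REST / TRANSITIONAL against quantile curves.

A reading strictly above the upper (55th by default) quantile curve at
its own timestamp is active; strictly below the lower (45th) curve is
resting; everything in between — including exact ties with either curve
— is transitional. The rule compares each reading to the curve value at
that reading's time, so it is level- and time-shift equivariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from tbshape.errors import ValidationError
from tbshape.trace_io import TbTrace

ACTIVE = "ACTIVE"
REST = "REST"
TRANSITIONAL = "TRANSITIONAL"

PHASES = (ACTIVE, REST, TRANSITIONAL)


@dataclass(frozen=True)
class PhasePartition:
    """Per-reading phase labels plus counts. Counts always sum to len(labels)."""

    labels: np.ndarray  # dtype str, values in PHASES
    n_active: int
    n_rest: int
    n_transitional: int

    def __post_init__(self) -> None:
        n = self.n_active + self.n_rest + self.n_transitional
        if n != self.labels.size:
            raise ValidationError("phase counts do not sum to number of labels")

    def __len__(self) -> int:
        return int(self.labels.size)


def classify_phases(trace: TbTrace, q45: np.ndarray, q55: np.ndarray) -> PhasePartition:
    """Label each reading relative to evaluated lower/upper quantile curves.

    Parameters
    ----------
    trace
        The readings to classify.
    q45, q55
        Lower and upper quantile-curve values evaluated at
        ``trace.time_h`` (rearranged so q45 <= q55 everywhere).
    """
    q45 = np.asarray(q45, dtype=float)
    q55 = np.asarray(q55, dtype=float)
    n = len(trace)
    if q45.shape != (n,) or q55.shape != (n,):
        raise ValidationError(
            f"curve series ({q45.size}, {q55.size}) not aligned to trace of length {n}"
        )
    if np.any(q45 > q55):
        i = int(np.argmax(q45 > q55))
        raise ValidationError(
            f"lower curve exceeds upper curve at index {i} "
            f"({q45[i]:g} > {q55[i]:g}); rearrange the curves first"
        )
    labels = np.full(n, TRANSITIONAL, dtype="U12")
    active = trace.tb_c > q55
    rest = trace.tb_c < q45
    labels[active] = ACTIVE
    labels[rest] = REST
    return PhasePartition(
        labels=labels,
        n_active=int(active.sum()),
        n_rest=int(rest.sum()),
        n_transitional=int(n - active.sum() - rest.sum()),
    )


def phase_subsets(
    trace: TbTrace, partition: PhasePartition
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (active, rest, overall) temperature reading sets.

    Active and rest exclude transitional readings; the overall set is the
    full marginal distribution including them.
    """
    if len(partition) != len(trace):
        raise ValidationError("partition not aligned to trace")
    active = trace.tb_c[partition.labels == ACTIVE]
    rest = trace.tb_c[partition.labels == REST]
    return active, rest, trace.tb_c.copy()
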