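"""Enrichment thresholds and detection limits from an unlabeled control population.

A cell counts as isotopically enriched — anabolically active — when its
atom percent exceeds the control mean by more than three control standard
deviations. Combining that threshold with the labeled substrate pool gives
the net-assimilation detection limit: the smallest X_net% a cell could have
and still be called active.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .errors import ConfigurationError, InsufficientControlError, InputDomainError
from .isotope import IsotopeMeasurement, SubstratePool, net_assimilation

__all__ = ["ControlStats", "fit_control_stats", "detection_limit", "is_enriched"]

_ATPCT_ATTR = {"C": "c13_atpct", "N": "n15_atpct"}


@dataclass
class ControlStats:
    """Unlabeled-population statistics for one element at one site.

    ``mean_atpct`` is the a_init of the mixing model. ``threshold_atpct`` is
    always mean + 3·SD. ``detection_limit_net_pct`` is filled in once a
    substrate pool is known (see :func:`detection_limit`).
    """

    element: str
    mean_atpct: float
    sd_atpct: float
    n_cells: int
    detection_limit_net_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if self.element not in ("C", "N"):
            raise InputDomainError(f"element must be 'C' or 'N', got {self.element!r}")
        if self.sd_atpct < 0:
            raise InputDomainError("control SD must be >= 0")
        if self.n_cells < 2:
            raise InsufficientControlError(
                f"need >= 2 control cells to estimate a spread, got {self.n_cells}"
            )

    @property
    def threshold_atpct(self) -> float:
        """Enrichment threshold: control mean + 3 standard deviations."""
        return self.mean_atpct + 3.0 * self.sd_atpct

    def to_dict(self) -> dict:
        return {
            "element": self.element,
            "mean_atpct": self.mean_atpct,
            "sd_atpct": self.sd_atpct,
            "n_cells": self.n_cells,
            "threshold_atpct": self.threshold_atpct,
            "detection_limit_net_pct": self.detection_limit_net_pct,
        }


def _extract_atpct(
    control_cells: Union[Iterable[IsotopeMeasurement], Sequence[float], np.ndarray],
    element: str,
) -> np.ndarray:
    attr = _ATPCT_ATTR.get(element)
    if attr is None:
        raise InputDomainError(f"element must be 'C' or 'N', got {element!r}")
    cells = list(control_cells)
    if cells and isinstance(cells[0], IsotopeMeasurement):
        values = np.array([getattr(c, attr) for c in cells], dtype=float)
    else:
        values = np.asarray(cells, dtype=float)
    return values[np.isfinite(values)]


def fit_control_stats(control_cells, element: str) -> ControlStats:
    """Mean, sample SD (n−1) and 3σ threshold of the unlabeled population.

    ``control_cells`` is a collection of :class:`IsotopeMeasurement` or a
    plain sequence of atom-percent values. Non-finite values are excluded.
    """
    values = _extract_atpct(control_cells, element)
    if values.size < 2:
        raise InsufficientControlError(
            f"need >= 2 finite control at.% values for {element}, got {values.size}"
        )
    return ControlStats(
        element=element,
        mean_atpct=float(np.mean(values)),
        sd_atpct=float(np.std(values, ddof=1)),
        n_cells=int(values.size),
    )


def detection_limit(stats: ControlStats, pool: SubstratePool) -> float:
    """Net-assimilation detection limit (X_net%) for a control + pool pairing.

    Evaluates the mixing model at the enrichment threshold: the minimum
    fraction of newly synthesized biomass that lifts a cell's at.% above
    mean + 3σ. Closed form: 100 · 3σ / (a_sub − a_init).
    """
    if pool.element != stats.element:
        raise ConfigurationError(
            f"pool element {pool.element!r} does not match control element {stats.element!r}"
        )
    if pool.tracer_atpct <= stats.mean_atpct:
        raise ConfigurationError(
            f"pool at {pool.tracer_atpct} at.% is not enriched above the "
            f"control mean {stats.mean_atpct} at.%"
        )
    return net_assimilation(
        min(stats.threshold_atpct, 100.0), stats.mean_atpct, pool.tracer_atpct
    ).x_net_pct


def is_enriched(measurement: IsotopeMeasurement, stats: ControlStats, element: str) -> bool:
    """True iff the cell's at.% strictly exceeds the 3σ enrichment threshold.

    A value exactly at the threshold is not enrichment (strict, one-sided
    upper test). A missing (NaN) at.% returns False; such cells are excluded
    from denominators upstream.
    """
    attr = _ATPCT_ATTR.get(element)
    if attr is None:
        raise InputDomainError(f"element must be 'C' or 'N', got {element!r}")
    if stats.element != element:
        raise ConfigurationError(
            f"control stats are for {stats.element!r}, asked about {element!r}"
        )
    value = getattr(measurement, attr)
    if not math.isfinite(value):
        return False
    return value > stats.threshold_atpct
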