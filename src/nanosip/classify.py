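"""Metabolic classification of single cells and community-level summaries.

After incubation with ¹³C-bicarbonate (autotrophy tracer) and ¹⁵N-amino
acids (general activity tracer), each cell's net carbon and nitrogen
assimilation (C_net%, N_net%) place it in one of five states: inactive, or
one of four active zones defined by the detection limits and the 1:1 and
2:1 N:C guide lines. Chemoautotrophs are zones II + IV (most or all new
carbon from bicarbonate); heterotrophs are zones I + III.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import InputDomainError, UndefinedResultError

__all__ = [
    "Category",
    "CellClassification",
    "CommunitySummary",
    "classify_cell",
    "classify_cells",
    "summarize_community",
    "weighted_average_percent",
    "co_enrichment_fraction",
    "round_half_away",
]

logger = logging.getLogger(__name__)

CHEMOAUTOTROPH_CATEGORIES = ("II_EXCL_AUTO", "IV_PRIM_AUTO")
HETEROTROPH_CATEGORIES = ("I_EXCL_HETERO", "III_PRIM_HETERO")


class Category(str, Enum):
    """Metabolic category of a single cell."""

    INACTIVE = "INACTIVE"
    I_EXCL_HETERO = "I_EXCL_HETERO"  # all new C organic
    II_EXCL_AUTO = "II_EXCL_AUTO"  # all new C from bicarbonate
    III_PRIM_HETERO = "III_PRIM_HETERO"  # <50% new C from bicarbonate
    IV_PRIM_AUTO = "IV_PRIM_AUTO"  # >=50% new C from bicarbonate

    def __str__(self) -> str:  # serialize as the bare name
        return self.value


@dataclass
class CellClassification:
    """Per-cell activity flags, nets and assigned metabolic category."""

    cell_id: str
    enriched_c: bool
    enriched_n: bool
    category: Category
    c_net_pct: float
    n_net_pct: float
    site: str = ""
    bottle: str = ""
    timepoint_days: Optional[float] = None
    taxon_label: str = "none"


def classify_cell(
    c_net: float,
    n_net: float,
    dl_c: float,
    dl_n: float,
    enriched_c: bool,
    enriched_n: bool,
) -> Category:
    """Assign one cell to a metabolic category by fixed first-match rules.

    A cell with neither isotope enriched is INACTIVE. Active cells are
    tested in order:

    1. exclusively heterotrophic: C_net% < C detection limit and
       N_net% > N detection limit (no bicarbonate-derived carbon);
    2. exclusively autotrophic: C_net% >= N_net% (all new carbon from
       bicarbonate; covers cells enriched in ¹³C only);
    3. primarily heterotrophic: N_net% >= 2·C_net% (<50% of new carbon
       from bicarbonate; the boundary line 2:1 belongs to this zone);
    4. primarily autotrophic: C_net% < N_net% < 2·C_net%.

    Rules 2-4 partition the (C_net, N_net) plane, so every active cell
    receives exactly one category; ties on the 1:1 line go to zone II and
    ties on the 2:1 line to zone III.
    """
    if dl_c <= 0 or dl_n <= 0:
        raise InputDomainError("detection limits must be > 0")
    if c_net < 0 or n_net < 0:
        raise InputDomainError("net assimilation percents must be >= 0 (post-clamp)")
    if not (enriched_c or enriched_n):
        return Category.INACTIVE
    if c_net < dl_c and n_net > dl_n:
        return Category.I_EXCL_HETERO
    if c_net >= n_net:
        return Category.II_EXCL_AUTO
    if n_net >= 2.0 * c_net:
        return Category.III_PRIM_HETERO
    return Category.IV_PRIM_AUTO


def classify_cells(
    c_net: np.ndarray,
    n_net: np.ndarray,
    dl_c: float,
    dl_n: float,
    enriched_c: np.ndarray,
    enriched_n: np.ndarray,
) -> np.ndarray:
    """Vectorized :func:`classify_cell`; returns an object array of Category."""
    if dl_c <= 0 or dl_n <= 0:
        raise InputDomainError("detection limits must be > 0")
    c = np.asarray(c_net, dtype=float)
    n = np.asarray(n_net, dtype=float)
    ec = np.asarray(enriched_c, dtype=bool)
    en = np.asarray(enriched_n, dtype=bool)
    if np.any(c < 0) or np.any(n < 0):
        raise InputDomainError("net assimilation percents must be >= 0 (post-clamp)")
    conditions = [
        ~(ec | en),
        (c < dl_c) & (n > dl_n),
        c >= n,
        n >= 2.0 * c,
    ]
    order = [
        Category.INACTIVE,
        Category.I_EXCL_HETERO,
        Category.II_EXCL_AUTO,
        Category.III_PRIM_HETERO,
        Category.IV_PRIM_AUTO,
    ]
    codes = np.select(conditions, range(4), default=4)
    return np.array(order, dtype=object)[codes]


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (presentation only)."""
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


@dataclass
class GroupSummary:
    n_cells: int
    n_active: int
    pct_active: float
    counts: Dict[str, int]
    pct_chemoauto_of_active: Optional[float]
    pct_hetero_of_active: Optional[float]

    def to_dict(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "n_active": self.n_active,
            "pct_active": self.pct_active,
            "counts": self.counts,
            "pct_chemoauto_of_active": self.pct_chemoauto_of_active,
            "pct_hetero_of_active": self.pct_hetero_of_active,
        }


@dataclass
class CommunitySummary:
    """Community-wide and per-group activity / metabolism breakdown.

    Percent fields are full precision; integer rounding is applied only in
    formatted reports. Chemoautotrophs are categories II + IV of the active
    cells, heterotrophs I + III, so the two percentages sum to 100 over
    active cells.
    """

    overall: GroupSummary
    groups: Dict[Tuple, GroupSummary] = field(default_factory=dict)
    group_keys: Sequence[str] = ()

    def to_dict(self) -> dict:
        return {
            "overall": self.overall.to_dict(),
            "group_keys": list(self.group_keys),
            "groups": {
                "|".join(str(k) for k in key): g.to_dict()
                for key, g in self.groups.items()
            },
        }


def _summarize_frame(frame: pd.DataFrame) -> GroupSummary:
    n_cells = int(len(frame))
    counts = {cat.value: int((frame["category"] == cat.value).sum()) for cat in Category}
    n_active = n_cells - counts[Category.INACTIVE.value]
    n_auto = sum(counts[c] for c in CHEMOAUTOTROPH_CATEGORIES)
    n_hetero = sum(counts[c] for c in HETEROTROPH_CATEGORIES)
    return GroupSummary(
        n_cells=n_cells,
        n_active=n_active,
        pct_active=100.0 * n_active / n_cells if n_cells else 0.0,
        counts=counts,
        pct_chemoauto_of_active=100.0 * n_auto / n_active if n_active else None,
        pct_hetero_of_active=100.0 * n_hetero / n_active if n_active else None,
    )


def classifications_to_frame(classifications: Iterable[CellClassification]) -> pd.DataFrame:
    records = [
        {
            "cell_id": c.cell_id,
            "site": c.site,
            "bottle": c.bottle,
            "timepoint_days": c.timepoint_days,
            "taxon_label": c.taxon_label,
            "enriched_c": c.enriched_c,
            "enriched_n": c.enriched_n,
            "category": c.category.value,
            "c_net_pct": c.c_net_pct,
            "n_net_pct": c.n_net_pct,
        }
        for c in classifications
    ]
    return pd.DataFrame.from_records(records)


def summarize_community(
    classifications: Iterable[CellClassification],
    group_keys: Sequence[str] = ("site", "bottle", "timepoint_days", "taxon_label"),
) -> CommunitySummary:
    """Counts and percentages overall and per metadata group.

    Groups with no classifiable cells are omitted with a logged warning.
    """
    frame = (
        classifications
        if isinstance(classifications, pd.DataFrame)
        else classifications_to_frame(classifications)
    )
    if frame.empty:
        raise InputDomainError("cannot summarize an empty collection of cells")
    overall = _summarize_frame(frame)
    groups: Dict[Tuple, GroupSummary] = {}
    if group_keys:
        for key, sub in frame.groupby(list(group_keys), dropna=False, sort=True):
            key = key if isinstance(key, tuple) else (key,)
            if sub.empty:  # pragma: no cover - groupby never yields empty, kept for contract
                logger.warning("group %s is empty; omitted from summary", key)
                continue
            groups[key] = _summarize_frame(sub)
    return CommunitySummary(overall=overall, groups=groups, group_keys=tuple(group_keys))


def weighted_average_percent(values: Sequence[Tuple[float, int]]) -> float:
    """Cell-count-weighted average of per-bottle percentages: Σ pᵢnᵢ / Σ nᵢ."""
    if not values:
        raise InputDomainError("need at least one (percent, n) pair")
    if any(n <= 0 for _, n in values):
        raise InputDomainError("all weights n must be > 0")
    total = sum(n for _, n in values)
    return sum(p * n for p, n in values) / total


def co_enrichment_fraction(
    classifications: Iterable[CellClassification],
    taxon_label: Optional[str],
    condition_isotope: str,
    outcome_isotope: str,
) -> float:
    """Percent of condition-isotope-enriched cells also enriched in the other.

    E.g. among ¹⁵N-enriched Thaumarchaeota, the percent also ¹³C-enriched
    (intact amino-acid uptake in a dual-label experiment). Isotopes are
    named "C" or "N". Raises :class:`UndefinedResultError` when no cell
    satisfies the conditioning enrichment — the quantity is undefined, not 0.
    """
    flag = {"C": "enriched_c", "N": "enriched_n", "13C": "enriched_c", "15N": "enriched_n"}
    try:
        cond_attr, out_attr = flag[condition_isotope], flag[outcome_isotope]
    except KeyError as exc:
        raise InputDomainError(f"unknown isotope name: {exc.args[0]!r}") from None
    cells = [
        c
        for c in classifications
        if taxon_label is None or c.taxon_label == taxon_label
    ]
    conditioned = [c for c in cells if getattr(c, cond_attr)]
    if not conditioned:
        raise UndefinedResultError(
            f"no {taxon_label or 'any-taxon'} cells enriched in {condition_isotope}; "
            "co-enrichment fraction is undefined"
        )
    both = sum(1 for c in conditioned if getattr(c, out_attr))
    return 100.0 * both / len(conditioned)
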