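"""File formats, experiment configuration and the end-to-end screen.

Input is a delimited ROI table (one row per cell) carrying either the four
raw ion-count columns (``c12c12, c12c13, c12n14, c12n15``) or pre-computed
atom-percent columns (``c13_atpct, n15_atpct``), plus optional metadata
columns. Output is a per-cell CSV and a summary JSON, both stamped with a
provenance block (tool version, config hash, seed). Lines beginning with
``#`` are provenance/comments and are skipped on read.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    CellClassification,
    Category,
    classify_cells,
    summarize_community,
)
from .errors import ConfigurationError, FormatError
from .isotope import (
    IsotopeMeasurement,
    RawCounts,
    SubstratePool,
    carbon_atom_percent_from_dimer,
    net_assimilation,
    nitrogen_atom_percent_from_counts,
)
from .thresholds import ControlStats, detection_limit, fit_control_stats

__all__ = [
    "ExperimentConfig",
    "read_roi_table",
    "write_roi_table",
    "read_percell_csv",
    "run_screen",
    "ScreenResult",
]

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ("c12c12", "c12c13", "c12n14", "c12n15")
ATPCT_COLUMNS = ("c13_atpct", "n15_atpct")
META_COLUMNS = ("cell_id", "site", "bottle", "timepoint_days", "taxon_label")


@dataclass
class ControlSource:
    """Where the unlabeled control population comes from: a ROI file of
    control cells, or inline per-element (mean, sd, n) statistics."""

    file: Optional[str] = None
    inline: Optional[Dict[str, Dict[str, float]]] = None  # element -> {mean_atpct, sd_atpct, n_cells}

    def __post_init__(self) -> None:
        if (self.file is None) == (self.inline is None):
            raise ConfigurationError("control source must be exactly one of file or inline stats")


@dataclass
class ExperimentConfig:
    """Everything the screen needs beyond the ROI table itself."""

    site: str
    pools: Dict[str, SubstratePool]
    control: ControlSource
    correction_factor: float = 1.0
    seed: int = 0
    outdir: Optional[str] = None
    make_figure: bool = False

    def __post_init__(self) -> None:
        if self.correction_factor <= 0:
            raise ConfigurationError("dimer correction_factor must be > 0")
        for element in ("C", "N"):
            if element not in self.pools:
                raise ConfigurationError(f"missing substrate pool for element {element}")

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        pools = {
            e: SubstratePool(
                element=e,
                concentration=float(p.get("concentration", 0.0)),
                tracer_atpct=float(p["tracer_atpct"]),
                label=str(p.get("label", "")),
            )
            for e, p in d["pools"].items()
        }
        ctrl = d["control"]
        control = ControlSource(file=ctrl.get("file"), inline=ctrl.get("inline"))
        return cls(
            site=str(d.get("site", "")),
            pools=pools,
            control=control,
            correction_factor=float(d.get("correction_factor", 1.0)),
            seed=int(d.get("seed", 0)),
            outdir=d.get("outdir"),
            make_figure=bool(d.get("make_figure", False)),
        )

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "ExperimentConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "site": self.site,
            "pools": {
                e: {
                    "concentration": p.concentration,
                    "tracer_atpct": p.tracer_atpct,
                    "label": p.label,
                }
                for e, p in self.pools.items()
            },
            "control": {"file": self.control.file, "inline": self.control.inline},
            "correction_factor": self.correction_factor,
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def read_roi_table(
    path: Union[str, Path],
    delimiter: str = ",",
    correction_factor: float = 1.0,
) -> List[IsotopeMeasurement]:
    """Read an ROI table into validated measurements.

    Accepts either count columns or at.% columns (counts win when both are
    present: at.% are then recomputed from counts). Rows failing validation
    (negative counts, zero ¹²C₂⁻ denominator, at.% outside [0, 100]) are
    reported with their line numbers and excluded; only header problems
    abort the read.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=delimiter, comment="#")
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty data section; returning no measurements", path)
        return []
    has_counts = all(c in frame.columns for c in COUNT_COLUMNS)
    has_atpct = all(c in frame.columns for c in ATPCT_COLUMNS)
    if not has_counts and not has_atpct:
        missing = [c for c in COUNT_COLUMNS + ATPCT_COLUMNS if c not in frame.columns]
        raise FormatError(
            f"{path}: header must provide either count columns {COUNT_COLUMNS} or "
            f"atom-percent columns {ATPCT_COLUMNS}; missing {missing}"
        )
    if frame.empty:
        logger.warning("%s: empty data section; returning no measurements", path)
        return []

    measurements: List[IsotopeMeasurement] = []
    for idx, row in frame.iterrows():
        line = idx + 2  # header is line 1
        try:
            raw = None
            if has_counts:
                counts = [row[c] for c in COUNT_COLUMNS]
                if any(pd.isna(v) for v in counts):
                    raise ValueError("missing ion count")
                raw = RawCounts(*(int(v) for v in counts))
                c13 = float(
                    carbon_atom_percent_from_dimer(raw.c13c, raw.c2, correction_factor)
                )
                n15 = float(nitrogen_atom_percent_from_counts(raw.cn15, raw.cn14))
            else:
                c13 = float(row["c13_atpct"])
                n15 = float(row["n15_atpct"])
            tp = row.get("timepoint_days")
            measurements.append(
                IsotopeMeasurement(
                    cell_id=str(row.get("cell_id", f"row{line}")),
                    c13_atpct=c13,
                    n15_atpct=n15,
                    raw_counts=raw,
                    site=str(row.get("site", "")) if pd.notna(row.get("site", "")) else "",
                    bottle=str(row.get("bottle", "")) if pd.notna(row.get("bottle", "")) else "",
                    timepoint_days=float(tp) if pd.notna(tp) else None,
                    taxon_label=str(row.get("taxon_label", "none"))
                    if pd.notna(row.get("taxon_label", "none"))
                    else "none",
                )
            )
        except (ValueError, ArithmeticError) as exc:
            logger.warning("%s line %d: row excluded (%s)", path, line, exc)
    return measurements


def _provenance_lines(config_hash: str, seed: int) -> List[str]:
    return [
        f"# nanosip {__version__}",
        f"# config_hash: {config_hash}",
        f"# seed: {seed}",
    ]


def write_roi_table(
    frame: pd.DataFrame, path: Union[str, Path], config_hash: str = "none", seed: int = 0
) -> None:
    """Write an ROI-schema DataFrame as CSV with a provenance header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\n".join(_provenance_lines(config_hash, seed)) + "\n")
        frame.to_csv(fh, index=False)


def read_percell_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read back a per-cell results CSV (skipping provenance comments).

    Uses round-trip float parsing so numeric columns come back bit-exact.
    """
    return pd.read_csv(path, comment="#", float_precision="round_trip")


@dataclass
class ScreenResult:
    """End-to-end screen output: per-cell table, stats, and summaries."""

    percell: pd.DataFrame
    control_stats: Dict[str, ControlStats]
    summary: dict
    classifications: List[CellClassification] = field(default_factory=list)


def _resolve_control(config: ExperimentConfig) -> Dict[str, ControlStats]:
    if config.control.file is not None:
        cells = read_roi_table(config.control.file, correction_factor=config.correction_factor)
        stats = {e: fit_control_stats(cells, e) for e in ("C", "N")}
    else:
        stats = {
            e: ControlStats(
                element=e,
                mean_atpct=float(config.control.inline[e]["mean_atpct"]),
                sd_atpct=float(config.control.inline[e]["sd_atpct"]),
                n_cells=int(config.control.inline[e]["n_cells"]),
            )
            for e in ("C", "N")
        }
    for e in ("C", "N"):
        stats[e].detection_limit_net_pct = detection_limit(stats[e], config.pools[e])
    return stats


def run_screen(
    config: ExperimentConfig,
    roi: Union[str, Path, List[IsotopeMeasurement]],
    outdir: Optional[Union[str, Path]] = None,
) -> ScreenResult:
    """Run the full screen: control stats → thresholds/detection limits →
    net assimilation → classification → community summaries.

    Deterministic given its inputs. When ``outdir`` (or ``config.outdir``)
    is set, writes ``percell.csv`` and ``summary.json`` there, plus
    ``zones.png`` when the figure is requested (figure failures never change
    the exit status of the analysis).
    """
    if isinstance(roi, (str, Path)):
        measurements = read_roi_table(roi, correction_factor=config.correction_factor)
    else:
        measurements = list(roi)
    stats = _resolve_control(config)
    thr_c, thr_n = stats["C"].threshold_atpct, stats["N"].threshold_atpct
    dl_c, dl_n = stats["C"].detection_limit_net_pct, stats["N"].detection_limit_net_pct

    records = []
    classifications: List[CellClassification] = []
    for m in measurements:
        net_c = net_assimilation(m.c13_atpct, stats["C"].mean_atpct, config.pools["C"].tracer_atpct)
        net_n = net_assimilation(m.n15_atpct, stats["N"].mean_atpct, config.pools["N"].tracer_atpct)
        records.append(
            {
                "cell_id": m.cell_id,
                "site": m.site or config.site,
                "bottle": m.bottle,
                "timepoint_days": m.timepoint_days,
                "taxon_label": m.taxon_label,
                "c13_atpct": m.c13_atpct,
                "n15_atpct": m.n15_atpct,
                "f_s_c_raw": net_c.f_s_raw,
                "f_s_n_raw": net_n.f_s_raw,
                "c_net_pct": net_c.x_net_pct,
                "n_net_pct": net_n.x_net_pct,
                "enriched_c": m.c13_atpct > thr_c,
                "enriched_n": m.n15_atpct > thr_n,
            }
        )
    percell = pd.DataFrame.from_records(records)
    if not percell.empty:
        categories = classify_cells(
            percell["c_net_pct"].to_numpy(),
            percell["n_net_pct"].to_numpy(),
            dl_c,
            dl_n,
            percell["enriched_c"].to_numpy(),
            percell["enriched_n"].to_numpy(),
        )
        percell["category"] = [c.value for c in categories]
        classifications = [
            CellClassification(
                cell_id=row.cell_id,
                enriched_c=bool(row.enriched_c),
                enriched_n=bool(row.enriched_n),
                category=Category(row.category),
                c_net_pct=row.c_net_pct,
                n_net_pct=row.n_net_pct,
                site=row.site,
                bottle=row.bottle if pd.notna(row.bottle) else "",
                timepoint_days=row.timepoint_days if pd.notna(row.timepoint_days) else None,
                taxon_label=row.taxon_label,
            )
            for row in percell.itertuples()
        ]
        community = summarize_community(classifications)
        community_dict = community.to_dict()
    else:
        percell["category"] = pd.Series(dtype=str)
        community_dict = {"overall": None, "group_keys": [], "groups": {}}
        logger.warning("screen produced no classifiable cells")

    summary = {
        "provenance": {
            "tool": "nanosip",
            "version": __version__,
            "config_hash": config.config_hash(),
            "seed": config.seed,
        },
        "config": config.to_dict(),
        "control_stats": {e: s.to_dict() for e, s in stats.items()},
        "detection_limits_net_pct": {"C": dl_c, "N": dl_n},
        "community": community_dict,
    }

    out = Path(outdir) if outdir is not None else (Path(config.outdir) if config.outdir else None)
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "percell.csv", "w") as fh:
            fh.write("\n".join(_provenance_lines(config.config_hash(), config.seed)) + "\n")
            percell.to_csv(fh, index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float) + "\n")
        if config.make_figure:
            try:
                from .plotting import zone_figure

                fig = zone_figure(percell, stats, config.pools)
                fig.savefig(out / "zones.png", dpi=150)
            except Exception as exc:  # figure is best-effort, never fatal
                logger.warning("zone figure failed: %s", exc)

    return ScreenResult(
        percell=percell, control_stats=stats, summary=summary, classifications=classifications
    )
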