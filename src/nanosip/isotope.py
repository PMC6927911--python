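"""Closed-form isotope arithmetic for single-cell nanoSIP data reduction.

Everything here is a pure function on scalars or numpy arrays: conversions
between isotope ratios and atom percent, reduction of the measured carbon
dimer (¹²C¹³C⁻/¹²C₂⁻) to a monomer ¹³C atom percent, concentration-weighted
mixing of labeled substrate pools, and the two-pool mixing model that turns
a cell's measured enrichment into the fraction of its biomass synthesized
during the incubation (net assimilation, X_net%).

Percent quantities are carried on the 0-100 scale throughout; fractions
appear only inside the mixing algebra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigurationError, InputDomainError, MeasurementInvalidError

__all__ = [
    "C13_NATURAL_ATPCT",
    "N15_NATURAL_ATPCT",
    "IsotopeMeasurement",
    "SubstratePool",
    "ElementNet",
    "NetAssimilation",
    "ratio_to_atom_percent",
    "atom_percent_to_ratio",
    "carbon_atom_percent_from_dimer",
    "nitrogen_atom_percent_from_counts",
    "substrate_pool_atom_percent",
    "net_assimilation",
    "fxnet_from_xnet",
    "xnet_from_fxnet",
]

#: Canonical natural-abundance atom percents, used as synthetic-data defaults.
#: Real analyses take a_init from the measured unlabeled control population.
C13_NATURAL_ATPCT = 1.11
N15_NATURAL_ATPCT = 0.366

VALID_TAXON_LABELS = frozenset({"thaumarchaeota", "bacteria", "unidentified", "none"})


@dataclass(frozen=True)
class RawCounts:
    """Ion counts for the four collected secondary-ion species."""

    c2: int  # 12C2-
    c13c: int  # 12C13C-
    cn14: int  # 12C14N-
    cn15: int  # 12C15N-

    def __post_init__(self) -> None:
        for name in ("c2", "c13c", "cn14", "cn15"):
            v = getattr(self, name)
            if v < 0:
                raise InputDomainError(f"ion count {name} must be >= 0, got {v}")


@dataclass
class IsotopeMeasurement:
    """One cell (ROI): measured ¹³C / ¹⁵N atom percent plus sample metadata.

    ``c13_atpct``/``n15_atpct`` may come straight from the instrument export
    or be derived from ``raw_counts`` by the declared conversions
    (:func:`carbon_atom_percent_from_dimer`,
    :func:`nitrogen_atom_percent_from_counts`).
    """

    cell_id: str
    c13_atpct: float
    n15_atpct: float
    raw_counts: Optional[RawCounts] = None
    site: str = ""
    bottle: str = ""
    timepoint_days: Optional[float] = None
    taxon_label: str = "none"

    def __post_init__(self) -> None:
        for name in ("c13_atpct", "n15_atpct"):
            v = getattr(self, name)
            if not math.isfinite(v) or not 0.0 <= v <= 100.0:
                raise InputDomainError(
                    f"{name} must be a finite atom percent in [0, 100], got {v}"
                )
        if self.taxon_label not in VALID_TAXON_LABELS:
            raise InputDomainError(
                f"taxon_label must be one of {sorted(VALID_TAXON_LABELS)}, "
                f"got {self.taxon_label!r}"
            )


@dataclass(frozen=True)
class SubstratePool:
    """An isotopically labeled substrate pool (e.g. spiked bicarbonate).

    ``tracer_atpct`` is the atom percent of the heavy isotope in the total
    pool available to cells — the a_sub of the mixing model.
    """

    element: str  # "C" or "N"
    concentration: float  # mol/L (nominal units are fine; only ratios matter)
    tracer_atpct: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.element not in ("C", "N"):
            raise InputDomainError(f"element must be 'C' or 'N', got {self.element!r}")
        if self.concentration < 0:
            raise InputDomainError("pool concentration must be >= 0")
        if not 0.0 <= self.tracer_atpct <= 100.0:
            raise InputDomainError("tracer_atpct must lie in [0, 100]")


@dataclass(frozen=True)
class ElementNet:
    """Two-pool mixing-model output for one element of one cell."""

    f_s_raw: float  # substrate-derived fraction before clamping (QC)
    f_s: float  # clamped to [0, 1]
    f_i: float  # 1 - f_s
    x_net_pct: float  # 100 * f_s / (f_s + f_i)
    fx_net_pct: Optional[float]  # relative to initial biomass; None at x = 100


@dataclass
class NetAssimilation:
    """Per-cell net assimilation for both elements."""

    cell_id: str
    carbon: ElementNet
    nitrogen: ElementNet

    @property
    def c_net_pct(self) -> float:
        return self.carbon.x_net_pct

    @property
    def n_net_pct(self) -> float:
        return self.nitrogen.x_net_pct


def ratio_to_atom_percent(r):
    """Convert a minor/major isotope ratio to atom percent, 100·r/(1+r).

    E.g. at.% ¹⁵N = 100 · ¹⁵N/(¹⁵N + ¹⁴N) = 100 · r/(1 + r) with
    r = ¹⁵N/¹⁴N. Accepts scalars or arrays; strictly increasing in r and
    bounded in [0, 100).
    """
    r = np.asarray(r, dtype=float)
    if np.any(~np.isfinite(r)) or np.any(r < 0):
        raise InputDomainError("isotope ratio must be finite and >= 0")
    out = 100.0 * r / (1.0 + r)
    return float(out) if out.ndim == 0 else out


def atom_percent_to_ratio(a):
    """Exact inverse of :func:`ratio_to_atom_percent`: r = a/(100 − a)."""
    a = np.asarray(a, dtype=float)
    if np.any(~np.isfinite(a)) or np.any(a < 0) or np.any(a >= 100):
        raise InputDomainError("atom percent must lie in [0, 100)")
    out = a / (100.0 - a)
    return float(out) if out.ndim == 0 else out


def carbon_atom_percent_from_dimer(count_c13c, count_c2, correction_factor: float = 1.0):
    """¹³C atom percent from the measured ¹²C¹³C⁻/¹²C₂⁻ dimer counts.

    Under random pairing of carbon atoms at ¹³C atom fraction a, the dimer
    ratio r_d = ¹²C¹³C/¹²C₂ = 2a(1−a)/(1−a)² = 2R where R = a/(1−a) is the
    monomer atomic ratio; hence R = r_d/2. A configurable multiplicative
    ``correction_factor`` is then applied to R (instrument calibration; 1.0
    means none) before converting to atom percent. With the factor at 1 the
    atom fraction equals r_d/(r_d + 2).
    """
    if correction_factor <= 0:
        raise InputDomainError("correction_factor must be > 0")
    count_c13c = np.asarray(count_c13c, dtype=float)
    count_c2 = np.asarray(count_c2, dtype=float)
    if np.any(count_c13c < 0) or np.any(count_c2 < 0):
        raise InputDomainError("ion counts must be >= 0")
    if np.any(count_c2 == 0):
        raise MeasurementInvalidError(
            "zero 12C2- counts: cell cannot be ratioed (flag, do not drop silently)"
        )
    r_d = count_c13c / count_c2
    return ratio_to_atom_percent(correction_factor * r_d / 2.0)


def nitrogen_atom_percent_from_counts(count_cn15, count_cn14):
    """¹⁵N atom percent from ¹²C¹⁵N⁻ and ¹²C¹⁴N⁻ counts (monomer species)."""
    count_cn15 = np.asarray(count_cn15, dtype=float)
    count_cn14 = np.asarray(count_cn14, dtype=float)
    if np.any(count_cn15 < 0) or np.any(count_cn14 < 0):
        raise InputDomainError("ion counts must be >= 0")
    if np.any(count_cn14 == 0):
        raise MeasurementInvalidError(
            "zero 12C14N- counts: cell cannot be ratioed (flag, do not drop silently)"
        )
    return ratio_to_atom_percent(count_cn15 / count_cn14)


def substrate_pool_atom_percent(
    spike_conc: float, spike_atpct: float, ambient_conc: float, ambient_atpct: float
) -> float:
    """Atom percent of the combined pool after spiking label into ambient.

    Concentration-weighted mean; always between the two input atom percents.
    """
    if spike_conc < 0 or ambient_conc < 0:
        raise InputDomainError("pool concentrations must be >= 0")
    total = spike_conc + ambient_conc
    if total == 0:
        raise InputDomainError("at least one pool must have nonzero concentration")
    return (spike_conc * spike_atpct + ambient_conc * ambient_atpct) / total


def net_assimilation(a_meas: float, a_init: float, a_sub: float) -> ElementNet:
    """Two-pool linear mixing model in atom-fraction space for one element.

    The cell's final biomass is modeled as a mix of original biomass at the
    control (initial) composition ``a_init`` and newly synthesized biomass at
    the substrate composition ``a_sub``:

        F_s = (a_meas − a_init) / (a_sub − a_init)    (substrate-derived)
        F_i = 1 − F_s                                  (initial biomass)
        X_net% = 100 · F_s / (F_s + F_i) = 100 · F_s

    F_s is clamped to [0, 1] for classification; the raw value is kept for
    QC so that noise below the control mean is visible but never turns into
    negative biomass.
    """
    for name, v in (("a_meas", a_meas), ("a_init", a_init), ("a_sub", a_sub)):
        if not math.isfinite(v) or not 0.0 <= v <= 100.0:
            raise InputDomainError(f"{name} must be a finite at.% in [0, 100], got {v}")
    if a_sub <= a_init:
        raise ConfigurationError(
            f"substrate pool at {a_sub} at.% is not enriched above the control "
            f"mean {a_init} at.%; an unlabeled substrate cannot trace"
        )
    f_s_raw = (a_meas - a_init) / (a_sub - a_init)
    f_s = min(1.0, max(0.0, f_s_raw))
    f_i = 1.0 - f_s
    x_net = 100.0 * f_s
    fx = fxnet_from_xnet(x_net) if x_net < 100.0 else None
    return ElementNet(f_s_raw=f_s_raw, f_s=f_s, f_i=f_i, x_net_pct=x_net, fx_net_pct=fx)


def fxnet_from_xnet(x):
    """Convert X_net% (new biomass / final biomass) to Fx_net% (new / initial).

    Fx = 100·x/(100 − x); diverges as x → 100 (all-new biomass has no
    initial biomass to compare against).
    """
    xa = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(xa)) or np.any(xa < 0):
        raise InputDomainError("X_net% must be finite and >= 0")
    if np.any(xa >= 100):
        raise InputDomainError("Fx_net% diverges at X_net% = 100 (all-new biomass)")
    out = 100.0 * xa / (100.0 - xa)
    return float(out) if out.ndim == 0 else out


def xnet_from_fxnet(fx):
    """Inverse conversion: X = 100·Fx/(Fx + 100); round-trips to machine precision."""
    fxa = np.asarray(fx, dtype=float)
    if np.any(~np.isfinite(fxa)) or np.any(fxa < 0):
        raise InputDomainError("Fx_net% must be finite and >= 0")
    out = 100.0 * fxa / (fxa + 100.0)
    return float(out) if out.ndim == 0 else out
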