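"""Acclimated response surfaces and the homeostasis ratio statistic.

From the per-tissue linear trends of the curve parameters (a, b, c) in the
acclimation temperature T_a, the acclimated respiration surface is

    R_d(T_t; T_a) = exp(a(T_a) + b(T_a)*T_t + c(T_a)*T_t**2),

the acclimated rate is its diagonal R_d,acc = R_d(T_a; T_a), and the
homeostasis ratio compares R_d,acc with the reference rate at 25 deg C:

    Acclim_Homeo(T_a) = R_d(T_a; T_a) / R_d(25; 25)   for T_a < 25
                      = R_d(25; 25) / R_d(T_a; T_a)   for T_a > 25

so values of 1 indicate fully homeostatic respiration and the statistic is
oriented the same way on both sides of the reference.  The reference is
25 deg C because that is the temperature at which the plants were grown
before acclimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .curves import PolynomialFit, evaluate_polynomial
from .synthetic import TISSUE_CLASSES4

logger = logging.getLogger(__name__)

PARAMS = ("a", "b", "c")
HOMEO_TA_LEVELS = (15.0, 20.0, 30.0, 35.0)
T_REF_DEFAULT = 25.0


@dataclass(frozen=True)
class ParameterTrendSet:
    """Per tissue class: (intercept, slope) of a, b and c versus T_a."""

    trends: Mapping[str, Mapping[str, tuple[float, float]]]

    def __post_init__(self):
        for tissue, tr in self.trends.items():
            for p in PARAMS:
                if p not in tr:
                    raise KeyError(f"missing trend for parameter {p!r} of {tissue!r}")
                icpt, slope = tr[p]
                if not (np.isfinite(icpt) and np.isfinite(slope)):
                    raise ValueError(f"non-finite trend for {tissue}/{p}")

    @property
    def tissues(self) -> tuple[str, ...]:
        ordered = [t for t in TISSUE_CLASSES4 if t in self.trends]
        ordered += sorted(set(self.trends) - set(TISSUE_CLASSES4))
        return tuple(ordered)

    @classmethod
    def from_trend_table(cls, table: pd.DataFrame) -> "ParameterTrendSet":
        """Build from a long trend table with columns
        ``tissue_class4, parameter, slope, intercept`` (one row per pair),
        e.g. the concatenated outputs of ``AcclimationAncova.lsm_trends``."""
        trends: dict[str, dict[str, tuple[float, float]]] = {}
        for row in table.itertuples():
            trends.setdefault(row.tissue_class4, {})[row.parameter] = (
                float(row.intercept), float(row.slope))
        return cls(trends)


@dataclass(frozen=True)
class AcclimationSurface:
    """The reconstructed map (T_t, T_a) -> R_d for one tissue class."""

    tissue_class4: str
    a: tuple[float, float]
    b: tuple[float, float]
    c: tuple[float, float]

    def params_at(self, t_acclim: float) -> tuple[float, float, float]:
        return (self.a[0] + self.a[1] * t_acclim,
                self.b[0] + self.b[1] * t_acclim,
                self.c[0] + self.c[1] * t_acclim)

    def evaluate(self, t_tissue, t_acclim):
        """R_d(T_t; T_a); strictly positive. Broadcasts over arrays."""
        t_tissue = np.asarray(t_tissue, dtype=float)
        t_acclim = np.asarray(t_acclim, dtype=float)
        a = self.a[0] + self.a[1] * t_acclim
        b = self.b[0] + self.b[1] * t_acclim
        c = self.c[0] + self.c[1] * t_acclim
        out = np.exp(a + b * t_tissue + c * t_tissue ** 2)
        return float(out) if out.ndim == 0 else out


def build_surface(trends: ParameterTrendSet, tissue_class4: str) -> AcclimationSurface:
    """Surface for one tissue class; raises ``KeyError`` on a missing trend."""
    tr = trends.trends[tissue_class4]
    return AcclimationSurface(tissue_class4=tissue_class4,
                              a=tuple(tr["a"]), b=tuple(tr["b"]), c=tuple(tr["c"]))


def build_surfaces(trends: ParameterTrendSet) -> dict[str, AcclimationSurface]:
    return {t: build_surface(trends, t) for t in trends.tissues}


def rd_at_acclimation(surface: AcclimationSurface, t_acclim):
    """R_d,acc: the surface on its diagonal, T_t = T_a."""
    return surface.evaluate(t_acclim, t_acclim)


def acclim_homeo(surface: AcclimationSurface, t_acclim: float,
                 t_ref: float = T_REF_DEFAULT) -> float:
    """Homeostasis ratio at one acclimation temperature (see module docstring).

    Exactly 1 at ``t_acclim == t_ref``; always positive.
    """
    if t_acclim == t_ref:
        return 1.0
    racc = float(rd_at_acclimation(surface, t_acclim))
    rref = float(rd_at_acclimation(surface, t_ref))
    return racc / rref if t_acclim < t_ref else rref / racc


@dataclass(frozen=True)
class HomeostasisResult:
    """Acclim_Homeo on the tissue x T_a grid with marginal averages.

    Averages are arithmetic means of the full-precision grid; rounding (for
    a printed table) happens only at report time.
    """

    grid: pd.DataFrame  # index T_a, columns tissue classes
    t_ref: float = T_REF_DEFAULT

    @property
    def tissue_averages(self) -> pd.Series:
        return self.grid.mean(axis=0)

    @property
    def ta_averages(self) -> pd.Series:
        return self.grid.mean(axis=1)

    @property
    def grand_average(self) -> float:
        return float(self.grid.to_numpy().mean())

    def to_frame(self, decimals: int | None = None) -> pd.DataFrame:
        """Report layout: T_a rows plus an Average row, tissue columns plus
        an Average column."""
        out = self.grid.copy()
        out["Average"] = self.ta_averages
        bottom = out.mean(axis=0)
        bottom["Average"] = self.grand_average
        out.index = pd.Index([f"{ta:g} C" for ta in self.grid.index], name="T_a")
        out.loc["Average"] = bottom
        return out.round(decimals) if decimals is not None else out


def homeostasis_table(surfaces: Mapping[str, AcclimationSurface],
                      ta_levels: Sequence[float] = HOMEO_TA_LEVELS,
                      t_ref: float = T_REF_DEFAULT) -> HomeostasisResult:
    """Acclim_Homeo for every surface at every acclimation temperature."""
    if not surfaces:
        raise ValueError("need at least one surface")
    ordered = [t for t in TISSUE_CLASSES4 if t in surfaces]
    ordered += sorted(set(surfaces) - set(TISSUE_CLASSES4))
    grid = pd.DataFrame(
        {t: [acclim_homeo(surfaces[t], ta, t_ref) for ta in ta_levels]
         for t in ordered},
        index=pd.Index([float(t) for t in ta_levels], name="T_a_C"),
    )
    return HomeostasisResult(grid=grid, t_ref=t_ref)


def acclim_homeo_individual(fit: PolynomialFit, reference_fit: PolynomialFit,
                            t_acclim: float, t_ref: float = T_REF_DEFAULT) -> float:
    """Per-individual homeostasis ratio from two fitted curves (the
    individual's own curve and a reference curve from plants acclimated to
    ``t_ref``).

    This is a per-individual variant of the population-level statistic; the
    canonical analysis computes Acclim_Homeo from the reconstructed
    population surfaces, not per individual.
    """
    if t_acclim == t_ref:
        return 1.0
    racc = evaluate_polynomial(fit, t_acclim)
    rref = evaluate_polynomial(reference_fit, t_ref)
    return racc / rref if t_acclim < t_ref else rref / racc


def compute_ratio_records(rd_fits: pd.DataFrame,
                          vcmax_fits: pd.DataFrame) -> pd.DataFrame:
    """Per-individual ln(R_d,acc / V_cmax,acc) records.

    Both curves are evaluated at the tissue temperature equal to the
    individual's acclimation temperature; each tissue's respiration is
    paired with the same individual's leaf V_cmax (per-gram).  Records with
    a non-positive or non-finite rate are excluded with a warning.  The
    output feeds :class:`~rdacclim.ancova.AcclimationAncova` unchanged
    (``parameter = "ln_ratio"``).
    """
    vc = vcmax_fits.set_index("individual_id")
    shared = rd_fits["individual_id"].isin(vc.index)
    if not shared.any():
        raise ValueError("no overlapping individuals between R_d and V_cmax fits")

    rows = []
    n_dropped = 0
    for row in rd_fits[shared].itertuples():
        ta = float(row.T_a_C)
        v = vc.loc[row.individual_id]
        rd_acc = float(np.exp(row.a + row.b * ta + row.c * ta * ta))
        vc_acc = float(np.exp(v["a"] + v["b"] * ta + v["c"] * ta * ta))
        if not (np.isfinite(rd_acc) and np.isfinite(vc_acc)
                and rd_acc > 0 and vc_acc > 0):
            n_dropped += 1
            continue
        tc4 = (row.tissue if row.tissue != "stem"
               else ("ps_stem" if row.tissue_class == "photosynthetic" else "nonps_stem"))
        rows.append(dict(
            individual_id=row.individual_id, species=row.species,
            tissue=row.tissue, tissue_class4=tc4, T_a_C=ta,
            rd_acc=rd_acc, vcmax_acc=vc_acc,
            parameter="ln_ratio", value=float(np.log(rd_acc / vc_acc))))
    if n_dropped:
        logger.warning("excluded %d ratio record(s) with invalid rates", n_dropped)
    cols = ["individual_id", "species", "tissue", "tissue_class4", "T_a_C",
            "rd_acc", "vcmax_acc", "parameter", "value"]
    return pd.DataFrame(rows, columns=cols)
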