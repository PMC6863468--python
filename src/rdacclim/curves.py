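"""Exponential-quadratic temperature-response curves.

Dark respiration (and V_cmax) temperature responses are modelled as

    R(T) = exp(a + b*T + c*T**2)

with T the tissue temperature in deg C.  ``a`` is the natural-log rate at
0 deg C (rate units: umol g-1 s-1), ``b`` (deg C-1) sets the relative
temperature sensitivity near 0 deg C and ``c`` (deg C-2) how that
sensitivity changes with warming.

Fitting happens either by exact ordinary least squares of ln(rate) on
(1, T, T**2) (``log_ols``, the default) or by iterative least squares on the
original flux scale initialised from the log fit (``original_nls``).  The
root-mean-square error is always reported on the original flux scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .errors import FitError

logger = logging.getLogger(__name__)

Scale = Literal["log_ols", "original_nls"]

#: minimum number of usable points for a curve fit
MIN_POINTS = 4
#: minimum number of distinct temperatures for a non-degenerate design
MIN_DISTINCT_TEMPS = 3


def convert_area_to_mass_flux(flux_area: float, area: float, dry_mass: float) -> float:
    """Convert an area-basis flux (umol m-2 s-1) to a dry-mass basis
    (umol g-1 s-1) given the tissue projected area (m2) and dry mass (g)."""
    if not area > 0:
        raise ValueError(f"area must be positive, got {area}")
    if not dry_mass > 0:
        raise ValueError(f"dry_mass must be positive, got {dry_mass}")
    return flux_area * area / dry_mass


@dataclass(frozen=True)
class TemperatureSeries:
    """One individual x tissue temperature series of positive rates."""

    individual_id: str
    species: str
    tissue: str
    tissue_class: str
    t_acclim: float
    temperatures: tuple[float, ...]
    rates: tuple[float, ...]

    def __post_init__(self):
        if len(self.temperatures) != len(self.rates):
            raise ValueError("temperatures and rates differ in length")
        if len(self.temperatures) < 1:
            raise ValueError("a series needs at least one point")
        if not np.all(np.isfinite(self.temperatures)):
            raise ValueError("temperatures must be finite")


@dataclass(frozen=True)
class PolynomialFit:
    """Fitted (a, b, c) for one series plus diagnostics.

    ``rmse`` is on the original flux scale (umol g-1 s-1); ``n_points`` is
    the number of points actually used.
    """

    a: float
    b: float
    c: float
    rmse: float
    n_points: int
    scale_used: Scale = "log_ols"

    def __post_init__(self):
        for name in ("a", "b", "c"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"parameter {name} is not finite")
        if self.rmse < 0:
            raise ValueError("rmse must be non-negative")
        if self.n_points < MIN_POINTS:
            raise ValueError(f"n_points must be >= {MIN_POINTS}")


class ExpQuadraticCurve(BaseEstimator):
    """Scikit-learn style estimator for the exponential-quadratic curve.

    Parameters
    ----------
    scale:
        ``"log_ols"`` (closed-form least squares of ln rate on 1, T, T^2) or
        ``"original_nls"`` (iterative least squares on the flux scale,
        initialised from the log fit).
    drop_nonpositive:
        Exclude non-positive rates before fitting, with a warning.
        Respiration fluxes should be positive; occasional negative
        instrument readings must not abort a batch.

    Attributes (after ``fit``)
    --------------------------
    a_, b_, c_ : float   fitted parameters
    rmse_ : float        root-mean-square error on the flux scale
    n_points_ : int      points used
    """

    def __init__(self, scale: Scale = "log_ols", drop_nonpositive: bool = True,
                 max_nfev: int = 1000):
        self.scale = scale
        self.drop_nonpositive = drop_nonpositive
        self.max_nfev = max_nfev

    # ------------------------------------------------------------------
    def fit(self, T: Sequence[float], rate: Sequence[float]) -> "ExpQuadraticCurve":
        T = np.asarray(T, dtype=float).ravel()
        rate = np.asarray(rate, dtype=float).ravel()
        if T.shape != rate.shape:
            raise ValueError("T and rate must have the same length")
        if self.scale not in ("log_ols", "original_nls"):
            raise ValueError(f"unknown scale {self.scale!r}")

        keep = np.isfinite(T) & np.isfinite(rate)
        if self.drop_nonpositive:
            pos = rate > 0
            n_dropped = int(np.sum(keep & ~pos))
            if n_dropped:
                warnings.warn(
                    f"dropping {n_dropped} non-positive rate(s) before log fitting",
                    UserWarning,
                    stacklevel=2,
                )
            keep &= pos
        elif np.any(rate[keep] <= 0):
            raise FitError("non-positive rates present and drop_nonpositive=False")

        T, rate = T[keep], rate[keep]
        if T.size < MIN_POINTS:
            raise FitError(
                f"need >= {MIN_POINTS} usable points, got {T.size}"
            )
        if np.unique(T).size < MIN_DISTINCT_TEMPS:
            raise FitError(
                f"degenerate design: fewer than {MIN_DISTINCT_TEMPS} distinct temperatures"
            )

        X = np.column_stack([np.ones_like(T), T, T * T])
        coef, *_ = np.linalg.lstsq(X, np.log(rate), rcond=None)

        if self.scale == "original_nls":
            def resid(p):
                return np.exp(p[0] + p[1] * T + p[2] * T * T) - rate

            sol = least_squares(resid, coef, method="lm", max_nfev=self.max_nfev)
            if not sol.success:
                raise FitError(f"original-scale fit did not converge: {sol.message}")
            coef = sol.x

        self.a_, self.b_, self.c_ = (float(v) for v in coef)
        pred = np.exp(self.a_ + self.b_ * T + self.c_ * T * T)
        self.rmse_ = float(np.sqrt(np.mean((rate - pred) ** 2)))
        self.n_points_ = int(T.size)
        return self

    def predict(self, T: Sequence[float] | float) -> np.ndarray | float:
        """Evaluate the fitted curve; strictly positive for finite T."""
        if not hasattr(self, "a_"):
            raise FitError("estimator is not fitted")
        return evaluate_polynomial(self.to_fit(), T)

    def to_fit(self) -> PolynomialFit:
        return PolynomialFit(
            a=self.a_, b=self.b_, c=self.c_, rmse=self.rmse_,
            n_points=self.n_points_, scale_used=self.scale,
        )


# ----------------------------------------------------------------------
# thin functional wrappers


def fit_polynomial(series: TemperatureSeries, scale: Scale = "log_ols") -> PolynomialFit:
    """Fit the exponential-quadratic model to one temperature series."""
    est = ExpQuadraticCurve(scale=scale).fit(series.temperatures, series.rates)
    return est.to_fit()


def evaluate_polynomial(fit: PolynomialFit, T):
    """Evaluate exp(a + b*T + c*T^2) at temperature(s) T (deg C)."""
    T = np.asarray(T, dtype=float)
    out = np.exp(fit.a + fit.b * T + fit.c * T * T)
    return float(out) if out.ndim == 0 else out


def fit_all_individuals(
    records: pd.DataFrame,
    scale: Scale = "log_ols",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every (individual, tissue, quantity) group of a measurement table.

    Parameters
    ----------
    records:
        Long table with columns ``individual_id, species, tissue,
        tissue_class, quantity, T_a_C, T_tissue_C, flux`` (mass basis).

    Returns
    -------
    fits, failures:
        ``fits`` has one row per successfully fitted group with columns
        ``individual_id, species, tissue, tissue_class, quantity, T_a_C,
        a, b, c, rmse, n_points, scale``.  ``failures`` enumerates groups
        that violated fit preconditions (they are reported, never silently
        dropped) with a ``reason`` column.
    """
    fit_rows: list[dict] = []
    fail_rows: list[dict] = []
    if len(records) == 0:
        cols = ["individual_id", "species", "tissue", "tissue_class", "quantity",
                "T_a_C", "a", "b", "c", "rmse", "n_points", "scale"]
        return pd.DataFrame(columns=cols), pd.DataFrame(
            columns=["individual_id", "tissue", "quantity", "reason"])

    keys = ["individual_id", "tissue", "quantity"]
    for (ind, tissue, quantity), grp in records.groupby(keys, sort=True):
        meta = grp.iloc[0]
        try:
            est = ExpQuadraticCurve(scale=scale).fit(
                grp["T_tissue_C"].to_numpy(), grp["flux"].to_numpy())
        except FitError as exc:
            fail_rows.append(dict(individual_id=ind, tissue=tissue,
                                  quantity=quantity, reason=str(exc)))
            continue
        fit_rows.append(dict(
            individual_id=ind, species=meta["species"], tissue=tissue,
            tissue_class=meta["tissue_class"], quantity=quantity,
            T_a_C=float(meta["T_a_C"]), a=est.a_, b=est.b_, c=est.c_,
            rmse=est.rmse_, n_points=est.n_points_, scale=scale,
        ))

    fits = pd.DataFrame(fit_rows)
    failures = pd.DataFrame(fail_rows, columns=["individual_id", "tissue",
                                                "quantity", "reason"])
    if len(fits):
        mean_rmse = fits.groupby("tissue")["rmse"].mean()
        for tissue, value in mean_rmse.items():
            logger.info("mean RMSE for %s: %.4g umol g-1 s-1", tissue, value)
    if len(failures):
        logger.warning("%d group(s) failed curve-fit preconditions", len(failures))
    return fits, failures
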