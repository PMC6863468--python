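"""Mixed-model ANCOVA of temperature-response parameters.

Each fitted curve parameter (a, b or c — or the log respiration-to-V_cmax
ratio) is regressed on species (categorical), acclimation temperature T_a
(continuous), tissue class (leaf, photosynthetic stem, non-photosynthetic
stem, root) and the T_a x tissue-class interaction, with a random intercept
per individual (tissues of one plant share an individual effect).
Estimation is restricted maximum likelihood via ``statsmodels`` MixedLM.

On top of the fitted model the module provides

* type-II Wald chi-square tests per model term (the convention of R's
  ``car::Anova``: each term is tested after all others, with terms that
  contain it handled by projecting onto the orthogonal complement of their
  coefficients under the fixed-effect covariance);
* least-squares-mean trends: the marginal slope and intercept of the
  parameter versus T_a per tissue class, averaging species levels with
  equal weights, with Satterthwaite degrees of freedom;
* a planned contrast of photosynthetic versus non-photosynthetic slopes;
* species marginal means with Tukey-adjusted pairwise comparisons.

Satterthwaite df are computed from the REML variance components: for a
contrast l, df = 2 (l'Cl)^2 / Var(l'Cl), with C = (X'V^-1 X)^-1, the
gradient of l'Cl taken with respect to (tau^2, sigma^2) and their
asymptotic covariance from the inverse REML Fisher information.  This is
the standard small-sample approximation; the Kenward-Roger variant used by
some R workflows shifts df and p slightly but not estimates or SEs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import ConvergenceError, SingularDesignError
from .synthetic import TISSUE_CLASSES4

logger = logging.getLogger(__name__)

PS_CLASSES = ("leaf", "ps_stem")
NONPS_CLASSES = ("nonps_stem", "root")


@dataclass(frozen=True)
class TrendEstimate:
    """Marginal slope (and intercept) of a parameter versus T_a for one
    tissue class; ``t = slope/se`` with Satterthwaite (or residual) df."""

    tissue_class4: str
    parameter: str
    slope: float
    intercept: float
    se: float
    df: float
    t: float
    p: float


@dataclass(frozen=True)
class ContrastResult:
    """Difference of group-mean slopes (photosynthetic - non-photosynthetic)."""

    estimate: float
    se: float
    df: float
    t: float
    p: float


def assemble_parameter_table(fits: pd.DataFrame,
                             metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    """Reshape a curve-fit table into long (individual, tissue, parameter) rows.

    ``fits`` is the output of :func:`rdacclim.curves.fit_all_individuals`.
    If ``fits`` lacks the grouping metadata (species, tissue_class, T_a_C),
    supply ``metadata`` keyed by ``individual_id``; fits without metadata
    raise a ``KeyError`` naming the orphans.
    """
    needed = ["species", "tissue_class", "T_a_C"]
    if metadata is not None:
        meta = metadata.set_index("individual_id") if "individual_id" in metadata else metadata
        missing = [i for i in fits["individual_id"].unique() if i not in meta.index]
        if missing:
            raise KeyError(f"fits without metadata for individuals: {missing}")
        fits = fits.drop(columns=[c for c in needed if c in fits], errors="ignore")
        fits = fits.join(meta[needed], on="individual_id")
    for col in needed:
        if col not in fits.columns:
            raise KeyError(f"fits table missing column {col!r}; pass metadata")

    if len(fits) == 0:
        return pd.DataFrame(columns=["individual_id", "species", "tissue",
                                     "tissue_class4", "T_a_C", "parameter", "value"])

    long = fits.melt(
        id_vars=["individual_id", "species", "tissue", "tissue_class", "T_a_C"],
        value_vars=["a", "b", "c"], var_name="parameter", value_name="value")
    long["tissue_class4"] = np.where(
        long["tissue"] == "stem",
        np.where(long["tissue_class"] == "photosynthetic", "ps_stem", "nonps_stem"),
        long["tissue"],
    )
    cols = ["individual_id", "species", "tissue", "tissue_class4", "T_a_C",
            "parameter", "value"]
    return long[cols].sort_values(
        ["parameter", "individual_id", "tissue"]).reset_index(drop=True)


class AcclimationAncova(BaseEstimator):
    """Mixed-model ANCOVA of one response parameter on species, T_a,
    tissue class and the T_a x tissue-class interaction.

    Parameters
    ----------
    df_method:
        ``"satterthwaite"`` (default) or ``"residual"`` (n - rank(X)).
    reml:
        Restricted maximum likelihood (default) or ML.

    Attributes (after ``fit``)
    --------------------------
    result_ : statsmodels MixedLMResults
    fe_params_ : pd.Series          fixed effects
    cov_fe_ : np.ndarray            (X' V^-1 X)^-1 at the REML estimates
    tau2_, sigma2_ : float          random-intercept and residual variances
    """

    def __init__(self, df_method: str = "satterthwaite", reml: bool = True):
        self.df_method = df_method
        self.reml = reml

    # ------------------------------------------------------------------
    def fit(self, records: pd.DataFrame, parameter: str | None = None
            ) -> "AcclimationAncova":
        """Fit the model to a long parameter table.

        ``records`` needs columns ``individual_id, species, tissue_class4,
        T_a_C, value`` (or ``parameter``/``value`` long format together with
        the ``parameter`` argument to select one response).
        """
        data = records.copy()
        if parameter is not None and "parameter" in data.columns:
            data = data[data["parameter"] == parameter]
        if len(data) == 0:
            raise ValueError("no records to fit")
        self.parameter_ = parameter or (
            data["parameter"].iloc[0] if "parameter" in data.columns else "value")

        d = pd.DataFrame({
            "value": data["value"].to_numpy(float),
            "species": data["species"].astype(str).to_numpy(),
            "T_a": data["T_a_C"].to_numpy(float),
            "tissue_class4": data["tissue_class4"].astype(str).to_numpy(),
            "individual": data["individual_id"].astype(str).to_numpy(),
        })
        if d["T_a"].nunique() < 2:
            raise SingularDesignError("T_a does not vary")
        for tc, grp in d.groupby("tissue_class4"):
            if grp["T_a"].nunique() < 2:
                raise SingularDesignError(
                    f"tissue class {tc!r} observed at a single T_a level")

        self.species_levels_ = sorted(d["species"].unique())
        present = set(d["tissue_class4"].unique())
        self.tissue_levels_ = [t for t in TISSUE_CLASSES4 if t in present]
        self.tissue_levels_ += sorted(present - set(TISSUE_CLASSES4))

        pieces = []
        if len(self.species_levels_) > 1:
            pieces.append("species")
        pieces.append("T_a")
        if len(self.tissue_levels_) > 1:
            pieces += ["tissue_class4", "T_a:tissue_class4"]
        formula = "value ~ " + " + ".join(pieces)

        y, X = patsy.dmatrices(formula, d, return_type="dataframe")
        self.design_info_ = X.design_info
        self.exog_names_ = list(X.columns)
        Xa = np.asarray(X, dtype=float)
        ya = np.asarray(y, dtype=float).ravel()
        if np.linalg.matrix_rank(Xa) < Xa.shape[1]:
            raise SingularDesignError("fixed-effect design matrix is rank deficient")

        groups, self.group_labels_ = pd.factorize(d["individual"])
        # standardise the response for numerical conditioning only; all
        # estimates are rescaled back (Wald, t and df are scale invariant)
        y_scale = float(np.std(ya))
        if not np.isfinite(y_scale) or y_scale == 0:
            y_scale = 1.0
        model = sm.MixedLM(ya / y_scale, Xa, groups=groups)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = None
            last_exc: Exception | None = None
            for method in (["lbfgs"], ["bfgs"], ["cg"], ["powell"]):
                try:
                    candidate = model.fit(reml=self.reml, method=method)
                except Exception as exc:  # noqa: BLE001 - retried, then surfaced
                    last_exc = exc
                    continue
                if candidate.converged:
                    result = candidate
                    break
            if result is None:
                raise ConvergenceError(
                    "mixed-model estimation did not converge"
                    + (f" ({last_exc})" if last_exc is not None else ""),
                    diagnostics={"formula": formula, "n": len(d)})

        self.result_ = result
        self.formula_ = formula
        self.data_ = d
        self.X_ = Xa
        self.y_ = ya
        self.groups_ = groups
        self.fe_params_ = pd.Series(np.asarray(result.fe_params) * y_scale,
                                    index=self.exog_names_)
        self.tau2_ = float(np.asarray(result.cov_re)[0, 0]) * y_scale ** 2
        self.sigma2_ = float(result.scale) * y_scale ** 2
        self._prepare_inference()
        return self

    # ------------------------------------------------------------------
    # variance machinery

    def _prepare_inference(self):
        n, p = self.X_.shape
        self.n_obs_, self.n_fe_ = n, p
        # group indicator matrix (n x q)
        q = self.groups_.max() + 1
        Z = np.zeros((n, q))
        Z[np.arange(n), self.groups_] = 1.0
        self._Z = Z
        sigma2 = max(self.sigma2_, 1e-12)
        tau2 = max(self.tau2_, 0.0)
        V = sigma2 * np.eye(n) + tau2 * (Z @ Z.T)
        Vinv = np.linalg.inv(V)
        XtVinv = self.X_.T @ Vinv
        self.cov_fe_ = np.linalg.inv(XtVinv @ self.X_)
        self._Vinv = Vinv
        self._VinvX = Vinv @ self.X_
        # REML projection P = Vinv - Vinv X C X' Vinv
        P = Vinv - self._VinvX @ self.cov_fe_ @ self._VinvX.T
        self._P = P
        # Fisher information of (tau2, sigma2): I_jk = 0.5 tr(P Vj P Vk)
        PZ = P @ Z
        A11 = float(np.sum((Z.T @ PZ) ** 2))          # tr(P J P J), J = ZZ'
        A12 = float(np.sum(PZ * PZ))                  # tr(P J P)
        A22 = float(np.sum(P * P))                    # tr(P P)
        info = 0.5 * np.array([[A11, A12], [A12, A22]])
        self._theta_cov = np.linalg.pinv(info)
        self.residual_df_ = float(n - p)

    def _contrast_var_df(self, l: np.ndarray) -> tuple[float, float]:
        """Variance of l'beta and its degrees of freedom."""
        l = np.asarray(l, dtype=float).ravel()
        var = float(l @ self.cov_fe_ @ l)
        if self.df_method == "residual":
            return var, self.residual_df_
        # Satterthwaite: df = 2 var^2 / Var(var)
        w = self._VinvX @ (self.cov_fe_ @ l)
        g = -np.array([float(np.sum((self._Z.T @ w) ** 2)), float(w @ w)])
        denom = float(g @ self._theta_cov @ g)
        if denom <= 0 or not np.isfinite(denom) or var <= 0:
            return var, self.residual_df_
        df = 2.0 * var * var / denom
        return var, float(np.clip(df, 1.0, 1e8))

    # ------------------------------------------------------------------
    # design rows for marginal quantities

    def _rows(self, species, t_a, tissue) -> np.ndarray:
        nd = pd.DataFrame({"species": [species], "T_a": [float(t_a)],
                           "tissue_class4": [tissue]})
        (m,) = patsy.build_design_matrices([self.design_info_], nd)
        return np.asarray(m, dtype=float)[0]

    def _avg_species_row(self, t_a: float, tissue: str) -> np.ndarray:
        rows = [self._rows(sp, t_a, tissue) for sp in self.species_levels_]
        return np.mean(rows, axis=0)

    def _slope_vector(self, tissue: str) -> np.ndarray:
        return self._avg_species_row(1.0, tissue) - self._avg_species_row(0.0, tissue)

    # ------------------------------------------------------------------
    # public inference

    def wald_table(self) -> pd.DataFrame:
        """Type-II Wald chi-square per fixed-effect term."""
        di = self.design_info_
        beta = self.fe_params_.to_numpy()
        p = len(beta)
        I_p = np.eye(p)
        term_names = [t for t in di.term_name_slices if t != "Intercept"]
        factors = {name: {f.name() for f in term.factors}
                   for name, term in zip(di.term_names, di.terms)}
        rows = []
        for name in term_names:
            own = list(range(*di.term_name_slices[name].indices(p)))
            rel_idx: list[int] = []
            for other in term_names:
                if other != name and factors[name] < factors[other]:
                    rel_idx += list(range(*di.term_name_slices[other].indices(p)))
            if not rel_idx:
                L = I_p[own, :]
            else:
                # orthogonal complement of the relatives' coefficients within
                # span(relatives + term), under the fixed-effect covariance
                Xc = I_p[:, rel_idx]
                Zc = I_p[:, rel_idx + own]
                M = Zc.T @ self.cov_fe_ @ Xc
                Q, _ = np.linalg.qr(M, mode="complete")
                rank = np.linalg.matrix_rank(M)
                L = (Zc @ Q[:, rank:]).T
            df = int(np.linalg.matrix_rank(L))
            Lb = L @ beta
            mid = L @ self.cov_fe_ @ L.T
            chisq = float(Lb @ np.linalg.solve(mid, Lb))
            rows.append(dict(term=name.replace("tissue_class4", "tissue"),
                             df=df, chisq=chisq, p=float(stats.chi2.sf(chisq, df))))
        return pd.DataFrame(rows)

    def lsm_trends(self) -> pd.DataFrame:
        """Least-squares-mean slope and intercept of the response versus T_a
        per tissue class (species averaged with equal weights)."""
        beta = self.fe_params_.to_numpy()
        rows = []
        for tissue in self.tissue_levels_:
            l_slope = self._slope_vector(tissue)
            l_icpt = self._avg_species_row(0.0, tissue)
            slope = float(l_slope @ beta)
            var, df = self._contrast_var_df(l_slope)
            se = float(np.sqrt(var))
            t = slope / se if se > 0 else np.nan
            p = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(t) else np.nan
            rows.append(dict(tissue_class4=tissue, parameter=self.parameter_,
                             slope=slope, intercept=float(l_icpt @ beta),
                             se=se, df=df, t=t, p=p))
        return pd.DataFrame(rows)

    def trend_estimates(self) -> list[TrendEstimate]:
        return [TrendEstimate(**row) for row in self.lsm_trends().to_dict("records")]

    def planned_contrast(self,
                         ps: Sequence[str] = PS_CLASSES,
                         nonps: Sequence[str] = NONPS_CLASSES) -> ContrastResult:
        """Photosynthetic minus non-photosynthetic mean of the per-tissue
        T_a slopes (unweighted group means)."""
        ps = [t for t in ps if t in self.tissue_levels_]
        nonps = [t for t in nonps if t in self.tissue_levels_]
        if not ps or not nonps:
            raise ValueError("both contrast groups must be non-empty")
        l = (np.mean([self._slope_vector(t) for t in ps], axis=0)
             - np.mean([self._slope_vector(t) for t in nonps], axis=0))
        beta = self.fe_params_.to_numpy()
        est = float(l @ beta)
        var, df = self._contrast_var_df(l)
        se = float(np.sqrt(var))
        t = est / se if se > 0 else 0.0
        return ContrastResult(estimate=est, se=se, df=df, t=t,
                              p=float(2.0 * stats.t.sf(abs(t), df)))

    def species_marginal_means(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Model-predicted mean per species (tissue classes averaged with
        equal weights, T_a at its observed mean) and Tukey-adjusted pairwise
        comparisons."""
        beta = self.fe_params_.to_numpy()
        ta_bar = float(self.data_["T_a"].mean())
        vecs = {}
        for sp in self.species_levels_:
            rows = [self._rows(sp, ta_bar, t) for t in self.tissue_levels_]
            vecs[sp] = np.mean(rows, axis=0)
        means = pd.DataFrame({
            "species": self.species_levels_,
            "mean": [float(vecs[sp] @ beta) for sp in self.species_levels_],
        })
        k = len(self.species_levels_)
        pair_rows = []
        for i in range(k):
            for j in range(i + 1, k):
                s1, s2 = self.species_levels_[i], self.species_levels_[j]
                l = vecs[s1] - vecs[s2]
                est = float(l @ beta)
                var, df = self._contrast_var_df(l)
                se = float(np.sqrt(var))
                t = est / se if se > 0 else 0.0
                if k > 1 and se > 0:
                    p = float(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df))
                else:
                    p = 1.0
                pair_rows.append(dict(species_1=s1, species_2=s2, estimate=est,
                                      se=se, df=df, t=t, p_tukey=min(1.0, p)))
        return means, pd.DataFrame(pair_rows)


# ----------------------------------------------------------------------
# functional wrappers


def fit_mixed_ancova(records: pd.DataFrame, response_parameter: str | None = None,
                     df_method: str = "satterthwaite") -> AcclimationAncova:
    """Fit the mixed-model ANCOVA for one response parameter."""
    return AcclimationAncova(df_method=df_method).fit(records, response_parameter)


def wald_type2(fit: AcclimationAncova) -> pd.DataFrame:
    return fit.wald_table()


def lsm_trends(fit: AcclimationAncova) -> pd.DataFrame:
    return fit.lsm_trends()


def planned_contrast(fit: AcclimationAncova,
                     ps: Sequence[str] = PS_CLASSES,
                     nonps: Sequence[str] = NONPS_CLASSES) -> ContrastResult:
    return fit.planned_contrast(ps=ps, nonps=nonps)


def species_marginal_means(fit: AcclimationAncova) -> tuple[pd.DataFrame, pd.DataFrame]:
    return fit.species_marginal_means()
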