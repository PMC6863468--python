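"""Synthetic study generator with stored ground truth.

Emulates the structure of the experiment the analysis assumes: eight species
grown at ~25 deg C, acclimated for 7 days to one of five temperatures
(15-35 deg C), then measured for dark respiration of up to three tissues
(leaf, stem, root) at tissue temperatures near {14, 23, 32, 41, ~45} deg C,
with an optional leaf V_cmax temperature series per individual.

Each individual x tissue follows the exponential-quadratic response

    R(T) = exp(a_i + b_i*T + c_i*T**2)

whose parameters drift linearly in the acclimation temperature T_a at
tissue-class-specific rates.  Species and individual effects enter the basal
parameter ``a`` only (in the motivating experiment only the basal rate
differed among species); measurement noise is multiplicative lognormal,
which keeps simulated fluxes positive and log-scale fitting well posed.

Randomness is organised as independent substreams derived from one master
seed: each (purpose, individual, tissue) triple gets its own
``SeedSequence([seed, purpose, i, j])``, so adding tissues or individuals
never perturbs other draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError

TISSUE_CLASSES4 = ("leaf", "ps_stem", "nonps_stem", "root")

# substream purpose tags for seed derivation
_PURPOSE_SPECIES = 1
_PURPOSE_INDIVIDUAL = 2
_PURPOSE_NOISE = 3
_PURPOSE_TOPTEMP = 4
_PURPOSE_VCMAX = 5
_PURPOSE_TRUTH = 6

#: per-species-per-T_a replication of the motivating study's sampling design,
#: for dark respiration and (second element) the paired V_cmax series.
#: T_a levels are 15, 20, 25, 30, 35 deg C.  Stem respiration was not
#: measured for Zea mays (stems too thick for the cuvette).
TABLE1_COUNTS: dict[str, tuple[tuple[int, ...], tuple[int, ...]]] = {
    "Betula alleghaniensis": ((1, 3, 0, 3, 1), (1, 3, 0, 3, 1)),
    "Cucumis sativa": ((3, 2, 1, 1, 2), (3, 2, 1, 1, 2)),
    "Glycine max": ((5, 2, 1, 6, 1), (2, 0, 1, 6, 1)),
    "Pinus nigra": ((2, 3, 3, 2, 2), (2, 3, 2, 2, 2)),
    "Pinus pinaster": ((1, 1, 3, 2, 4), (1, 1, 1, 2, 4)),
    "Pinus pinea": ((1, 1, 2, 1, 0), (1, 1, 2, 1, 0)),
    "Pinus sylvestris": ((1, 1, 2, 3, 3), (1, 1, 2, 3, 3)),
    "Zea mays": ((3, 2, 2, 4, 3), (3, 2, 1, 0, 0)),
}

#: herbaceous crops carry green (photosynthetic) stems; woody species do not
_PS_STEM_SPECIES = frozenset({"Cucumis sativa", "Glycine max", "Zea mays"})

TA_LEVELS_DEFAULT = (15.0, 20.0, 25.0, 30.0, 35.0)


@dataclass(frozen=True)
class DesignSpec:
    """Sampling design: who is measured, at which acclimation temperature."""

    species_names: tuple[str, ...]
    ta_levels: tuple[float, ...]
    replication: Mapping[tuple[str, float], int]
    tissue_plan: Mapping[str, tuple[str, ...]]
    tissue_class_map: Mapping[tuple[str, str], str]
    vcmax_replication: Mapping[tuple[str, float], int] | None = None
    seed: int = 0

    def __post_init__(self):
        if len(self.ta_levels) == 0:
            raise DesignError("ta_levels must be non-empty")
        if not all(b > a for a, b in zip(self.ta_levels, self.ta_levels[1:])):
            raise DesignError("ta_levels must be strictly increasing")
        for key, n in self.replication.items():
            if n < 0:
                raise DesignError(f"negative count for {key}")
            if key[0] not in self.tissue_plan:
                raise DesignError(f"species {key[0]!r} missing from tissue_plan")

    @property
    def n_individuals(self) -> int:
        return int(sum(self.replication.values()))

    def tissue_class4(self, species: str, tissue: str) -> str:
        """Four-level tissue class: leaf, ps_stem, nonps_stem or root."""
        if tissue == "stem":
            cls = self.tissue_class_map[(species, tissue)]
            return "ps_stem" if cls == "photosynthetic" else "nonps_stem"
        return tissue


def make_design(
    preset: str | None = "table1",
    *,
    species: Sequence[str] | None = None,
    ta_levels: Sequence[float] = TA_LEVELS_DEFAULT,
    n_per_cell: int = 2,
    replication: Mapping[tuple[str, float], int] | None = None,
    tissue_plan: Mapping[str, Sequence[str]] | None = None,
    tissue_class_map: Mapping[tuple[str, str], str] | None = None,
    seed: int = 0,
) -> DesignSpec:
    """Build a :class:`DesignSpec`.

    ``preset="table1"`` reproduces the motivating study's per-cell counts
    (84 individuals over 8 species x 5 acclimation temperatures, no Zea mays
    stems).  ``preset="balanced"`` builds ``species x ta_levels`` cells with
    ``n_per_cell`` individuals each.  ``preset=None`` requires explicit
    ``replication``.
    """
    ta_levels = tuple(float(t) for t in ta_levels)

    if preset == "table1":
        ta_levels = TA_LEVELS_DEFAULT
        rep: dict[tuple[str, float], int] = {}
        vrep: dict[tuple[str, float], int] = {}
        plan: dict[str, tuple[str, ...]] = {}
        cmap: dict[tuple[str, str], str] = {}
        for sp, (counts, vcounts) in TABLE1_COUNTS.items():
            for ta, n, nv in zip(ta_levels, counts, vcounts):
                rep[(sp, ta)] = n
                vrep[(sp, ta)] = nv
            tissues = ["leaf", "stem", "root"]
            if sp == "Zea mays":
                tissues.remove("stem")
            plan[sp] = tuple(tissues)
            cmap[(sp, "leaf")] = "photosynthetic"
            cmap[(sp, "root")] = "non_photosynthetic"
            if "stem" in tissues:
                cmap[(sp, "stem")] = (
                    "photosynthetic" if sp in _PS_STEM_SPECIES else "non_photosynthetic"
                )
        return DesignSpec(tuple(TABLE1_COUNTS), ta_levels, rep, plan, cmap,
                          vcmax_replication=vrep, seed=seed)

    if preset == "balanced":
        if species is None:
            species = [f"species_{i + 1}" for i in range(2)]
        species = tuple(species)
        rep = {(sp, ta): int(n_per_cell) for sp in species for ta in ta_levels}
        if tissue_plan is None:
            tissue_plan = {sp: ("leaf", "stem", "root") for sp in species}
        plan = {sp: tuple(ts) for sp, ts in tissue_plan.items()}
        if tissue_class_map is None:
            tissue_class_map = {}
            for sp, tissues in plan.items():
                for t in tissues:
                    tissue_class_map[(sp, t)] = (
                        "photosynthetic" if t == "leaf" else "non_photosynthetic"
                    )
        return DesignSpec(species, ta_levels, rep, plan, dict(tissue_class_map),
                          seed=seed)

    if preset is None:
        if replication is None or tissue_plan is None or tissue_class_map is None:
            raise DesignError(
                "custom designs need replication, tissue_plan and tissue_class_map")
        species = tuple(sorted({sp for sp, _ in replication}))
        plan = {sp: tuple(ts) for sp, ts in tissue_plan.items()}
        return DesignSpec(species, ta_levels, dict(replication), plan,
                          dict(tissue_class_map), seed=seed)

    raise DesignError(f"unknown design preset {preset!r}")


# ----------------------------------------------------------------------
# ground-truth parameters


def _anchored(value_at_25: float, slope: float) -> tuple[float, float]:
    """(intercept at T_a = 0, slope) from a value anchored at T_a = 25."""
    return (value_at_25 - 25.0 * slope, slope)


def default_trends() -> dict[str, dict[str, tuple[float, float]]]:
    """Default generating trends: (intercept, slope) of each curve parameter
    as a linear function of T_a, per tissue class.

    Anchors at T_a = 25 deg C: a = -6.5 (ln umol g-1 s-1), b = 0.10 deg C-1,
    c = -0.0005 deg C-2 for every tissue.  Photosynthetic tissues do not
    acclimate (zero slopes); non-photosynthetic tissues shift b and c with
    T_a at the magnitudes the motivating experiment estimated
    (b: -0.005 deg C-1 per deg C; c: ~ +9e-5 deg C-2 per deg C).
    """
    slopes = {
        "leaf": dict(a=0.0, b=0.0, c=0.0),
        "ps_stem": dict(a=0.0, b=0.0, c=0.0),
        "nonps_stem": dict(a=0.0, b=-0.005, c=0.000083),
        "root": dict(a=0.0, b=-0.005, c=0.000094),
    }
    return {
        tissue: {
            "a": _anchored(-6.5, s["a"]),
            "b": _anchored(0.10, s["b"]),
            "c": _anchored(-0.0005, s["c"]),
        }
        for tissue, s in slopes.items()
    }


def default_vcmax_trends() -> dict[str, tuple[float, float]]:
    """Leaf V_cmax (per gram) generating trends: same curve shape as leaf
    respiration, basal level set so that R_d/V_cmax at 25 deg C is ~0.025,
    within the range the motivating experiment reported across species."""
    return {"a": _anchored(-2.8, 0.0), "b": _anchored(0.10, 0.0),
            "c": _anchored(-0.0005, 0.0)}


@dataclass(frozen=True)
class TrueParameters:
    """Generating truth: per-tissue-class linear trends of (a, b, c) in T_a,
    variance components and the measurement-temperature grid."""

    trends: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=default_trends)
    vcmax_trends: Mapping[str, tuple[float, float]] = field(
        default_factory=default_vcmax_trends)
    species_offset_sd: float = 0.5
    individual_offset_sd: float = 0.2
    noise_sd_log: float = 0.15
    temp_grid: tuple[float, ...] = (14.0, 23.0, 32.0, 41.0, 45.0)
    top_temp_jitter_sd: float = 0.5

    def __post_init__(self):
        for name in ("species_offset_sd", "individual_offset_sd",
                     "noise_sd_log", "top_temp_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if len(self.temp_grid) < 4:
            raise ValueError("temp_grid needs >= 4 points")

    def params_at(self, tissue_class4: str, t_acclim: float) -> tuple[float, float, float]:
        tr = self.trends[tissue_class4]
        return tuple(tr[p][0] + tr[p][1] * t_acclim for p in ("a", "b", "c"))

    def vcmax_params_at(self, t_acclim: float) -> tuple[float, float, float]:
        return tuple(self.vcmax_trends[p][0] + self.vcmax_trends[p][1] * t_acclim
                     for p in ("a", "b", "c"))


@dataclass(frozen=True)
class TrueParameterConfig:
    """Means and dispersion used by :func:`draw_true_parameters`.

    ``intercept_sd`` / ``slope_sd`` jitter the trend coefficients around
    their means (both default to 0, i.e. the means are returned exactly);
    the remaining fields pass through to :class:`TrueParameters`.
    """

    mean_trends: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=default_trends)
    mean_vcmax_trends: Mapping[str, tuple[float, float]] = field(
        default_factory=default_vcmax_trends)
    intercept_sd: float = 0.0
    slope_sd: float = 0.0
    species_offset_sd: float = 0.5
    individual_offset_sd: float = 0.2
    noise_sd_log: float = 0.15
    temp_grid: tuple[float, ...] = (14.0, 23.0, 32.0, 41.0, 45.0)
    top_temp_jitter_sd: float = 0.5

    def __post_init__(self):
        if self.intercept_sd < 0 or self.slope_sd < 0:
            raise ValueError("sd values must be >= 0")
        for tissue, tr in self.mean_trends.items():
            for p, (icpt, slope) in tr.items():
                if not (np.isfinite(icpt) and np.isfinite(slope)):
                    raise ValueError(f"non-finite mean trend for {tissue}/{p}")


def draw_true_parameters(config: TrueParameterConfig | None = None,
                         seed: int = 0) -> TrueParameters:
    """Draw a :class:`TrueParameters` around the configured means.

    Deterministic given ``seed``; with zero ``intercept_sd`` and
    ``slope_sd`` the configured means are returned exactly.
    """
    if config is None:
        config = TrueParameterConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, _PURPOSE_TRUTH]))
    trends = {}
    for tissue, tr in config.mean_trends.items():
        trends[tissue] = {
            p: (icpt + (config.intercept_sd and rng.normal(0.0, config.intercept_sd)),
                slope + (config.slope_sd and rng.normal(0.0, config.slope_sd)))
            for p, (icpt, slope) in tr.items()
        }
    return TrueParameters(
        trends=trends,
        vcmax_trends=dict(config.mean_vcmax_trends),
        species_offset_sd=config.species_offset_sd,
        individual_offset_sd=config.individual_offset_sd,
        noise_sd_log=config.noise_sd_log,
        temp_grid=tuple(config.temp_grid),
        top_temp_jitter_sd=config.top_temp_jitter_sd,
    )


# ----------------------------------------------------------------------
# simulation


@dataclass(frozen=True)
class GeneratedStudy:
    """Simulated measurements plus everything needed for recovery tests."""

    records: pd.DataFrame
    vcmax_records: pd.DataFrame
    truth: TrueParameters
    individual_params: pd.DataFrame  # realised (a, b, c) per individual x tissue


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def _individual_index(design: DesignSpec):
    """Stable enumeration of individuals: (index, species, T_a, id)."""
    out = []
    i = 0
    for sp in design.species_names:
        sp_tag = sp.replace(" ", "_")
        for ta in design.ta_levels:
            n = design.replication.get((sp, ta), 0)
            for k in range(n):
                out.append((i, sp, ta, f"{sp_tag}__{ta:g}C__{k + 1}"))
                i += 1
    return out


def _species_offsets(design: DesignSpec, truth: TrueParameters, seed: int):
    return {
        sp: (truth.species_offset_sd and
             float(_rng(seed, _PURPOSE_SPECIES, j).normal(0.0, truth.species_offset_sd)))
        for j, sp in enumerate(design.species_names)
    }


def simulate_measurements(design: DesignSpec, truth: TrueParameters) -> GeneratedStudy:
    """Simulate the dark-respiration measurement table for a design.

    Each record's flux is exp(a_i + b_i*T + c_i*T**2) * exp(eps) with
    eps ~ Normal(0, noise_sd_log**2); the top grid temperature is jittered
    by Normal(0, top_temp_jitter_sd) per individual x tissue.  With
    ``noise_sd_log = 0`` every point lies exactly on the generating curve.
    """
    seed = design.seed
    sp_offset = _species_offsets(design, truth, seed)
    sp_index = {sp: j for j, sp in enumerate(design.species_names)}
    grid = np.asarray(truth.temp_grid, dtype=float)
    top = int(np.argmax(grid))

    rec_rows: list[dict] = []
    par_rows: list[dict] = []
    for i, sp, ta, ind_id in _individual_index(design):
        ind_off = (truth.individual_offset_sd and
                   float(_rng(seed, _PURPOSE_INDIVIDUAL, i).normal(
                       0.0, truth.individual_offset_sd)))
        for j, tissue in enumerate(design.tissue_plan[sp]):
            tc4 = design.tissue_class4(sp, tissue)
            a0, b0, c0 = truth.params_at(tc4, ta)
            a_i = a0 + sp_offset[sp] + ind_off
            temps = grid.copy()
            if truth.top_temp_jitter_sd:
                temps[top] += float(_rng(seed, _PURPOSE_TOPTEMP, i, j).normal(
                    0.0, truth.top_temp_jitter_sd))
            mu = np.exp(a_i + b0 * temps + c0 * temps ** 2)
            if truth.noise_sd_log:
                eps = _rng(seed, _PURPOSE_NOISE, i, j).normal(
                    0.0, truth.noise_sd_log, size=temps.size)
                flux = mu * np.exp(eps)
            else:
                flux = mu
            cls2 = ("photosynthetic" if tc4 in ("leaf", "ps_stem")
                    else "non_photosynthetic")
            for T, f in zip(temps, flux):
                rec_rows.append(dict(
                    individual_id=ind_id, species=sp, tissue=tissue,
                    tissue_class=cls2, quantity="rd", T_a_C=ta,
                    T_tissue_C=float(T), flux=float(f), flux_basis="mass",
                    area_m2=np.nan, dry_mass_g=np.nan))
            par_rows.append(dict(individual_id=ind_id, species=sp,
                                 tissue=tissue, tissue_class4=tc4, T_a_C=ta,
                                 a=a_i, b=b0, c=c0))

    records = pd.DataFrame(rec_rows)
    params = pd.DataFrame(par_rows)
    vcmax = simulate_vcmax(design, truth)
    return GeneratedStudy(records=records, vcmax_records=vcmax, truth=truth,
                          individual_params=params)


def simulate_vcmax(design: DesignSpec, truth: TrueParameters) -> pd.DataFrame:
    """Simulate leaf V_cmax temperature series (per-gram units).

    Uses the same generating form and noise model as the respiration
    records, restricted to leaf-bearing individuals; per-cell counts follow
    ``design.vcmax_replication`` when given (a subset of the respiration
    individuals, matching studies where not every A/Ci curve succeeds),
    otherwise the full replication.
    """
    seed = design.seed
    vrep = design.vcmax_replication or design.replication
    grid = np.asarray(truth.temp_grid, dtype=float)
    top = int(np.argmax(grid))

    rows: list[dict] = []
    for i, sp, ta, ind_id in _individual_index(design):
        if "leaf" not in design.tissue_plan[sp]:
            continue
        # the first n_v individuals of each (species, T_a) cell carry V_cmax
        k = int(ind_id.rsplit("__", 1)[1])
        if k > vrep.get((sp, ta), 0):
            continue
        a0, b0, c0 = truth.vcmax_params_at(ta)
        temps = grid.copy()
        if truth.top_temp_jitter_sd:
            temps[top] += float(_rng(seed, _PURPOSE_VCMAX, i, 0).normal(
                0.0, truth.top_temp_jitter_sd))
        mu = np.exp(a0 + b0 * temps + c0 * temps ** 2)
        if truth.noise_sd_log:
            eps = _rng(seed, _PURPOSE_VCMAX, i, 1).normal(
                0.0, truth.noise_sd_log, size=temps.size)
            flux = mu * np.exp(eps)
        else:
            flux = mu
        for T, f in zip(temps, flux):
            rows.append(dict(
                individual_id=ind_id, species=sp, tissue="leaf",
                tissue_class="photosynthetic", quantity="vcmax", T_a_C=ta,
                T_tissue_C=float(T), flux=float(f), flux_basis="mass",
                area_m2=np.nan, dry_mass_g=np.nan))
    cols = ["individual_id", "species", "tissue", "tissue_class", "quantity",
            "T_a_C", "T_tissue_C", "flux", "flux_basis", "area_m2", "dry_mass_g"]
    return pd.DataFrame(rows, columns=cols)
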