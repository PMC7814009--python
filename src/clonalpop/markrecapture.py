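"""Closed-population abundance estimation from multi-day trap surveys.

Implements the Schnabel multi-census estimator

    N_hat = sum_t(C_t * M_t) / sum_t(R_t)

with C_t the day-t catch, M_t the marked animals at large before day t and
R_t the day-t recaptures, a saturating (asymptotic-regression) fit of the
cumulative marking curve y = a (1 - exp(-c x)), a bathymetry-stratified
extrapolation from sexually mature (trappable) animals to the whole
population, and a parametric/resampling bootstrap that combines the
component uncertainties into one standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "TrapSurvey",
    "Stratum",
    "Strata",
    "HandCatch",
    "AbundanceEstimate",
    "SaturationFit",
    "schnabel",
    "fit_saturation",
    "stratified_total",
    "bootstrap_se",
    "ZeroRecaptureError",
    "SaturationFitError",
]

SURVEY_COLUMNS = ["day", "trap_id", "stratum_id", "catch", "new_marks", "recaptures"]

#: size above which an animal is retained by the traps (cm)
MATURE_SIZE_CUTOFF_CM = 6.0


class ZeroRecaptureError(ValueError):
    """No recaptures: the Schnabel ratio is undefined.

    Use ``schnabel(..., chapman=True)`` for the +1-corrected variant, which
    stays finite without recaptures.
    """


class SaturationFitError(RuntimeError):
    pass


@dataclass
class TrapSurvey:
    """Per-day, per-trap catch records of a closed-population survey.

    ``data`` has columns day, trap_id, stratum_id, catch, new_marks,
    recaptures. Marks persist across days; day indices start at 1.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SURVEY_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"survey table missing columns {missing}")
        if (self.data[["catch", "new_marks", "recaptures"]] < 0).any().any():
            raise ValueError("counts must be nonnegative")

    @classmethod
    def from_csv(cls, path) -> "TrapSurvey":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def daily(self) -> pd.DataFrame:
        """Pool traps: per-day totals C_t, R_t, new marks, and M_t.

        M_t is the number of marked animals at large before day t
        (cumulative new marks through day t-1).
        """
        agg = (
            self.data.groupby("day")[["catch", "new_marks", "recaptures"]]
            .sum()
            .sort_index()
        )
        agg["marked_at_large"] = agg["new_marks"].cumsum().shift(1, fill_value=0)
        bad = agg["recaptures"] > np.minimum(agg["catch"], agg["marked_at_large"])
        if bad.any():
            raise ValueError(
                f"recaptures exceed min(catch, marked at large) on days "
                f"{list(agg.index[bad])}"
            )
        return agg

    def per_trap_catch(self) -> pd.DataFrame:
        """Total catch per trap with its stratum label."""
        return (
            self.data.groupby(["trap_id", "stratum_id"])["catch"]
            .sum()
            .reset_index()
        )


@dataclass(frozen=True)
class Stratum:
    stratum_id: str
    depth_range: str  # e.g. "<=4m"
    area_m2: float
    n_traps: int

    @property
    def area_per_trap(self) -> float:
        if self.n_traps == 0:
            raise ValueError(f"stratum {self.stratum_id} has no traps")
        return self.area_m2 / self.n_traps


@dataclass
class Strata:
    strata: list[Stratum]
    area_se_fraction: float = 0.10  # assumed relative SE of trap areas

    @property
    def total_area(self) -> float:
        return sum(s.area_m2 for s in self.strata)

    def area_per_trap(self) -> dict[str, float]:
        return {s.stratum_id: s.area_per_trap for s in self.strata}

    @property
    def n_traps(self) -> int:
        return sum(s.n_traps for s in self.strata)


def lake_reilingen_strata() -> Strata:
    """Bathymetric strata of the surveyed lake: depth bands, areas, traps."""
    return Strata(
        [
            Stratum("shallow", "<=4m", 47_500.0, 10),
            Stratum("mid", "5-10m", 16_000.0, 4),
            Stratum("deep", ">10m", 29_000.0, 4),
        ]
    )


@dataclass(frozen=True)
class AbundanceEstimate:
    n_hat: float
    se: float
    components: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_hat <= 0:
            raise ValueError("abundance estimate must be positive")
        if self.se < 0:
            raise ValueError("SE must be nonnegative")


def schnabel(survey: TrapSurvey, chapman: bool = False) -> AbundanceEstimate:
    """Schnabel multi-census estimate with Poisson-recapture SE.

    Traps are pooled into one closed population. The SE treats the total
    recapture count as Poisson and propagates it through the ratio:
    SE = N_hat / sqrt(sum R_t). ``chapman=True`` applies the +1 correction
    to the denominator (finite even with zero recaptures).
    """
    daily = survey.daily()
    if len(daily) < 2:
        raise ValueError("need at least 2 survey days")
    num = float((daily["catch"] * daily["marked_at_large"]).sum())
    total_r = float(daily["recaptures"].sum())
    if chapman:
        n_hat = num / (total_r + 1.0)
    else:
        if total_r < 1:
            raise ZeroRecaptureError(
                "no recaptures observed; rerun with chapman=True"
            )
        n_hat = num / total_r
    se = n_hat / np.sqrt(max(total_r, 1.0))
    return AbundanceEstimate(
        n_hat=n_hat,
        se=se,
        components={
            "sum_CM": num,
            "sum_R": total_r,
            "estimator": "chapman" if chapman else "schnabel",
            "se_method": "poisson-on-recaptures",
        },
    )


@dataclass(frozen=True)
class SaturationFit:
    a: float  # asymptote, animals
    c: float  # rate, per day
    se_a: float
    se_c: float
    rss: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.a * (1.0 - np.exp(-self.c * np.asarray(x, dtype=float)))


def _saturation(x, a, c):
    return a * (1.0 - np.exp(-c * x))


def fit_saturation(x, y, max_iterations: int = 10_000) -> SaturationFit:
    """Least-squares fit of the marking-saturation curve y = a(1 - e^{-cx}).

    Initialization: a0 = 1.2 * max(y); c0 from a two-point
    log-linearization of 1 - y/a0 at the first and last points. Parameter
    SEs come from the Jacobian-based covariance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points to fit two parameters")
    if np.any(np.diff(y) < 0):
        raise ValueError("cumulative marking curve must be nondecreasing")
    a0 = 1.2 * float(y.max())
    frac = np.clip(1.0 - y / a0, 1e-12, None)
    with np.errstate(divide="ignore"):
        slopes = -np.log(frac) / np.where(x == 0, np.nan, x)
    c0 = float(np.nanmedian(slopes))
    if not np.isfinite(c0) or c0 <= 0:
        c0 = 1.0 / max(x.max(), 1.0)
    try:
        popt, pcov = curve_fit(
            _saturation,
            x,
            y,
            p0=(a0, c0),
            maxfev=max_iterations,
            method="trf",
            bounds=((0.0, 0.0), (np.inf, np.inf)),
        )
    except RuntimeError as exc:
        raise SaturationFitError(f"saturation fit failed: {exc}") from exc
    a_hat, c_hat = popt
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    rss = float(np.sum((y - _saturation(x, *popt)) ** 2))
    if c_hat * x.max() < 0.1:
        warnings.warn(
            "marking curve is still linear (c * x_max < 0.1): the asymptote "
            "is an extrapolation far beyond the data and poorly identified",
            stacklevel=2,
        )
    return SaturationFit(a=float(a_hat), c=float(c_hat), se_a=float(perr[0]), se_c=float(perr[1]), rss=rss)


@dataclass
class HandCatch:
    """Hand-netting observations: point densities and a size sample.

    densities_per_m2: animal densities at the hand-catch sampling points
    (all size classes). sizes_cm: measured sizes of hand-caught animals;
    the mature fraction is the share above the 6 cm trap cutoff.
    """

    densities_per_m2: np.ndarray
    sizes_cm: np.ndarray

    def __post_init__(self) -> None:
        self.densities_per_m2 = np.asarray(self.densities_per_m2, dtype=float)
        self.sizes_cm = np.asarray(self.sizes_cm, dtype=float)
        if self.sizes_cm.size == 0:
            raise ValueError("size sample is empty")

    @property
    def mature_fraction(self) -> float:
        return float(np.mean(self.sizes_cm > MATURE_SIZE_CUTOFF_CM))

    @classmethod
    def from_csv(cls, density_path, sizes_path) -> "HandCatch":
        dens = pd.read_csv(density_path)["density_per_m2"].to_numpy()
        sizes = pd.read_csv(sizes_path)["size_cm"].to_numpy()
        return cls(dens, sizes)


def stratified_total(
    mature_estimate: float,
    strata: Strata,
    hand_catch: HandCatch,
    trap_catches: pd.DataFrame | None = None,
) -> AbundanceEstimate:
    """Extrapolate a mature-animal estimate to the whole population.

    Each trap is treated as the sampling point for its stratum's
    area-per-trap. When per-trap catch totals are supplied (columns
    trap_id, stratum_id, catch), the mature estimate is area-reweighted by

        factor = sum_i catch_i * area_i / (mean_area * sum_i catch_i)

    which is a no-op when every trap covers the same area. The total is
    the (corrected) mature abundance divided by the mature fraction f of
    the hand-catch size distribution; an independent cross-check of
    hand-catch density x lake area is reported alongside.
    """
    f = hand_catch.mature_fraction
    if f <= 0:
        raise ZeroDivisionError("mature fraction is zero; cannot extrapolate")
    area_per_trap = strata.area_per_trap()
    mean_area = strata.total_area / strata.n_traps

    factor = 1.0
    if trap_catches is not None and trap_catches["catch"].sum() > 0:
        areas = trap_catches["stratum_id"].map(area_per_trap).to_numpy(dtype=float)
        catches = trap_catches["catch"].to_numpy(dtype=float)
        factor = float((catches * areas).sum() / (mean_area * catches.sum()))

    corrected_mature = mature_estimate * factor
    total = corrected_mature / f
    density_check = (
        float(np.mean(hand_catch.densities_per_m2) * strata.total_area)
        if hand_catch.densities_per_m2.size
        else np.nan
    )
    return AbundanceEstimate(
        n_hat=total,
        se=0.0,
        components={
            "mature_estimate": mature_estimate,
            "area_correction_factor": factor,
            "corrected_mature": corrected_mature,
            "mature_fraction": f,
            "area_per_trap_m2": area_per_trap,
            "hand_catch_density_total": density_check,
            "lake_area_m2": strata.total_area,
        },
    )


def bootstrap_se(
    mature_estimate: AbundanceEstimate,
    saturation: SaturationFit | None,
    strata: Strata,
    hand_catch: HandCatch,
    trap_catches: pd.DataFrame | None = None,
    n_reps: int = 10_000,
    seed: int = 0,
) -> AbundanceEstimate:
    """Combined SE of the total-population estimate by bootstrap.

    Each replicate perturbs the mature (Schnabel) estimate and the
    saturation asymptote a (normal draws with their SEs), the stratum
    areas (normal, 10% relative SE by default), and resamples the
    hand-catch sizes with replacement to vary the mature fraction.
    Nonpositive draws are rejected and redrawn; the rejection count is
    reported. The point estimate is the unperturbed stratified total.
    """
    if n_reps < 100:
        warnings.warn(f"n_reps={n_reps} < 100: bootstrap SE will be unstable", stacklevel=2)
    rng = np.random.default_rng(seed)
    point = stratified_total(mature_estimate.n_hat, strata, hand_catch, trap_catches)

    sizes = hand_catch.sizes_cm
    n_sizes = sizes.size
    rejected = 0
    totals = np.empty(n_reps)
    for rep in range(n_reps):
        while True:
            m = rng.normal(mature_estimate.n_hat, mature_estimate.se)
            if (
                saturation is not None
                and np.isfinite(saturation.se_a)
                and saturation.se_a > 0
            ):
                a = rng.normal(saturation.a, saturation.se_a)
                if a <= 0:
                    rejected += 1
                    continue
                # scale the mature estimate by the perturbed asymptote ratio
                m = m * (a / saturation.a)
            areas = np.array(
                [
                    rng.normal(s.area_m2, strata.area_se_fraction * s.area_m2)
                    for s in strata.strata
                ]
            )
            if m <= 0 or np.any(areas <= 0):
                rejected += 1
                continue
            boot_sizes = sizes[rng.integers(0, n_sizes, n_sizes)]
            f = float(np.mean(boot_sizes > MATURE_SIZE_CUTOFF_CM))
            if f <= 0:
                rejected += 1
                continue
            break
        boot_strata = Strata(
            [
                Stratum(s.stratum_id, s.depth_range, float(area), s.n_traps)
                for s, area in zip(strata.strata, areas)
            ],
            area_se_fraction=strata.area_se_fraction,
        )
        hc = HandCatch(hand_catch.densities_per_m2, boot_sizes)
        totals[rep] = stratified_total(m, boot_strata, hc, trap_catches).n_hat
    se = float(np.std(totals, ddof=1))
    components = dict(point.components)
    components.update(
        {
            "n_reps": n_reps,
            "rejected_draws": rejected,
            "schnabel_se": mature_estimate.se,
            "asymptote_se": saturation.se_a if saturation is not None else 0.0,
            "area_se_fraction": strata.area_se_fraction,
        }
    )
    return AbundanceEstimate(n_hat=point.n_hat, se=se, components=components)
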