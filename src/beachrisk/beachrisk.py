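"""Quantitative cancer-risk assessment for children playing on oil-spill-contaminated beaches.

The model estimates incremental lifetime cancer risk to young children from
contact with a polycyclic aromatic hydrocarbon (by default benzo[b]fluoranthene)
present in three beach media — sediment, weathered oil, and tarballs — via three
exposure routes:

* **oral** (non-dietary ingestion of sand),
* **dermal** (uptake through soil adhering to skin, one loading event per
  exposure day), and
* **inhalation** (suspended solid-phase particulates; no gas phase).

Each route follows the standard EPA RAGS low-dose-linear form

    risk = dose x slope factor

with route-specific average daily doses (mg/(kg*day)):

    dose_oral       = C * IRs * RBA * EF * CF / BW
    dose_dermal     = C * SA * AF * ABS * EF * CF / BW
    dose_inhalation = C * (1/PEF) * IRa * ET * EF / BW

where ``EF = F * ED / AT`` is the dimensionless exposure factor. ``ET``
(hours/day) enters the inhalation dose as a bare multiplier, without a /24
normalisation — a dimensional quirk of the published parameterisation that is
kept as-is so that published point estimates are reproduced (see
docs/methods.md).

Uncertainty in body weight, skin surface area, beach-visit frequency, and
medium concentration is propagated by plain Monte Carlo over triangular
distributions whose (min, likeliest, max) triples summarise field observations
(the likeliest value is the observed median used as a stand-in for the mode).
A synthetic-cohort generator emulates the per-child observation records such a
field study collects, and the min/median/max "plug-in" summarisation that
turns them into triangular distribution assumptions, so the entire pipeline is
testable without any external data.

Sections below, in pipeline order:

1.  module configuration (logging, display precision, defaults)
2.  domain types and validation
3.  deterministic dose/risk arithmetic and the point-risk table
4.  triangular distributions and inverse-CDF sampling
5.  Monte Carlo uncertainty propagation
6.  synthetic cohort generation, summarisation, and triangular refit
7.  scenario configuration files, bundled scenarios, report rendering
"""

from __future__ import annotations

import dataclasses
import logging
import math
import tomllib
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ROUTES",
    "MEDIA",
    "ChemicalToxicity",
    "ExposureProfile",
    "MediumConcentration",
    "RiskTable",
    "TriangularDist",
    "SimulationSpec",
    "SimulationSummary",
    "ChildObservation",
    "CohortSummary",
    "Scenario",
    "ScenarioError",
    "exposure_factor",
    "resolved_exposure_factor",
    "dose_oral",
    "dose_dermal",
    "dose_inhalation",
    "route_risk",
    "risk_table",
    "triangular_ppf",
    "sample_triangular",
    "run_simulation",
    "summarize_samples",
    "generate_cohort",
    "summarize_cohort",
    "fit_triangular",
    "write_cohort",
    "read_cohort",
    "cohort_to_frame",
    "bundled_scenarios",
    "load_scenario",
    "render_point_report",
    "render_simulation_report",
]

# --------------------------------------------------------------------------- #
# 1. Configuration
# --------------------------------------------------------------------------- #

logger = logging.getLogger("beachrisk")

#: Exposure routes, in report order.
ROUTES: tuple[str, ...] = ("oral", "dermal", "inhalation")

#: Recognised beach media, in report order.
MEDIA: tuple[str, ...] = ("sediment", "weathered_oil", "tar")

#: Default Monte Carlo iteration count.
DEFAULT_ITERATIONS: int = 1000

#: Above this lifetime risk the linear low-dose model is not credible; the
#: engine emits a warning but does not clamp (risks are never capped at 1).
RISK_WARN_THRESHOLD: float = 0.01

#: Display precision of rendered reports: 3 significant figures.
_REPORT_FORMAT = "{:.2e}"

#: Parameters that may be sampled in a Monte Carlo run.
SAMPLABLE_PARAMETERS: frozenset[str] = frozenset(
    {"body_weight", "skin_surface_area", "frequency", "concentration"}
)


def _require_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be > 0, got {value}")


def _require_nonnegative(name: str, value: float) -> None:
    if not value >= 0:
        raise ValueError(f"{name} must be >= 0, got {value}")


# --------------------------------------------------------------------------- #
# 2. Domain types
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class ChemicalToxicity:
    """Per-chemical, per-route toxicity constants.

    Parameters
    ----------
    name
        Chemical identifier, e.g. ``"benzo[b]fluoranthene"``.
    rba_oral
        Relative bioavailability of the ingested chemical in soil (fraction
        in [0, 1]).
    slope_oral, slope_dermal, slope_inhalation
        Route-specific cancer slope factors, risk per mg/(kg*day).
    abs_dermal
        Dermal absorption fraction per skin-loading event, in [0, 1].
    """

    name: str
    rba_oral: float
    slope_oral: float
    abs_dermal: float
    slope_dermal: float
    slope_inhalation: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("chemical name must be non-empty")
        for f in ("rba_oral", "slope_oral", "abs_dermal", "slope_dermal",
                  "slope_inhalation"):
            _require_nonnegative(f, getattr(self, f))
        if self.rba_oral > 1:
            raise ValueError(f"rba_oral must be <= 1, got {self.rba_oral}")
        if self.abs_dermal > 1:
            raise ValueError(f"abs_dermal must be <= 1, got {self.abs_dermal}")


@dataclass(frozen=True)
class ExposureProfile:
    """One population's complete exposure-parameter set.

    Parameters
    ----------
    body_weight
        BW, kg.
    frequency
        F, beach-visit frequency, days/year.
    duration
        ED, exposure duration, years.
    averaging_time
        AT, days; a lifetime averaging time (~78 y) for cancer endpoints.
    intake_rate_soil
        IRs, incidental soil ingestion rate, mg/day.
    conversion_factor
        CF, the mg->kg mass conversion, nominally 1e-6; applied exactly once
        in the oral and dermal doses, never in inhalation.
    skin_surface_area
        SA, exposed skin per event, cm^2.
    adherence_factor
        AF, soil adhering to skin, mg/cm^2.
    particulate_emission_factor
        PEF, soil-to-air partitioning, m^3/kg.
    inhalation_rate
        IRa, m^3/day.
    exposure_time
        ET, hours/day at the beach.
    exposure_factor_override
        Optional EF in (0, 1) that wins over ``F*ED/AT`` when set; used to
        reproduce published parameter sets whose printed EF is not consistent
        with their printed F, ED, AT.
    """

    body_weight: float
    frequency: float
    duration: float
    averaging_time: float
    intake_rate_soil: float
    conversion_factor: float
    skin_surface_area: float
    adherence_factor: float
    particulate_emission_factor: float
    inhalation_rate: float
    exposure_time: float
    exposure_factor_override: float | None = None

    def __post_init__(self) -> None:
        for f in ("body_weight", "duration", "averaging_time",
                  "intake_rate_soil", "conversion_factor", "skin_surface_area",
                  "adherence_factor", "particulate_emission_factor",
                  "inhalation_rate"):
            _require_positive(f, getattr(self, f))
        # zero visits or zero hours on the beach are valid: no exposure
        for f in ("frequency", "exposure_time"):
            _require_nonnegative(f, getattr(self, f))
        if self.frequency * self.duration > self.averaging_time:
            raise ValueError(
                "frequency * duration exceeds averaging_time "
                f"({self.frequency} * {self.duration} > {self.averaging_time})"
            )
        ef = self.exposure_factor_override
        if ef is not None and not 0 < ef < 1:
            raise ValueError(
                f"exposure_factor_override must be in (0, 1), got {ef}"
            )


@dataclass(frozen=True)
class MediumConcentration:
    """Chemical concentration (mg/kg) measured in one beach medium."""

    medium: str
    concentration: float

    def __post_init__(self) -> None:
        if self.medium not in MEDIA:
            raise ValueError(
                f"medium must be one of {MEDIA}, got {self.medium!r}"
            )
        _require_nonnegative("concentration", self.concentration)


@dataclass(frozen=True)
class RiskTable:
    """Medium x route matrix of lifetime excess cancer risks, with margins.

    ``cells[(medium, route)]`` holds the per-cell risk; ``route_totals``,
    ``medium_totals`` and ``grand_total`` are plain sums (route doses combine
    additively for aggregate exposure).
    """

    media: tuple[str, ...]
    cells: Mapping[tuple[str, str], float]
    route_totals: Mapping[str, float]
    medium_totals: Mapping[str, float]
    grand_total: float

    def to_frame(self) -> pd.DataFrame:
        """Return the table as a DataFrame (media rows + Total, route columns + total)."""
        rows = {}
        for m in self.media:
            rows[m] = {r: self.cells[(m, r)] for r in ROUTES}
            rows[m]["total"] = self.medium_totals[m]
        rows["total"] = dict(self.route_totals) | {"total": self.grand_total}
        return pd.DataFrame.from_dict(rows, orient="index")


@dataclass(frozen=True)
class TriangularDist:
    """A triangular(min, likeliest, max) distribution assumption.

    ``likeliest`` is the distribution mode; in this pipeline it is typically a
    field-data *median* standing in for the mode (the plug-in rule used to
    distil observation records into distribution assumptions).
    """

    minimum: float
    likeliest: float
    maximum: float

    def __post_init__(self) -> None:
        if not self.minimum <= self.likeliest <= self.maximum:
            raise ValueError(
                "triangular parameters must satisfy minimum <= likeliest <= "
                f"maximum, got ({self.minimum}, {self.likeliest}, {self.maximum})"
            )
        if not self.minimum < self.maximum:
            raise ValueError(
                f"degenerate triangular distribution: minimum == maximum == {self.minimum}"
            )

    # closed-form moments -- handy for users; tests check samples against
    # independent references, not against these.
    def mean(self) -> float:
        return (self.minimum + self.likeliest + self.maximum) / 3.0

    def variance(self) -> float:
        a, c, b = self.minimum, self.likeliest, self.maximum
        return (a * a + b * b + c * c - a * b - a * c - b * c) / 18.0

    def median(self) -> float:
        a, c, b = self.minimum, self.likeliest, self.maximum
        if c - a >= (b - a) / 2.0:
            return a + math.sqrt((b - a) * (c - a) / 2.0)
        return b - math.sqrt((b - a) * (b - c) / 2.0)


@dataclass(frozen=True)
class SimulationSpec:
    """Everything needed for one reproducible Monte Carlo run.

    ``distributions`` maps a subset of {body_weight, skin_surface_area,
    frequency, concentration} to triangular assumptions; parameters not
    sampled are taken from ``fixed_profile`` (and ``concentration`` from the
    fixed ``concentration`` field, which is required exactly when no
    concentration distribution is supplied).
    """

    iterations: int
    seed: int
    distributions: Mapping[str, TriangularDist]
    fixed_profile: ExposureProfile
    tox: ChemicalToxicity
    concentration: float | None = None

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError(f"iterations must be >= 1, got {self.iterations}")
        unknown = set(self.distributions) - SAMPLABLE_PARAMETERS
        if unknown:
            raise ValueError(
                f"unknown sampled parameter(s) {sorted(unknown)}; "
                f"allowed: {sorted(SAMPLABLE_PARAMETERS)}"
            )
        if ("concentration" in self.distributions) == (self.concentration is not None):
            raise ValueError(
                "supply exactly one of a concentration distribution or a "
                "fixed concentration"
            )
        if self.concentration is not None:
            _require_nonnegative("concentration", self.concentration)


@dataclass(frozen=True)
class SimulationSummary:
    """Per-route Monte Carlo summaries: mean and empirical 2.5%/97.5% quantiles.

    ``samples`` retains the per-iteration route risks (route -> 1-D array).
    """

    mean: Mapping[str, float]
    quantile_2_5: Mapping[str, float]
    quantile_97_5: Mapping[str, float]
    iterations: int
    seed: int
    samples: Mapping[str, np.ndarray] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {r: [self.mean[r], self.quantile_2_5[r], self.quantile_97_5[r]]
             for r in ROUTES},
            index=["mean", "2.5%", "97.5%"],
        )


@dataclass(frozen=True)
class ChildObservation:
    """One synthetic per-child field record."""

    child_id: str
    body_weight: float
    skin_surface_area: float
    beach_frequency: int

    def __post_init__(self) -> None:
        _require_positive("body_weight", self.body_weight)
        _require_positive("skin_surface_area", self.skin_surface_area)
        if self.beach_frequency < 1:
            raise ValueError(
                f"beach_frequency must be >= 1, got {self.beach_frequency}"
            )


@dataclass(frozen=True)
class CohortSummary:
    """Min/median/max/mean of one observed parameter over a cohort of n children."""

    parameter: str
    minimum: float
    median: float
    maximum: float
    mean: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not self.minimum <= self.median <= self.maximum:
            raise ValueError(
                "summary must satisfy minimum <= median <= maximum, got "
                f"({self.minimum}, {self.median}, {self.maximum})"
            )


class ScenarioError(ValueError):
    """A scenario file failed to parse or validate."""


@dataclass(frozen=True)
class Scenario:
    """A fully-specified, runnable risk-assessment scenario (one chemical,
    one exposure population, one set of medium concentrations, optional
    distribution assumptions for Monte Carlo)."""

    name: str
    tox: ChemicalToxicity
    media: tuple[MediumConcentration, ...]
    profile: ExposureProfile
    distributions: Mapping[str, TriangularDist] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("scenario name must be non-empty")
        unknown = set(self.distributions) - SAMPLABLE_PARAMETERS
        if unknown:
            raise ScenarioError(
                f"[distributions] has unknown parameter(s) {sorted(unknown)}"
            )


# --------------------------------------------------------------------------- #
# 3. Deterministic dose and risk arithmetic
# --------------------------------------------------------------------------- #


def exposure_factor(frequency: float, duration: float, averaging_time: float) -> float:
    """Dimensionless exposure factor EF = F * ED / AT.

    Parameters
    ----------
    frequency
        F, exposure days per year (0 allowed: no exposure).
    duration
        ED, exposure duration in years.
    averaging_time
        AT, averaging time in days (lifetime, ~28489 d, for cancer endpoints).

    Returns
    -------
    float
        The fraction of the averaging time during which exposure occurs.
    """
    if frequency < 0 or duration < 0:
        raise ValueError("frequency and duration must be >= 0")
    if averaging_time <= 0:
        raise ValueError(f"averaging_time must be > 0, got {averaging_time}")
    return frequency * duration / averaging_time


def resolved_exposure_factor(profile: ExposureProfile) -> float:
    """The EF a profile actually uses: its override if set, else F*ED/AT."""
    if profile.exposure_factor_override is not None:
        return profile.exposure_factor_override
    return exposure_factor(profile.frequency, profile.duration,
                           profile.averaging_time)


def dose_oral(concentration: float, profile: ExposureProfile,
              tox: ChemicalToxicity) -> float:
    """Average daily dose from incidental ingestion, mg/(kg*day).

    ``C * IRs * RBA * EF * CF / BW``.
    """
    _require_nonnegative("concentration", concentration)
    ef = resolved_exposure_factor(profile)
    return (concentration * profile.intake_rate_soil * tox.rba_oral * ef
            * profile.conversion_factor / profile.body_weight)


def dose_dermal(concentration: float, profile: ExposureProfile,
                tox: ChemicalToxicity) -> float:
    """Average daily dose from dermal uptake, mg/(kg*day).

    ``C * SA * AF * ABS * EF * CF / BW``; one skin-loading event per exposure
    day.
    """
    _require_nonnegative("concentration", concentration)
    ef = resolved_exposure_factor(profile)
    return (concentration * profile.skin_surface_area * profile.adherence_factor
            * tox.abs_dermal * ef * profile.conversion_factor
            / profile.body_weight)


def dose_inhalation(concentration: float, profile: ExposureProfile,
                    tox: ChemicalToxicity) -> float:
    """Average daily dose from inhaled suspended particulates, mg/(kg*day).

    ``C * (1/PEF) * IRa * ET * EF / BW``. No mass-conversion factor appears in
    this route (PEF already carries the kg), and ET (hours/day) is applied as
    a bare multiplier with no /24 — see docs/methods.md for the dimensional
    caveat this inherits from the published parameterisation.
    """
    _require_nonnegative("concentration", concentration)
    ef = resolved_exposure_factor(profile)
    return (concentration / profile.particulate_emission_factor
            * profile.inhalation_rate * profile.exposure_time * ef
            / profile.body_weight)


_DOSE_FUNCTIONS = {
    "oral": dose_oral,
    "dermal": dose_dermal,
    "inhalation": dose_inhalation,
}


def route_risk(dose: float, slope_factor: float) -> float:
    """Lifetime excess cancer risk = dose x slope factor.

    The linear low-dose product is returned uncapped; above
    ``RISK_WARN_THRESHOLD`` (0.01) a warning is emitted because the linear
    model is not credible there.
    """
    _require_nonnegative("dose", dose)
    _require_nonnegative("slope_factor", slope_factor)
    risk = dose * slope_factor
    if risk > RISK_WARN_THRESHOLD:
        warnings.warn(
            f"risk {risk:.3g} exceeds {RISK_WARN_THRESHOLD}; the linear "
            "low-dose model is not credible at this level",
            UserWarning,
            stacklevel=2,
        )
    return risk


def _slope(tox: ChemicalToxicity, route: str) -> float:
    return getattr(tox, f"slope_{route}")


def risk_table(media: Sequence[MediumConcentration], profile: ExposureProfile,
               tox: ChemicalToxicity) -> RiskTable:
    """Point risks for every (medium, route) cell, with marginal totals.

    Each cell is ``route_risk(dose_route(C_medium), slope_route)``; the
    margins are plain sums (multi-route, multi-medium doses combine
    additively for aggregate exposure estimates).
    """
    if not media:
        raise ValueError("media must be non-empty")
    labels = [m.medium for m in media]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate medium labels in {labels}")

    cells: dict[tuple[str, str], float] = {}
    for m in media:
        for route in ROUTES:
            dose = _DOSE_FUNCTIONS[route](m.concentration, profile, tox)
            cells[(m.medium, route)] = route_risk(dose, _slope(tox, route))

    route_totals = {r: math.fsum(cells[(lab, r)] for lab in labels)
                    for r in ROUTES}
    medium_totals = {lab: math.fsum(cells[(lab, r)] for r in ROUTES)
                     for lab in labels}
    grand_total = math.fsum(route_totals.values())
    return RiskTable(
        media=tuple(labels),
        cells=cells,
        route_totals=route_totals,
        medium_totals=medium_totals,
        grand_total=grand_total,
    )


# --------------------------------------------------------------------------- #
# 4. Triangular distributions: inverse CDF and sampling
# --------------------------------------------------------------------------- #


def triangular_ppf(u, dist: TriangularDist):
    """Inverse CDF of a triangular distribution (vectorised in ``u``).

    For ``u < (c - a)/(b - a)``::

        x = a + sqrt(u * (b - a) * (c - a))

    otherwise::

        x = b - sqrt((1 - u) * (b - a) * (b - c))

    with a = minimum, c = likeliest (mode), b = maximum.
    """
    a, c, b = dist.minimum, dist.likeliest, dist.maximum
    u = np.asarray(u, dtype=float)
    if np.any((u < 0) | (u > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    split = (c - a) / (b - a)
    lower = a + np.sqrt(u * (b - a) * (c - a))
    upper = b - np.sqrt((1.0 - u) * (b - a) * (b - c))
    x = np.where(u < split, lower, upper)
    return float(x) if x.ndim == 0 else x


def sample_triangular(dist: TriangularDist, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` iid triangular variates by inverse-CDF transform of U(0,1).

    All samples lie in ``[dist.minimum, dist.maximum]``; the sequence is fully
    determined by the state of ``rng``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    u = rng.random(n)
    return np.atleast_1d(triangular_ppf(u, dist))


# --------------------------------------------------------------------------- #
# 5. Monte Carlo uncertainty propagation
# --------------------------------------------------------------------------- #


def summarize_samples(samples, probabilities) -> np.ndarray:
    """Empirical quantiles by linear interpolation between order statistics.

    This is numpy's default ``linear`` convention: the p-quantile of sorted
    values x_(1) <= ... <= x_(n) interpolates at rank ``1 + p*(n-1)``. The
    result is monotone in ``probabilities``; p=0 and p=1 return the sample
    minimum and maximum.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("samples must be non-empty")
    probabilities = np.asarray(probabilities, dtype=float)
    if np.any((probabilities < 0) | (probabilities > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return np.quantile(samples, probabilities, method="linear")


def run_simulation(spec: SimulationSpec) -> SimulationSummary:
    """Propagate triangular parameter uncertainty through the risk equations.

    Per iteration, one value is drawn independently for each sampled
    parameter; the exposure profile is rebuilt with the draws; and the oral,
    dermal, and inhalation risks are evaluated for the sampled (single)
    concentration. When ``frequency`` is sampled, EF is recomputed per
    iteration from F*ED/AT with the profile's fixed ED and AT (any EF
    override is discarded for sampled iterations). Returns per-route means
    and empirical 2.5%/97.5% quantiles; per-iteration risks are retained in
    ``summary.samples``.

    Identical spec + seed gives bit-identical output: parameters are sampled
    in fixed alphabetical order from a ``numpy`` PCG64 generator seeded with
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.iterations
    draws: dict[str, np.ndarray] = {}
    for name in sorted(spec.distributions):
        draws[name] = sample_triangular(spec.distributions[name], n, rng)

    base = spec.fixed_profile
    bw = draws.get("body_weight", np.full(n, base.body_weight))
    sa = draws.get("skin_surface_area", np.full(n, base.skin_surface_area))
    conc = draws.get("concentration", np.full(n, spec.concentration))
    freq = draws.get("frequency")

    logger.info("running %d Monte Carlo iterations (seed=%d, sampled: %s)",
                n, spec.seed, ", ".join(sorted(spec.distributions)) or "none")

    replace = dataclasses.replace
    risks = {r: np.empty(n) for r in ROUTES}
    for i in range(n):
        fields: dict[str, float] = {
            "body_weight": float(bw[i]),
            "skin_surface_area": float(sa[i]),
        }
        if freq is not None:
            fields["frequency"] = float(freq[i])
            fields["exposure_factor_override"] = None
        prof = replace(base, **fields)
        c = float(conc[i])
        for route in ROUTES:
            risks[route][i] = (_DOSE_FUNCTIONS[route](c, prof, spec.tox)
                               * _slope(spec.tox, route))

    mean = {r: float(np.mean(risks[r])) for r in ROUTES}
    lo = {r: float(summarize_samples(risks[r], 0.025)) for r in ROUTES}
    hi = {r: float(summarize_samples(risks[r], 0.975)) for r in ROUTES}
    return SimulationSummary(
        mean=mean, quantile_2_5=lo, quantile_97_5=hi,
        iterations=n, seed=spec.seed, samples=risks,
    )


# --------------------------------------------------------------------------- #
# 6. Synthetic cohorts
# --------------------------------------------------------------------------- #

#: Observed-parameter names, in record order, with their cohort-file columns.
_COHORT_COLUMNS = {
    "body_weight": "body_weight_kg",
    "skin_surface_area": "skin_surface_area_cm2",
    "beach_frequency": "beach_frequency_days_per_year",
}


def generate_cohort(n: int, distributions: Mapping[str, TriangularDist],
                    rng: np.random.Generator) -> list[ChildObservation]:
    """Simulate per-child field records from triangular assumptions.

    Body weight, skin surface area, and beach-visit frequency are drawn
    independently (a stated simplification: BW and SA are physically
    correlated, but the downstream analysis assumes independence too).
    Frequency is rounded to the nearest whole visit and floored at 1 — an
    observed child visited at least once.

    ``distributions`` must provide ``body_weight``, ``skin_surface_area``,
    and ``frequency``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    missing = {"body_weight", "skin_surface_area", "frequency"} - set(distributions)
    if missing:
        raise ValueError(f"missing distribution(s) for {sorted(missing)}")
    bw = sample_triangular(distributions["body_weight"], n, rng)
    sa = sample_triangular(distributions["skin_surface_area"], n, rng)
    freq = sample_triangular(distributions["frequency"], n, rng)
    visits = np.maximum(np.rint(freq).astype(int), 1)
    width = len(str(n))
    return [
        ChildObservation(
            child_id=f"child-{i + 1:0{width}d}",
            body_weight=float(bw[i]),
            skin_surface_area=float(sa[i]),
            beach_frequency=int(visits[i]),
        )
        for i in range(n)
    ]


def cohort_to_frame(cohort: Sequence[ChildObservation]) -> pd.DataFrame:
    """Cohort as a DataFrame with the on-disk column names."""
    return pd.DataFrame(
        {
            "child_id": [c.child_id for c in cohort],
            "body_weight_kg": [c.body_weight for c in cohort],
            "skin_surface_area_cm2": [c.skin_surface_area for c in cohort],
            "beach_frequency_days_per_year": [c.beach_frequency for c in cohort],
        }
    )


def summarize_cohort(
    cohort: Sequence[ChildObservation],
) -> dict[str, CohortSummary]:
    """Exact min/median/max/mean per observed parameter.

    The median of an even-length cohort is the mean of the central pair.
    Summaries are invariant under reordering of the cohort.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    out: dict[str, CohortSummary] = {}
    for param in _COHORT_COLUMNS:
        # sorted so every statistic (incl. the mean's summation order) is
        # exactly invariant under cohort reordering
        values = np.sort(np.array([getattr(c, param) for c in cohort],
                                  dtype=float))
        out[param] = CohortSummary(
            parameter=param,
            minimum=float(values.min()),
            median=float(np.median(values)),
            maximum=float(values.max()),
            mean=float(values.mean()),
            n=len(cohort),
        )
    return out


def fit_triangular(summary: CohortSummary) -> TriangularDist:
    """Plug-in triangular assumption: (min, median, max) of the cohort.

    The observed median stands in for the distribution's likeliest value
    (mode); this is deliberately *not* a maximum-likelihood fit.
    """
    if summary.minimum == summary.maximum:
        raise ValueError(
            f"cannot fit a triangular distribution to {summary.parameter}: "
            "all observations equal"
        )
    return TriangularDist(summary.minimum, summary.median, summary.maximum)


def write_cohort(cohort: Sequence[ChildObservation], path: str | Path) -> None:
    """Write a cohort as a tab-separated table with header.

    Floats are written with 17 significant digits so a write/read cycle
    reproduces the cohort exactly.
    """
    cohort_to_frame(cohort).to_csv(path, sep="\t", index=False,
                                   float_format="%.17g")


def read_cohort(path: str | Path) -> list[ChildObservation]:
    """Read a cohort written by :func:`write_cohort`."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"child_id", *_COHORT_COLUMNS.values()}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort file {path} is missing column(s) {sorted(missing)}")
    return [
        ChildObservation(
            child_id=str(row.child_id),
            body_weight=float(row.body_weight_kg),
            skin_surface_area=float(row.skin_surface_area_cm2),
            beach_frequency=int(row.beach_frequency_days_per_year),
        )
        for row in df.itertuples(index=False)
    ]


# --------------------------------------------------------------------------- #
# 7. Scenario configuration and reports
# --------------------------------------------------------------------------- #

_CHEMICAL_FIELDS = ("name", "rba_oral", "slope_oral", "abs_dermal",
                    "slope_dermal", "slope_inhalation")
_EXPOSURE_FIELDS = ("body_weight", "frequency", "duration", "averaging_time",
                    "intake_rate_soil", "conversion_factor",
                    "skin_surface_area", "adherence_factor",
                    "particulate_emission_factor", "inhalation_rate",
                    "exposure_time")


def bundled_scenarios() -> tuple[str, ...]:
    """Names of the scenarios shipped with the package."""
    pkg = resources.files(__package__) / "scenarios"
    return tuple(sorted(p.name.removesuffix(".toml")
                        for p in pkg.iterdir() if p.name.endswith(".toml")))


def _scenario_source(name_or_path: str | Path) -> tuple[str, bytes]:
    path = Path(name_or_path)
    if path.suffix == ".toml" or path.exists():
        if not path.exists():
            raise ScenarioError(f"scenario file {path} does not exist")
        return str(path), path.read_bytes()
    bundled = resources.files(__package__) / "scenarios" / f"{name_or_path}.toml"
    if bundled.is_file():
        return str(name_or_path), bundled.read_bytes()
    raise ScenarioError(
        f"no scenario file {name_or_path!r} and no bundled scenario of that "
        f"name (bundled: {', '.join(bundled_scenarios())})"
    )


def _numeric(section: str, key: str, raw: Mapping) -> float:
    if key not in raw:
        raise ScenarioError(f"[{section}] is missing required field {key!r}")
    value = raw[key]
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ScenarioError(
            f"[{section}] field {key!r} must be numeric, got {value!r}"
        )
    return float(value)


def load_scenario(name_or_path: str | Path) -> Scenario:
    """Load and fully validate a scenario from TOML.

    ``name_or_path`` may be a file path or the name of a bundled scenario
    (see :func:`bundled_scenarios`). The file needs ``[chemical]``,
    ``[concentrations]`` and ``[exposure]`` tables and may add
    ``[distributions]`` with per-parameter ``minimum``/``likeliest``/
    ``maximum`` triples. Every domain invariant is enforced at load time with
    an error message naming the offending field.
    """
    label, blob = _scenario_source(name_or_path)
    try:
        raw = tomllib.loads(blob.decode("utf-8"))
    except tomllib.TOMLDecodeError as exc:
        raise ScenarioError(f"cannot parse scenario {label}: {exc}") from exc

    for section in ("chemical", "concentrations", "exposure"):
        if section not in raw:
            raise ScenarioError(f"scenario {label} is missing [{section}]")

    chem_raw = raw["chemical"]
    if "name" not in chem_raw or not isinstance(chem_raw["name"], str):
        raise ScenarioError("[chemical] requires a string field 'name'")
    try:
        tox = ChemicalToxicity(
            name=chem_raw["name"],
            **{f: _numeric("chemical", f, chem_raw)
               for f in _CHEMICAL_FIELDS if f != "name"},
        )

        media = tuple(
            MediumConcentration(medium=m,
                                concentration=_numeric("concentrations", m,
                                                       raw["concentrations"]))
            for m in raw["concentrations"]
        )

        exp_raw = raw["exposure"]
        override = None
        if "exposure_factor_override" in exp_raw:
            override = _numeric("exposure", "exposure_factor_override", exp_raw)
        profile = ExposureProfile(
            **{f: _numeric("exposure", f, exp_raw) for f in _EXPOSURE_FIELDS},
            exposure_factor_override=override,
        )

        dists: dict[str, TriangularDist] = {}
        for param, triple in raw.get("distributions", {}).items():
            if not isinstance(triple, Mapping):
                raise ScenarioError(
                    f"[distributions] entry {param!r} must be a table with "
                    "minimum/likeliest/maximum"
                )
            dists[param] = TriangularDist(
                minimum=_numeric(f"distributions.{param}", "minimum", triple),
                likeliest=_numeric(f"distributions.{param}", "likeliest", triple),
                maximum=_numeric(f"distributions.{param}", "maximum", triple),
            )

        return Scenario(
            name=str(raw.get("name", label)),
            tox=tox,
            media=media,
            profile=profile,
            distributions=dists,
        )
    except ScenarioError:
        raise
    except ValueError as exc:
        raise ScenarioError(f"scenario {label} is invalid: {exc}") from exc


def _fmt(value: float, raw: bool) -> str:
    return repr(value) if raw else _REPORT_FORMAT.format(value)


def render_point_report(table: RiskTable, raw: bool = False) -> str:
    """Render a point-risk table as deterministic tab-separated text.

    One row per medium plus a Total row; one column per route plus a total
    column; values in 3-significant-figure scientific notation (full
    precision with ``raw=True``).
    """
    lines = ["medium\t" + "\t".join(ROUTES) + "\ttotal"]
    for m in table.media:
        cells = [_fmt(table.cells[(m, r)], raw) for r in ROUTES]
        lines.append("\t".join([m, *cells, _fmt(table.medium_totals[m], raw)]))
    totals = [_fmt(table.route_totals[r], raw) for r in ROUTES]
    lines.append("\t".join(["total", *totals, _fmt(table.grand_total, raw)]))
    return "\n".join(lines) + "\n"


def render_simulation_report(summary: SimulationSummary, raw: bool = False) -> str:
    """Render Monte Carlo summaries (rows: mean, 2.5%, 97.5%; columns: routes)."""
    lines = ["statistic\t" + "\t".join(ROUTES)]
    for label, stats in (("mean", summary.mean),
                         ("2.5%", summary.quantile_2_5),
                         ("97.5%", summary.quantile_97_5)):
        lines.append("\t".join([label, *(_fmt(stats[r], raw) for r in ROUTES)]))
    return "\n".join(lines) + "\n"
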