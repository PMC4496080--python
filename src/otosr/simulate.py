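"""Synthetic inputs with the statistical structure the pipeline assumes.

Every stage of the pipeline can be exercised without any external download:

* :func:`simulate_geology` — watershed unit tables whose candidate-variable
  span matches the real covariate construction (a pool of 22 age classes
  plus intrusive/extrusive rock fractions plus weighted mean age);
* :func:`simulate_water` — baseline ⁸⁷Sr/⁸⁶Sr values generated from a known
  ("truth") isoscape model plus Gaussian noise, with three river-group
  labels assigned by thresholding the noise-free signal — the inverse of the
  regression stage, for parameter-recovery tests;
* :func:`simulate_transect` — piecewise-constant otolith series with known
  changepoints and river-group memberships, i.i.d. Gaussian instrument
  noise, and integration points spaced at the laser cadence
  (30 um/s x 0.262 s ~= 7.86 um per point);
* :func:`simulate_cohort` — a fixed 22-fish cohort (14 analyzable dourada,
  5 piramutaba, 3 piraíba) whose movement histories encode the study
  conditions: 10/14 dourada with multi-segment histories of which 2 cross
  river groups, 2/5 piramutaba moving within the mainstem group, and 2/3
  piraíba crossing between the Beni-Madeira and mainstem groups.

Segment means are drawn from the per-group empirical value pools of the
bundled water baseline, so simulated separations are realistic rather than
invented.  The default transect noise SD of 1e-3 approximates
per-integration scatter, an order of magnitude above the aggregate
standard-error of a marine shell reference standard.  All generators are
pure functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import OtosrError, ValidationError
from .geology import (
    MEAN_AGE_NAME,
    GeologyUnit,
    covariates_for_watersheds,
    load_age_class_bounds,
)
from .groups import DEFAULT_GROUPS
from .movement import POINT_SPACING_UM, Transect
from .regression import INTERCEPT, IsoscapeModel

#: Age classes offered to the geology generator (22 classes; with the two
#: informative rock classes this spans the two dozen candidate variables the
#: covariate construction is designed around).
DEFAULT_AGE_CLASS_POOL = (
    "neogene",
    "paleogene",
    "cretaceous",
    "jurassic",
    "triassic",
    "permian",
    "carboniferous",
    "devonian",
    "silurian",
    "ordovician",
    "cambrian",
    "ediacaran",
    "cryogenian",
    "tonian",
    "stenian",
    "ectasian",
    "calymmian",
    "statherian",
    "orosirian",
    "rhyacian",
    "siderian",
    "neoarchean",
)

DEFAULT_TRANSECT_NOISE_SD = 1e-3
DEFAULT_WATER_NOISE_SD = 2e-3

#: Minimum separation imposed between consecutive simulated segment means so
#: that a changepoint is physically meaningful relative to instrument noise.
DEFAULT_MIN_SEPARATION = 3e-3


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def truth_model(
    coefficients: Mapping[str, float], include_intercept: bool | None = None
) -> IsoscapeModel:
    """Wrap plain coefficients as a generator ("truth") isoscape model.

    Only prediction machinery is meaningful on the result; fit statistics are
    placeholders.
    """
    coeffs = dict(coefficients)
    if include_intercept is None:
        include_intercept = INTERCEPT in coeffs
    terms = tuple(t for t in coeffs if t != INTERCEPT)
    p = len(terms) + int(include_intercept)
    return IsoscapeModel(
        terms=terms,
        coefficients=coeffs,
        include_intercept=include_intercept,
        n_obs=p + 3,
        residual_variance=0.0,
        adjusted_r2=1.0,
        aicc=float("nan"),
        design_moment_inverse=np.eye(p),
    )


def simulate_geology(
    n_watersheds: int,
    age_class_pool: Sequence[str] | None = None,
    units_per_watershed: tuple[int, int] = (3, 8),
    seed: int | np.random.Generator = 0,
) -> list[GeologyUnit]:
    """Random watershed geology tables over a pool of age classes.

    Each watershed gets a random number of units; every unit draws an age
    class (bounds from the bundled chart table), a broad rock class and a
    log-normal outcrop area.
    """
    if n_watersheds < 1:
        raise ValidationError("n_watersheds must be >= 1")
    pool = tuple(age_class_pool) if age_class_pool is not None else DEFAULT_AGE_CLASS_POOL
    if not pool:
        raise OtosrError("age class pool is empty")
    bounds = load_age_class_bounds()
    unknown = [c for c in pool if c not in bounds.index]
    if unknown:
        raise ValidationError(f"age classes missing from the bounds table: {unknown}")
    rng = _rng(seed)
    lo, hi = units_per_watershed
    units: list[GeologyUnit] = []
    width = len(str(n_watersheds))
    for w in range(n_watersheds):
        wid = f"ws{w + 1:0{width}d}"
        k = int(rng.integers(lo, hi + 1))
        classes = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
        for ci in classes:
            cls = pool[int(ci)]
            units.append(
                GeologyUnit(
                    watershed_id=wid,
                    age_class=cls,
                    age_min=float(bounds.loc[cls, "age_min_ma"]),
                    age_max=float(bounds.loc[cls, "age_max_ma"]),
                    rock_class=str(
                        rng.choice(
                            ["other", "intrusive", "extrusive"], p=[0.6, 0.2, 0.2]
                        )
                    ),
                    area=float(rng.lognormal(mean=9.0, sigma=1.0)),
                )
            )
    return units


def simulate_water(
    units: Sequence[GeologyUnit],
    truth: IsoscapeModel,
    noise_sd: float = DEFAULT_WATER_NOISE_SD,
    seed: int | np.random.Generator = 0,
    group_labels: Sequence[str] = DEFAULT_GROUPS,
):
    """Water baseline generated from a known isoscape model.

    sr_ratio = truth prediction + N(0, noise_sd²); river-group labels are
    assigned by cutting the *noise-free* predictions into three equal-count
    bands (low / middle / high ratio), mirroring the three-group structure of
    the real baseline.
    """
    from .io import WaterSite  # local import: io depends on this module's peers

    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = _rng(seed)
    covs = covariates_for_watersheds(units)
    ids = sorted(covs)
    # a known class absent from a watershed drains zero area there; a factor
    # that is no age class, rock class or mean age is a configuration error
    known: set[str] = set(load_age_class_bounds().index)
    known.update(("intrusive", "extrusive", MEAN_AGE_NAME))
    for c in covs.values():
        known.update(c.as_dict())
    factors = {f for t in truth.terms for f in t.split(":")}
    unknown = sorted(factors - known)
    if unknown:
        raise ValidationError(
            f"truth-model factor(s) not computable from this geology: {unknown}"
        )
    rows = []
    for w in ids:
        d = covs[w].as_dict()
        for f in factors:
            d.setdefault(f, 0.0)
        rows.append(d)
    clean = np.array([truth.predict(d) for d in rows])
    noisy = clean + rng.normal(0.0, noise_sd, size=len(ids))
    lo, hi = np.quantile(clean, [1 / 3, 2 / 3])
    sites = []
    for wid, mu, x in zip(ids, clean, noisy):
        g = group_labels[0] if mu <= lo else group_labels[1] if mu <= hi else group_labels[2]
        sites.append(
            WaterSite(
                site_name=wid,
                source="simulated",
                river=wid,
                group_label=g,
                sr_ratio=float(np.clip(x, 0.700001, 0.799999)),
                covariates=covs[wid],
            )
        )
    return sites


@dataclass(frozen=True)
class TransectSpec:
    """Blueprint for one simulated fish."""

    sample_id: str
    group_sequence: tuple[str, ...]
    segment_lengths: tuple[int, ...]  # integration points per segment
    species: str | None = None
    noise_sd: float = DEFAULT_TRANSECT_NOISE_SD
    spacing_um: float = POINT_SPACING_UM
    means: tuple[float, ...] | None = None  # override the group-pool draw

    def __post_init__(self):
        if len(self.group_sequence) != len(self.segment_lengths):
            raise ValidationError(
                f"{self.sample_id}: group sequence and lengths differ in length"
            )
        if any(m < 1 for m in self.segment_lengths):
            raise ValidationError(f"{self.sample_id}: segment lengths must be >= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class TransectTruth:
    """Generator-side record of what a simulated transect contains."""

    sample_id: str
    changepoints: tuple[int, ...]  # interior indices, start of each new segment
    means: tuple[float, ...]
    group_labels: tuple[str, ...]
    noise_sd: float


def group_pools_from_baseline(
    sites=None, consistent: bool = True
) -> dict[str, list[float]]:
    """Per-group empirical ⁸⁷Sr/⁸⁶Sr pools from a water baseline
    (bundled baseline by default; outliers excluded, predicted included).

    With ``consistent`` (default) a pool keeps only values that the
    discriminant fitted to the same baseline assigns back to their own
    group; otherwise a simulated truth could label a segment with a group
    whose own classifier disagrees, and no segmentation could ever recover
    it.  On the bundled baseline this drops a single mainstem value that
    sits in the Beni-Madeira score region.
    """
    if sites is None:
        from .io import load_water_baseline

        sites = load_water_baseline()
    keep = {s.site_name for s in sites}
    if consistent:
        from .groups import apparent_error

        rep = apparent_error(sites)
        keep = {
            s.site_name
            for s in sites
            if s.site_name not in rep.misclassified
        }
    pools: dict[str, list[float]] = {}
    for s in sites:
        if s.outlier or s.group_label is None or s.site_name not in keep:
            continue
        pools.setdefault(s.group_label, []).append(s.sr_ratio)
    return pools


def _draw_means(
    spec: TransectSpec,
    pools: Mapping[str, Sequence[float]],
    rng: np.random.Generator,
    min_separation: float,
) -> list[float]:
    means: list[float] = []
    for g in spec.group_sequence:
        if g not in pools or not pools[g]:
            raise ValidationError(f"{spec.sample_id}: unknown group label {g!r}")
        pool = np.asarray(pools[g], dtype=float)
        if not means:
            means.append(float(rng.choice(pool)))
            continue
        prev = means[-1]
        ok = pool[np.abs(pool - prev) >= min_separation]
        if len(ok):
            means.append(float(rng.choice(ok)))
        else:  # fall back to the most separated value available
            means.append(float(pool[np.argmax(np.abs(pool - prev))]))
    return means


def simulate_transect(
    spec: TransectSpec,
    pools: Mapping[str, Sequence[float]] | None = None,
    seed: int | np.random.Generator = 0,
    min_separation: float = DEFAULT_MIN_SEPARATION,
) -> tuple[Transect, TransectTruth]:
    """One piecewise-constant transect plus its generating truth.

    Segment means come from ``spec.means`` when given, otherwise they are
    drawn from the per-group pools with consecutive means forced at least
    ``min_separation`` apart (a changepoint smaller than instrument noise is
    not a movement signal).
    """
    rng = _rng(seed)
    pools = pools if pools is not None else group_pools_from_baseline()
    means = (
        list(spec.means)
        if spec.means is not None
        else _draw_means(spec, pools, rng, min_separation)
    )
    signal = np.concatenate(
        [np.full(m, mu) for m, mu in zip(spec.segment_lengths, means)]
    )
    n = len(signal)
    ratios = signal + rng.normal(0.0, spec.noise_sd, size=n)
    distances = spec.spacing_um * np.arange(1, n + 1)
    cps = tuple(np.cumsum(spec.segment_lengths)[:-1].tolist())
    transect = Transect(
        sample_id=spec.sample_id,
        species=spec.species,
        distances=distances,
        ratios=ratios,
    )
    truth = TransectTruth(
        sample_id=spec.sample_id,
        changepoints=cps,
        means=tuple(means),
        group_labels=spec.group_sequence,
        noise_sd=spec.noise_sd,
    )
    return transect, truth


_W, _B, _L = DEFAULT_GROUPS


def default_cohort_specs() -> list[TransectSpec]:
    """The default simulated cohort, mirroring the study's analyzable catch.

    14 dourada: 10 with multi-segment histories (2 crossing river groups),
    4 resident; 5 piramutaba: 2 moving within the mainstem group; 3 piraíba:
    2 crossing between Beni-Madeira and the mainstem group.
    """
    d = []
    # dourada with group crossings (estuary-to-shield and shield-to-Madeira)
    d.append(TransectSpec("D01", (_W, _L), (150, 170), species="dourada"))
    d.append(TransectSpec("D02", (_L, _B, _W, _B), (110, 90, 70, 110), species="dourada"))
    # dourada moving between stable signatures inside the mainstem group
    for i, lengths in enumerate(
        [(140, 120), (100, 160), (90, 120, 100), (170, 110), (130, 150),
         (120, 100), (150, 90), (80, 140, 90)],
        start=3,
    ):
        d.append(TransectSpec(f"D{i:02d}", tuple([_W] * len(lengths)), lengths,
                              species="dourada"))
    # resident dourada
    for i, n in enumerate([260, 320, 280, 240], start=11):
        d.append(TransectSpec(f"D{i:02d}", (_W,), (n,), species="dourada"))
    # piramutaba: mainstem residents, two with a within-group move
    d.append(TransectSpec("P01", (_W, _W), (140, 130), species="piramutaba"))
    d.append(TransectSpec("P02", (_W, _W), (120, 150), species="piramutaba"))
    for i, n in enumerate([270, 230, 300], start=3):
        d.append(TransectSpec(f"P{i:02d}", (_W,), (n,), species="piramutaba"))
    # piraíba: two crossing between Beni-Madeira and the mainstem
    d.append(TransectSpec("F01", (_B, _W), (160, 150), species="piraiba"))
    d.append(TransectSpec("F02", (_W, _B), (130, 160), species="piraiba"))
    d.append(TransectSpec("F03", (_W,), (290,), species="piraiba"))
    return d


def simulate_cohort(
    seed: int | np.random.Generator = 0,
    specs: Sequence[TransectSpec] | None = None,
    pools: Mapping[str, Sequence[float]] | None = None,
    min_separation: float = DEFAULT_MIN_SEPARATION,
) -> list[tuple[Transect, TransectTruth]]:
    """Simulate a whole cohort (default: :func:`default_cohort_specs`)."""
    rng = _rng(seed)
    specs = list(specs) if specs is not None else default_cohort_specs()
    pools = pools if pools is not None else group_pools_from_baseline()
    return [
        simulate_transect(spec, pools, rng, min_separation) for spec in specs
    ]
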