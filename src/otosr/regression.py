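"""The geology -> ⁸⁷Sr/⁸⁶Sr isoscape regression.

The response is a river's baseline ⁸⁷Sr/⁸⁶Sr ratio; candidates are its
watershed's geologic covariates (age-class and rock-class area fractions,
area-weighted mean age) plus, optionally, their pairwise products.  Model
search is over all term subsets of size <= ``max_terms`` (four by default:
with two dozen candidates plus interactions, anything larger invites
over-parameterisation at n ~ 20).  The search criterion is AICc, the
small-sample Akaike criterion; the search itself is exhaustive when the
model space is small and a seeded genetic algorithm otherwise.  A validation
fraction can be withheld before the search to assess out-of-sample
prediction error.

Ordinary least squares itself (and nothing else) is delegated to
statsmodels; selection, AICc bookkeeping and the prediction-interval
machinery are implemented here so that a fitted model is a small,
JSON-serialisable object that can be stored and reapplied to new
watersheds.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    CollinearTermsError,
    OtosrError,
    UndefinedCriterionError,
    ValidationError,
)
from .geology import CandidateMatrix

INTERCEPT = "(intercept)"


def interaction_name(a: str, b: str) -> str:
    """Canonical name of a pairwise interaction (factor order-free)."""
    lo, hi = sorted((a, b))
    return f"{lo}:{hi}"


def term_columns(
    frame: pd.DataFrame, terms: Sequence[str]
) -> pd.DataFrame:
    """Evaluate main-effect and ``a:b`` interaction terms on a covariate frame."""
    cols = {}
    for t in terms:
        if ":" in t:
            a, b = t.split(":", 1)
            for nm in (a, b):
                if nm not in frame.columns:
                    raise ValidationError(f"missing covariate {nm!r} for term {t!r}")
            cols[t] = frame[a] * frame[b]
        else:
            if t not in frame.columns:
                raise ValidationError(f"missing covariate {t!r}")
            cols[t] = frame[t]
    return pd.DataFrame(cols, index=frame.index)


def candidate_terms(
    matrix: CandidateMatrix, allow_interactions: bool = True
) -> list[str]:
    """Main effects plus (optionally) all pairwise interactions."""
    terms = list(matrix.variables)
    if allow_interactions:
        terms += [
            interaction_name(a, b)
            for a, b in itertools.combinations(matrix.variables, 2)
        ]
    return terms


@dataclass(frozen=True)
class IsoscapeModel:
    """A fitted isoscape regression, sufficient for out-of-sample prediction.

    ``design_moment_inverse`` stores (X'X)^-1 for the fitted design (intercept
    first when present), which together with the residual variance yields the
    prediction variance at any new covariate vector.
    """

    terms: tuple[str, ...]
    coefficients: Mapping[str, float]  # includes INTERCEPT when fitted
    include_intercept: bool
    n_obs: int
    residual_variance: float
    adjusted_r2: float
    aicc: float
    design_moment_inverse: np.ndarray = field(repr=False)

    @property
    def df_resid(self) -> int:
        return self.n_obs - len(self.terms) - int(self.include_intercept)

    @property
    def n_parameters(self) -> int:
        """Estimated parameters counted by AICc: coefficients + variance."""
        return len(self.terms) + int(self.include_intercept) + 1

    def design_row(self, covariates: Mapping[str, float]) -> np.ndarray:
        row = []
        if self.include_intercept:
            row.append(1.0)
        for t in self.terms:
            if ":" in t:
                a, b = t.split(":", 1)
                for nm in (a, b):
                    if nm not in covariates:
                        raise ValidationError(
                            f"covariates missing {nm!r} needed by term {t!r}"
                        )
                row.append(covariates[a] * covariates[b])
            else:
                if t not in covariates:
                    raise ValidationError(f"covariates missing term {t!r}")
                row.append(covariates[t])
        return np.asarray(row, dtype=float)

    def predict(self, covariates: Mapping[str, float]) -> float:
        beta = np.array(
            ([self.coefficients[INTERCEPT]] if self.include_intercept else [])
            + [self.coefficients[t] for t in self.terms]
        )
        return float(self.design_row(covariates) @ beta)

    def to_json(self) -> str:
        return json.dumps(
            {
                "terms": list(self.terms),
                "coefficients": dict(self.coefficients),
                "include_intercept": self.include_intercept,
                "n_obs": self.n_obs,
                "residual_variance": self.residual_variance,
                "adjusted_r2": self.adjusted_r2,
                "aicc": self.aicc,
                "design_moment_inverse": self.design_moment_inverse.tolist(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "IsoscapeModel":
        d = json.loads(text)
        return cls(
            terms=tuple(d["terms"]),
            coefficients=d["coefficients"],
            include_intercept=d["include_intercept"],
            n_obs=d["n_obs"],
            residual_variance=d["residual_variance"],
            adjusted_r2=d["adjusted_r2"],
            aicc=d["aicc"],
            design_moment_inverse=np.asarray(d["design_moment_inverse"]),
        )


@dataclass(frozen=True)
class SrPrediction:
    """Point prediction with a prediction-interval halfwidth for one new
    watershed (an interval for a new observation, not for the mean)."""

    watershed_id: str
    predicted_ratio: float
    interval_halfwidth: float
    level: float = 0.95


def fit_ols(
    response: Sequence[float],
    design: pd.DataFrame,
    include_intercept: bool = True,
) -> IsoscapeModel:
    """Least-squares fit of ``response`` on the given term columns.

    ``design`` holds one column per model term, already evaluated (see
    :func:`term_columns`).  Adjusted R² uses the usual
    1 - (1 - R²)(n - 1)/(n - p - 1) with p counting non-intercept terms.
    """
    y = np.asarray(response, dtype=float)
    terms = tuple(design.columns)
    n = len(y)
    p = len(terms) + int(include_intercept)
    if n <= len(terms) + 2:
        raise ValidationError(
            f"need n > number of terms + 2 (n={n}, terms={len(terms)})"
        )
    X = design.to_numpy(dtype=float)
    if include_intercept:
        X = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # point at the terms spanning the null space of X
        _, sv, vt = np.linalg.svd(X)
        null = vt[-1]
        names = ([INTERCEPT] if include_intercept else []) + list(terms)
        bad = [nm for nm, w in zip(names, null) if abs(w) > 1e-8]
        raise CollinearTermsError(bad)
    res = sm.OLS(y, X).fit()
    rss = float(res.ssr)
    tss = float(((y - y.mean()) ** 2).sum()) if include_intercept else float(
        (y**2).sum()
    )
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    dfn = n - 1 if include_intercept else n
    adj = 1.0 - (1.0 - r2) * dfn / (n - p) if n > p else float("nan")
    coeffs = {}
    params = list(res.params)
    if include_intercept:
        coeffs[INTERCEPT] = float(params.pop(0))
    coeffs.update({t: float(b) for t, b in zip(terms, params)})
    model = IsoscapeModel(
        terms=terms,
        coefficients=coeffs,
        include_intercept=include_intercept,
        n_obs=n,
        residual_variance=rss / (n - p) if n > p else float("nan"),
        adjusted_r2=adj,
        aicc=float("nan"),
        design_moment_inverse=np.linalg.inv(X.T @ X),
    )
    return _with_aicc(model, rss)


def _gaussian_aic(n: int, rss: float, k: int) -> float:
    # profile Gaussian log-likelihood: -n/2 (log(2 pi rss/n) + 1)
    if rss <= 0:
        return -math.inf
    ll = -0.5 * n * (math.log(2.0 * math.pi * rss / n) + 1.0)
    return -2.0 * ll + 2.0 * k


def _with_aicc(model: IsoscapeModel, rss: float) -> IsoscapeModel:
    k = model.n_parameters
    n = model.n_obs
    if n - k - 1 <= 0:
        raise UndefinedCriterionError(
            f"AICc undefined for n={n}, k={k} (n - k - 1 <= 0)"
        )
    aic = _gaussian_aic(n, rss, k)
    val = aic + 2.0 * k * (k + 1) / (n - k - 1)
    return IsoscapeModel(
        terms=model.terms,
        coefficients=model.coefficients,
        include_intercept=model.include_intercept,
        n_obs=n,
        residual_variance=model.residual_variance,
        adjusted_r2=model.adjusted_r2,
        aicc=val,
        design_moment_inverse=model.design_moment_inverse,
    )


def aicc(model: IsoscapeModel) -> float:
    """Small-sample Akaike criterion of a fitted model,
    AIC + 2k(k+1)/(n-k-1), with k counting coefficients, intercept and the
    residual variance."""
    return model.aicc


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm knobs (reproducible given ``seed``)."""

    population: int = 50
    generations: int = 200
    mutation_rate: float = 0.1
    elitism: int = 2
    seed: int = 0


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of a model search."""

    model: IsoscapeModel  # final model (refit on all rows when requested)
    search_model: IsoscapeModel  # AICc-best model on the search subset
    validation_index: tuple[str, ...]
    validation_residuals: Mapping[str, float]
    exhaustive: bool
    n_models_evaluated: int


def _count_models(n_candidates: int, max_terms: int) -> int:
    return sum(math.comb(n_candidates, k) for k in range(1, max_terms + 1))


def _fit_terms(
    terms: Sequence[str],
    frame: pd.DataFrame,
    y: Sequence[float],
    include_intercept: bool,
) -> IsoscapeModel | None:
    try:
        return fit_ols(y, term_columns(frame, terms), include_intercept)
    except (CollinearTermsError, UndefinedCriterionError, ValidationError):
        return None


def ga_select(
    candidates: CandidateMatrix,
    response: Sequence[float],
    max_terms: int = 4,
    allow_interactions: bool = True,
    ga_config: GAConfig | None = None,
    validation_fraction: float = 1.0 / 3.0,
    include_intercept: bool = True,
    method: str = "auto",
    exhaustive_threshold: int = 2000,
    refit_full: bool = True,
) -> SelectionResult:
    """Search for the AICc-best term subset of size <= ``max_terms``.

    A validation subset (``validation_fraction`` of the rows, drawn with the
    GA seed *before* any search) is withheld from selection and reported as
    held-out residuals of the chosen model.  ``method`` is "exhaustive",
    "ga", or "auto" (exhaustive whenever the model space has at most
    ``exhaustive_threshold`` members — the GA is a search heuristic, not a
    different criterion, so the two agree wherever enumeration is feasible).
    With ``refit_full`` the selected term set is refit on every supplied row
    before being returned as the final model.
    """
    ga_config = ga_config or GAConfig()
    y = pd.Series(np.asarray(response, dtype=float), index=candidates.frame.index)
    pool = candidate_terms(candidates, allow_interactions)
    if not pool:
        raise OtosrError("candidate set is empty")
    if not 0.0 <= validation_fraction < 1.0:
        raise ValidationError("validation_fraction must be in [0, 1)")

    rng = np.random.default_rng(ga_config.seed)
    n = len(y)
    n_val = int(round(n * validation_fraction))
    val_idx = (
        sorted(rng.choice(n, size=n_val, replace=False).tolist()) if n_val else []
    )
    val_mask = np.zeros(n, dtype=bool)
    val_mask[val_idx] = True
    train_frame = candidates.frame.loc[~val_mask]
    train_y = y[~val_mask]
    if len(train_y) < 8:
        raise ValidationError(
            f"need >= 8 usable sites for selection, got {len(train_y)}"
        )

    cache: dict[tuple[str, ...], IsoscapeModel | None] = {}

    def fit(terms: tuple[str, ...]) -> IsoscapeModel | None:
        if terms not in cache:
            cache[terms] = _fit_terms(terms, train_frame, train_y, include_intercept)
        return cache[terms]

    def key(terms: Iterable[str]) -> tuple[str, ...]:
        return tuple(sorted(set(terms)))

    exhaustive = method == "exhaustive" or (
        method == "auto" and _count_models(len(pool), max_terms) <= exhaustive_threshold
    )
    best: IsoscapeModel | None = None
    if exhaustive:
        for k in range(1, max_terms + 1):
            for combo in itertools.combinations(pool, k):
                m = fit(key(combo))
                if m is not None and (best is None or m.aicc < best.aicc):
                    best = m
    else:
        best = _ga_search(pool, fit, key, max_terms, ga_config, rng)
    if best is None:
        raise OtosrError("no fittable model found in the candidate space")

    val_resid: dict[str, float] = {}
    for i in val_idx:
        row = candidates.frame.iloc[i].to_dict()
        val_resid[str(candidates.frame.index[i])] = float(
            y.iloc[i] - best.predict(row)
        )

    final = best
    if refit_full and n_val:
        refit = _fit_terms(best.terms, candidates.frame, y, include_intercept)
        if refit is not None:
            final = refit
    return SelectionResult(
        model=final,
        search_model=best,
        validation_index=tuple(str(candidates.frame.index[i]) for i in val_idx),
        validation_residuals=val_resid,
        exhaustive=exhaustive,
        n_models_evaluated=len(cache),
    )


def _ga_search(pool, fit, key, max_terms, cfg: GAConfig, rng) -> IsoscapeModel | None:
    """Seeded GA over term subsets: tournament-free ranked selection,
    union-and-trim crossover, add/drop/swap mutation, small elitism."""

    def random_individual():
        k = int(rng.integers(1, max_terms + 1))
        return key(rng.choice(pool, size=min(k, len(pool)), replace=False))

    def score(ind):
        m = fit(ind)
        return math.inf if m is None or not ind else m.aicc

    def mutate(ind):
        ind = list(ind)
        op = rng.random()
        if (op < 1 / 3 or len(ind) <= 1) and len(ind) < max_terms:
            extra = [t for t in pool if t not in ind]
            if extra:
                ind.append(extra[int(rng.integers(len(extra)))])
        elif op < 2 / 3 and len(ind) > 1:
            ind.pop(int(rng.integers(len(ind))))
        else:
            extra = [t for t in pool if t not in ind]
            if extra and ind:
                ind[int(rng.integers(len(ind)))] = extra[
                    int(rng.integers(len(extra)))
                ]
        return key(ind)

    def crossover(a, b):
        union = list(dict.fromkeys(list(a) + list(b)))
        k = int(rng.integers(1, max_terms + 1))
        if len(union) > k:
            union = list(rng.choice(union, size=k, replace=False))
        return key(union)

    n_immigrants = max(2, cfg.population // 10)
    popn = [random_individual() for _ in range(cfg.population)]
    for _ in range(cfg.generations):
        ranked = sorted(popn, key=score)
        nxt = ranked[: cfg.elitism]
        # rank-weighted parent draw (better AICc, higher weight)
        w = np.arange(len(ranked), 0, -1, dtype=float)
        w /= w.sum()
        while len(nxt) < cfg.population - n_immigrants:
            ia, ib = rng.choice(len(ranked), size=2, p=w)
            child = crossover(ranked[ia], ranked[ib])
            if rng.random() < cfg.mutation_rate:
                child = mutate(child)
            nxt.append(child)
        # random immigrants keep the population from collapsing onto one
        # local optimum in small, plateau-rich model spaces
        while len(nxt) < cfg.population:
            nxt.append(random_individual())
        popn = nxt
    best_ind = min(popn, key=score)
    return fit(best_ind)


def predict_interval(
    model: IsoscapeModel,
    covariates: Mapping[str, float],
    level: float = 0.95,
    watershed_id: str = "",
) -> SrPrediction:
    """Point prediction and prediction-interval halfwidth at new covariates.

    halfwidth = t_{(1+level)/2, n-p} * sqrt(s² (1 + x'(X'X)⁻¹x)); the "1 +"
    makes this an interval for a new single observation, always wider than
    the confidence interval for the regression mean at the same point.
    """
    x = model.design_row(covariates)
    mu = model.predict(covariates)
    leverage = float(x @ model.design_moment_inverse @ x)
    tq = float(stats.t.ppf(0.5 * (1.0 + level), model.df_resid))
    hw = tq * math.sqrt(model.residual_variance * (1.0 + leverage))
    return SrPrediction(
        watershed_id=watershed_id,
        predicted_ratio=mu,
        interval_halfwidth=hw,
        level=level,
    )


def fit_terms_on_sites(
    sites: Sequence,
    terms: Sequence[str],
    include_intercept: bool = True,
) -> IsoscapeModel:
    """Fit a fixed term set on water sites (sampled, non-outlier only)."""
    from .geology import build_candidate_matrix

    usable = [s for s in sites if not s.outlier and not s.predicted]
    matrix = build_candidate_matrix(usable)
    y = [s.sr_ratio for s in usable]
    return fit_ols(y, term_columns(matrix.frame, terms), include_intercept)


def select_on_sites(
    sites: Sequence,
    validation_fraction: float = 0.0,
    seed: int = 0,
    **kwargs,
) -> SelectionResult:
    """AICc model selection on the sampled, non-outlier water sites."""
    from .geology import build_candidate_matrix

    usable = [s for s in sites if not s.outlier and not s.predicted]
    matrix = build_candidate_matrix(usable)
    y = [s.sr_ratio for s in usable]
    cfg = kwargs.pop("ga_config", None) or GAConfig(seed=seed)
    return ga_select(
        matrix,
        y,
        ga_config=cfg,
        validation_fraction=validation_fraction,
        **kwargs,
    )
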