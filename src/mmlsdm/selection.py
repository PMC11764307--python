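"""Model selection over feature subsets and model families.

Candidates are scored by MML message length or by the classical penalized
likelihood criteria (AIC, AICc, BIC).  Subsets can be enumerated
exhaustively, or searched with the unimodal walk over subset sizes: start
at size floor(K/2), probe both neighbors, then walk in the improving
direction while the per-size minimum message length keeps strictly
decreasing.  The walk evaluates every subset of each visited size, so it
is exact whenever the per-size minima are unimodal in size.

Conventions (all config-exposed): ties break by smaller subset size, then
lexicographic subset order, then family declaration order; AIC/AICc/BIC
count every free continuous parameter (intercept and the NB dispersion or
hardcore radius included) and take n as the number of points for
pattern-based families and the number of cells otherwise; the intercept
-only (empty-subset) model competes under MML, whose discrete prior codes
D = 0 explicitly, but not under the classical criteria.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .covariates import CovariateGrid
from .errors import InvalidArgumentError, MmlsdmError, NoModelError
from .families import DATA_VIEWS, FittedModel, fit_family
from .mml import MMLConfig, message_length

__all__ = [
    "CRITERIA",
    "SelectionConfig",
    "SelectionOutcome",
    "aic",
    "aicc",
    "bic",
    "exhaustive_select",
    "mml_search",
    "multi_family_select",
    "exhaustive_subsets",
    "search_subsets",
]

logger = logging.getLogger(__name__)

CRITERIA = ("MML", "AIC", "AICc", "BIC")


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion -2l + 2k."""
    return -2.0 * loglik + 2.0 * k


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: AIC + 2k(k+1)/(n-k-1); needs n > k+1."""
    if n <= k + 1:
        raise InvalidArgumentError(
            f"AICc undefined for n={n} <= k+1={k + 1}")
    return aic(loglik, k) + 2.0 * k * (k + 1) / (n - k - 1)


def bic(loglik: float, k: int, n: int) -> float:
    """Bayesian information criterion -2l + k ln n."""
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    return -2.0 * loglik + k * np.log(n)


@dataclass(frozen=True)
class SelectionConfig:
    include_empty_mml: bool = True
    k_features_only: bool = False  # classical criteria count features only
    n_convention: str = "auto"  # auto | points | cells
    mml: MMLConfig = field(default_factory=MMLConfig)


@dataclass
class SelectionOutcome:
    criterion: str
    family: str
    best: FittedModel
    subset: tuple
    score: float
    per_size_minima: dict
    evaluated_count: int

    def to_json(self) -> str:
        return json.dumps({
            "criterion": self.criterion,
            "family": self.family,
            "subset": list(self.subset),
            "score": self.score,
            "per_size_minima": {str(k): v for k, v in
                                sorted(self.per_size_minima.items())},
            "evaluated_count": self.evaluated_count,
            "tie_break": "score, then subset size, then lexicographic "
                         "subset, then family declaration order",
        })


# -- generic subset enumeration over an arbitrary scorer ---------------------
# Exposed separately so search behavior can be validated against brute force
# on synthetic score functions, independent of any model fitting.

def exhaustive_subsets(score_fn, K: int, lo: int = 1):
    """Score every subset of sizes lo..K; return
    (best_subset, best_score, per_size_minima, evaluated_count).

    ``score_fn(subset_tuple) -> float`` (inf marks an unscorable subset).
    Ties break by (score, size, lexicographic subset).
    """
    if K < 1:
        raise InvalidArgumentError("K must be >= 1")
    best = None
    minima = {}
    count = 0
    for size in range(lo, K + 1):
        for subset in itertools.combinations(range(K), size):
            s = score_fn(subset)
            count += 1
            if np.isfinite(s):
                if size not in minima or s < minima[size]:
                    minima[size] = s
                key = (s, size, subset)
                if best is None or key < best:
                    best = key
    if best is None:
        raise NoModelError("no candidate subset could be scored")
    return best[2], best[0], minima, count


def search_subsets(score_fn, K: int, lo: int = 1):
    """Unimodal walk over subset sizes; same return signature as
    :func:`exhaustive_subsets`.

    Per visited size the minimum over all C(K, size) subsets is computed;
    the walk starts at floor(K/2), sets its direction toward the smaller
    neighboring per-size minimum, and continues while the next size
    strictly improves, clamped to [lo, K].
    """
    if K < 1:
        raise InvalidArgumentError("K must be >= 1")
    evaluated = {}
    count = [0]

    def eval_size(size):
        if size in evaluated:
            return evaluated[size][0]
        best = None
        for subset in itertools.combinations(range(K), size):
            s = score_fn(subset)
            count[0] += 1
            if np.isfinite(s):
                key = (s, subset)
                if best is None or key < best:
                    best = key
        evaluated[size] = best if best is not None else (np.inf, None)
        return evaluated[size][0]

    k = min(max(K // 2, lo), K)
    eval_size(k)
    left = eval_size(k - 1) if k - 1 >= lo else np.inf
    right = eval_size(k + 1) if k + 1 <= K else np.inf
    direction = -1 if left < right else 1
    while lo <= k + direction <= K and eval_size(k + direction) < eval_size(k):
        k += direction

    finite = {sz: sc for sz, (sc, sub) in evaluated.items()
              if np.isfinite(sc)}
    if not finite:
        raise NoModelError("no candidate subset could be scored")
    best_size = min(finite, key=lambda sz: (finite[sz], sz,
                                            evaluated[sz][1]))
    return (evaluated[best_size][1], finite[best_size], finite, count[0])


# -- fit-backed scoring ------------------------------------------------------

class _FitScorer:
    """Caches fits per subset and scores them under a given criterion."""

    def __init__(self, data, grid: CovariateGrid, family: str, K: int,
                 config: SelectionConfig, cache=None, fit_kwargs=None):
        self.data = data
        self.grid = grid
        self.family = family
        self.K = K
        self.config = config
        self.cache = cache if cache is not None else {}
        self.fit_kwargs = fit_kwargs or {}

    def fit(self, subset):
        if subset not in self.cache:
            try:
                self.cache[subset] = fit_family(
                    self.family, self.data, self.grid, subset,
                    **self.fit_kwargs)
            except MmlsdmError as exc:
                logger.warning("skipping %s subset %s: %s",
                               self.family, subset, exc)
                self.cache[subset] = None
        return self.cache[subset]

    def _n(self, model):
        conv = self.config.n_convention
        if conv == "points":
            return model.n_points
        if conv == "cells":
            return model.n_cells
        return (model.n_points if DATA_VIEWS[self.family] == "pattern"
                else model.n_cells)

    def score(self, subset, criterion):
        model = self.fit(subset)
        if model is None:
            return np.inf
        if criterion == "MML":
            return message_length(model, self.K, self.config.mml).total
        k = len(model.subset) if self.config.k_features_only \
            else model.n_params
        n = self._n(model)
        try:
            if criterion == "AIC":
                return aic(model.loglik, k)
            if criterion == "AICc":
                return aicc(model.loglik, k, n)
            if criterion == "BIC":
                return bic(model.loglik, k, n)
        except InvalidArgumentError:
            return np.inf
        raise InvalidArgumentError(f"unknown criterion {criterion!r}")


def _lo(criterion, config):
    return 0 if (criterion == "MML" and config.include_empty_mml) else 1


def exhaustive_select(data, grid: CovariateGrid, family: str, K: int,
                      criterion: str = "MML",
                      config: SelectionConfig | None = None,
                      cache=None, **fit_kwargs) -> SelectionOutcome:
    """Score all 2^K - 1 nonempty subsets (plus the intercept-only model
    under MML) and return the argmin."""
    config = config or SelectionConfig()
    _validate(criterion, K)
    scorer = _FitScorer(data, grid, family, K, config, cache, fit_kwargs)
    subset, score, minima, count = exhaustive_subsets(
        lambda s: scorer.score(s, criterion), K, lo=_lo(criterion, config))
    return SelectionOutcome(criterion, family, scorer.fit(subset), subset,
                            score, minima, count)


def mml_search(data, grid: CovariateGrid, family: str, K: int,
               config: SelectionConfig | None = None,
               cache=None, **fit_kwargs) -> SelectionOutcome:
    """Unimodal message-length search over subset sizes (MML criterion)."""
    config = config or SelectionConfig()
    _validate("MML", K)
    scorer = _FitScorer(data, grid, family, K, config, cache, fit_kwargs)
    subset, score, minima, count = search_subsets(
        lambda s: scorer.score(s, "MML"), K, lo=_lo("MML", config))
    return SelectionOutcome("MML", family, scorer.fit(subset), subset,
                            score, minima, count)


def multi_family_select(data_views: dict, grid: CovariateGrid, families,
                        K: int, criterion: str = "MML",
                        config: SelectionConfig | None = None,
                        caches: dict | None = None) -> SelectionOutcome:
    """Run the per-family selection and return the family-wise best.

    ``data_views`` maps family name to the data object it consumes.  MML
    uses the size search per family; classical criteria enumerate
    exhaustively.  Under equal family priors message lengths are directly
    comparable across families; ties keep the first family in declared
    order.
    """
    config = config or SelectionConfig()
    if not families:
        raise InvalidArgumentError("at least one family required")
    best = None
    for fam in families:
        cache = caches.get(fam) if caches is not None else None
        try:
            if criterion == "MML":
                out = mml_search(data_views[fam], grid, fam, K, config,
                                 cache=cache)
            else:
                out = exhaustive_select(data_views[fam], grid, fam, K,
                                        criterion, config, cache=cache)
        except NoModelError:
            logger.warning("family %s produced no scorable model", fam)
            continue
        if best is None or out.score < best.score:
            best = out
    if best is None:
        raise NoModelError("no family produced a scorable model")
    return best


def _validate(criterion, K):
    if criterion not in CRITERIA:
        raise InvalidArgumentError(f"unknown criterion {criterion!r}")
    if K < 1:
        raise InvalidArgumentError("K must be >= 1")
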