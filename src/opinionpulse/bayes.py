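"""Bayesian net-sentiment (PSS) estimation.

Daily polarity proportions theta_i = n_i / N (positive, neutral,
negative) summarize only the posts that happened to be sampled, so the
net sentiment PSS = theta_pos - theta_neg carries sampling uncertainty
that grows as daily volume shrinks.  The model here is the conjugate
Dirichlet–multinomial:

* prior   alpha_i = base + w * (polarity counts over the preceding
  window, default the trailing 7 days); with no history this reduces to
  the balanced non-informative prior (base, base, base);
* posterior alpha_i' = alpha_i + n_i for the day's counts;
* PSS point estimate = posterior mean (alpha_pos' - alpha_neg') / sum;
* equal-tailed credible interval from Monte-Carlo Dirichlet draws of
  theta_pos - theta_neg.

The default prior weight 1/7 makes a full week of history worth about
one average day of data, so the prior stabilizes thin days without
dominating busy ones.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

DEFAULT_WINDOW_DAYS = 7
DEFAULT_PRIOR_WEIGHT = 1.0 / 7.0
DEFAULT_BASE = 1.0
DEFAULT_LEVEL = 0.95
DEFAULT_N_MC = 20000


@dataclass(frozen=True)
class PolarityCounts:
    """Daily polarity counts for one stratum."""

    date: dt.date
    stratum: str
    n_pos: int
    n_neu: int
    n_neg: int

    def __post_init__(self):
        if min(self.n_pos, self.n_neu, self.n_neg) < 0:
            raise ValueError("polarity counts must be non-negative")

    @property
    def N(self) -> int:
        return self.n_pos + self.n_neu + self.n_neg

    def vector(self) -> np.ndarray:
        return np.array([self.n_pos, self.n_neu, self.n_neg], dtype=float)


@dataclass(frozen=True)
class DirichletParams:
    """Pseudo-count parameterization of a Dirichlet over (pos, neu, neg)."""

    alpha_pos: float
    alpha_neu: float
    alpha_neg: float

    def __post_init__(self):
        if min(self.alpha_pos, self.alpha_neu, self.alpha_neg) <= 0:
            raise ValueError("Dirichlet parameters must be positive")

    def vector(self) -> np.ndarray:
        return np.array([self.alpha_pos, self.alpha_neu, self.alpha_neg])

    @property
    def total(self) -> float:
        return self.alpha_pos + self.alpha_neu + self.alpha_neg

    def mean(self) -> np.ndarray:
        return self.vector() / self.total


@dataclass(frozen=True)
class PssEstimate:
    """Point PSS with an equal-tailed credible interval."""

    date: dt.date | None
    stratum: str | None
    pss_point: float
    ci_low: float
    ci_high: float
    level: float
    n_mc: int
    prior_only: bool = False
    n_obs: int = 0


def polarity_proportions(counts: PolarityCounts) -> np.ndarray:
    """theta_i = n_i / N; undefined (ValueError) when N = 0."""
    if counts.N == 0:
        raise ValueError(
            f"polarity proportions undefined for N=0 "
            f"({counts.stratum} {counts.date})"
        )
    return counts.vector() / counts.N


def pss_point(theta: Sequence[float]) -> float:
    """Net sentiment: positive minus negative probability."""
    theta = np.asarray(theta, dtype=float)
    return float(theta[0] - theta[2])


def build_prior(history: Iterable[PolarityCounts],
                prior_weight: float = DEFAULT_PRIOR_WEIGHT,
                base: float = DEFAULT_BASE) -> DirichletParams:
    """Informative prior from a preceding window of counts.

    alpha_i = base + prior_weight * sum(history n_i).  An empty history
    yields the balanced non-informative prior (base, base, base).
    """
    if prior_weight < 0:
        raise ValueError("prior_weight must be non-negative")
    if base <= 0:
        raise ValueError("base must be positive")
    totals = np.zeros(3)
    for h in history:
        totals += h.vector()
    alpha = base + prior_weight * totals
    return DirichletParams(*alpha)


def posterior(prior: DirichletParams, counts: PolarityCounts) -> DirichletParams:
    """Conjugate update: alpha_i' = alpha_i + n_i."""
    return DirichletParams(*(prior.vector() + counts.vector()))


def pss_credible_interval(post: DirichletParams,
                          level: float = DEFAULT_LEVEL,
                          n_mc: int = DEFAULT_N_MC,
                          seed: int | np.random.Generator | None = None,
                          date: dt.date | None = None,
                          stratum: str | None = None,
                          prior_only: bool = False,
                          n_obs: int = 0) -> PssEstimate:
    """Equal-tailed credible interval for theta_pos - theta_neg.

    The point estimate is the closed-form posterior mean; only the
    interval bounds are Monte-Carlo (``n_mc`` Dirichlet draws).
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if n_mc < 1000:
        raise ValueError("n_mc must be >= 1000")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    alpha = post.vector()
    point = float((alpha[0] - alpha[2]) / alpha.sum())
    samples = rng.dirichlet(alpha, size=n_mc)
    diffs = samples[:, 0] - samples[:, 2]
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(diffs, [tail, 1.0 - tail])
    return PssEstimate(date=date, stratum=stratum, pss_point=point,
                       ci_low=float(lo), ci_high=float(hi), level=level,
                       n_mc=n_mc, prior_only=prior_only, n_obs=n_obs)


def daily_pss_series(counts: Sequence[PolarityCounts],
                     window_days: int = DEFAULT_WINDOW_DAYS,
                     prior_weight: float = DEFAULT_PRIOR_WEIGHT,
                     base: float = DEFAULT_BASE,
                     level: float = DEFAULT_LEVEL,
                     n_mc: int = DEFAULT_N_MC,
                     seed: int | None = None) -> list[PssEstimate]:
    """Daily PSS with rolling informative priors, per stratum.

    ``counts`` may mix strata; each stratum is processed independently:
    strata in sorted order, dates ascending within a stratum, one random
    stream spawned per stratum from ``seed``.  A day with N = 0 yields
    the prior-only estimate, flagged.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    by_stratum: dict[str, list[PolarityCounts]] = {}
    for c in counts:
        by_stratum.setdefault(c.stratum, []).append(c)
    strata = sorted(by_stratum)
    streams = np.random.SeedSequence(seed).spawn(len(strata))
    estimates: list[PssEstimate] = []
    for stratum, stream in zip(strata, streams):
        rng = np.random.default_rng(stream)
        series = sorted(by_stratum[stratum], key=lambda c: c.date)
        dates = [c.date for c in series]
        if len(set(dates)) != len(dates):
            raise ValueError(f"duplicate dates in stratum {stratum!r}")
        for i, day in enumerate(series):
            lo = day.date - dt.timedelta(days=window_days)
            history = [h for h in series[:i] if lo <= h.date < day.date]
            prior = build_prior(history, prior_weight=prior_weight, base=base)
            post = posterior(prior, day)
            estimates.append(pss_credible_interval(
                post, level=level, n_mc=n_mc, seed=rng,
                date=day.date, stratum=stratum, prior_only=(day.N == 0),
                n_obs=day.N))
    return estimates


def weekly_average(series: Sequence[PssEstimate]) -> list[tuple[dt.date, float]]:
    """Mean point PSS over consecutive 7-day blocks.

    Blocks are anchored at the earliest date in the series; blocks with
    no days are omitted.
    """
    if not series:
        raise ValueError("weekly_average requires a non-empty series")
    start = min(e.date for e in series)
    blocks: dict[int, list[float]] = {}
    for e in series:
        blocks.setdefault((e.date - start).days // 7, []).append(e.pss_point)
    return [
        (start + dt.timedelta(days=7 * k), float(np.mean(v)))
        for k, v in sorted(blocks.items())
    ]


# ---------------------------------------------------------------------------
# DataFrame-level plumbing

def polarity_counts_frame(frame: pd.DataFrame, stratify_by: str = "nation",
                          dense: bool = True,
                          date_range: tuple[dt.date, dt.date] | None = None
                          ) -> list[PolarityCounts]:
    """Aggregate a labelled working DataFrame into daily PolarityCounts.

    Requires a ``polarity`` column with no missing values.  With
    ``dense`` (default), every (day, stratum) pair in the observed or
    given date extent is emitted, zero-count days included, so the
    rolling prior sees calendar gaps.
    """
    from .engagement import NATION, STRATIFIERS
    from .io import UNKNOWN_RACE

    if frame["polarity"].isna().any():
        raise ValueError("polarity column has missing values; classify first")
    if stratify_by == "nation":
        work = frame.assign(stratum=NATION)
    elif stratify_by == "state":
        work = frame.rename(columns={"state": "stratum"})
        work = work[work["stratum"] != "NA"]
    elif stratify_by == "race":
        work = frame[frame["race"] != UNKNOWN_RACE].rename(columns={"race": "stratum"})
    elif stratify_by == "topic":
        work = (frame[["date", "polarity", "topics"]]
                .explode("topics").dropna(subset=["topics"])
                .rename(columns={"topics": "stratum"}))
    else:
        raise ValueError(f"stratify_by must be one of {STRATIFIERS}")
    pivot = (work.groupby(["date", "stratum", "polarity"]).size()
                 .unstack("polarity", fill_value=0))
    for col in ("positive", "neutral", "negative"):
        if col not in pivot.columns:
            pivot[col] = 0
    pivot = pivot[["positive", "neutral", "negative"]]
    if dense and len(pivot):
        if date_range is not None:
            start, end = date_range
        else:
            obs = pivot.index.get_level_values("date")
            start, end = min(obs), max(obs)
        days = [start + dt.timedelta(days=i) for i in range((end - start).days + 1)]
        strata = sorted(set(pivot.index.get_level_values("stratum")))
        full = pd.MultiIndex.from_product([days, strata], names=["date", "stratum"])
        pivot = pivot.reindex(full, fill_value=0)
    return [
        PolarityCounts(date=d, stratum=s, n_pos=int(r["positive"]),
                       n_neu=int(r["neutral"]), n_neg=int(r["negative"]))
        for (d, s), r in pivot.iterrows()
    ]


_ESTIMATE_COLUMNS = ["date", "stratum", "pss", "ci_low", "ci_high", "N",
                     "level", "n_mc", "prior_only"]


def estimates_to_frame(estimates: Sequence[PssEstimate]) -> pd.DataFrame:
    if not estimates:
        return pd.DataFrame(columns=_ESTIMATE_COLUMNS)
    return pd.DataFrame([
        {"date": e.date, "stratum": e.stratum, "pss": e.pss_point,
         "ci_low": e.ci_low, "ci_high": e.ci_high, "N": e.n_obs,
         "level": e.level, "n_mc": e.n_mc, "prior_only": e.prior_only}
        for e in estimates
    ])


class DirichletNetSentiment(BaseEstimator, TransformerMixin):
    """Transformer: labelled working DataFrame -> daily PSS estimates.

    Thin estimator facade over :func:`daily_pss_series`; see the module
    docstring for the model.
    """

    def __init__(self, stratify_by: str = "nation",
                 window_days: int = DEFAULT_WINDOW_DAYS,
                 prior_weight: float = DEFAULT_PRIOR_WEIGHT,
                 base: float = DEFAULT_BASE, level: float = DEFAULT_LEVEL,
                 n_mc: int = DEFAULT_N_MC, random_state: int | None = None,
                 date_range: tuple[dt.date, dt.date] | None = None):
        self.stratify_by = stratify_by
        self.window_days = window_days
        self.prior_weight = prior_weight
        self.base = base
        self.level = level
        self.n_mc = n_mc
        self.random_state = random_state
        self.date_range = date_range

    def fit(self, X=None, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        counts = polarity_counts_frame(X, stratify_by=self.stratify_by,
                                       date_range=self.date_range)
        estimates = daily_pss_series(
            counts, window_days=self.window_days,
            prior_weight=self.prior_weight, base=self.base,
            level=self.level, n_mc=self.n_mc, seed=self.random_state)
        return estimates_to_frame(estimates)
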