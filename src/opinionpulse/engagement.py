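"""Public Engagement Score (PES).

Raw discussion volume scales sublinearly with population, so comparing
daily post counts across regions of different sizes is not meaningful.
PES divides the daily count by population raised to a scaling exponent,

    PES = N / pop^beta,

with beta in the empirically observed 0.67–0.78 range; the default is
0.725.  Race strata are normalized by national race populations; topic
strata use the national total population (there is no "topic
population").
"""

from __future__ import annotations

import datetime as dt
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import RACE_LABELS, UNKNOWN_RACE, TweetRecord

DEFAULT_BETA = 0.725
NATION = "US"

STRATIFIERS = ("nation", "state", "race", "topic")


def compute_pes(N: float, pop: int, beta: float = DEFAULT_BETA) -> float:
    """Evaluate N / pop**beta.

    ``pop`` must be >= 1 and ``beta`` > 0; N must be >= 0.
    """
    if pop < 1:
        raise ValueError(f"population must be >= 1, got {pop}")
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    if N < 0:
        raise ValueError(f"count must be non-negative, got {N}")
    return N / pop ** beta


def tweets_to_frame(records: Iterable[TweetRecord]) -> pd.DataFrame:
    """Flatten records into the pipeline's working DataFrame."""
    rows = [
        (r.message_id, r.tweet_date, r.tweet_text, r.state, r.surname, r.polarity)
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=["message_id", "date", "text", "state", "surname", "polarity"],
    )


def _stratum_counts(frame: pd.DataFrame, stratify_by: str) -> pd.DataFrame:
    """Daily counts per stratum; topic rows count a post once per topic."""
    if stratify_by == "nation":
        g = frame.groupby("date").size()
        out = g.reset_index(name="N")
        out["stratum"] = NATION
    elif stratify_by == "state":
        g = frame.groupby(["date", "state"]).size()
        out = g.reset_index(name="N").rename(columns={"state": "stratum"})
    elif stratify_by == "race":
        if "race" not in frame.columns:
            raise ValueError("race stratification requires a 'race' column "
                             "(run the race imputer first)")
        sub = frame[frame["race"] != UNKNOWN_RACE]
        g = sub.groupby(["date", "race"]).size()
        out = g.reset_index(name="N").rename(columns={"race": "stratum"})
    elif stratify_by == "topic":
        if "topics" not in frame.columns:
            raise ValueError("topic stratification requires a 'topics' column "
                             "(run the topic tagger first)")
        exploded = frame[["date", "topics"]].explode("topics").dropna(subset=["topics"])
        g = exploded.groupby(["date", "topics"]).size()
        out = g.reset_index(name="N").rename(columns={"topics": "stratum"})
    else:
        raise ValueError(f"stratify_by must be one of {STRATIFIERS}")
    return out[["date", "stratum", "N"]]


def _dense(out: pd.DataFrame, dates: Sequence[dt.date],
           strata: Sequence[str]) -> pd.DataFrame:
    full = pd.MultiIndex.from_product([list(dates), list(strata)],
                                      names=["date", "stratum"])
    dense = (out.set_index(["date", "stratum"])
                .reindex(full, fill_value=0)
                .reset_index())
    dense["N"] = dense["N"].astype(int)
    return dense


class EngagementScorer(BaseEstimator, TransformerMixin):
    """Transformer computing daily PES per stratum.

    Parameters
    ----------
    populations : mapping stratum -> population
        For ``state`` stratification: per-state populations.  For
        ``race``: national race-group populations.  For ``nation`` and
        ``topic``: must contain the national total under ``"US"``.
    stratify_by : one of {"nation", "state", "race", "topic"}
    beta : float, default 0.725
    dense_grid : bool, default False
        Emit N = 0 rows for every (study day, stratum) pair with no posts.
    date_range : (date, date) or None
        Grid extent when ``dense_grid``; defaults to the observed extent.
    """

    def __init__(self, populations: Mapping[str, int] | None = None,
                 stratify_by: str = "nation", beta: float = DEFAULT_BETA,
                 dense_grid: bool = False,
                 date_range: tuple[dt.date, dt.date] | None = None):
        self.populations = populations
        self.stratify_by = stratify_by
        self.beta = beta
        self.dense_grid = dense_grid
        self.date_range = date_range

    def fit(self, X=None, y=None):
        if self.populations is None:
            raise ValueError("populations mapping is required")
        if self.stratify_by not in STRATIFIERS:
            raise ValueError(f"stratify_by must be one of {STRATIFIERS}")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        self.populations_ = dict(self.populations)
        return self

    def transform(self, X) -> pd.DataFrame:
        """``X``: iterable of TweetRecord or the working DataFrame."""
        if not hasattr(self, "populations_"):
            self.fit()
        frame = X if isinstance(X, pd.DataFrame) else tweets_to_frame(X)
        out = _stratum_counts(frame, self.stratify_by)
        if self.dense_grid:
            if self.date_range is not None:
                start, end = self.date_range
            elif len(out):
                start, end = out["date"].min(), out["date"].max()
            else:
                raise ValueError("dense grid on an empty corpus needs date_range")
            dates = [start + dt.timedelta(days=i)
                     for i in range((end - start).days + 1)]
            if self.stratify_by == "state":
                strata = sorted(set(out["stratum"]))
            elif self.stratify_by == "race":
                strata = [r for r in RACE_LABELS]
            elif self.stratify_by == "topic":
                strata = sorted(set(out["stratum"]))
            else:
                strata = [NATION]
            out = _dense(out, dates, strata)
        if self.stratify_by in ("nation", "topic"):
            pops = {s: self._national_pop() for s in out["stratum"].unique()}
        else:
            pops = {}
            for s in out["stratum"].unique():
                if s == "NA":
                    continue
                if s not in self.populations_:
                    raise ValueError(f"no population entry for stratum {s!r}")
                pops[s] = self.populations_[s]
            out = out[out["stratum"] != "NA"].reset_index(drop=True)
        out["pop"] = [pops[s] for s in out["stratum"]]
        out["beta"] = self.beta
        out["pes"] = out["N"].to_numpy() / out["pop"].to_numpy(float) ** self.beta
        return out.sort_values(["date", "stratum"], kind="mergesort").reset_index(drop=True)

    def _national_pop(self) -> int:
        if NATION not in self.populations_:
            raise ValueError("nation/topic stratification requires a 'US' "
                             "population entry")
        return self.populations_[NATION]


def daily_pes(tweets, populations: Mapping[str, int],
              stratify_by: str = "nation", beta: float = DEFAULT_BETA,
              dense_grid: bool = False,
              date_range: tuple[dt.date, dt.date] | None = None) -> pd.DataFrame:
    """Daily PES table: columns date, stratum, N, pop, beta, pes."""
    scorer = EngagementScorer(populations=populations, stratify_by=stratify_by,
                              beta=beta, dense_grid=dense_grid,
                              date_range=date_range)
    return scorer.fit().transform(tweets)
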