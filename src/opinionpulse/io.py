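"""Record types and tabular I/O for the opinion-mining pipeline.

The pipeline consumes four kinds of tables: a geo-located post corpus
(JSONL or CSV), a region population table (CSV), a census-style
surname-to-race percentage table (CSV), and optional daily count series
(CSV).  Everything is plain text; dates are UTC calendar days.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

POLARITIES: tuple[str, ...] = ("positive", "neutral", "negative")

#: 48 contiguous US states plus the District of Columbia.
CONTIGUOUS_STATES: tuple[str, ...] = (
    "AL", "AZ", "AR", "CA", "CO", "CT", "DE", "DC", "FL", "GA", "ID", "IL",
    "IN", "IA", "KS", "KY", "LA", "ME", "MD", "MA", "MI", "MN", "MS", "MO",
    "MT", "NE", "NV", "NH", "NJ", "NM", "NY", "NC", "ND", "OH", "OK", "OR",
    "PA", "RI", "SC", "SD", "TN", "TX", "UT", "VT", "VA", "WA", "WV", "WI",
    "WY",
)

RACE_LABELS: tuple[str, ...] = (
    "white", "black", "api", "aian", "two_prace", "hispanic",
)
UNKNOWN_RACE = "unknown"


@dataclass(frozen=True)
class TweetRecord:
    """One social-media post.

    ``polarity`` is either one of :data:`POLARITIES` (pre-labelled input,
    which bypasses the classifier) or ``None`` (to be classified).
    ``surname`` is ``None`` when the user profile exposes no usable last
    name; such posts end up in the ``unknown`` race stratum.
    """

    message_id: str
    tweet_date: dt.date
    tweet_text: str
    state: str = "NA"
    surname: str | None = None
    polarity: str | None = None

    def replace(self, **kw) -> "TweetRecord":
        return replace(self, **kw)


@dataclass(frozen=True)
class SurnameRaceRow:
    """Race/ethnicity percentage distribution for one surname.

    Percentages are stored renormalized so the six fields sum to exactly
    100 (the published tables carry rounding residue and suppressed
    cells).
    """

    surname: str
    pct_white: float
    pct_black: float
    pct_api: float
    pct_aian: float
    pct_2prace: float
    pct_hispanic: float

    def percentages(self) -> np.ndarray:
        return np.array(
            [self.pct_white, self.pct_black, self.pct_api,
             self.pct_aian, self.pct_2prace, self.pct_hispanic]
        )

    def probabilities(self) -> np.ndarray:
        """Sampling probabilities in :data:`RACE_LABELS` order."""
        return self.percentages() / 100.0


@dataclass
class ParseError:
    line: int
    message: str


@dataclass
class TweetParseResult:
    """Parsed records plus the per-record errors collected along the way.

    ``len(records) + len(errors)`` equals the number of data lines in the
    input: nothing is dropped silently.
    """

    records: list[TweetRecord] = field(default_factory=list)
    errors: list[ParseError] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return len(self.errors)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


_MANDATORY_COLUMNS = ("message_id", "tweet_date", "tweet_text")


def _parse_date(value: str) -> dt.date:
    return dt.date.fromisoformat(str(value).strip())


def _record_from_mapping(obj: Mapping, line: int) -> TweetRecord:
    for col in _MANDATORY_COLUMNS:
        if col not in obj or obj[col] in (None, ""):
            raise ValueError(f"missing mandatory field {col!r}")
    surname = obj.get("surname")
    if surname is not None:
        surname = str(surname).strip() or None
    state = obj.get("state")
    state = str(state).strip() if state not in (None, "") else "NA"
    polarity = obj.get("polarity")
    if polarity in (None, ""):
        polarity = None
    elif polarity not in POLARITIES:
        raise ValueError(f"unknown polarity {polarity!r}")
    return TweetRecord(
        message_id=str(obj["message_id"]),
        tweet_date=_parse_date(obj["tweet_date"]),
        tweet_text=str(obj["tweet_text"]),
        state=state,
        surname=surname,
        polarity=polarity,
    )


def read_tweets(path: str | Path, format: str | None = None) -> TweetParseResult:
    """Read a post corpus from JSONL or CSV.

    Malformed records (bad date, missing field, broken JSON) are collected
    as :class:`ParseError` with their line number; well-formed records are
    returned in file order.  A missing mandatory *column* in a CSV header
    is a fatal :class:`ValueError`.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unknown corpus format {format!r}")
    result = TweetParseResult()
    if format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    obj = json.loads(line)
                    result.records.append(_record_from_mapping(obj, lineno))
                except (ValueError, KeyError) as exc:
                    result.errors.append(ParseError(lineno, str(exc)))
    else:
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            missing = [c for c in _MANDATORY_COLUMNS if c not in header]
            if missing:
                raise ValueError(f"corpus CSV missing mandatory columns: {missing}")
            for lineno, row in enumerate(reader, start=2):
                try:
                    result.records.append(_record_from_mapping(row, lineno))
                except ValueError as exc:
                    result.errors.append(ParseError(lineno, str(exc)))
    for err in result.errors:
        logger.warning("%s line %d: %s", path.name, err.line, err.message)
    return result


def write_tweets(records: Iterable[TweetRecord], path: str | Path) -> None:
    """Write a corpus as JSONL (one object per line, stable key order)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            obj = {
                "message_id": rec.message_id,
                "tweet_date": rec.tweet_date.isoformat(),
                "tweet_text": rec.tweet_text,
                "state": rec.state,
            }
            if rec.surname is not None:
                obj["surname"] = rec.surname
            if rec.polarity is not None:
                obj["polarity"] = rec.polarity
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# Surname table

_SURNAME_COLUMNS = ("name", "white", "black", "api", "aian", "two_prace", "hispanic")
ROW_SUM_TOLERANCE = 0.5


def normalize_surname(raw: str | None) -> str:
    """Trim, strip diacritics (NFKD), and uppercase a surname.

    Returns the empty string for absent/blank input.
    """
    import unicodedata

    if raw is None:
        return ""
    decomposed = unicodedata.normalize("NFKD", raw.strip())
    stripped = "".join(c for c in decomposed if not unicodedata.combining(c))
    return stripped.upper()


def read_surname_table(path: str | Path) -> dict[str, SurnameRaceRow]:
    """Read a census-style ``name,white,black,api,aian,two_prace,hispanic``
    CSV (percent units).

    Surnames are uppercased; rows whose six percentages deviate from 100
    by more than ``0.5`` are rejected with a warning; accepted rows are
    rescaled to sum to exactly 100.  Duplicate surnames: last row wins.
    """
    path = Path(path)
    table: dict[str, SurnameRaceRow] = {}
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _SURNAME_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"surname CSV missing columns: {missing}")
        for row in reader:
            name = normalize_surname(row["name"])
            pcts = np.array([float(row[c]) for c in _SURNAME_COLUMNS[1:]])
            if np.any(pcts < 0) or np.any(pcts > 100):
                logger.warning("surname %s: percentage outside [0,100]; rejected", name)
                continue
            total = float(pcts.sum())
            if abs(total - 100.0) > ROW_SUM_TOLERANCE:
                logger.warning(
                    "surname %s: row sums to %.2f (deviates from 100 by more "
                    "than %.1f); rejected", name, total, ROW_SUM_TOLERANCE,
                )
                continue
            pcts = pcts * (100.0 / total)
            if name in table:
                logger.warning("surname %s: duplicate row, last wins", name)
            table[name] = SurnameRaceRow(name, *pcts)
    return table


def default_surname_table() -> dict[str, SurnameRaceRow]:
    """The six-surname example table shipped with the package."""
    with resources.as_file(
        resources.files("opinionpulse.data") / "surname_race.csv"
    ) as p:
        return read_surname_table(p)


# ---------------------------------------------------------------------------
# Population tables and daily series

def read_population_table(path: str | Path) -> dict[str, int]:
    """Read a ``region,population`` CSV into a mapping."""
    df = pd.read_csv(path, dtype={"region": str})
    if list(df.columns) != ["region", "population"]:
        raise ValueError("population CSV must have columns region,population")
    if df["region"].duplicated().any():
        dupes = df.loc[df["region"].duplicated(), "region"].tolist()
        raise ValueError(f"duplicate region codes: {dupes}")
    pops = {str(r): int(p) for r, p in zip(df["region"], df["population"])}
    bad = [r for r, p in pops.items() if p <= 0]
    if bad:
        raise ValueError(f"non-positive populations for regions: {bad}")
    return pops


def default_state_populations() -> dict[str, int]:
    """2010 census resident populations, 48 contiguous states + DC."""
    with resources.as_file(
        resources.files("opinionpulse.data") / "state_populations.csv"
    ) as p:
        return read_population_table(p)


def default_race_populations() -> dict[str, int]:
    """2010 census national populations per race/ethnicity group."""
    with resources.as_file(
        resources.files("opinionpulse.data") / "race_populations.csv"
    ) as p:
        return read_population_table(p)


def read_daily_series(path: str | Path) -> pd.Series:
    """Read a ``date,value`` CSV into a date-indexed Series.

    Dates must be strictly increasing and values non-negative.
    """
    df = pd.read_csv(path)
    if list(df.columns) != ["date", "value"]:
        raise ValueError("daily series CSV must have columns date,value")
    dates = [_parse_date(d) for d in df["date"]]
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise ValueError("daily series dates must be strictly increasing")
    values = df["value"].astype(float)
    if (values < 0).any():
        raise ValueError("daily series values must be non-negative")
    return pd.Series(values.to_numpy(), index=pd.Index(dates, name="date"),
                     name="value")


def write_daily_series(series: pd.Series, path: str | Path) -> None:
    df = pd.DataFrame({"date": [d.isoformat() for d in series.index],
                       "value": series.to_numpy()})
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Score tables

def write_daily_scores(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a score table with a deterministic column order and 12
    significant digits for reals, so that write-then-read round-trips.
    """
    path = Path(path)
    cols = list(frame.columns)
    # stable canonical ordering: identifiers first, then everything else
    lead = [c for c in ("date", "stratum", "period") if c in cols]
    rest = [c for c in cols if c not in lead]
    out = frame[lead + rest].copy()
    if "date" in out.columns:
        out["date"] = [
            d.isoformat() if hasattr(d, "isoformat") else str(d)
            for d in out["date"]
        ]
    out.to_csv(path, index=False, float_format="%.12g")


def read_daily_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "date" in df.columns:
        df["date"] = [_parse_date(d) for d in df["date"]]
    return df
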