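"""End-to-end orchestration: corpus -> scores -> period summaries.

The study window is partitioned into four sub-periods at three
vaccine-milestone dates (defaults: the efficacy announcement
2020-11-09, the first administered dose 2020-12-14, and the 100-million
-doses mark 2021-03-12; a boundary day starts the new regime).  The
pipeline emits daily PES and daily PSS (with credible intervals) per
stratification, weekly PSS averages, per-period five-number summaries,
the race classification-rate report, and a run manifest.  Everything is
deterministic given the configured seeds.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import shutil
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayes import (
    daily_pss_series,
    estimates_to_frame,
    polarity_counts_frame,
    weekly_average,
)
from .engagement import NATION, daily_pes, tweets_to_frame
from .io import (
    default_race_populations,
    default_state_populations,
    default_surname_table,
    read_daily_series,
    read_population_table,
    read_surname_table,
    read_tweets,
    write_daily_scores,
    write_daily_series,
)
from .race import SurnameRaceImputer
from .sentiment import MultinomialPolarityClassifier
from .synthetic import STUDY_END, STUDY_START, default_study_config, generate_corpus
from .topics import TopicLexicon, TopicTagger, default_lexicon

logger = logging.getLogger(__name__)

DEFAULT_BOUNDARIES = (
    dt.date(2020, 11, 9), dt.date(2020, 12, 14), dt.date(2021, 3, 12),
)


@dataclass(frozen=True)
class PeriodPartition:
    """Four sub-periods cut at three ordered boundary dates.

    ``period_of(d)`` is 1 before ``b1``, 2 in [b1, b2), 3 in [b2, b3),
    4 from ``b3`` on — the event day starts the new regime.
    """

    start: dt.date
    end: dt.date
    b1: dt.date = DEFAULT_BOUNDARIES[0]
    b2: dt.date = DEFAULT_BOUNDARIES[1]
    b3: dt.date = DEFAULT_BOUNDARIES[2]

    def __post_init__(self):
        if not (self.start <= self.b1 < self.b2 < self.b3 <= self.end):
            raise ValueError("boundaries must satisfy start <= B1 < B2 < B3 <= end")

    def period_of(self, day: dt.date) -> int:
        if not self.start <= day <= self.end:
            raise ValueError(f"date {day} outside the study window "
                             f"[{self.start}, {self.end}]")
        if day < self.b1:
            return 1
        if day < self.b2:
            return 2
        if day < self.b3:
            return 3
        return 4


def partition_periods(dates: Sequence[dt.date],
                      boundaries: PeriodPartition) -> dict[dt.date, int]:
    """Map every date to its sub-period label (1-4)."""
    return {d: boundaries.period_of(d) for d in dates}


@dataclass(frozen=True)
class QuartileSummary:
    """Five-number summary of a score distribution within one period."""

    stratum: str
    period: int
    min: float
    q1: float
    median: float
    q3: float
    max: float
    n: int


def quartile_summary(values: Sequence[float], stratum: str = "",
                     period: int = 0, method: str = "linear") -> QuartileSummary:
    """Five-number summary using an interpolation rule from np.quantile.

    The default ``linear`` rule is the inclusive-median convention
    (Excel QUARTILE.INC / R type 7); other np.quantile methods may be
    selected via ``method``.
    """
    values = np.asarray(list(values), float)
    if values.size == 0:
        raise ValueError("quartile_summary requires at least one value")
    q = np.quantile(values, [0.0, 0.25, 0.5, 0.75, 1.0], method=method)
    return QuartileSummary(stratum=stratum, period=int(period),
                           min=float(q[0]), q1=float(q[1]), median=float(q[2]),
                           q3=float(q[3]), max=float(q[4]), n=int(values.size))


# ---------------------------------------------------------------------------
# Configuration

_DEFAULT_CONFIG = {
    "corpus": None,
    "synthetic": None,
    "state_populations": None,
    "race_populations": None,
    "surname_table": None,
    "lexicon": None,
    "classifier_model": None,
    "case_series": None,
    "vaccination_series": None,
    "beta": 0.725,
    "window_days": 7,
    "prior_weight": 1.0 / 7.0,
    "prior_base": 1.0,
    "level": 0.95,
    "n_mc": 2000,
    "quantile_method": "linear",
    "seeds": {"race": 20201001, "pss": 20210521},
    "study_window": {"start": STUDY_START.isoformat(),
                     "end": STUDY_END.isoformat()},
    "periods": {"b1": "2020-11-09", "b2": "2020-12-14", "b3": "2021-03-12"},
    "output_dir": "opinionpulse_out",
}

STRATIFIERS = ("nation", "state", "race", "topic")


def load_config(source: str | Path | Mapping) -> dict:
    """Merge a YAML file or mapping over the built-in defaults."""
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(source)
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in _DEFAULT_CONFIG.items()}
    for k, v in user.items():
        if k not in cfg:
            raise ValueError(f"unknown config key {k!r}")
        if isinstance(cfg[k], dict) and isinstance(v, Mapping):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def _load_corpus(cfg: dict):
    if cfg["corpus"] is not None:
        result = read_tweets(cfg["corpus"])
        return list(result.records), len(result.errors)
    if cfg["synthetic"] is not None:
        syn = dict(cfg["synthetic"])
        config = default_study_config(seed=int(syn.get("seed", 0)),
                                      base_rate=float(syn.get("base_rate", 242.0)))
        records, _ = generate_corpus(config)
        return records, 0
    raise ValueError("config must name a corpus or a synthetic section")


def run_pipeline(config: str | Path | Mapping,
                 out_dir: str | Path | None = None,
                 force: bool = False) -> Path:
    """Run the full analysis; returns the output directory.

    Outputs: ``pes_<stratifier>.csv``, ``pss_<stratifier>.csv``,
    ``pss_weekly_<stratifier>.csv``, ``quartiles_pes.csv``,
    ``quartiles_pss.csv``, ``race_summary.json``, ``manifest.json`` and,
    when configured, pass-through ``case_series.csv`` /
    ``vaccination_series.csv``.  On any stage failure the partially
    written directory is removed.
    """
    cfg = load_config(config)
    out = Path(out_dir if out_dir is not None else cfg["output_dir"])
    if out.exists():
        if not force:
            raise FileExistsError(f"output directory {out} already exists")
        shutil.rmtree(out)
    tmp = out.with_name(out.name + ".partial")
    if tmp.exists():
        shutil.rmtree(tmp)
    tmp.mkdir(parents=True)
    try:
        manifest = _run_stages(cfg, tmp)
        with (tmp / "manifest.json").open("w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        tmp.rename(out)
    except BaseException:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
    return out


def _run_stages(cfg: dict, out: Path) -> dict:
    window = cfg["study_window"]
    start = dt.date.fromisoformat(str(window["start"]))
    end = dt.date.fromisoformat(str(window["end"]))
    periods = PeriodPartition(
        start=start, end=end,
        b1=dt.date.fromisoformat(str(cfg["periods"]["b1"])),
        b2=dt.date.fromisoformat(str(cfg["periods"]["b2"])),
        b3=dt.date.fromisoformat(str(cfg["periods"]["b3"])),
    )
    seeds = cfg["seeds"]

    # -- stage: corpus ----------------------------------------------------
    records, n_parse_errors = _load_corpus(cfg)
    n_total = len(records)
    records = [r for r in records if start <= r.tweet_date <= end]
    n_window = len(records)
    if n_window < n_total:
        logger.info("corpus: dropped %d records outside the study window",
                    n_total - n_window)
    if not records:
        raise ValueError("no corpus records inside the study window")
    logger.info("corpus: %d records, %d parse errors", n_window, n_parse_errors)
    frame = tweets_to_frame(records)

    # -- stage: polarity --------------------------------------------------
    missing = frame["polarity"].isna()
    if missing.any():
        if cfg["classifier_model"] is None:
            raise ValueError(
                f"{int(missing.sum())} records lack polarity labels and no "
                "classifier_model is configured")
        model = MultinomialPolarityClassifier.load(cfg["classifier_model"])
        frame.loc[missing, "polarity"] = model.predict(
            frame.loc[missing, "text"].tolist())
    logger.info("polarity: %d pre-labelled, %d classified",
                int((~missing).sum()), int(missing.sum()))

    # -- stage: topics ----------------------------------------------------
    lexicon = (TopicLexicon.from_yaml(cfg["lexicon"])
               if cfg["lexicon"] else default_lexicon())
    frame = TopicTagger(lexicon=lexicon).fit().transform(frame)
    logger.info("topics: %d posts carry at least one topic",
                int(sum(bool(t) for t in frame["topics"])))

    # -- stage: race ------------------------------------------------------
    table = (read_surname_table(cfg["surname_table"])
             if cfg["surname_table"] else default_surname_table())
    imputer = SurnameRaceImputer(surname_table=table,
                                 random_state=int(seeds["race"]))
    frame = imputer.fit().transform(frame)
    race_summary = imputer.summary_
    logger.info("race: matched fraction %.3f", race_summary["matched_fraction"])
    with (out / "race_summary.json").open("w", encoding="utf-8") as fh:
        json.dump(race_summary, fh, indent=2, sort_keys=True)

    # -- stage: populations ----------------------------------------------
    state_pops = (read_population_table(cfg["state_populations"])
                  if cfg["state_populations"] else default_state_populations())
    race_pops = (read_population_table(cfg["race_populations"])
                 if cfg["race_populations"] else default_race_populations())
    populations = dict(state_pops)
    populations.update(race_pops)
    populations.setdefault(NATION, sum(state_pops.values()))

    # -- stage: PES -------------------------------------------------------
    beta = float(cfg["beta"])
    pes_frames = {}
    for strat in STRATIFIERS:
        pes = daily_pes(frame, populations, stratify_by=strat, beta=beta,
                        dense_grid=True, date_range=(start, end))
        pes_frames[strat] = pes
        write_daily_scores(pes, out / f"pes_{strat}.csv")
    logger.info("pes: wrote %d stratifications", len(STRATIFIERS))

    # -- stage: PSS -------------------------------------------------------
    pss_daily = {}
    pss_weekly = {}
    for k, strat in enumerate(STRATIFIERS):
        counts = polarity_counts_frame(frame, stratify_by=strat,
                                       date_range=(start, end))
        estimates = daily_pss_series(
            counts, window_days=int(cfg["window_days"]),
            prior_weight=float(cfg["prior_weight"]),
            base=float(cfg["prior_base"]), level=float(cfg["level"]),
            n_mc=int(cfg["n_mc"]), seed=int(seeds["pss"]) + k)
        daily = estimates_to_frame(estimates)
        pss_daily[strat] = daily
        write_daily_scores(daily, out / f"pss_{strat}.csv")
        weekly_rows = []
        for stratum in sorted(daily["stratum"].unique()):
            sub = [e for e in estimates if e.stratum == stratum]
            for week_start, mean in weekly_average(sub):
                weekly_rows.append((week_start, stratum, mean))
        weekly = pd.DataFrame(weekly_rows, columns=["date", "stratum", "pss"])
        pss_weekly[strat] = weekly
        write_daily_scores(weekly, out / f"pss_weekly_{strat}.csv")
    logger.info("pss: wrote daily and weekly series")

    # -- stage: per-period quartile summaries -----------------------------
    method = str(cfg["quantile_method"])
    pes_rows = []
    for strat, pes in pes_frames.items():
        pes = pes.assign(period=[periods.period_of(d) for d in pes["date"]])
        for (stratum, period), grp in pes.groupby(["stratum", "period"]):
            s = quartile_summary(grp["pes"], stratum=stratum, period=period,
                                 method=method)
            pes_rows.append((strat, s.stratum, s.period, s.min, s.q1,
                             s.median, s.q3, s.max, s.n))
    qcols = ["stratify_by", "stratum", "period", "min", "q1", "median",
             "q3", "max", "n"]
    write_daily_scores(pd.DataFrame(pes_rows, columns=qcols),
                       out / "quartiles_pes.csv")
    pss_rows = []
    for strat, weekly in pss_weekly.items():
        weekly = weekly.assign(period=[periods.period_of(d)
                                       for d in weekly["date"]])
        for (stratum, period), grp in weekly.groupby(["stratum", "period"]):
            s = quartile_summary(grp["pss"], stratum=stratum, period=period,
                                 method=method)
            pss_rows.append((strat, s.stratum, s.period, s.min, s.q1,
                             s.median, s.q3, s.max, s.n))
    write_daily_scores(pd.DataFrame(pss_rows, columns=qcols),
                       out / "quartiles_pss.csv")
    logger.info("quartiles: wrote per-period summaries")

    # -- stage: aligned external series -----------------------------------
    for key, name in (("case_series", "case_series.csv"),
                      ("vaccination_series", "vaccination_series.csv")):
        if cfg[key]:
            series = read_daily_series(cfg[key])
            aligned = series[(series.index >= start) & (series.index <= end)]
            write_daily_series(aligned, out / name)

    return {
        "package_version": __version__,
        "generated_at": dt.datetime.now(dt.timezone.utc).isoformat(),
        "parameters": {
            "beta": beta,
            "window_days": int(cfg["window_days"]),
            "prior_weight": float(cfg["prior_weight"]),
            "prior_base": float(cfg["prior_base"]),
            "level": float(cfg["level"]),
            "n_mc": int(cfg["n_mc"]),
            "quantile_method": method,
            "study_window": [start.isoformat(), end.isoformat()],
            "period_boundaries": [periods.b1.isoformat(),
                                  periods.b2.isoformat(),
                                  periods.b3.isoformat()],
        },
        "seeds": {k: int(v) for k, v in seeds.items()},
        "counts": {
            "records_total": n_total,
            "records_in_window": n_window,
            "parse_errors": n_parse_errors,
            "race_matched": race_summary["matched"],
        },
    }
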