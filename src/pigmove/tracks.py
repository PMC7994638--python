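"""GPS fix handling: parsing, cleaning, regularization, and step derivation.

A *fix* is one GPS location (animal, UTC timestamp, projected x/y in
metres).  Cleaning removes duplicate timestamps, an initial post-capture
acclimation window (the first 48 h after deployment, when movement can be
affected by anesthesia), and any locations recorded after mortality onset.
Cleaned tracks are *regularized* to a target fix interval: 30-min schedules
are thinned to hourly, and runs interrupted by gaps are split into
contiguous *bursts*.  Each burst yields a step series — step lengths,
turning angles, and the clock hour of each step's start — the observation
streams of the movement HMM.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .distributions import wrap_angle

logger = logging.getLogger(__name__)

LOW_FORAGE = "low_forage"
HIGH_FORAGE = "high_forage"

#: 48-hour acclimation window dropped after collar deployment
ACCLIMATION = pd.Timedelta(hours=48)

REQUIRED_COLUMNS = ("animal_id", "timestamp", "x", "y")


class FixFormatError(ValueError):
    """The fix table is structurally unusable (e.g. a missing column)."""


@dataclasses.dataclass
class CleaningLog:
    """Counts of fixes removed by each cleaning rule."""

    n_duplicates: int = 0
    n_acclimation: int = 0
    n_post_mortality: int = 0


@dataclasses.dataclass
class Track:
    """A cleaned, time-ordered fix sequence for one animal."""

    animal_id: str
    fixes: pd.DataFrame  # columns t, x, y (t tz-aware UTC, strictly increasing)
    deploy_time: pd.Timestamp
    sex: Optional[str] = None
    log: CleaningLog = dataclasses.field(default_factory=CleaningLog)

    @property
    def empty(self) -> bool:
        return len(self.fixes) == 0

    def __len__(self) -> int:
        return len(self.fixes)


@dataclasses.dataclass
class Burst:
    """A maximal run of fixes at the target interval (within tolerance)."""

    animal_id: str
    burst_id: int
    fixes: pd.DataFrame
    interval: float  # seconds

    def __len__(self) -> int:
        return len(self.fixes)


@dataclasses.dataclass
class StepSeries:
    """Derived movement observations for one burst.

    ``turns[0]`` is NaN: the first step of a burst has no preceding heading,
    so its angle term is omitted from the HMM likelihood.
    """

    animal_id: str
    burst_id: int
    t: np.ndarray  # start time of each step (datetime64)
    steps: np.ndarray  # step length (m), length n_fixes - 1
    turns: np.ndarray  # turning angle (rad) in (-pi, pi], NaN where missing
    hours: np.ndarray  # clock hour of step start, [0, 24)
    season: str

    def __len__(self) -> int:
        return len(self.steps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": self.animal_id,
                "burst_id": self.burst_id,
                "t": self.t,
                "step_m": self.steps,
                "turn_rad": self.turns,
                "hour": self.hours,
                "season": self.season,
            }
        )


def parse_fixes(path) -> pd.DataFrame:
    """Read a fix table from CSV.

    Expected columns: ``animal_id``, ``timestamp`` (ISO-8601), ``x``, ``y``
    and optionally ``sex`` and ``mortality`` (0/1).  Coordinates must be in
    a projected metric CRS.  Malformed rows (unparseable timestamp or
    non-finite coordinates) are dropped and reported; their 0-based row
    numbers are listed in ``result.attrs["rejected_rows"]``.

    Raises
    ------
    FixFormatError
        If a mandatory column is absent.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FixFormatError(
            f"fix table {path} is missing mandatory column(s): {', '.join(missing)}"
        )
    t = pd.to_datetime(df["timestamp"], errors="coerce", utc=True, format="ISO8601")
    x = pd.to_numeric(df["x"], errors="coerce")
    y = pd.to_numeric(df["y"], errors="coerce")
    bad = t.isna() | ~np.isfinite(x) | ~np.isfinite(y)
    rejected = df.index[bad].tolist()
    if rejected:
        logger.warning("parse_fixes: rejected %d malformed row(s): %s",
                       len(rejected), rejected)
    out = pd.DataFrame(
        {"animal_id": df["animal_id"].astype(str), "t": t, "x": x, "y": y}
    )
    if "sex" in df.columns:
        out["sex"] = df["sex"]
    if "mortality" in df.columns:
        out["mortality"] = pd.to_numeric(df["mortality"], errors="coerce").fillna(0).astype(int)
    out = out[~bad].reset_index(drop=True)
    out.attrs["rejected_rows"] = rejected
    return out


def clean(
    fixes: pd.DataFrame,
    deploy_time,
    mortality_time=None,
    sex: Optional[str] = None,
) -> Track:
    """Apply the fix-cleaning rules for one animal.

    Rules, in order: sort by time; collapse duplicate timestamps to the
    first occurrence; drop fixes earlier than ``deploy_time + 48 h``
    (half-open: a fix at exactly +48 h is retained); drop fixes at or after
    ``mortality_time``.  An empty result is returned as an empty ``Track``,
    not an error.
    """
    ids = fixes["animal_id"].unique()
    if len(ids) > 1:
        raise ValueError(f"clean() expects fixes from a single animal, got {ids}")
    animal_id = str(ids[0]) if len(ids) else "<empty>"
    deploy_time = pd.Timestamp(deploy_time)
    if deploy_time.tzinfo is None:
        deploy_time = deploy_time.tz_localize("UTC")
    df = fixes.sort_values("t", kind="stable").reset_index(drop=True)
    log = CleaningLog()

    dup = df["t"].duplicated(keep="first")
    log.n_duplicates = int(dup.sum())
    df = df[~dup]

    early = df["t"] < deploy_time + ACCLIMATION
    log.n_acclimation = int(early.sum())
    df = df[~early]

    if mortality_time is not None:
        mt = pd.Timestamp(mortality_time)
        if mt.tzinfo is None:
            mt = mt.tz_localize("UTC")
        dead = df["t"] >= mt
        log.n_post_mortality = int(dead.sum())
        df = df[~dead]

    if sex is None and "sex" in df.columns and len(df):
        sex = str(df["sex"].iloc[0])
    df = df[["t", "x", "y"]].reset_index(drop=True)
    if df.empty:
        logger.info("clean: track %s empty after cleaning", animal_id)
    logger.debug(
        "clean %s: %d duplicates, %d acclimation, %d post-mortality removed",
        animal_id, log.n_duplicates, log.n_acclimation, log.n_post_mortality,
    )
    return Track(animal_id=animal_id, fixes=df, deploy_time=deploy_time,
                 sex=sex, log=log)


def regularize(track: Track, interval: float = 3600.0, tol: float = 300.0) -> list[Burst]:
    """Cut a cleaned track into bursts at the target fix interval.

    If the track's median inter-fix gap matches *half* the target interval
    (a 30-min schedule against an hourly target), the track is first thinned
    to every other fix starting from the first.  The thinned series is then
    split wherever the gap falls outside ``interval ± tol``; fragments
    shorter than 3 fixes (too short to yield a turning angle) are discarded.
    """
    df = track.fixes
    if len(df) < 2:
        return []
    dt = df["t"].diff().dt.total_seconds().to_numpy()[1:]
    med = float(np.median(dt))
    if abs(med - interval / 2.0) <= tol:
        df = df.iloc[::2].reset_index(drop=True)
        logger.info("regularize %s: thinned 30-min schedule to %ds", track.animal_id, int(interval))
        dt = df["t"].diff().dt.total_seconds().to_numpy()[1:]

    good = np.abs(dt - interval) <= tol
    # burst boundaries where the gap to the previous fix is off-schedule
    boundary = np.concatenate(([True], ~good))
    seg_ids = np.cumsum(boundary) - 1
    bursts: list[Burst] = []
    n_discarded = 0
    bid = 0
    for seg in np.unique(seg_ids):
        part = df[seg_ids == seg]
        if len(part) < 3:
            n_discarded += 1
            continue
        bursts.append(Burst(track.animal_id, bid, part.reset_index(drop=True), interval))
        bid += 1
    if n_discarded:
        logger.info("regularize %s: discarded %d fragment(s) shorter than 3 fixes",
                    track.animal_id, n_discarded)
    return bursts


def assign_season(t) -> str:
    """Map a timestamp to the forage-availability season.

    January–April is the low-forage season (winter/early spring, peak
    trapping); May–December is the high-forage season (spring green-up
    through fall/early-winter mast).
    """
    month = pd.Timestamp(t).month
    return LOW_FORAGE if month <= 4 else HIGH_FORAGE


def compute_steps(burst: Burst) -> StepSeries:
    """Derive step lengths, turning angles, and hour covariate for a burst.

    For fixes p_0..p_{n-1}: n-1 step lengths (Euclidean distance between
    consecutive fixes) and n-2 turning angles (signed change in heading,
    counterclockwise positive, wrapped to (-pi, pi]).  The hour covariate is
    the fractional clock hour of the step's starting fix.
    """
    n = len(burst)
    if n < 3:
        raise ValueError(f"burst must have at least 3 fixes, got {n}")
    x = burst.fixes["x"].to_numpy(dtype=float)
    y = burst.fixes["y"].to_numpy(dtype=float)
    t = burst.fixes["t"]
    dx = np.diff(x)
    dy = np.diff(y)
    steps = np.hypot(dx, dy)
    headings = np.arctan2(dy, dx)
    turns = np.full(n - 1, np.nan)
    turns[1:] = wrap_angle(np.diff(headings))
    tt = t.iloc[:-1]
    hours = (
        tt.dt.hour + tt.dt.minute / 60.0 + tt.dt.second / 3600.0
    ).to_numpy(dtype=float)
    season = assign_season(t.iloc[0])
    return StepSeries(
        animal_id=burst.animal_id,
        burst_id=burst.burst_id,
        t=tt.to_numpy(),
        steps=steps,
        turns=turns,
        hours=hours,
        season=season,
    )


def steps_to_frame(series: Sequence[StepSeries]) -> pd.DataFrame:
    """Concatenate step series into one tidy table."""
    if not series:
        return pd.DataFrame(
            columns=["animal_id", "burst_id", "t", "step_m", "turn_rad", "hour", "season"]
        )
    return pd.concat([s.to_frame() for s in series], ignore_index=True)


def preprocess(
    fixes: pd.DataFrame,
    deploy_times=None,
    mortality_times=None,
    interval: float = 3600.0,
    tol: float = 300.0,
) -> list[StepSeries]:
    """Full fix-to-steps pipeline for a multi-animal fix table.

    ``deploy_times``/``mortality_times`` are optional mappings keyed by
    animal id; when deployment is not given, the first fix time is used.
    """
    out: list[StepSeries] = []
    for animal_id, grp in fixes.groupby("animal_id", sort=True):
        dep = (deploy_times or {}).get(animal_id, grp["t"].min())
        mort = (mortality_times or {}).get(animal_id)
        track = clean(grp, dep, mort)
        if track.empty:
            continue
        for burst in regularize(track, interval=interval, tol=tol):
            out.append(compute_steps(burst))
    return out
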