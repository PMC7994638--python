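"""Synthetic study system: landscapes, movement tracks, selection points.

The generator emulates the structure of a southeastern US pine-savanna
telemetry study: tens of GPS-collared wild pigs split by sex and by a
low-forage (January–April) vs high-forage (May–December) season, hourly
fixes, a heterogeneous 30-m land-cover mosaic dominated by upland pine
with bottomland hardwood drains, and used-available selection with known
coefficients and per-animal random intercepts.

Movement and selection are simulated *separately* — tracks in habitat-free
(ballistic) mode from the state-switching model, selection point-wise from
an exponential RSF — because the two analyses estimate separate quantities
and coupling them in one simulator would conflate the estimands.

Default emission parameters are the published sex-by-season estimates for
the three behavioral states (resting, foraging, traveling): gamma step
means/SDs in metres and wrapped-Cauchy angular means in radians.  The
angular concentrations are not published; defaults (0.8, 0.6, 0.85) give
the reported character of each state — tight reversal-dominated turning at
rest and while foraging, near-straight traveling.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import LineString

from .distributions import wcauchy_rvs, wrap_angle
from .hmm import HMMParams, _tcov_design
from .landscape import CLASS_CODES, Landscape, Raster
from .tracks import HIGH_FORAGE, LOW_FORAGE, StepSeries, Track, assign_season

__all__ = [
    "EMISSION_DEFAULTS",
    "DEFAULT_RHOS",
    "default_hmm_params",
    "LandscapeConfig",
    "TrackSimConfig",
    "RSFSimConfig",
    "make_landscape",
    "simulate_track",
    "simulate_fix_table",
    "simulate_rsf_points",
]

# (sex, season) -> dict of per-state emission parameters
# states ordered resting, foraging, traveling (ascending mean step)
EMISSION_DEFAULTS = {
    ("female", LOW_FORAGE): {
        "means": (11.4, 37.70, 244.30),
        "sds": (7.38, 23.24, 220.97),
        "turn_means": (3.14, 3.11, 0.001),
    },
    ("female", HIGH_FORAGE): {
        "means": (19.25, 67.29, 276.62),
        "sds": (13.08, 48.32, 227.91),
        "turn_means": (-3.11, 3.14, 0.07),
    },
    ("male", LOW_FORAGE): {
        "means": (9.68, 33.00, 398.43),
        "sds": (6.31, 23.11, 385.81),
        "turn_means": (-3.12, -3.12, -0.04),
    },
    ("male", HIGH_FORAGE): {
        "means": (14.27, 52.46, 420.70),
        "sds": (9.56, 34.67, 406.12),
        "turn_means": (3.11, 3.13, 0.02),
    },
}

#: wrapped-Cauchy concentrations (resting, foraging, traveling)
DEFAULT_RHOS = (0.8, 0.6, 0.85)

#: default stay probability of the generating transition matrix
DEFAULT_STAY = 0.8


def default_hmm_params(
    sex: str,
    season: str,
    covariate_form: str = "none",
    stay: float = DEFAULT_STAY,
    diel_amplitude: float = 0.0,
) -> HMMParams:
    """Generating HMM parameters for a sex-season stratum.

    With ``stay`` = 0.8 and three states the transition matrix is 0.8 on
    the diagonal, 0.1 off.  ``diel_amplitude`` > 0 adds a cosine term of
    that magnitude to every off-diagonal transition logit (requires the
    cosinor covariate form), giving a diel cycle in state occupancy.
    """
    em = EMISSION_DEFAULTS[(sex, season)]
    K = 3
    tpm = np.full((K, K), (1.0 - stay) / (K - 1))
    np.fill_diagonal(tpm, stay)
    params = HMMParams.constant_transitions(
        means=np.array(em["means"]),
        sds=np.array(em["sds"]),
        turn_means=np.array(em["turn_means"]),
        rhos=np.array(DEFAULT_RHOS),
        tpm=tpm,
        covariate_form=covariate_form,
    )
    if diel_amplitude:
        if covariate_form != "cosinor":
            raise ValueError("diel_amplitude requires covariate_form='cosinor'")
        params.beta[:, 1] = diel_amplitude
    return params


# -- landscape -------------------------------------------------------------

@dataclasses.dataclass
class LandscapeConfig:
    """Synthetic landscape: extent, class mixture, features, seed.

    Default class weights follow the study-area composition (about half
    upland pine, a quarter bottomland hardwood, the rest shrub/herb,
    upland hardwood, developed, and other cover).
    """

    extent: float = 15_000.0  # metres (square)
    cell: float = 30.0
    weights: dict = dataclasses.field(
        default_factory=lambda: {
            "upland_pine": 0.50,
            "bottomland_hardwood": 0.25,
            "shrub_herb": 0.10,
            "upland_hardwood": 0.08,
            "developed": 0.03,
            "other": 0.04,
        }
    )
    patch_scale: float = 600.0  # metres; correlation length of patches
    n_streams: int = 3
    n_primary_roads: int = 1
    n_secondary_roads: int = 4
    canopy_smoothness: float = 300.0  # metres
    seed: int = 0

    def __post_init__(self):
        total = sum(self.weights.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"class weights must sum to 1, got {total}")
        if self.extent % self.cell:
            raise ValueError("extent must be a multiple of the cell size")


def _smooth_field(n: int, sigma_cells: float, rng) -> np.ndarray:
    field = rng.standard_normal((n, n))
    if sigma_cells > 0:
        field = ndimage.gaussian_filter(field, sigma=sigma_cells, mode="reflect")
    return field


def _random_polyline(extent: float, rng, n_seg: int = 40) -> LineString:
    """A random-walk polyline crossing the extent (stream/road analog)."""
    edge = rng.integers(4)
    t = rng.uniform(0.2, 0.8)
    start = {
        0: (0.0, t * extent),
        1: (extent, t * extent),
        2: (t * extent, 0.0),
        3: (t * extent, extent),
    }[edge]
    heading = {0: 0.0, 1: np.pi, 2: np.pi / 2, 3: -np.pi / 2}[edge]
    step = extent / n_seg * 1.4
    pts = [start]
    x, y = start
    for _ in range(n_seg):
        heading += rng.normal(0.0, 0.35)
        x += step * np.cos(heading)
        y += step * np.sin(heading)
        pts.append((x, y))
        if not (0 <= x <= extent and 0 <= y <= extent):
            break
    line = LineString(pts)
    return line.intersection(shapely.box(0, 0, extent, extent))


def make_landscape(config: LandscapeConfig) -> Landscape:
    """Generate a co-registered class raster, feature polylines, and canopy.

    The class raster comes from a Gaussian random field smoothed to the
    patch scale and thresholded at the quantiles of the class weights,
    which yields contiguous patches with the requested areal mixture.
    Canopy is a second smoothed field rescaled to [0, 100] and elevated
    inside forested classes.
    """
    rng = np.random.default_rng(config.seed)
    n = int(config.extent / config.cell)
    field = _smooth_field(n, config.patch_scale / config.cell / 2.0, rng)

    names = list(config.weights)
    w = np.array([config.weights[k] for k in names])
    positive = w > 0
    edges = np.quantile(field, np.cumsum(w)[:-1]) if len(w) > 1 else []
    classes = np.digitize(field, edges)
    codes = np.array([CLASS_CODES[k] for k in names])
    class_raster = codes[classes]
    # degenerate mixtures (a single positive weight) map everything there
    if positive.sum() == 1:
        class_raster = np.full((n, n), codes[np.argmax(w)])

    def lines(count):
        geoms = [_random_polyline(config.extent, rng) for _ in range(count)]
        geoms = [g for g in geoms if not g.is_empty]
        return shapely.union_all(geoms) if geoms else LineString()

    streams = lines(config.n_streams)
    primary = lines(config.n_primary_roads)
    secondary = lines(config.n_secondary_roads)

    canopy_field = _smooth_field(n, config.canopy_smoothness / config.cell / 2.0, rng)
    lo, hi = canopy_field.min(), canopy_field.max()
    canopy = (canopy_field - lo) / (hi - lo + 1e-12) * 60.0
    forested = np.isin(
        class_raster,
        [CLASS_CODES["upland_pine"], CLASS_CODES["bottomland_hardwood"],
         CLASS_CODES["upland_hardwood"]],
    )
    canopy = np.clip(canopy + 40.0 * forested, 0.0, 100.0)

    return Landscape(
        classes=Raster(class_raster.astype(np.int32), 0.0, 0.0, config.cell),
        canopy=Raster(canopy, 0.0, 0.0, config.cell),
        streams=streams,
        primary_roads=primary,
        secondary_roads=secondary,
    )


# -- movement --------------------------------------------------------------

@dataclasses.dataclass
class TrackSimConfig:
    """Track simulation: animals per sex-season stratum, steps, schedule."""

    n_animals: int = 8  # per sex-season stratum
    n_steps: int = 1000
    interval: float = 3600.0  # seconds
    sexes: tuple = ("female", "male")
    seasons: tuple = (LOW_FORAGE, HIGH_FORAGE)
    start_spread: float = 10_000.0  # metres; animals scattered over this box
    start_origin: tuple = (0.0, 0.0)
    seed: int = 0


def simulate_track(
    params: HMMParams,
    n_steps: int,
    start: tuple[float, float] = (0.0, 0.0),
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    t0: str | pd.Timestamp = "2014-01-15 00:00:00+00:00",
    interval: float = 3600.0,
    animal_id: str = "sim",
):
    """Simulate one movement track from a fitted or specified HMM.

    States follow the initial distribution then the (hour-dependent)
    transition matrix evaluated at each step's clock hour; the step length
    comes from the state's gamma, the turning angle from its wrapped
    Cauchy, and positions accumulate heading (first heading uniform).

    Returns ``(track, states, series)``: the fix-level :class:`Track`, the
    1-based true state per step, and the derived :class:`StepSeries`.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    K = params.n_states
    t0 = pd.Timestamp(t0)
    if t0.tzinfo is None:
        t0 = t0.tz_localize("UTC")
    times = t0 + pd.to_timedelta(np.arange(n_steps + 1) * interval, unit="s")
    hours = (
        times.hour + times.minute / 60.0 + times.second / 3600.0
    ).to_numpy(dtype=float)[: n_steps + 1]

    tcov = _tcov_design(hours, params.covariate_form)
    states = np.empty(n_steps, dtype=int)
    states[0] = rng.choice(K, p=params.delta)
    # transition into step t happens at step t's starting hour
    for t in range(1, n_steps):
        G = _transition_from_row(params, tcov[t])
        states[t] = rng.choice(K, p=G[states[t - 1]])

    shapes = (params.means / params.sds) ** 2
    scales = params.sds**2 / params.means
    steps = rng.gamma(shapes[states], scales[states])
    turns = np.full(n_steps, np.nan)
    for k in range(K):
        sel = np.nonzero(states[1:] == k)[0] + 1
        if sel.size:
            turns[sel] = wcauchy_rvs(
                params.turn_means[k], params.rhos[k], sel.size, rng
            )

    headings = np.empty(n_steps)
    headings[0] = rng.uniform(-np.pi, np.pi)
    for t in range(1, n_steps):
        headings[t] = headings[t - 1] + turns[t]
    headings = wrap_angle(headings)

    x = np.concatenate([[start[0]], start[0] + np.cumsum(steps * np.cos(headings))])
    y = np.concatenate([[start[1]], start[1] + np.cumsum(steps * np.sin(headings))])

    fixes = pd.DataFrame({"t": times, "x": x, "y": y})
    track = Track(
        animal_id=animal_id,
        fixes=fixes,
        deploy_time=t0 - pd.Timedelta(hours=48),
    )
    series = StepSeries(
        animal_id=animal_id,
        burst_id=0,
        t=times[:-1].to_numpy(),
        steps=steps,
        turns=turns,
        hours=hours[:-1],
        season=assign_season(t0),
    )
    return track, states + 1, series


def _transition_from_row(params: HMMParams, tc: np.ndarray) -> np.ndarray:
    K = params.n_states
    G = np.empty((K, K))
    p = 0
    for i in range(K):
        etas = np.zeros(K)
        for j in range(K):
            if j != i:
                etas[j] = params.beta[p] @ tc
                p += 1
        ex = np.exp(etas - etas[i])
        G[i] = ex / ex.sum()
    return G


SEASON_START = {LOW_FORAGE: "2014-01-15 00:00:00+00:00",
                HIGH_FORAGE: "2014-06-15 00:00:00+00:00"}


def simulate_fix_table(config: TrackSimConfig, params_by_stratum=None):
    """Simulate a multi-animal fix table across sex-season strata.

    Returns ``(fixes, truth)``: a tidy fix CSV table (animal_id, timestamp,
    x, y, sex) and a step-level truth table with the true state labels.
    """
    rng = np.random.default_rng(config.seed)
    fix_rows = []
    truth_rows = []
    for sex in config.sexes:
        for season in config.seasons:
            params = (params_by_stratum or {}).get(
                (sex, season), default_hmm_params(sex, season)
            )
            for a in range(config.n_animals):
                aid = f"{sex[0].upper()}{a:02d}"
                start = (
                    config.start_origin[0] + rng.uniform(0, config.start_spread),
                    config.start_origin[1] + rng.uniform(0, config.start_spread),
                )
                track, states, series = simulate_track(
                    params, config.n_steps, start=start, rng=rng,
                    t0=SEASON_START[season], interval=config.interval,
                    animal_id=aid,
                )
                df = track.fixes.copy()
                df["animal_id"] = aid
                df["sex"] = sex
                fix_rows.append(df)
                truth_rows.append(
                    pd.DataFrame(
                        {
                            "animal_id": aid,
                            "sex": sex,
                            "season": season,
                            "t": series.t,
                            "true_state": states,
                        }
                    )
                )
    fixes = pd.concat(fix_rows, ignore_index=True)
    fixes = fixes.rename(columns={"t": "timestamp"})[
        ["animal_id", "timestamp", "x", "y", "sex"]
    ]
    truth = pd.concat(truth_rows, ignore_index=True)
    return fixes, truth


# -- selection -------------------------------------------------------------

@dataclasses.dataclass
class RSFSimConfig:
    """Used-point simulation: true selection coefficients and heterogeneity.

    ``beta`` applies to covariates standardized over the region's
    systematic availability grid; ``tau`` is the SD of per-animal normal
    random intercepts.
    """

    beta: dict = dataclasses.field(
        default_factory=lambda: {
            "d_bottomland": -0.8,
            "d_stream": -0.4,
            "d_pine": 0.3,
            "canopy": 0.5,
        }
    )
    tau: float = 0.5
    n_animals: int = 8
    n_used: int = 250  # per animal
    seed: int = 0


def simulate_rsf_points(
    config: RSFSimConfig,
    covariates: dict,
    region,
    stats=None,
    rng: Optional[np.random.Generator] = None,
):
    """Draw used points from an exponential RSF by rejection sampling.

    Proposals are uniform in ``region`` (a shapely polygon); acceptance is
    proportional to ``exp(beta' z(s) + b_animal)`` with ``z`` the
    standardized covariates and ``b_animal ~ N(0, tau^2)`` a per-animal
    log-encounter-rate offset.  Selection strength is shared across
    animals; the offset scales each animal's expected number of used
    points (Poisson around ``n_used * exp(b)``), which is what a random
    intercept absorbs in the used-available logit.

    Returns ``(points, stats)``: a DataFrame (animal_id, x, y) and the
    StandardizationStats used, computed from a systematic sample of the
    region when not supplied.
    """
    from .homerange import grid_sample
    from .landscape import extract, standardize

    if rng is None:
        rng = np.random.default_rng(config.seed)
    if stats is None:
        avail = grid_sample(region, spacing=90.0)
        table = extract(pd.DataFrame({"x": avail[:, 0], "y": avail[:, 1]}), covariates)
        _, stats = standardize(table, columns=list(config.beta))

    names = list(config.beta)
    beta = np.array([config.beta[k] for k in names])
    minx, miny, maxx, maxy = region.bounds
    shapely.prepare(region)

    # upper bound for the acceptance ratio from the covariate grids
    zmax = 0.0
    for k, b in config.beta.items():
        z = (covariates[k].values - float(stats.mean[k])) / float(stats.sd[k])
        zmax += max(b * z.min(), b * z.max())

    rows = []
    offsets = rng.normal(0.0, config.tau, config.n_animals) if config.tau > 0 \
        else np.zeros(config.n_animals)
    for a in range(config.n_animals):
        aid = f"S{a:02d}"
        n_target = max(1, int(rng.poisson(config.n_used * np.exp(offsets[a]))))
        n_acc = 0
        n_prop = 0
        xs: list[float] = []
        ys: list[float] = []
        while n_acc < n_target:
            m = max(4 * (n_target - n_acc), 256)
            px = rng.uniform(minx, maxx, m)
            py = rng.uniform(miny, maxy, m)
            inside = shapely.intersects_xy(region, px, py)
            px, py = px[inside], py[inside]
            n_prop += m
            if px.size == 0:
                continue
            eta = np.zeros(px.size)
            for k, b in zip(names, beta):
                v = covariates[k].value_at(px, py)
                eta += b * (v - float(stats.mean[k])) / float(stats.sd[k])
            acc = rng.random(px.size) < np.exp(eta - zmax)
            take = min(int(acc.sum()), n_target - n_acc)
            idx = np.nonzero(acc)[0][:take]
            xs.extend(px[idx])
            ys.extend(py[idx])
            n_acc += take
            if n_prop > 200 * n_target and n_acc < max(1, n_prop * 1e-4):
                raise RuntimeError(
                    "rejection acceptance rate below 1e-4; rescale beta"
                )
        rows.append(pd.DataFrame({"animal_id": aid, "x": xs, "y": ys}))
    return pd.concat(rows, ignore_index=True), stats
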