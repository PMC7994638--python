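"""End-to-end orchestration of the behavioral-state selection workflow.

The full model grid for a two-sex, two-season study is:

* 8 movement HMMs (2- and 3-state, per sex x season), AIC-selected;
* 4 second-order RSF GLMs (per sex x season): kernel-home-range grid
  points (used) vs buffered-MCP study-area grid points (available);
* 12 third-order RSF GLMMs (per sex x season x decoded behavioral state):
  GPS fixes in that state (used) vs home-range grid points (available),
  with a per-animal random intercept.

:func:`run_pipeline` executes the grid from an :class:`AnalysisConfig`,
writing every artifact (decoded steps, fit files, diel profiles, summary
tables, odds reports) under the output directory together with the run
seed and a hash of the configuration.  All randomness flows from the one
top-level seed, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import homerange, landscape as land, rsf as rsfmod, synthetic, tracks
from .distributions import circular_mean
from .hmm import MovementHMM, select_states

logger = logging.getLogger(__name__)

STATE_NAMES = {1: "resting", 2: "foraging", 3: "traveling"}


@dataclasses.dataclass
class AnalysisConfig:
    """Everything a pipeline run needs; serializable to/from YAML."""

    out_dir: str = "pigmove_out"
    seed: int = 1
    # inputs; when fixes_csv is None the synthetic generator supplies data
    fixes_csv: Optional[str] = None
    landscape_dir: Optional[str] = None
    sexes: Sequence[str] = ("female", "male")
    seasons: Sequence[str] = (tracks.LOW_FORAGE, tracks.HIGH_FORAGE)
    # preprocessing
    interval: float = 3600.0
    tolerance: float = 300.0
    # HMM settings
    n_states_list: Sequence[int] = (2, 3)
    n_starts: int = 25
    transition_covariate: str = "cosinor"
    # sampling and home-range settings
    spacing: float = 90.0
    buffer_m: float = 1200.0
    kde_cell: float = 30.0
    isopleth_level: float = 0.95
    # RSF settings
    pearson_threshold: float = 0.6
    priority: Sequence[str] = tuple(land.DEFAULT_PRIORITY)
    n_quad: int = 15
    # synthetic-data sizes (used only when fixes_csv is None)
    sim_extent: float = 15_000.0
    sim_n_animals: int = 8
    sim_n_steps: int = 1000
    sim_diel_amplitude: float = 1.0

    def __post_init__(self):
        # normalize sequence fields so YAML round trips compare equal
        self.sexes = tuple(self.sexes)
        self.seasons = tuple(self.seasons)
        self.n_states_list = tuple(int(k) for k in self.n_states_list)
        self.priority = tuple(self.priority)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        payload = json.loads(json.dumps(dataclasses.asdict(self)))
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# -- summaries -------------------------------------------------------------

def diel_profile(states: np.ndarray, hours: np.ndarray, n_states: int) -> pd.DataFrame:
    """Proportion of decoded steps in each state per integer clock hour.

    Rows are hours 0..23; an hour with no steps is left as NaN (flagged
    missing, not zero-filled).  Populated rows sum to 1.
    """
    states = np.asarray(states)
    hours = np.asarray(hours)
    bins = np.floor(hours).astype(int) % 24
    out = np.full((24, n_states), np.nan)
    for h in range(24):
        sel = bins == h
        n = int(sel.sum())
        if n == 0:
            continue
        for k in range(n_states):
            out[h, k] = np.sum(states[sel] == k + 1) / n
    return pd.DataFrame(
        out,
        index=pd.Index(range(24), name="hour"),
        columns=[f"state_{k + 1}" for k in range(n_states)],
    )


def state_summaries(decoded: pd.DataFrame, n_states: int) -> pd.DataFrame:
    """Per-state summary: mean step +/- SE and circular mean turn angle.

    ``decoded`` needs columns step_m, turn_rad, state.  SE is SD/sqrt(n);
    a state with fewer than 2 steps gets a missing SE.
    """
    rows = []
    for k in range(1, n_states + 1):
        sub = decoded[decoded["state"] == k]
        n = len(sub)
        steps = sub["step_m"].to_numpy(dtype=float)
        turns = sub["turn_rad"].to_numpy(dtype=float)
        turns = turns[np.isfinite(turns)]
        rows.append(
            {
                "state": k,
                "behavior": STATE_NAMES.get(k, f"state_{k}"),
                "n_steps": n,
                "mean_step_m": steps.mean() if n else np.nan,
                "se_step_m": steps.std(ddof=1) / np.sqrt(n) if n >= 2 else np.nan,
                "circ_mean_turn_rad": circular_mean(turns) if turns.size else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("state")


def location_count_summary(counts: Sequence[int]) -> dict:
    """Mean +/- SE and range of per-animal location counts."""
    c = np.asarray(counts, dtype=float)
    return {
        "n_animals": int(c.size),
        "n_locations": int(c.sum()),
        "mean_locations": float(c.mean()),
        "se_locations": float(c.std(ddof=1) / np.sqrt(c.size)) if c.size >= 2 else np.nan,
        "min_locations": int(c.min()),
        "max_locations": int(c.max()),
    }


# -- pipeline --------------------------------------------------------------

@dataclasses.dataclass
class PipelineReport:
    """Paths and key tables produced by one pipeline run."""

    out_dir: Path
    hmm_fits: dict
    selected: dict
    glm_reports: dict
    glmm_reports: dict
    diel: dict
    summaries: dict

    @property
    def n_hmm(self) -> int:
        return len(self.hmm_fits)

    @property
    def n_glm(self) -> int:
        return len(self.glm_reports)

    @property
    def n_glmm(self) -> int:
        return len(self.glmm_reports)


class StageError(RuntimeError):
    def __init__(self, stage, exc):
        super().__init__(f"pipeline stage {stage!r} failed: {exc}")
        self.stage = stage


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n)]


def run_pipeline(config: AnalysisConfig) -> PipelineReport:
    """Execute the full workflow; see the module docstring for the grid."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    seeds = iter(_child_seeds(config.seed, 64))
    meta = {"seed": config.seed, "config_digest": config.digest()}
    config.to_yaml(out / "config.yaml")

    stage = "inputs"
    try:
        if config.fixes_csv is None:
            sim_seed = next(seeds)
            lconf = synthetic.LandscapeConfig(
                extent=config.sim_extent, seed=sim_seed
            )
            scape = synthetic.make_landscape(lconf)
            params = {
                (sex, season): synthetic.default_hmm_params(
                    sex, season, covariate_form="cosinor",
                    diel_amplitude=config.sim_diel_amplitude,
                )
                for sex in config.sexes for season in config.seasons
            }
            tconf = synthetic.TrackSimConfig(
                n_animals=config.sim_n_animals,
                n_steps=config.sim_n_steps,
                sexes=tuple(config.sexes),
                seasons=tuple(config.seasons),
                start_spread=0.6 * config.sim_extent,
                start_origin=(0.2 * config.sim_extent, 0.2 * config.sim_extent),
                seed=sim_seed,
            )
            fixes_raw, truth = synthetic.simulate_fix_table(tconf, params)
            fixes_raw.to_csv(out / "fixes.csv", index=False)
            truth.to_csv(out / "true_states.csv", index=False)
            fixes = tracks.parse_fixes(out / "fixes.csv")
        else:
            fixes = tracks.parse_fixes(config.fixes_csv)
            if config.landscape_dir is None:
                raise ValueError("landscape_dir is required with external fixes")
            scape = _load_landscape(Path(config.landscape_dir))
        if "sex" in fixes.columns:
            sex_of = dict(zip(fixes["animal_id"], fixes["sex"]))
        else:
            sex_of = {aid: config.sexes[0] for aid in fixes["animal_id"].unique()}

        stage = "preprocess"
        series = tracks.preprocess(
            fixes, interval=config.interval, tol=config.tolerance
        )
        steps_df = tracks.steps_to_frame(series)
        logger.info("preprocess: %d bursts, %d steps", len(series), len(steps_df))

        stage = "hmm"
        hmm_fits = {}
        selected = {}
        decoded_parts = []
        for sex in config.sexes:
            for season in config.seasons:
                stratum = [
                    s for s in series
                    if s.season == season and sex_of.get(s.animal_id) == sex
                ]
                if not stratum:
                    raise ValueError(f"no data for stratum {sex}/{season}")
                fits = []
                for K in config.n_states_list:
                    model = MovementHMM(
                        stratum, n_states=K,
                        transition_covariate=config.transition_covariate,
                    )
                    res = model.fit(n_starts=config.n_starts, seed=next(seeds))
                    hmm_fits[(sex, season, K)] = res
                    res.save(out / f"hmm_{sex}_{season}_{K}state.json")
                    fits.append(res)
                    logger.info(
                        "hmm %s/%s K=%d: logL=%.2f AIC=%.2f",
                        sex, season, K, res.loglik, res.aic,
                    )
                best = select_states(fits)
                selected[(sex, season)] = best
                part = tracks.steps_to_frame(stratum)
                part["sex"] = sex
                part["state"] = best.decode()
                decoded_parts.append(part)
        decoded = pd.concat(decoded_parts, ignore_index=True)
        decoded.to_csv(out / "steps_decoded.csv", index=False)

        stage = "summaries"
        diel = {}
        summaries = {}
        for (sex, season), best in selected.items():
            sub = decoded[(decoded["sex"] == sex) & (decoded["season"] == season)]
            K = best.params.n_states
            prof = diel_profile(
                sub["state"].to_numpy(), sub["hour"].to_numpy(), K
            )
            prof.to_csv(out / f"diel_{sex}_{season}.csv")
            diel[(sex, season)] = prof
            summ = state_summaries(sub, K)
            counts = sub.groupby("animal_id").size()
            loc = location_count_summary(counts.to_numpy())
            summ.attrs.update(loc)
            summ.to_csv(out / f"state_summary_{sex}_{season}.csv")
            summaries[(sex, season)] = summ

        stage = "homerange"
        import shapely as _shp

        all_xy = fixes[["x", "y"]].to_numpy(dtype=float)
        study_mcp = homerange.mcp(all_xy)
        study_area = homerange.buffer_region(study_mcp, config.buffer_m)
        # availability cannot extend beyond the mapped landscape
        study_area = study_area.intersection(_shp.box(*scape.classes.bounds))
        available_xy = homerange.grid_sample(study_area, spacing=config.spacing)
        hr_points = {}  # (animal, season) -> grid points in 95% kernel isopleth
        fixes_season = fixes.assign(
            season=[tracks.assign_season(t) for t in fixes["t"]]
        )
        for (aid, season), grp in fixes_season.groupby(["animal_id", "season"]):
            xy = grp[["x", "y"]].to_numpy(dtype=float)
            if len(xy) < 5:
                continue
            surf = homerange.kde_surface(xy, cell=config.kde_cell)
            iso = homerange.isopleth(surf, level=config.isopleth_level)
            pts = homerange.grid_sample(iso, spacing=config.spacing)
            pts = pts[scape.classes.inside(pts[:, 0], pts[:, 1])]
            hr_points[(aid, season)] = pts
        pd.DataFrame(available_xy, columns=["x", "y"]).assign(
            stratum="available"
        ).to_csv(out / "available_locations.csv", index=False)
        pd.concat(
            [
                pd.DataFrame(p, columns=["x", "y"]).assign(
                    animal_id=aid, season=s
                )
                for (aid, s), p in sorted(hr_points.items())
            ],
            ignore_index=True,
        ).to_csv(out / "homerange_locations.csv", index=False)

        stage = "covariates"
        cov_rasters = land.covariate_rasters(scape)
        cov_names = list(cov_rasters)
        avail_table = land.extract(
            pd.DataFrame({"x": available_xy[:, 0], "y": available_xy[:, 1]}),
            cov_rasters,
        )
        retained, corr = land.pearson_screen(
            avail_table, threshold=config.pearson_threshold,
            priority=config.priority, columns=cov_names,
        )
        corr.to_csv(out / "covariate_correlations.csv")
        logger.info("covariates retained after screen: %s", retained)

        stage = "rsf_second_order"
        glm_reports = {}
        for sex in config.sexes:
            for season in config.seasons:
                used_parts = [
                    pd.DataFrame({"x": p[:, 0], "y": p[:, 1], "animal_id": aid})
                    for (aid, s), p in hr_points.items()
                    if s == season and sex_of.get(aid) == sex and len(p)
                ]
                used = pd.concat(used_parts, ignore_index=True)
                used_table = land.extract(used, cov_rasters)
                frame = pd.concat(
                    [used_table.assign(used=1), avail_table.assign(used=0)],
                    ignore_index=True,
                )
                design = rsfmod.UsedAvailableDesign.from_frame(
                    frame, retained, sex=sex, season=season, order=2
                )
                res = rsfmod.UsedAvailableLogit(design).fit()
                rep = res.odds_report()
                rep.insert(0, "sex", sex)
                rep.insert(1, "season", season)
                rep["auc"] = res.auc()
                rep.to_csv(out / f"rsf2_{sex}_{season}.csv")
                glm_reports[(sex, season)] = rep
                logger.info("rsf2 %s/%s: AUC=%.3f", sex, season, res.auc())

        stage = "rsf_third_order"
        glmm_reports = {}
        fix_cov = land.extract(
            fixes_season[["animal_id", "season", "x", "y", "t"]], cov_rasters
        )
        key = ["animal_id", "t"]
        dec = decoded.merge(
            fix_cov, left_on=["animal_id", "t"], right_on=key, how="inner",
            suffixes=("", "_cov"),
        )
        for sex in config.sexes:
            for season in config.seasons:
                K = selected[(sex, season)].params.n_states
                avail_parts = [
                    pd.DataFrame({"x": p[:, 0], "y": p[:, 1], "animal_id": aid})
                    for (aid, s), p in hr_points.items()
                    if s == season and sex_of.get(aid) == sex and len(p)
                ]
                avail = land.extract(
                    pd.concat(avail_parts, ignore_index=True), cov_rasters
                )
                for k in range(1, K + 1):
                    used = dec[
                        (dec["sex"] == sex)
                        & (dec["season"] == season)
                        & (dec["state"] == k)
                    ]
                    frame = pd.concat(
                        [
                            used[["animal_id", "x", "y", *retained]].assign(used=1),
                            avail[["animal_id", "x", "y", *retained]].assign(used=0),
                        ],
                        ignore_index=True,
                    )
                    design = rsfmod.UsedAvailableDesign.from_frame(
                        frame, retained, group_col="animal_id",
                        sex=sex, season=season, behavior=STATE_NAMES.get(k, str(k)),
                    )
                    res = rsfmod.MixedUsedAvailableLogit(
                        design, n_quad=config.n_quad
                    ).fit()
                    rep = res.odds_report()
                    name = STATE_NAMES.get(k, f"state{k}")
                    rep.insert(0, "sex", sex)
                    rep.insert(1, "season", season)
                    rep.insert(2, "behavior", name)
                    rep["auc"] = res.auc()
                    rep["tau"] = res.tau
                    rep.to_csv(out / f"rsf3_{sex}_{season}_{name}.csv")
                    glmm_reports[(sex, season, k)] = rep
                    logger.info(
                        "rsf3 %s/%s/%s: AUC=%.3f tau=%.3f",
                        sex, season, name, res.auc(), res.tau,
                    )
    except Exception as exc:
        meta["failed_stage"] = stage
        (out / "run_meta.json").write_text(json.dumps(meta, indent=1))
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc

    meta["elapsed_s"] = round(time.time() - t_start, 2)
    meta["n_hmm"] = len(hmm_fits)
    meta["n_glm"] = len(glm_reports)
    meta["n_glmm"] = len(glmm_reports)
    (out / "run_meta.json").write_text(json.dumps(meta, indent=1))
    logger.info("pipeline complete in %.1fs", meta["elapsed_s"])
    return PipelineReport(
        out_dir=out,
        hmm_fits=hmm_fits,
        selected=selected,
        glm_reports=glm_reports,
        glmm_reports=glmm_reports,
        diel=diel,
        summaries=summaries,
    )


def _load_landscape(directory: Path) -> land.Landscape:
    """Load a landscape from a directory of standard-named files."""
    return land.Landscape(
        classes=land.Raster.read_ascii(directory / "classes.asc"),
        canopy=land.Raster.read_ascii(directory / "canopy.asc"),
        streams=_union(land.read_geojson(directory / "streams.geojson")),
        primary_roads=_union(land.read_geojson(directory / "primary_roads.geojson")),
        secondary_roads=_union(land.read_geojson(directory / "secondary_roads.geojson")),
    )


def _union(geoms):
    import shapely

    return shapely.union_all(geoms)


def save_landscape(scape: land.Landscape, directory: Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scape.classes.write_ascii(directory / "classes.asc")
    scape.canopy.write_ascii(directory / "canopy.asc")
    land.write_geojson(directory / "streams.geojson", [scape.streams])
    land.write_geojson(directory / "primary_roads.geojson", [scape.primary_roads])
    land.write_geojson(directory / "secondary_roads.geojson", [scape.secondary_roads])
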