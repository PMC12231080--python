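"""End-to-end orchestration: simulate -> interpolate -> metrics ->
perimeter effect -> models, as one reproducible, file-based run.

Every stage writes its artifacts to disk (text formats only) so any stage
can be rerun or inspected in isolation; a JSON manifest records inputs,
outputs, seeds, and SHA-256 checksums. Re-running with the same config and
seed reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .covariates import patch_covariate_means
from .dob import DOBGrid, interpolate_dob
from .grid import GridSpec, derive_rng
from .landcover import CODE, COVER_TYPES, LandcoverGrid, cover_proportions
from .metrics import compute_spread_metrics
from .models import (fit_aspen_models, fit_cover_contrasts, fit_fpe_covariate_lm,
                     fit_fpe_doy_smooth, model_summary_frame, prepare_response,
                     select_model)
from .perimeter import fpe_records_for_fire, sign_tests_by_group
from .synthetic import (Detection, FireEvent, SpreadParams, generate_covariate_grid,
                        generate_landscape, sample_detections, simulate_fire)

_LANDSCAPE_KEYS = {"n_rows", "n_cols", "pixel_size", "weights", "patchiness",
                   "aspen_strata", "aspen_jitter", "matrix_split"}
_SPREAD_KEYS = {"base_spread_prob", "weather_coupling", "max_days", "multipliers",
                "substeps_per_day"}
_DETECTION_KEYS = {"rate", "jitter_sigma", "min_per_day"}
_ANALYSIS_KEYS = {"covariates", "covariate_scale", "sample_fraction", "half_width",
                  "interior_mode", "ignition_doy_min", "ignition_doy_max"}


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run.

    Defaults are the package's standard synthetic study conditions: fires
    sampled round-robin from three landscape strata of increasing aspen
    abundance (conifer-dominated, mixed, aspen-rich — emulating a regional
    sample of fires), finely interspersed 60-m aspen stands, a strongly
    aspen-penalized contact-process spread whose front advances several
    pixels per day, sparse jittered detections with a daily-overpass floor,
    and two daily weather covariates of which the fire-weather index
    actually drives spread. Setting ``landscape.weights`` replaces the
    strata with one fixed class-weight map for every fire.
    """

    seed: int = 0
    n_fires: int = 6
    out_dir: str = "run"
    landscape: dict = field(default_factory=lambda: {
        "n_rows": 180, "n_cols": 180, "pixel_size": 30.0,
        "weights": None,
        "aspen_strata": [0.06, 0.40, 0.62],
        "aspen_jitter": [0.85, 1.15],
        "matrix_split": {"warm_conifer": 0.55, "cool_conifer": 0.15,
                         "herbaceous": 0.15, "shrub": 0.09, "woodland": 0.06},
        "patchiness": 60.0,
    })
    spread: dict = field(default_factory=lambda: {
        "base_spread_prob": 0.45, "weather_coupling": 0.15, "max_days": 30,
        "substeps_per_day": 6, "multipliers": {"aspen": 0.01},
    })
    detection: dict = field(default_factory=lambda: {
        "rate": 3.0, "jitter_sigma": 30.0, "min_per_day": 1})
    analysis: dict = field(default_factory=lambda: {
        "covariates": ["FWI", "Tmax"], "covariate_scale": 1500.0,
        "sample_fraction": 0.001, "half_width": 60.0, "interior_mode": "full",
        "ignition_doy_min": 150, "ignition_doy_max": 280,
    })

    def __post_init__(self) -> None:
        if self.n_fires < 1:
            raise ValueError("n_fires must be >= 1")
        for block, allowed, defaults in (
            (self.landscape, _LANDSCAPE_KEYS, RunConfig.__dataclass_fields__["landscape"].default_factory()),
            (self.spread, _SPREAD_KEYS, RunConfig.__dataclass_fields__["spread"].default_factory()),
            (self.detection, _DETECTION_KEYS, RunConfig.__dataclass_fields__["detection"].default_factory()),
            (self.analysis, _ANALYSIS_KEYS, RunConfig.__dataclass_fields__["analysis"].default_factory()),
        ):
            unknown = set(block) - allowed
            if unknown:
                raise ValueError(f"unknown config keys: {sorted(unknown)}")
            for k, v in defaults.items():
                block.setdefault(k, v)
        # fail fast on invalid sub-blocks before any stage runs
        self.grid_spec()
        SpreadParams(
            base_spread_prob=self.spread["base_spread_prob"],
            weather_coupling=self.spread["weather_coupling"],
            max_days=self.spread["max_days"],
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def grid_spec(self) -> GridSpec:
        ls = self.landscape
        return GridSpec(int(ls["n_rows"]), int(ls["n_cols"]), float(ls["pixel_size"]))

    def spread_params(self, fire_seed: int) -> SpreadParams:
        sp = self.spread
        mult = dict(SpreadParams().per_type_multiplier)
        mult.update(sp.get("multipliers") or {})
        return SpreadParams(
            base_spread_prob=float(sp["base_spread_prob"]),
            per_type_multiplier=mult,
            weather_coupling=float(sp["weather_coupling"]),
            max_days=int(sp["max_days"]),
            rng_seed=fire_seed,
            substeps_per_day=int(sp.get("substeps_per_day", 1)),
        )

    def fire_weights(self, fire_id: str, index: int) -> dict[str, float]:
        """Per-fire landscape class weights (stratified unless fixed)."""
        ls = self.landscape
        if ls.get("weights"):
            return dict(ls["weights"])
        strata = list(ls["aspen_strata"])
        lo, hi = ls["aspen_jitter"]
        rng = derive_rng(self.seed, "aspen_weight", fire_id)
        wa = strata[index % len(strata)] * float(rng.uniform(lo, hi))
        wa = min(max(wa, 0.0), 0.95)
        split = ls["matrix_split"]
        total = sum(split.values())
        return {"aspen": wa, **{k: (1 - wa) * v / total for k, v in split.items()}}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _flammable_ignition(landcover: LandcoverGrid, params: SpreadParams) -> tuple[int, int]:
    """Flammable cell nearest the grid center."""
    mult = params.multiplier_array()[np.maximum(landcover.classes, 0)]
    mult[landcover.classes == landcover.nodata] = 0.0
    rows, cols = np.nonzero(mult > 0)
    if rows.size == 0:
        raise ValueError("landscape has no flammable cells")
    ci, cj = landcover.spec.n_rows // 2, landcover.spec.n_cols // 2
    k = int(np.argmin((rows - ci) ** 2 + (cols - cj) ** 2))
    return int(rows[k]), int(cols[k])


@dataclass
class SimulatedFire:
    fire_id: str
    landcover: LandcoverGrid
    fire: FireEvent
    ignition_doy: int
    covariate_grids: dict[str, list]


def simulate_study(config: RunConfig) -> list[SimulatedFire]:
    """Generate the study's fires in memory (the simulate stage)."""
    spec = config.grid_spec()
    an = config.analysis
    out: list[SimulatedFire] = []
    for i in range(config.n_fires):
        fire_id = f"fire_{i:03d}"
        fire_seed = int(derive_rng(config.seed, "fire_seed", fire_id).integers(2 ** 31))
        landcover = generate_landscape(
            spec, config.fire_weights(fire_id, i),
            config.landscape["patchiness"], fire_seed,
        )
        n_days = int(config.spread["max_days"])
        grids = {
            name: generate_covariate_grid(
                spec, name, float(an["covariate_scale"]), 0.0, n_days,
                config.seed, fire_id=fire_id,
            )
            for name in an["covariates"]
        }
        # the fire-weather index drives the spread process when present
        driver = an["covariates"][0] if an["covariates"] else None
        weather = (
            np.array([g.values.mean() for g in grids[driver]]) if driver else None
        )
        params = config.spread_params(fire_seed)
        ignition = _flammable_ignition(landcover, params)
        fire = simulate_fire(landcover, ignition, params, weather, fire_id=fire_id)
        fire.detections = sample_detections(
            fire.true_dob, float(config.detection["rate"]),
            float(config.detection["jitter_sigma"]), fire_seed, fire_id=fire_id,
            min_per_day=int(config.detection.get("min_per_day", 1)),
        )
        rng = derive_rng(config.seed, "doy", fire_id)
        doy = int(rng.integers(int(an["ignition_doy_min"]), int(an["ignition_doy_max"]) + 1))
        out.append(SimulatedFire(fire_id, landcover, fire, doy, grids))
    return out


def build_patch_table(sim: SimulatedFire, dob: DOBGrid, config: RunConfig) -> pd.DataFrame:
    """Metrics stage for one fire: patches + coverage + covariate means."""
    an = config.analysis
    patches = compute_spread_metrics(dob, sim.fire.detections, sim.fire_id)
    for p in patches:
        p.coverage = cover_proportions(sim.landcover, p.pixels).proportions
        patch_covariate_means(
            p, sim.covariate_grids, dob.spec,
            fraction=float(an["sample_fraction"]), seed=config.seed,
        )
        p.covariates["DOY"] = float(sim.ignition_doy + p.day - 1)
    df = fio.patch_table(patches)
    for g in COVER_TYPES:
        df[g] = df[g].fillna(0.0)
    return df


def run_all(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute every stage, write all artifacts, return the run manifest."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "n_fires": config.n_fires,
                      "stages": {}, "checksums": {}}
    written: list[Path] = []

    def _register(path: Path) -> None:
        written.append(path)

    # --- simulate ---------------------------------------------------------
    try:
        sims = simulate_study(config)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    fires_dir = out / "fires"
    for sim in sims:
        d = fires_dir / sim.fire_id
        d.mkdir(parents=True, exist_ok=True)
        fio.write_ascii_grid(sim.landcover, d / "landcover.asc")
        fio.write_ascii_grid(sim.fire.true_dob, d / "true_dob.asc")
        fio.write_perimeter_geojson(
            sim.fire.perimeter, d / "perimeter.geojson",
            {"fire_id": sim.fire_id, "ignition_doy": sim.ignition_doy},
        )
        fio.write_detections_csv(sim.fire.detections, sim.fire_id, d / "detections.csv")
        for p in (d / "landcover.asc", d / "true_dob.asc", d / "perimeter.geojson",
                  d / "detections.csv"):
            _register(p)
    manifest["stages"]["simulate"] = [s.fire_id for s in sims]

    # --- interpolate ------------------------------------------------------
    dobs: dict[str, DOBGrid] = {}
    for sim in sims:
        try:
            dob = interpolate_dob(sim.fire, sim.landcover.spec)
        except Exception as exc:
            raise RuntimeError(
                f"stage 'interpolate' failed for {sim.fire_id}: {exc}") from exc
        dobs[sim.fire_id] = dob
        path = fires_dir / sim.fire_id / "dob.asc"
        fio.write_ascii_grid(dob, path)
        _register(path)
    manifest["stages"]["interpolate"] = len(dobs)

    # --- metrics ----------------------------------------------------------
    tables = []
    for sim in sims:
        try:
            tables.append(build_patch_table(sim, dobs[sim.fire_id], config))
        except Exception as exc:
            raise RuntimeError(f"stage 'metrics' failed for {sim.fire_id}: {exc}") from exc
    patch_df = pd.concat(tables, ignore_index=True)
    patch_path = out / "patches.csv"
    patch_df.to_csv(patch_path, index=False)
    _register(patch_path)
    manifest["stages"]["metrics"] = {"n_patches": int(len(patch_df))}

    # --- perimeter effect -------------------------------------------------
    records = []
    fire_meta = []
    skipped_fires = []
    an = config.analysis
    for sim in sims:
        try:
            recs = fpe_records_for_fire(
                sim.fire_id, sim.fire.perimeter, sim.landcover,
                half_width=float(an["half_width"]),
                interior_mode=str(an["interior_mode"]),
            )
        except ValueError as exc:
            if "no interior" in str(exc):
                # fire too small to have a deep interior at this half-width
                skipped_fires.append(sim.fire_id)
                continue
            raise RuntimeError(
                f"stage 'perimeter-effect' failed for {sim.fire_id}: {exc}") from exc
        except Exception as exc:
            raise RuntimeError(
                f"stage 'perimeter-effect' failed for {sim.fire_id}: {exc}") from exc
        records.extend(recs)
        cov_means = {
            name: float(np.mean([g.values.mean() for g in grids]))
            for name, grids in sim.covariate_grids.items()
        }
        aspen_fpe = next(r.fpe for r in recs if r.group == "aspen")
        fire_meta.append({"fire_id": sim.fire_id, "fpe": aspen_fpe,
                          "doy": sim.ignition_doy, **cov_means})
    fpe_df = pd.DataFrame(
        [{"fire_id": r.fire_id, "group": r.group, "perimeter_prop": r.perimeter_prop,
          "interior_prop": r.interior_prop, "fpe": r.fpe} for r in records]
    )
    fpe_path = out / "fpe.csv"
    fpe_df.to_csv(fpe_path, index=False)
    _register(fpe_path)
    sign_df = pd.DataFrame([dataclasses.asdict(s) for s in sign_tests_by_group(records)])
    sign_path = out / "sign_tests.csv"
    sign_df.to_csv(sign_path, index=False)
    _register(sign_path)
    fire_df = pd.DataFrame(fire_meta)
    fire_path = out / "fires.csv"
    fire_df.to_csv(fire_path, index=False)
    _register(fire_path)
    manifest["stages"]["perimeter_effect"] = {
        "n_fires": int(fire_df.shape[0]),
        "skipped_no_interior": skipped_fires,
    }

    # --- models -----------------------------------------------------------
    try:
        table = prepare_response(patch_df, pixel_size=config.grid_spec().pixel_size)
        results = {}
        for response in ("log10_area_ha", "log10_linear_m"):
            for flag, res in fit_aspen_models(table, response).items():
                results[f"aspen|{response}|{flag}"] = res
            contrasts, skipped = fit_cover_contrasts(
                table, [c for c in COVER_TYPES if c != "aspen"], response)
            for ct, res in contrasts.items():
                results[f"contrast:{ct}|{response}"] = res
            selected, trace = select_model(
                table, response, ["aspen"] + list(an["covariates"]) + ["DOY"])
            results[f"selected|{response}"] = selected
            manifest["stages"].setdefault("selection", {})[response] = trace.steps
        summary = model_summary_frame(results)
        models_path = out / "model_summaries.csv"
        summary.to_csv(models_path, index=False)
        _register(models_path)
        notes = []
        aspen_fires = fire_df.dropna(subset=["fpe"])
        if len(aspen_fires) >= 10:
            lm = fit_fpe_covariate_lm(aspen_fires, list(an["covariates"]))
            lm_path = out / "fpe_lm.csv"
            lm.to_csv(lm_path, index=False)
            _register(lm_path)
        else:
            notes.append("fpe~covariate linear models skipped: fewer than 10 fires")
        if len(aspen_fires) >= 20 and aspen_fires["doy"].max() - aspen_fires["doy"].min() >= 60:
            sm_res = fit_fpe_doy_smooth(aspen_fires["fpe"], aspen_fires["doy"])
            gam_df = pd.DataFrame({"doy": sm_res.grid, "fitted": sm_res.fitted,
                                   "ci_low": sm_res.ci_low, "ci_high": sm_res.ci_high})
            gam_path = out / "fpe_doy_smooth.csv"
            gam_df.to_csv(gam_path, index=False)
            _register(gam_path)
            manifest["stages"]["fpe_doy_smooth"] = {
                "edf": sm_res.edf, "p_value": sm_res.p_value, "r2": sm_res.r2}
        else:
            notes.append("fpe~doy smooth skipped: needs >=20 fires spanning >=60 days")
        report = out / "model_report.txt"
        report.write_text(_text_report(results, sign_df, notes))
        _register(report)
        manifest["stages"]["models"] = {"n_models": len(results), "notes": notes}
    except Exception as exc:
        raise RuntimeError(f"stage 'models' failed: {exc}") from exc

    manifest["checksums"] = {str(p.relative_to(out)): _sha256(p) for p in written}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _text_report(results, sign_df, notes) -> str:
    lines = ["Fire progression model report", "=" * 31, ""]
    for key, res in results.items():
        lines.append(f"[{key}] n={res.n_patches} patches / {res.n_fires} fires, "
                     f"AIC={res.aic:.1f}, R2m={res.r2_marginal:.3f}, "
                     f"R2c={res.r2_conditional:.3f}"
                     + (" (singular -> OLS)" if res.singular else ""))
        for fe in res.fixed_effects:
            lines.append(f"    {fe.term:>24s}  b={fe.estimate:+.4f}  "
                         f"se={fe.se:.4f}  p={fe.p_value:.3g}")
        lines.append("")
    lines.append("Sign tests (Bonferroni-adjusted):")
    lines.append(sign_df.to_string(index=False))
    for n in notes:
        lines.append(f"NOTE: {n}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# deterministic unit-test fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("barrier_ring", "two_day_strip", "spot_fire")


def make_fixture(name: str, out: str | Path | None = None) -> dict:
    """Tiny deterministic fires used by the unit tests.

    * ``barrier_ring`` — a landscape with a closed impermeable aspen annulus
      around the center and the fire it confines.
    * ``two_day_strip`` — a rectangular burn whose DOB splits days {1, 2} at
      a known Voronoi bisector between two detections.
    * ``spot_fire`` — a DOB grid whose day-3 patch has no shared boundary
      with earlier days (a spot fire) plus the detection that seeds it.
    """
    if name == "barrier_ring":
        fx = _barrier_ring_fixture()
    elif name == "two_day_strip":
        fx = _two_day_strip_fixture()
    elif name == "spot_fire":
        fx = _spot_fire_fixture()
    else:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    if out is not None:
        outp = Path(out)
        outp.mkdir(parents=True, exist_ok=True)
        if "landcover" in fx:
            fio.write_ascii_grid(fx["landcover"], outp / "landcover.asc")
        if "dob" in fx:
            fio.write_ascii_grid(fx["dob"], outp / "dob.asc")
        if "fire" in fx:
            fio.write_perimeter_geojson(fx["fire"].perimeter, outp / "perimeter.geojson")
            fio.write_detections_csv(fx["fire"].detections, fx["fire"].fire_id,
                                     outp / "detections.csv")
        if "detections" in fx:
            fio.write_detections_csv(fx["detections"], name, outp / "detections.csv")
    return fx


def _barrier_ring_fixture(seed: int = 11, radius: tuple[int, int] = (18, 21),
                          n: int = 60) -> dict:
    spec = GridSpec(n, n, 30.0)
    classes = np.full((n, n), CODE["warm_conifer"], dtype=np.int16)
    ci = cj = n // 2
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    cheb = np.maximum(np.abs(ii - ci), np.abs(jj - cj))
    ring = (cheb >= radius[0]) & (cheb <= radius[1])
    classes[ring] = CODE["aspen"]
    landcover = LandcoverGrid(spec, classes)
    params = SpreadParams(base_spread_prob=0.6,
                          per_type_multiplier={"aspen": 0.0},
                          max_days=80, rng_seed=seed)
    fire = simulate_fire(landcover, (ci, cj), params, fire_id="barrier_ring")
    fire.detections = sample_detections(fire.true_dob, rate=100.0, jitter_sigma=0.0,
                                        seed=seed, fire_id="barrier_ring")
    return {"landcover": landcover, "fire": fire, "ring_mask": ring,
            "inner_radius": radius[0], "center": (ci, cj)}


def _two_day_strip_fixture() -> dict:
    # 5 x 10 rectangle of 30-m cells; detections at the centers of columns 0
    # and 9 on the middle row. The x = 150 m bisector puts columns 0-4 on
    # day 1 and columns 5-9 on day 2.
    spec = GridSpec(5, 10, 30.0)
    day = np.full((5, 10), 1, dtype=np.int32)
    day[:, 5:] = 2
    dob = DOBGrid(spec, day)
    detections = [Detection(15.0, -75.0, 1), Detection(285.0, -75.0, 2)]
    from .grid import footprint_polygon

    perimeter = footprint_polygon(np.ones((5, 10), dtype=bool), spec)
    fire = FireEvent("two_day_strip", None, perimeter, detections, dob)
    return {"dob": dob, "fire": fire, "detections": detections,
            "bisector_x": 150.0}


def _spot_fire_fixture() -> dict:
    # days 1-2 grow a blob in the west; day 3 is an isolated 3x3 spot fire in
    # the east with a detection at its center cell.
    spec = GridSpec(15, 30, 30.0)
    day = np.full((15, 30), -1, dtype=np.int32)
    day[6:9, 2:5] = 1
    day[5:10, 5:8] = 2
    day[6:9, 20:23] = 3  # far from the day-2 front: discontinuous
    dob = DOBGrid(spec, day)
    cx, cy = spec.center_of(np.array([7]), np.array([21]))
    detections = [Detection(float(cx[0]), float(cy[0]), 3)]
    return {"dob": dob, "detections": detections, "spot_center_cell": (7, 21)}
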