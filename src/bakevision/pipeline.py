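"""Reproducible end-to-end orchestration of the cookie quality analysis.

Each stage reads the artifacts of the previous one from a shared output
directory and writes its own, together with a log line recording the config
hash, the stage seed and library versions.  One global seed fans out to
per-stage seeds through a fixed affine scheme (``seed * 1009 + offset mod
2^31``), so any stage can be rerun in isolation and reproduce itself exactly.

Stage order (artifacts in parentheses):

1.  ``simulate``        (images/, wavelengths.json, samples.csv, truth.csv)
2.  ``segment``         (masks/)
3.  ``train-browning``  (models/browning_model.json, set1/scores.csv)
4.  ``score``           (<design>/scores.csv)
5.  ``fit-surface``     (models/surface.json)
6.  ``train-water``     (models/water_model.json)
7.  ``predict-water``   (report/predictions.csv)
8.  ``report``          (report/: predictions, score summary, zone map, water maps)
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from . import browning_fda, browning_surface, segmentation, spectral_io, synth_bakery, water_plsr

__all__ = ["PipelineConfig", "AnalysisResult", "stage_seed", "run", "analyze"]

logger = logging.getLogger("bakevision")

#: Per-stage offsets of the seed fan-out.
STAGE_OFFSETS: dict[str, int] = {
    "simulate_set1": 11,
    "simulate_set2": 12,
    "train_water": 31,
}

COMMANDS = (
    "simulate",
    "segment",
    "train-browning",
    "score",
    "fit-surface",
    "train-water",
    "predict-water",
    "report",
)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: ``(seed * 1009 + offset) mod 2^31``."""
    return (int(global_seed) * 1009 + STAGE_OFFSETS[stage]) % (2**31)


@dataclasses.dataclass
class PipelineConfig:
    """Pipeline-level options; simulator keys mirror SimulationConfig fields."""

    seed: int = 0
    design: str = "set2"
    simulator: dict[str, Any] = dataclasses.field(default_factory=dict)
    train_fraction: float = 2.0 / 3.0
    n_folds: int = 5
    max_components: int = 10
    ridge: float | None = None
    gaussian_sigma: float = 1.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def simulation_config(self, seed: int) -> synth_bakery.SimulationConfig:
        return synth_bakery.SimulationConfig(seed=seed, **self.simulator)


def _log_stage(outdir: Path, command: str, cfg: PipelineConfig, seed: int | None) -> None:
    logdir = outdir / "logs"
    logdir.mkdir(parents=True, exist_ok=True)
    line = (
        f"{datetime.now(timezone.utc).isoformat()} command={command} "
        f"config_hash={cfg.config_hash()} seed={seed} "
        f"bakevision={__version__} numpy={np.__version__} scipy={scipy.__version__}\n"
    )
    with open(logdir / f"{command}.log", "a") as fh:
        fh.write(line)
    logger.info("stage %s done (seed=%s, config=%s)", command, seed, cfg.config_hash())


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path}; run the `{producer}` command first"
        )
    return path


def _design_dir(outdir: Path, design: str) -> Path:
    return outdir / design


def _load_design(outdir: Path, design: str, with_masks: bool = True):
    ddir = _design_dir(outdir, design)
    samples = spectral_io.read_table(_require(ddir / "samples.csv", "simulate"))
    sidecar = _require(ddir / "wavelengths.json", "simulate")
    images, masks = [], []
    for cid in samples["id"]:
        img = spectral_io.read_image(ddir / "images" / f"{cid}.tif", sidecar=sidecar)
        images.append(img)
        if with_masks:
            masks.append(spectral_io.read_mask(_require(ddir / "masks" / f"{cid}.tif", "segment")))
    return samples, images, masks


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def run_simulate(outdir: Path, cfg: PipelineConfig, design: str) -> None:
    seed = stage_seed(cfg.seed, f"simulate_{design}")
    sim_cfg = cfg.simulation_config(seed)
    ds = synth_bakery.generate_set(design, sim_cfg, seed=seed)
    ddir = _design_dir(outdir, design)
    (ddir / "images").mkdir(parents=True, exist_ok=True)
    sidecar = ddir / "wavelengths.json"
    sidecar.write_text(
        json.dumps({"wavelengths_nm": list(sim_cfg.wavelengths_nm)}, sort_keys=True,
                   separators=(",", ":")) + "\n"
    )
    for img, cid in zip(ds.images, ds.records["id"]):
        spectral_io.write_image(img, ddir / "images" / f"{cid}.tif", sidecar=sidecar)
    spectral_io.write_table(ds.records, ddir / "samples.csv")
    spectral_io.write_table(ds.truth, ddir / "truth.csv")
    _log_stage(outdir, "simulate", cfg, seed)


def run_segment(outdir: Path, cfg: PipelineConfig, design: str) -> None:
    samples, images, _ = _load_design(outdir, design, with_masks=False)
    ddir = _design_dir(outdir, design)
    for img, cid in zip(images, samples["id"]):
        spectral_io.write_mask(segmentation.segment(img), ddir / "masks" / f"{cid}.tif")
    _log_stage(outdir, "segment", cfg, None)


def run_train_browning(outdir: Path, cfg: PipelineConfig) -> None:
    samples, images, masks = _load_design(outdir, "set1")
    labels = [
        browning_fda.consensus_class(r.votes_under, r.votes_adequate, r.votes_over)
        for r in samples.itertuples()
    ]
    pixels, groups = browning_fda.build_pixel_dataset(images, masks, labels)
    model = browning_fda.fit_fda(pixels, groups, ridge=cfg.ridge)
    model.wavelengths_nm = images[0].wavelengths_nm

    scores = [
        browning_fda.mean_browning_score(browning_fda.score_pixels(img, m, model), m)
        for img, m in zip(images, masks)
    ]
    samples = samples.assign(mean_score=scores)
    group_means = samples.groupby("time_min")["mean_score"].mean().to_dict()
    limits = browning_fda.compute_class_limits(group_means)
    model.limit_under_adequate, model.limit_adequate_over = limits
    samples = samples.assign(
        predicted_class=[browning_fda.classify_cookie(s, limits) for s in scores]
    )
    (outdir / "models").mkdir(parents=True, exist_ok=True)
    model.to_json(outdir / "models" / "browning_model.json")
    spectral_io.write_table(
        samples[["id", "time_min", "temp_c", "mean_score", "predicted_class"]],
        _design_dir(outdir, "set1") / "scores.csv",
    )
    _log_stage(outdir, "train-browning", cfg, None)


def _load_browning_model(outdir: Path) -> browning_fda.FDAModel:
    path = _require(outdir / "models" / "browning_model.json", "train-browning")
    return browning_fda.FDAModel.from_json(path)


def run_score(outdir: Path, cfg: PipelineConfig, design: str) -> None:
    model = _load_browning_model(outdir)
    limits = (model.limit_under_adequate, model.limit_adequate_over)
    samples, images, masks = _load_design(outdir, design)
    scores = [
        browning_fda.mean_browning_score(browning_fda.score_pixels(img, m, model), m)
        for img, m in zip(images, masks)
    ]
    out = samples[["id", "time_min", "temp_c"]].assign(
        mean_score=scores,
        predicted_class=[browning_fda.classify_cookie(s, limits) for s in scores],
    )
    spectral_io.write_table(out, _design_dir(outdir, design) / "scores.csv")
    _log_stage(outdir, "score", cfg, None)


def run_fit_surface(outdir: Path, cfg: PipelineConfig) -> None:
    scores = spectral_io.read_table(
        _require(_design_dir(outdir, "set2") / "scores.csv", "score")
    )
    surface, _ = browning_surface.fit_surface(
        scores["mean_score"], scores["time_min"], scores["temp_c"]
    )
    (outdir / "models").mkdir(parents=True, exist_ok=True)
    surface.to_json(outdir / "models" / "surface.json")
    _log_stage(outdir, "fit-surface", cfg, None)


def run_train_water(outdir: Path, cfg: PipelineConfig) -> None:
    samples, images, masks = _load_design(outdir, "set2")
    X = np.vstack([water_plsr.mean_spectrum(img, m) for img, m in zip(images, masks)])
    y = np.array(
        [water_plsr.water_fraction(r.initial_mass_g, r.dried_mass_g) for r in samples.itertuples()]
    )
    seed = stage_seed(cfg.seed, "train_water")
    spec = water_plsr.SplitSpec(train_fraction=cfg.train_fraction, n_folds=cfg.n_folds, seed=seed)
    train_ids, test_ids = water_plsr.split_train_test(list(samples["id"]), spec)
    idx = {cid: i for i, cid in enumerate(samples["id"])}
    tr = [idx[c] for c in train_ids]
    te = [idx[c] for c in test_ids]
    k = water_plsr.cv_select_components(X[tr], y[tr], spec, max_components=cfg.max_components)
    model = water_plsr.fit_plsr(X[tr], y[tr], k)
    model.wavelengths_nm = images[0].wavelengths_nm
    model.cv_seed = seed
    (outdir / "models").mkdir(parents=True, exist_ok=True)
    model.to_json(outdir / "models" / "water_model.json")
    split = pd.DataFrame(
        {"id": list(samples["id"]), "role": ["train" if i in set(tr) else "test" for i in range(len(idx))]}
    )
    spectral_io.write_table(split, _design_dir(outdir, "set2") / "water_split.csv")
    _log_stage(outdir, "train-water", cfg, seed)


def run_predict_water(outdir: Path, cfg: PipelineConfig) -> None:
    model_path = _require(outdir / "models" / "water_model.json", "train-water")
    model = water_plsr.PLSRModel.from_json(model_path)
    samples, images, masks = _load_design(outdir, "set2")
    rows = []
    for r, img, m in zip(samples.itertuples(), images, masks):
        measured = water_plsr.water_fraction(r.initial_mass_g, r.dried_mass_g)
        predicted = float(model.predict(water_plsr.mean_spectrum(img, m))[0])
        rows.append(
            {
                "id": r.id,
                "time_min": r.time_min,
                "temp_c": r.temp_c,
                "measured_pct": measured,
                "predicted_pct": predicted,
                "deviation": predicted - measured,
            }
        )
    (outdir / "report").mkdir(parents=True, exist_ok=True)
    spectral_io.write_table(pd.DataFrame(rows), outdir / "report" / "predictions.csv")
    _log_stage(outdir, "predict-water", cfg, None)


def run_report(outdir: Path, cfg: PipelineConfig) -> None:
    """Collect the headline artifacts: predictions, score summary, zones, maps."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    predictions = _require(outdir / "report" / "predictions.csv", "predict-water")
    model = _load_browning_model(outdir)
    limits = (model.limit_under_adequate, model.limit_adequate_over)
    surface = browning_surface.ResponseSurface.from_json(
        _require(outdir / "models" / "surface.json", "fit-surface")
    )
    water_model = water_plsr.PLSRModel.from_json(
        _require(outdir / "models" / "water_model.json", "train-water")
    )
    rdir = outdir / "report"
    rdir.mkdir(parents=True, exist_ok=True)

    # Score summary per baking-time group (box-plot style statistics).
    scores1 = spectral_io.read_table(_require(_design_dir(outdir, "set1") / "scores.csv", "train-browning"))
    summary = (
        scores1.groupby("time_min")["mean_score"].agg(["mean", "min", "max"]).reset_index()
    )
    spectral_io.write_table(summary, rdir / "score_summary.csv")

    # Zone map over the validity box.
    times = np.linspace(surface.time_range[0], surface.time_range[1], 61)
    temps = np.linspace(surface.temp_range[0], surface.temp_range[1], 51)
    zones = browning_surface.zone_map(surface, limits, times, temps)
    pd.DataFrame(zones, index=temps, columns=times).to_csv(rdir / "zone_map.csv")
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.contourf(times, temps, zones, levels=[-0.5, 0.5, 1.5, 2.5], colors=["#f5e3c3", "#c98c4a", "#5e3a1d"])
    ax.set_xlabel("baking time (min)")
    ax.set_ylabel("oven temperature (degC)")
    ax.set_title("browning zones (light: underbaked, dark: overbaked)")
    fig.savefig(rdir / "zone_map.png", dpi=120)
    plt.close(fig)

    # Pixel-wise water maps for the coolest-oven time series.
    samples, images, masks = _load_design(outdir, "set2")
    sel = samples[(samples["temp_c"] == samples["temp_c"].min()) & (samples["replicate"] == 0)]
    for r in sel.itertuples():
        i = samples.index[samples["id"] == r.id][0]
        wmap = water_plsr.water_map(images[i], masks[i], water_model, gaussian_sigma=cfg.gaussian_sigma)
        fig, ax = plt.subplots(figsize=(4, 4))
        im = ax.imshow(wmap, cmap="jet")
        fig.colorbar(im, ax=ax, label="water (%)")
        ax.set_axis_off()
        ax.set_title(f"{r.id}")
        fig.savefig(rdir / f"water_map_{r.id}.png", dpi=120)
        plt.close(fig)
    _log_stage(outdir, "report", cfg, None)


@dataclasses.dataclass
class AnalysisResult:
    """Everything the end-to-end in-memory analysis produces for one seed."""

    fda_model: browning_fda.FDAModel
    fda_peak_nm: float
    limits: tuple[float, float]
    set1_scores: pd.DataFrame
    set2_scores: pd.DataFrame
    surface: browning_surface.ResponseSurface
    sensitivity_ratio: float
    plsr_model: water_plsr.PLSRModel
    n_components: int
    coeff_peak_nm: float
    rmsep_train: float
    rmsep_test: float
    y_measured: np.ndarray
    y_predicted_test: np.ndarray
    n_train: int
    n_test: int


def analyze(
    seed: int,
    sim_config: synth_bakery.SimulationConfig | None = None,
    split: water_plsr.SplitSpec | None = None,
    max_components: int = 10,
) -> AnalysisResult:
    """Run the full study in memory for one seed and collect headline numbers.

    Mirrors the disk pipeline: generate both designs, segment, train the
    browning score on the sensory-labelled first set, score the second set
    and fit the response surface, then train and evaluate the PLSR water
    model on a random 2/3-1/3 split of the second set.
    """
    sim_config = sim_config if sim_config is not None else synth_bakery.SimulationConfig()
    set1 = synth_bakery.generate_set("set1", sim_config, seed=stage_seed(seed, "simulate_set1"))
    set2 = synth_bakery.generate_set("set2", sim_config, seed=stage_seed(seed, "simulate_set2"))
    masks1 = [segmentation.segment(img) for img in set1.images]
    masks2 = [segmentation.segment(img) for img in set2.images]
    lam = set1.images[0].wavelengths_nm

    # Browning score anchored to the panel consensus of the first set.
    labels = [
        browning_fda.consensus_class(r.votes_under, r.votes_adequate, r.votes_over)
        for r in set1.records.itertuples()
    ]
    pixels, groups = browning_fda.build_pixel_dataset(set1.images, masks1, labels)
    fda = browning_fda.fit_fda(pixels, groups)
    fda.wavelengths_nm = lam
    s1 = [
        browning_fda.mean_browning_score(browning_fda.score_pixels(img, m, fda), m)
        for img, m in zip(set1.images, masks1)
    ]
    set1_scores = set1.records.assign(mean_score=s1)
    limits = browning_fda.compute_class_limits(
        set1_scores.groupby("time_min")["mean_score"].mean().to_dict()
    )
    fda.limit_under_adequate, fda.limit_adequate_over = limits

    # Response surface over the second set's time x temperature grid.
    s2 = [
        browning_fda.mean_browning_score(browning_fda.score_pixels(img, m, fda), m)
        for img, m in zip(set2.images, masks2)
    ]
    set2_scores = set2.records.assign(mean_score=s2)
    surface, _ = browning_surface.fit_surface(
        set2_scores["mean_score"], set2_scores["time_min"], set2_scores["temp_c"]
    )
    center = (
        float(np.median(np.unique(set2_scores["time_min"]))),
        float(np.mean((surface.temp_range[0], surface.temp_range[1]))),
    )
    ratio = browning_surface.sensitivity_ratio(surface, *center)

    # Water model on mean spectra of the second set.
    X = np.vstack([water_plsr.mean_spectrum(img, m) for img, m in zip(set2.images, masks2)])
    y = np.array(
        [water_plsr.water_fraction(r.initial_mass_g, r.dried_mass_g) for r in set2.records.itertuples()]
    )
    split = split if split is not None else water_plsr.SplitSpec(seed=stage_seed(seed, "train_water"))
    tr, te = water_plsr.split_train_test(list(range(len(y))), split)
    k = water_plsr.cv_select_components(X[tr], y[tr], split, max_components=max_components)
    plsr = water_plsr.fit_plsr(X[tr], y[tr], k)
    plsr.wavelengths_nm = lam
    plsr.cv_seed = split.seed
    y_pred_test = plsr.predict(X[te])

    return AnalysisResult(
        fda_model=fda,
        fda_peak_nm=float(lam[int(np.argmax(np.abs(fda.loadings[0])))]),
        limits=limits,
        set1_scores=set1_scores,
        set2_scores=set2_scores,
        surface=surface,
        sensitivity_ratio=float(ratio),
        plsr_model=plsr,
        n_components=k,
        coeff_peak_nm=float(lam[int(np.argmax(np.abs(plsr.coefficient_vector)))]),
        rmsep_train=water_plsr.rmsep(plsr.predict(X[tr]), y[tr]),
        rmsep_test=water_plsr.rmsep(y_pred_test, y[te]),
        y_measured=y,
        y_predicted_test=np.asarray(y_pred_test),
        n_train=len(tr),
        n_test=len(te),
    )


def run(command: str, outdir: str | Path, cfg: PipelineConfig, design: str | None = None) -> None:
    """Dispatch one pipeline command (see :data:`COMMANDS`)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = design or cfg.design
    if command == "simulate":
        run_simulate(outdir, cfg, design)
    elif command == "segment":
        run_segment(outdir, cfg, design)
    elif command == "train-browning":
        run_train_browning(outdir, cfg)
    elif command == "score":
        run_score(outdir, cfg, design)
    elif command == "fit-surface":
        run_fit_surface(outdir, cfg)
    elif command == "train-water":
        run_train_water(outdir, cfg)
    elif command == "predict-water":
        run_predict_water(outdir, cfg)
    elif command == "report":
        run_report(outdir, cfg)
    else:
        raise ValueError(f"unknown command {command!r}; expected one of {COMMANDS}")
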