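"""End-to-end pipeline: simulate -> extract -> fit -> associate.

Stages, in dependency order:

* **simulate** -- write the build and validation cohort CSVs and a small
  imaging subset (synthetic face PNGs, landmark JSONs, ground-truth masks).
* **extract** -- run the image pipeline (crop, ridge filter, Fourier
  enhancement, spot detection, calibration) over the imaging subset and
  write per-image feature scores plus the persisted calibrations.
* **fit** -- cross-validate the nine age models on the build cohort, refit
  each on the full build cohort (refining models with negative
  coefficients), validate on the independent cohort, and write model JSONs
  and a performance report.
* **associate** -- compute periorbital skin age on the validation cohort
  with the full (model 7) final model and write the disease-association
  table, PCA loadings and adjusted analyses.

A single global seed fans out to per-stage seeds as
``stage_seed = (global_seed * 1_000_003 + stage_index) % 2**31``, so any
stage can be rerun in isolation and reproduce its artifacts. Every run
writes a manifest recording the config hash, seeds, package version and a
SHA-256 checksum per output file; rerunning an unchanged config reproduces
the checksums of all deterministic artifacts byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import __version__
from .landmarks import LandmarkSet
from .synthetic import (
    FaceImageSpec,
    CohortConfig,
    build_cohort_config,
    validation_cohort_config,
    generate_cohort,
    generate_periorbital_image,
    FEATURE_NAMES,
)
from .image_features import (
    RidgeParams,
    BandParams,
    CalibrationStore,
    crop_periorbital_roi,
    to_grayscale,
    hessian_ridge_response,
    fft_enhance,
    raw_wrinkle_fraction,
    raw_spot_fraction,
    calibrate_scores,
    SIDES,
    _WRINKLE_REGION_OF,
    _SPOT_REGION_OF,
)
from .age_models import model_catalog, PeriorbitalAgeModel, cross_validate, validate_model
from .association import DiseaseAssociationStudy
from .io import write_cohort, read_cohort

log = logging.getLogger("periskin")

STAGES = ("simulate", "extract", "fit", "associate")


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    stages: tuple[str, ...] = STAGES
    n_images: int = 12              # imaging subset rendered per run
    image: FaceImageSpec = field(default_factory=FaceImageSpec)
    build: CohortConfig = field(default_factory=build_cohort_config)
    validation: CohortConfig = field(default_factory=validation_cohort_config)
    ridge: RidgeParams = field(default_factory=RidgeParams)
    band: BandParams = field(default_factory=BandParams)
    cv_folds: int = 10
    model_numbers: tuple[int, ...] = tuple(range(1, 10))
    fdr_family: str = "all"
    log_level: str = "INFO"

    def to_json(self) -> str:
        def encode(obj):
            if dataclasses.is_dataclass(obj):
                return asdict(obj)
            raise TypeError(type(obj))

        return json.dumps(asdict(self), indent=2, sort_keys=True, default=encode)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)

        def tup(v):
            return tuple(tuple(x) if isinstance(x, list) else x for x in v)

        def load_dc(dc_cls, sub: dict):
            fixed = {}
            for f in dataclasses.fields(dc_cls):
                v = sub[f.name]
                if isinstance(v, list):
                    v = tup(v)
                elif isinstance(v, dict):
                    v = {k: tuple(x) if isinstance(x, list) else x for k, x in v.items()}
                fixed[f.name] = v
            return dc_cls(**fixed)

        return cls(
            stages=tuple(d["stages"]),
            n_images=d["n_images"],
            image=load_dc(FaceImageSpec, d["image"]),
            build=load_dc(CohortConfig, d["build"]),
            validation=load_dc(CohortConfig, d["validation"]),
            ridge=load_dc(RidgeParams, d["ridge"]),
            band=load_dc(BandParams, d["band"]),
            cv_folds=d["cv_folds"],
            model_numbers=tuple(d["model_numbers"]),
            fdr_family=d["fdr_family"],
            log_level=d["log_level"],
        )


@dataclass
class RunManifest:
    """Provenance record of one run: seeds, config hash, file checksums."""

    config_hash: str
    global_seed: int
    stage_seeds: dict[str, int]
    version: str
    started: float
    finished: float = 0.0
    files: dict[str, str] = field(default_factory=dict)  # relpath -> sha256
    completed_stages: list[str] = field(default_factory=list)
    failed_stage: str | None = None

    def record(self, out_dir: Path, path: Path) -> None:
        rel = str(path.relative_to(out_dir))
        self.files[rel] = hashlib.sha256(path.read_bytes()).hexdigest()

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (global_seed * 1_000_003 + STAGES.index(stage)) % 2**31


def run_pipeline(config: RunConfig, out_dir: str | Path, seed: int = 0) -> RunManifest:
    """Execute the enabled stages and return the run manifest.

    A stage failure aborts the run; the manifest (always written to
    ``manifest.json``) then names the failing stage and flags the partial
    outputs produced so far.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    unknown = [s for s in config.stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s): {', '.join(unknown)}")

    config_text = config.to_json()
    manifest = RunManifest(
        config_hash=hashlib.sha256(config_text.encode()).hexdigest(),
        global_seed=seed,
        stage_seeds={s: stage_seed(seed, s) for s in config.stages},
        version=__version__,
        started=time.time(),
    )
    (out / "config.json").write_text(config_text)
    manifest.record(out, out / "config.json")

    runners = {
        "simulate": _stage_simulate,
        "extract": _stage_extract,
        "fit": _stage_fit,
        "associate": _stage_associate,
    }
    try:
        for stage in STAGES:
            if stage not in config.stages:
                continue
            log.info("running stage %s", stage)
            for path in runners[stage](config, out, stage_seed(seed, stage)):
                manifest.record(out, path)
            manifest.completed_stages.append(stage)
    except Exception:
        manifest.failed_stage = stage
        manifest.finished = time.time()
        manifest.save(out / "manifest.json")
        raise RuntimeError(f"pipeline stage {stage!r} failed; partial outputs flagged in manifest")
    manifest.finished = time.time()
    manifest.save(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# stages (each yields the files it wrote)
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, out: Path, seed: int):
    build = dataclasses.replace(config.build, seed=seed)
    val = dataclasses.replace(config.validation, seed=seed + 1)
    for name, cohort_cfg in (("cohort_build.csv", build), ("cohort_validation.csv", val)):
        write_cohort(generate_cohort(cohort_cfg), out / name)
        yield out / name

    img_dir = out / "images"
    img_dir.mkdir(exist_ok=True)
    for i in range(config.n_images):
        spec = dataclasses.replace(config.image, seed=seed + 100 + i)
        image, lm, truth = generate_periorbital_image(spec)
        Image.fromarray(image).save(img_dir / f"face_{i:03d}.png")
        lm.save(img_dir / f"face_{i:03d}_landmarks.json")
        Image.fromarray((truth.wrinkle_mask * 255).astype(np.uint8)).save(
            img_dir / f"face_{i:03d}_wrinkle_mask.png"
        )
        Image.fromarray((truth.spot_mask * 255).astype(np.uint8)).save(
            img_dir / f"face_{i:03d}_spot_mask.png"
        )
        for suffix in ("", "_landmarks.json", "_wrinkle_mask.png", "_spot_mask.png"):
            yield img_dir / f"face_{i:03d}{suffix or '.png'}"


def _load_images(out: Path):
    img_dir = out / "images"
    faces = sorted(img_dir.glob("face_???.png"))
    if not faces:
        raise FileNotFoundError("no simulated images found; run the simulate stage first")
    for png in faces:
        stem = png.stem
        image = np.asarray(Image.open(png))
        lm = LandmarkSet.load(img_dir / f"{stem}_landmarks.json")
        yield stem, image, lm


def _stage_extract(config: RunConfig, out: Path, seed: int):
    # first pass: raw fractions per index over the imaging subset
    raw: dict[str, list[float]] = {k: [] for k in (*_WRINKLE_REGION_OF, *_SPOT_REGION_OF)}
    names = []
    for stem, image, lm in _load_images(out):
        names.append(stem)
        for index, region in _WRINKLE_REGION_OF.items():
            vals = []
            for side in SIDES:
                patch, _ = crop_periorbital_roi(image, lm, region, side)
                resp = hessian_ridge_response(to_grayscale(patch), config.ridge)
                vals.append(raw_wrinkle_fraction(fft_enhance(resp, config.band), config.ridge.threshold))
            raw[index].append(float(np.mean(vals)))
        for index, region in _SPOT_REGION_OF.items():
            vals = []
            for side in SIDES:
                patch, _ = crop_periorbital_roi(image, lm, region, side)
                vals.append(raw_spot_fraction(patch))
            raw[index].append(float(np.mean(vals)))

    # calibrate on the subset itself (a reference cohort in real use); small
    # subsets fall back to full-range bounds via the conservative percentiles
    store = CalibrationStore()
    scores: dict[str, np.ndarray] = {}
    for index, fractions in raw.items():
        arr = np.asarray(fractions)
        if arr.size >= 30:
            calib = calibrate_scores(arr, kind="wrinkle" if index.startswith("W") else "spot", region=index)
        else:
            lo, hi = float(arr.min()), float(arr.max())
            if hi - lo < 1e-12:
                hi = lo + 1e-6
            from .image_features import ScoreCalibration

            calib = ScoreCalibration(
                kind="wrinkle" if index.startswith("W") else "spot",
                region=index,
                lower=lo,
                upper=hi,
                provenance=f"imaging-subset-minmax (n={arr.size})",
            )
        store.add(calib)
        scores[index] = np.asarray(calib.apply(arr))

    store.save(out / "calibrations.json")
    yield out / "calibrations.json"

    table = pd.DataFrame({"image": names, **{k: np.round(v, 3) for k, v in scores.items()}})
    table.to_csv(out / "image_features.csv", index=False)
    yield out / "image_features.csv"


def _stage_fit(config: RunConfig, out: Path, seed: int):
    build = read_cohort(out / "cohort_build.csv")
    val = read_cohort(out / "cohort_validation.csv")
    catalog = model_catalog()

    models_dir = out / "models"
    models_dir.mkdir(exist_ok=True)
    report_rows = []
    for number in config.model_numbers:
        subset = catalog[number]
        cv = cross_validate(build, subset, k=config.cv_folds, seed=seed + number)
        final = PeriorbitalAgeModel.from_catalog(build, number, training_id="build").fit()
        refined = final.refine()
        val_r = validate_model(refined, val)
        path = models_dir / f"model_{number}.json"
        refined.save(path)
        yield path
        report_rows.append(
            {
                "model": number,
                "features": "+".join(subset),
                "cv_mean_r": round(cv.mean_r, 4),
                "validation_r": round(val_r, 4),
                "refined": refined.refined,
                "removed": "+".join(refined.removed),
            }
        )
        log.info("model %d: CV r = %.3f, validation r = %.3f", number, cv.mean_r, val_r)

    pd.DataFrame(report_rows).to_csv(out / "model_report.csv", index=False)
    yield out / "model_report.csv"


def _stage_associate(config: RunConfig, out: Path, seed: int):
    build = read_cohort(out / "cohort_build.csv")
    val = read_cohort(out / "cohort_validation.csv")
    final = PeriorbitalAgeModel.from_catalog(build, 7, training_id="build").fit().refine()
    skin_age = final.predict(val)

    results = DiseaseAssociationStudy(val, skin_age, fdr_family=config.fdr_family).fit()
    table = results.table.copy()
    for col in ("beta_age", "beta_skin_age"):
        table[col] = table[col].round(4)
    table.to_csv(out / "association_table.csv", index=False)
    yield out / "association_table.csv"

    payload = {
        "pc1_r": results.pc1_r,
        "pc1_p": results.pc1_p,
        "explained_variance_ratio": results.pca.explained_variance_ratio.tolist(),
        "pc1_loadings": {k: float(v) for k, v in results.pca.pc1_loadings.items()},
        "significant": results.significant,
        "adjusted": {
            name: {"beta": res.beta, "p": res.pvalue} for name, res in results.adjusted.items()
        },
    }
    (out / "association_pca.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    yield out / "association_pca.json"
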