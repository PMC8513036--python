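"""File formats, run configuration and the end-to-end pipeline.

All exchange formats are plain text: peak tables and feature matrices as
UTF-8 comma-separated CSV with '.' decimals and mandatory headers, spectra
as MGF (negative-mode CHARGE such as ``2-``; TITLE carries the spectrum
id), reports as CSV/JSON.  Melanoma is the positive class in every report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml
from pyteomics import mgf as _mgf

from . import __version__
from .discriminant import (
    ClassificationReport,
    CrossValPlan,
    _confusion,
    ablation,
    classify,
    cross_validate,
    fit_lda,
    select_features,
)
from .fragments import Spectrum
from .masses import parse_composition
from .quantify import (
    PEAK_TABLE_COLUMNS,
    FeatureMatrix,
    PeakTable,
    glycan_sums,
    group_summary,
    isomer_ratios,
    relative_areas,
)

__all__ = [
    "DataError",
    "RunConfig",
    "read_peak_table",
    "write_peak_table",
    "read_mgf",
    "write_mgf",
    "read_feature_matrix",
    "write_feature_matrix",
    "run_pipeline",
]

logger = logging.getLogger("glycolda")


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class RunConfig:
    """Analysis knobs with their documented defaults; YAML round-trippable."""

    peak_table: str = "peak_table.csv"
    out_dir: str = "glycolda_out"
    k_features: int = 10
    tol_ppm: float = 10.0
    n_train: int = 25
    n_reps: int = 10
    stratified: bool = False
    nested: bool = False
    shrinkage: float = 1e-3
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def read_peak_table(path: Union[str, Path]) -> PeakTable:
    """Read and validate a long-format peak-area CSV.

    Missing (sample, isomer) combinations are filled with zero area and
    logged; duplicated rows, schema violations, unknown class labels and
    malformed composition strings are errors naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"peak table not found: {path}")
    df = pd.read_csv(path)
    missing_cols = [c for c in PEAK_TABLE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise DataError(f"{path}: missing columns {missing_cols}")
    for row, comp in df["composition"].items():
        try:
            parse_composition(str(comp))
        except ValueError as err:
            raise DataError(f"{path} row {row + 2}: {err}") from err
    dup = df.duplicated(["sample_id", "composition", "isomer_index"], keep=False)
    if dup.any():
        first = df.index[dup][0]
        raise DataError(
            f"{path} row {first + 2}: duplicate (sample, composition, isomer) entry"
        )
    if not pd.api.types.is_numeric_dtype(df["area"]):
        bad = df.index[pd.to_numeric(df["area"], errors="coerce").isna()][0]
        raise DataError(f"{path} row {bad + 2}: non-numeric area")
    # fill missing isomers with zero so every sample covers the same set
    isomers = df[["composition", "isomer_index", "rt_min"]].drop_duplicates(
        ["composition", "isomer_index"]
    )
    samples = df[["sample_id", "class"]].drop_duplicates("sample_id")
    full = samples.merge(isomers, how="cross")
    merged = full.merge(
        df[["sample_id", "composition", "isomer_index", "area"]],
        on=["sample_id", "composition", "isomer_index"],
        how="left",
    )
    n_filled = int(merged["area"].isna().sum())
    if n_filled:
        logger.warning("%s: filled %d missing isomer entries with zero area", path, n_filled)
        merged["area"] = merged["area"].fillna(0.0)
    try:
        return PeakTable(merged[PEAK_TABLE_COLUMNS])
    except ValueError as err:
        raise DataError(f"{path}: {err}") from err


def write_peak_table(table: PeakTable, path: Union[str, Path]) -> None:
    table.data.to_csv(path, index=False, float_format="%.6g")


def _prescan_mgf(path: Path) -> None:
    """Cheap structural scan to attach line numbers to MGF format errors."""
    open_line = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if s == "BEGIN IONS":
                if open_line is not None:
                    raise DataError(
                        f"{path} line {lineno}: BEGIN IONS inside unterminated block "
                        f"opened at line {open_line}"
                    )
                open_line = lineno
            elif s == "END IONS":
                if open_line is None:
                    raise DataError(f"{path} line {lineno}: END IONS without BEGIN IONS")
                open_line = None
            elif open_line is not None and s and "=" not in s:
                parts = s.split()
                try:
                    [float(p) for p in parts[:2]]
                except ValueError:
                    raise DataError(f"{path} line {lineno}: non-numeric peak entry {s!r}")
    if open_line is not None:
        raise DataError(f"{path}: unterminated BEGIN IONS block opened at line {open_line}")


def read_mgf(path: Union[str, Path]) -> list[Spectrum]:
    """Read negative-mode MS/MS spectra from an MGF file, sorted by TITLE."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"MGF file not found: {path}")
    _prescan_mgf(path)
    spectra = []
    with _mgf.read(str(path), use_index=False) as reader:
        for entry in reader:
            params = entry["params"]
            charge_list = params.get("charge", [1])
            charge = int(charge_list[0])
            spectra.append(
                Spectrum(
                    precursor_mz=float(params["pepmass"][0]),
                    charge=abs(charge),
                    mz_array=entry["m/z array"],
                    intensity_array=entry["intensity array"],
                    source_id=str(params.get("title", "")),
                )
            )
    spectra.sort(key=lambda s: s.source_id)
    return spectra


def write_mgf(spectra: list[Spectrum], path: Union[str, Path]) -> None:
    entries = []
    for spec in spectra:
        entries.append(
            {
                "m/z array": spec.mz_array,
                "intensity array": spec.intensity_array,
                "params": {
                    "title": spec.source_id,
                    "pepmass": spec.precursor_mz,
                    "charge": [-abs(spec.charge)],
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def write_feature_matrix(features: FeatureMatrix, path: Union[str, Path]) -> None:
    out = features.values.copy()
    out.insert(0, "class", features.labels)
    out.index.name = "sample_id"
    out.to_csv(path)


def read_feature_matrix(path: Union[str, Path]) -> FeatureMatrix:
    path = Path(path)
    if not path.exists():
        raise DataError(f"feature matrix not found: {path}")
    df = pd.read_csv(path, index_col="sample_id")
    if "class" not in df.columns:
        raise DataError(f"{path}: missing 'class' column")
    labels = df.pop("class")
    return FeatureMatrix(df, labels)


def build_features(table: PeakTable) -> FeatureMatrix:
    """quantify stage: isomer %, glycan sums, and all within-glycan ratios."""
    return isomer_ratios(glycan_sums(relative_areas(table)))


def run_pipeline(config: RunConfig) -> dict:
    """Run quantify → select → fit/classify → ablate → crossval; write artifacts.

    Returns a manifest dict (also written as JSON) recording the seed, the
    package version, the config hash and all output paths.  Outputs are a
    pure function of (input file, config); re-running with the same inputs
    reproduces them byte for byte.
    """
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    table = read_peak_table(config.peak_table)  # fail before creating outputs
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage quantify: %d samples", len(table.samples))
    features = build_features(table)
    write_feature_matrix(features, out / "feature_matrix.csv")
    summary = group_summary(features)
    summary.to_csv(out / "group_summary.csv", float_format="%.6g")

    logger.info("stage select: k=%d", config.k_features)
    scores = select_features(features, config.k_features)
    pd.DataFrame(
        [(s.rank, s.feature, s.fisher_index) for s in scores],
        columns=["rank", "feature", "fisher_index"],
    ).to_csv(out / "feature_scores.csv", index=False, float_format="%.6g")
    selected = [s.feature for s in scores]

    logger.info("stage classify (resubstitution)")
    model = fit_lda(features, selected, shrinkage=config.shrinkage)
    pred, proj = classify(model, features)
    coords = pd.DataFrame(
        {"class": features.labels, "predicted": pred, "projection": proj}
    )
    coords.index.name = "sample_id"
    coords.to_csv(out / "projection.csv", float_format="%.6g")
    resub = ClassificationReport(*_confusion(features.labels, pred))

    logger.info("stage ablate: %d variables", len(selected))
    abl = ablation(features, selected, shrinkage=config.shrinkage)
    pd.DataFrame(
        [{"omitted": f, **rep.as_dict()} for f, rep in abl.items()]
    ).to_csv(out / "ablation.csv", index=False)

    logger.info(
        "stage crossval: n_train=%d reps=%d nested=%s", config.n_train,
        config.n_reps, config.nested,
    )
    plan = CrossValPlan(
        n_train=config.n_train,
        n_reps=config.n_reps,
        seed=config.seed,
        stratified=config.stratified,
    )
    cv = cross_validate(
        features,
        plan,
        features=None if config.nested else selected,
        k=config.k_features,
        nested=config.nested,
        shrinkage=config.shrinkage,
    )
    reports = {"classification": resub.as_dict(), "cross_validation": cv.as_dict()}
    (out / "classification_report.json").write_text(json.dumps(reports, indent=2))

    manifest = {
        "glycolda_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.digest(),
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline complete: %s", out)
    return manifest
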