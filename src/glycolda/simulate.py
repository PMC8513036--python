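"""Synthetic cohorts and MS/MS spectra emulating the serum-AGP glycomics study.

The generator produces a 37-sample cohort (18 melanoma, 19 control) over a
synthetic catalog of 102 sialylated N-glycan isomers, with class-dependent
structure matching the qualitative biology: fucosylated glycans up in
melanoma, their nonfucosylated counterparts down, and within-glycan
abundance shifted toward later-eluting (more α-2,6-sialylated) isomers.
Per-isomer abundances are drawn from a positive right-skewed noise model
(lognormal by default, gamma as an alternative) at class-adjusted means,
then multiplied by a per-sample instrument-response scale, so the raw
areas are NOT closed to 100 — relative-area normalization has to recover
the compositional structure.

The default catalog (baseline means, RSDs, retention times) is a synthetic
placeholder shipped as a reviewable CSV: the study's true per-isomer
abundances were never published.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .fragments import Spectrum, diagnostic_sialic_ions, enumerate_fragments
from .masses import IonSpec, mz, neutral_mass
from .quantify import (
    PEAK_TABLE_COLUMNS,
    PeakTable,
    iso_feature,
    ratio_feature,
    sum_feature,
)
from .topology import GlycanTopology

__all__ = [
    "CohortConfig",
    "CohortTruth",
    "DEFAULT_EFFECTS",
    "DEFAULT_RATIO_SHIFTS",
    "DEFAULT_PLANTED_FEATURES",
    "default_catalog",
    "generate_cohort",
    "generate_spectrum",
]

#: Multiplicative melanoma effects on baseline means.  Keys are either a
#: composition (applied to all its isomers) or a single isomer descriptor.
#: Directions follow the study's reported biology: the fucosylated
#: biantennary-extended species up, its nonfucosylated counterparts down,
#: and milder up-effects on peripheral multiply-fucosylated glycans.
DEFAULT_EFFECTS: dict[str, float] = {
    "N6H7S2F": 1.8,
    "N5H6S2": 0.55,
    "N5H6S3": 0.85,
    "N6H7S3": 0.85,
    "N5H6S3F": 1.1,
    "N5H6S3F2": 1.2,
    "N5H6S3F3": 1.3,
    "N6H7S4F": 1.2,
    "N6H7S4F2": 1.25,
}

#: Within-glycan abundance shifts (composition, donor isomer, acceptor
#: isomer, fraction of the donor's mean moved), melanoma class only —
#: modelling the increased share of later-eluting (more α-2,6) isomers.
DEFAULT_RATIO_SHIFTS: list[tuple[str, int, int, float]] = [
    ("N5H6S2", 4, 5, 0.30),
    ("N5H6S3F", 1, 2, 0.30),
    ("N6H7S2", 3, 5, 0.30),
    ("N6H7S2", 4, 5, 0.25),
    ("N6H7S2F", 2, 3, 0.30),
]

#: The ten designated informative features (the Table-1-shaped panel).
DEFAULT_PLANTED_FEATURES: list[str] = [
    ratio_feature("N5H6S2", 4, 5),
    iso_feature("N5H6S2", 4),
    iso_feature("N5H6S2", 5),
    sum_feature("N5H6S2"),
    ratio_feature("N5H6S3F", 1, 2),
    ratio_feature("N6H7S2", 3, 5),
    ratio_feature("N6H7S2", 4, 5),
    ratio_feature("N6H7S2F", 2, 3),
    iso_feature("N6H7S2F", 3),
    sum_feature("N6H7S2F"),
]


def default_catalog() -> pd.DataFrame:
    """The shipped synthetic catalog of 102 isomers.

    Columns: composition, isomer_index, rt_min, baseline_mean_pct, rsd_pct.
    """
    ref = importlib.resources.files("glycolda").joinpath("data/default_catalog.csv")
    with ref.open("r") as fh:
        return pd.read_csv(fh, comment="#")


@dataclass
class CohortConfig:
    """Study-condition parameters for cohort generation."""

    n_melanoma: int = 18
    n_control: int = 19
    catalog: Optional[pd.DataFrame] = None  # default_catalog() when None
    effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    ratio_shifts: list[tuple[str, int, int, float]] = field(
        default_factory=lambda: list(DEFAULT_RATIO_SHIFTS)
    )
    planted_features: list[str] = field(
        default_factory=lambda: list(DEFAULT_PLANTED_FEATURES)
    )
    noise: str = "lognormal"
    sample_scale_sd: float = 0.3  # lognormal sigma of the per-sample response factor
    glycan_cv: float = 0.25  # CV of the shared within-glycan (common-mode) factor
    area_scale: float = 1e4  # arbitrary-unit scale of raw areas
    seed: int = 0

    def validate(self) -> None:
        if self.n_melanoma < 0 or self.n_control < 0:
            raise ValueError("n_melanoma and n_control must be >= 0")
        if self.noise not in ("lognormal", "gamma"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.sample_scale_sd < 0:
            raise ValueError("sample_scale_sd must be >= 0")
        if self.glycan_cv < 0:
            raise ValueError("glycan_cv must be >= 0")
        for key, eff in self.effects.items():
            if eff <= 0:
                raise ValueError(f"effect for {key!r} must be > 0")
        for comp, donor, acceptor, frac in self.ratio_shifts:
            if not 0 <= frac < 1:
                raise ValueError(
                    f"shifted fraction for {comp} isomers {donor}->{acceptor} "
                    "must be in [0, 1)"
                )


@dataclass
class CohortTruth:
    """Ground truth of a generated cohort: sufficient to recompute the
    expected relative-abundance fold change of every isomer analytically."""

    planted_features: list[str]
    class_means: pd.DataFrame  # index (composition, isomer_index); control/melanoma mean %
    sample_classes: pd.Series
    seed: int

    def expected_fold_changes(self) -> pd.Series:
        """Expected melanoma/control fold change of each isomer's relative %."""
        ctrl = self.class_means["control"]
        mel = self.class_means["melanoma"]
        fc = (mel / mel.sum()) / (ctrl / ctrl.sum())
        fc.name = "expected_fold_change"
        return fc


def _class_means(config: CohortConfig, catalog: pd.DataFrame) -> pd.DataFrame:
    base = catalog.set_index(["composition", "isomer_index"])["baseline_mean_pct"]
    mel = base.copy()
    for key, eff in config.effects.items():
        if "|iso" in key:
            comp, iso = key.split("|iso")
            target = (comp, int(iso))
            if target not in mel.index:
                raise ValueError(f"effect key {key!r} not in catalog")
            mel.loc[target] *= eff
        else:
            mask = mel.index.get_level_values(0) == key
            if not mask.any():
                raise ValueError(f"effect key {key!r} not in catalog")
            mel.loc[mask] *= eff
    for comp, donor, acceptor, frac in config.ratio_shifts:
        for iso in (donor, acceptor):
            if (comp, iso) not in mel.index:
                raise ValueError(f"ratio shift references missing isomer {comp}|iso{iso}")
        moved = frac * mel.loc[(comp, donor)]
        mel.loc[(comp, donor)] -= moved
        mel.loc[(comp, acceptor)] += moved
    return pd.DataFrame({"control": base, "melanoma": mel})


def generate_cohort(config: CohortConfig) -> tuple[PeakTable, CohortTruth]:
    """Generate a raw peak-area table plus its ground truth."""
    config.validate()
    catalog = config.catalog if config.catalog is not None else default_catalog()
    rng = np.random.default_rng(config.seed)
    means = _class_means(config, catalog)
    rsd = catalog.set_index(["composition", "isomer_index"])["rsd_pct"] / 100.0

    sample_ids = [f"MM{i + 1:02d}" for i in range(config.n_melanoma)] + [
        f"CTRL{i + 1:02d}" for i in range(config.n_control)
    ]
    classes = ["melanoma"] * config.n_melanoma + ["control"] * config.n_control

    compositions = means.index.get_level_values(0)
    comp_codes, _ = pd.factorize(compositions)
    n_comps = comp_codes.max() + 1
    g_sigma = np.sqrt(np.log1p(config.glycan_cv**2))

    rows = []
    for sample, cls in zip(sample_ids, classes):
        mu = means[cls].to_numpy() * config.area_scale
        r = rsd.to_numpy()
        # shared within-glycan factor: isomer ratios are more stable than levels
        glycan_factor = np.exp(
            g_sigma * rng.standard_normal(n_comps) - g_sigma**2 / 2
        )[comp_codes]
        if config.noise == "lognormal":
            sigma = np.sqrt(np.log1p(r**2))
            draws = mu / np.sqrt(1 + r**2) * np.exp(sigma * rng.standard_normal(len(mu)))
        else:  # gamma with matching mean and CV
            shape = 1.0 / r**2
            draws = rng.gamma(shape, mu / shape)
        scale = float(np.exp(config.sample_scale_sd * rng.standard_normal()))
        areas = draws * glycan_factor * scale
        for (comp, iso), rt, area in zip(
            means.index, catalog["rt_min"].to_numpy(), areas
        ):
            rows.append((sample, cls, comp, iso, rt, area))
    table = PeakTable(pd.DataFrame(rows, columns=PEAK_TABLE_COLUMNS))
    truth = CohortTruth(
        planted_features=list(config.planted_features),
        class_means=means,
        sample_classes=pd.Series(classes, index=pd.Index(sample_ids, name="sample_id")),
        seed=config.seed,
    )
    return table, truth


def generate_spectrum(
    topology: GlycanTopology,
    n_noise_peaks: int = 20,
    seed: int = 0,
    charge: int = 2,
    base_intensity: float = 1000.0,
) -> Spectrum:
    """Simulate a negative-mode MS/MS spectrum of one glycan topology.

    Peaks are placed at every singly charged Y/Z/B/C fragment m/z up to two
    cleavages, plus the linkage diagnostics applicable under the topology's
    sialic tags, with lognormal intensities decaying with fragment size;
    uniform low-intensity noise peaks are added.  The planted fragment
    labels are recorded in ``spectrum.annotations["planted"]``.
    """
    rng = np.random.default_rng(seed)
    comp = topology.composition()
    precursor = mz(neutral_mass(comp), IonSpec(charge))
    fragments = enumerate_fragments(
        topology, ion_types={"B", "C", "Y", "Z"}, max_cleavages=2
    )
    # Core fucose stays attached during fragmentation (the basis of the
    # core/antenna diagnostic): drop reducing-end ions that cleaved it off.
    n_core_fuc = topology.fucose_positions.count("core")
    if n_core_fuc:
        fragments = [
            f
            for f in fragments
            if f.ion_type not in ("Y", "Z") or f.composition.n_fuc >= n_core_fuc
        ]
    tags = set(topology.sialic_linkages)
    for diag in diagnostic_sialic_ions():
        if comp.n_neuac >= 1 and diag.diagnostic_for in tags:
            fragments.append(diag)
    mzs, intens, labels = [], [], []
    for frag in fragments:
        size_penalty = 0.9 ** frag.composition.n_residues
        inten = base_intensity * size_penalty * np.exp(0.4 * rng.standard_normal())
        mzs.append(frag.mz)
        intens.append(inten)
        labels.append(frag.label)
    if n_noise_peaks:
        lo = 150.0
        hi = max(precursor, lo + 1)
        noise_mz = rng.uniform(lo, hi, n_noise_peaks)
        noise_int = base_intensity * 0.01 * rng.uniform(0.1, 1.0, n_noise_peaks)
        mzs.extend(noise_mz)
        intens.extend(noise_int)
    return Spectrum(
        precursor_mz=precursor,
        charge=charge,
        mz_array=np.array(mzs),
        intensity_array=np.array(intens),
        source_id=f"synthetic:{comp}:seed{seed}",
        annotations={"planted": labels, "seed": seed},
    )
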