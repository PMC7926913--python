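"""Synthetic LC-qToF-MS feature lists with planted origin markers.

The generator emulates the statistical structure an untargeted olive-oil
origin study produces after vendor peak picking: per-injection lists of
(retention time, m/z, intensity) features for ~95 oils from four origin
groups, analysed in duplicate with periodic solvent blanks.

Model, per catalogued compound ``j`` with base intensity ``B_j``:

* oil-level latent intensity  ``L_ij = B_j * f_j(group_i) * exp(sigma_bio * z)``
  where ``f_j`` is the planted marker fold change (1 for non-markers),
* injection intensity          ``L_ij * exp(sigma_inj * z')``  (duplicates share
  the oil latent and differ only by this multiplicative injection noise),
* observed coordinates jittered per injection:
  ``rt + N(0, rt_jitter_sd)`` seconds, ``mz + N(0, mz_jitter_sd)`` mDa,
* detection: a compound is present in an oil with its per-feature presence
  probability (drawn once per oil so duplicate injections agree), and
  missing compounds are simply absent from the list (zero in the table).

Blanks contain a configurable fraction of the background catalogue at a
reduced level plus the contaminant compounds at full level; no markers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._core import (
    BLANK_GROUP,
    ConfigError,
    FeatureList,
    ORIGIN_GROUPS,
    SampleMeta,
    log,
    samples_frame,
)

#: Sample counts of the reference design (95 oils total).
DEFAULT_GROUP_SIZES = {"Esp": 26, "Gre": 13, "Ita": 39, "Pt": 17}


@dataclass
class SimConfig:
    """Study-design and noise parameters of the synthetic cohort.

    Defaults reproduce the reference design: 26/13/39/17 oils for
    Spain/Greece/Italy/Portugal analysed in duplicate (190 injections), a
    blank every ten injections (19 blanks), ~2000 background compounds per
    sample over RT 0.5-17 min and m/z 50-1000, and one >=4-fold marker
    compound per origin group.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    n_blanks: int = 19
    n_replicates: int = 2
    n_background: int = 2000
    n_markers_per_group: int = 1
    marker_fold_change: float = 4.0
    n_contaminants: int = 50
    #: scalar detection probability, or a (a, b) pair meaning per-feature
    #: probabilities are drawn from Beta(a, b) (markers/contaminants then
    #: use 0.95 so planted structure remains detectable).
    presence_prob: float | tuple[float, float] = 0.95
    #: log10 range of base intensities (uniform draw per compound).
    intensity_log10_range: tuple[float, float] = (4.0, 6.0)
    #: lognormal sigma of oil-to-oil biological variation (natural log).
    biological_sigma: float = 0.35
    #: lognormal sigma of injection noise; 0.10 gives a duplicate CV of ~10%.
    injection_sigma: float = 0.10
    #: fraction of background compounds also present in blanks ...
    blank_feature_frac: float = 0.3
    #: ... and their intensity in blanks relative to the oil level.
    blank_level_frac: float = 0.1
    rt_range: tuple[float, float] = (0.5, 17.0)
    mz_range: tuple[float, float] = (50.0, 1000.0)
    rt_jitter_sd: float = 0.1  # seconds
    mz_jitter_sd: float = 1.0  # mDa
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_blanks",
            "n_replicates",
            "n_background",
            "n_markers_per_group",
            "n_contaminants",
        ):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigError(f"{name} must be a non-negative integer, got {v!r}")
        if not self.n_per_group or any(n < 0 for n in self.n_per_group.values()):
            raise ConfigError(f"n_per_group must map groups to counts >= 0, got {self.n_per_group!r}")
        if BLANK_GROUP in self.n_per_group:
            raise ConfigError("n_per_group must not contain the Blank group; use n_blanks")
        if self.marker_fold_change < 1:
            raise ConfigError(f"marker_fold_change must be >= 1, got {self.marker_fold_change!r}")
        if isinstance(self.presence_prob, tuple):
            a, b = self.presence_prob
            if a <= 0 or b <= 0:
                raise ConfigError(f"presence_prob Beta parameters must be > 0, got {self.presence_prob!r}")
        elif not 0 <= self.presence_prob <= 1:
            raise ConfigError(f"presence_prob must lie in [0, 1], got {self.presence_prob!r}")
        if not 0 <= self.blank_feature_frac <= 1:
            raise ConfigError(f"blank_feature_frac must lie in [0, 1], got {self.blank_feature_frac!r}")
        if self.blank_level_frac < 0:
            raise ConfigError(f"blank_level_frac must be >= 0, got {self.blank_level_frac!r}")
        for name in ("biological_sigma", "injection_sigma", "rt_jitter_sd", "mz_jitter_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)!r}")
        for name in ("rt_range", "mz_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ConfigError(f"{name} must be an increasing (low, high) pair, got {(lo, hi)!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("presence_prob", "intensity_log10_range", "rt_range", "mz_range"):
            if isinstance(d[key], tuple):
                d[key] = list(d[key])
        return d


@dataclass
class GroundTruth:
    """True compound catalogue behind a simulated cohort.

    ``features`` has one row per catalogued compound with its true
    coordinates, base intensity, kind (background / marker / contaminant),
    the origin group a marker is elevated in, and the planted fold change.
    """

    features: pd.DataFrame

    @property
    def markers(self) -> pd.DataFrame:
        return self.features[self.features["kind"] == "marker"]


@dataclass
class SimDataset:
    feature_lists: list[FeatureList]
    samples: list[SampleMeta]
    ground_truth: GroundTruth
    config: SimConfig


def _make_catalog(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    groups = list(config.n_per_group)
    n_mark = config.n_markers_per_group * len(groups)
    n = config.n_background + n_mark + config.n_contaminants
    kinds = (
        ["background"] * config.n_background
        + ["marker"] * n_mark
        + ["contaminant"] * config.n_contaminants
    )
    marker_group = [""] * config.n_background
    for g in groups:
        marker_group += [g] * config.n_markers_per_group
    marker_group += [""] * config.n_contaminants

    lo10, hi10 = config.intensity_log10_range
    cat = pd.DataFrame(
        {
            "feature_id": [f"F{i:05d}" for i in range(n)],
            "kind": kinds,
            "group": marker_group,
            "rt_min": rng.uniform(*config.rt_range, size=n),
            "mz": rng.uniform(*config.mz_range, size=n),
            "base_intensity": 10.0 ** rng.uniform(lo10, hi10, size=n),
        }
    )
    if isinstance(config.presence_prob, tuple):
        a, b = config.presence_prob
        p = rng.beta(a, b, size=n)
        p[np.asarray(kinds) != "background"] = 0.95
    else:
        p = np.full(n, float(config.presence_prob))
    cat["presence_prob"] = p
    cat["fold_change"] = np.where(cat["kind"] == "marker", config.marker_fold_change, 1.0)
    in_blank = np.zeros(n, dtype=bool)
    bg = cat.index[cat["kind"] == "background"].to_numpy()
    n_in = int(round(config.blank_feature_frac * len(bg)))
    if n_in:
        in_blank[rng.choice(bg, size=n_in, replace=False)] = True
    in_blank[cat["kind"] == "contaminant"] = True
    cat["in_blank"] = in_blank
    cat["blank_level"] = np.where(
        cat["kind"] == "contaminant", 1.0, config.blank_level_frac
    ) * cat["in_blank"]
    return cat.set_index("feature_id")


def _emit_injection(
    meta: SampleMeta,
    latent: np.ndarray,
    present: np.ndarray,
    cat: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
) -> FeatureList:
    idx = np.flatnonzero(present)
    inten = latent[idx] * np.exp(config.injection_sigma * rng.standard_normal(idx.size))
    rt = cat["rt_min"].to_numpy()[idx] + rng.standard_normal(idx.size) * (
        config.rt_jitter_sd / 60.0
    )
    mz = cat["mz"].to_numpy()[idx] + rng.standard_normal(idx.size) * (
        config.mz_jitter_sd / 1000.0
    )
    feats = pd.DataFrame({"rt_min": rt, "mz": mz, "intensity": inten})
    return FeatureList(sample=meta, features=feats)


def generate_dataset(config: SimConfig | None = None) -> SimDataset:
    """Simulate one cohort: per-injection feature lists, metadata, ground truth.

    Identical config and seed give byte-identical output (a single
    ``numpy.random.default_rng(seed)`` drives every draw in a fixed order).
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    cat = _make_catalog(config, rng)
    base = cat["base_intensity"].to_numpy()
    presence = cat["presence_prob"].to_numpy()
    kinds = cat["kind"].to_numpy()
    marker_of = cat["group"].to_numpy()

    feature_lists: list[FeatureList] = []
    metas: list[SampleMeta] = []

    for group, n_oils in config.n_per_group.items():
        fold = np.where((kinds == "marker") & (marker_of == group), cat["fold_change"], 1.0)
        for i in range(n_oils):
            oil_id = f"{group}{i + 1:02d}"
            latent = (
                base
                * fold
                * np.exp(config.biological_sigma * rng.standard_normal(len(cat)))
            )
            present = rng.random(len(cat)) < presence
            for rep in range(1, config.n_replicates + 1):
                meta = SampleMeta(
                    sample_id=f"{oil_id}_r{rep}", oil_id=oil_id, group=group, replicate=rep
                )
                metas.append(meta)
                feature_lists.append(
                    _emit_injection(meta, latent, present, cat, config, rng)
                )

    blank_level = cat["blank_level"].to_numpy()
    for i in range(config.n_blanks):
        oil_id = f"Blank{i + 1:02d}"
        latent = (
            base
            * blank_level
            * np.exp(config.biological_sigma * rng.standard_normal(len(cat)))
        )
        present = (blank_level > 0) & (rng.random(len(cat)) < presence)
        meta = SampleMeta(sample_id=f"{oil_id}_r1", oil_id=oil_id, group=BLANK_GROUP, replicate=1)
        metas.append(meta)
        feature_lists.append(_emit_injection(meta, latent, present, cat, config, rng))

    log.info(
        "simulated %d injections (%d oils, %d blanks), catalogue of %d compounds",
        len(metas),
        sum(config.n_per_group.values()),
        config.n_blanks,
        len(cat),
    )
    return SimDataset(
        feature_lists=feature_lists,
        samples=metas,
        ground_truth=GroundTruth(features=cat.reset_index()),
        config=config,
    )


def write_feature_lists(dataset: SimDataset, directory: str | Path) -> dict[str, object]:
    """Write one CSV per injection plus metadata, ground truth and config.

    Returns a dict with the metadata path and the list of feature-file
    paths.  The files round-trip losslessly through
    :func:`oliveauth.bucketing.read_feature_lists`.
    """
    directory = Path(directory)
    feat_dir = directory / "features"
    feat_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for fl in dataset.feature_lists:
        path = feat_dir / f"{fl.sample.sample_id}.csv"
        fl.features.to_csv(path, index=False)
        paths.append(path)
    meta_path = directory / "samples.csv"
    samples_frame(dataset.samples).to_csv(meta_path)
    dataset.ground_truth.features.to_csv(directory / "ground_truth.csv", index=False)
    with open(directory / "sim_config.json", "w") as fh:
        json.dump(dataset.config.to_dict(), fh, indent=2, sort_keys=True)
    return {"metadata": meta_path, "features": paths}
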