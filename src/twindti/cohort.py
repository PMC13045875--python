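"""Synthetic twin-cohort generator with known ACE/ADE covariance structure.

Emulates the data layout of a two-site TBSS twin study: a roster of MZ/DZ
pairs (shared age, per-twin sex, scanner site, exclusion flags), a long
regional-metric table whose within-pair covariance follows the biometric
algebra, and tiny labelled skeleton volumes for exercising the extraction
stage.

Trait values are built from latent standard-normal factors scaled by the
square roots of the standardized components:

* additive factor — shared by MZ co-twins; for DZ co-twins built as
  ``sqrt(1/2)*shared + sqrt(1/2)*unique`` so the additive latents correlate
  0.5 within the pair;
* dominance factor — shared by MZ; ``sqrt(1/4)*shared + sqrt(3/4)*unique``
  for DZ (correlation 0.25);
* shared-environment factor — identical within every pair;
* unique-environment factor — independent per twin.

This reproduces the population within-pair correlations ``A + C + D`` (MZ)
and ``A/2 + C + D/4`` (DZ) exactly.  Linear age and sex effects and
additive + multiplicative scanner batch effects are layered on top in the
location/scale form assumed by ComBat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas import ANALYSIS_REGIONS, METRICS

__all__ = [
    "TwinPairRecord",
    "SimulationConfig",
    "build_roster",
    "retained_pairs",
    "roster_to_frame",
    "simulate_regional_values",
    "simulate_skeleton_volumes",
]

EXCLUSION_REASONS = ("psychiatric", "missing_mri", "low_quality_dti")

# physiologically plausible metric scales: FA dimensionless, diffusivities mm^2/s
METRIC_SCALES: dict[str, tuple[float, float]] = {
    "FA": (0.50, 0.06),
    "MD": (0.80e-3, 0.04e-3),
    "AD": (1.20e-3, 0.06e-3),
    "RD": (0.65e-3, 0.05e-3),
}


@dataclass(frozen=True)
class TwinPairRecord:
    pair_id: str
    zygosity: str  # "MZ" | "DZ"
    sex_1: str  # "M" | "F"
    sex_2: str
    age: float  # years, shared within the pair
    scanner: str
    excluded_reason: str = "none"

    def __post_init__(self) -> None:
        if self.zygosity not in ("MZ", "DZ"):
            raise ValueError(f"zygosity {self.zygosity!r}")
        if self.zygosity == "MZ" and self.sex_1 != self.sex_2:
            raise ValueError(f"MZ pair {self.pair_id} with discordant sexes")
        if self.age <= 0:
            raise ValueError(f"pair {self.pair_id}: age must be positive")

    @property
    def subject_ids(self) -> tuple[str, str]:
        return f"{self.pair_id}_1", f"{self.pair_id}_2"


@dataclass(frozen=True)
class SimulationConfig:
    """True generative parameters for a synthetic twin cohort.

    ``components_by_region`` maps region name to ``(model, A, C, D, E)``
    standardized variance fractions (C = 0 under ADE, D = 0 under ACE;
    fractions sum to 1 with E > 0).  Covariate and batch effects are given
    per metric as multiples of that metric's trait SD where dimensionless.
    """

    n_mz: int = 33
    n_dz: int = 48
    components_by_region: dict[str, tuple[str, float, float, float, float]] = field(
        default_factory=lambda: {
            r: ("ACE", 0.5, 0.2, 0.0, 0.3) for r in ANALYSIS_REGIONS
        }
    )
    metrics: tuple[str, ...] = METRICS
    age_effect: float = 0.02  # trait-SD units per year of age
    sex_effect: float = 0.10  # additive male-minus-female offset, trait-SD units
    batch_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"site_A": (0.0, 1.0), "site_B": (0.30, 1.20)}
    )
    batch_probs: dict[str, float] | None = None  # default: 47/81, 34/81 two-site split
    opposite_sex_dz_fraction: float = 10 / 48
    age_range: tuple[float, float] = (9.0, 32.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_mz < 0 or self.n_dz < 0:
            raise ValueError("pair counts must be non-negative")
        if not self.components_by_region:
            raise ValueError("components_by_region must name at least one region")
        for region, (model, A, C, D, E) in self.components_by_region.items():
            if model not in ("ACE", "ADE"):
                raise ValueError(f"{region}: model {model!r}")
            if min(A, C, D, E) < 0 or E <= 0:
                raise ValueError(f"{region}: components must be >= 0 with E > 0")
            if model == "ACE" and (D != 0 or abs(A + C + E - 1) > 1e-8):
                raise ValueError(f"{region}: ACE needs D=0 and A+C+E=1")
            if model == "ADE" and (C != 0 or abs(A + D + E - 1) > 1e-8):
                raise ValueError(f"{region}: ADE needs C=0 and A+D+E=1")
        if not 0 <= self.opposite_sex_dz_fraction <= 1:
            raise ValueError("opposite_sex_dz_fraction outside [0, 1]")
        if self.age_range[0] <= 0 or self.age_range[1] < self.age_range[0]:
            raise ValueError("invalid age_range")


def _site_probs(config: SimulationConfig) -> tuple[list[str], np.ndarray]:
    sites = sorted(config.batch_effects)
    if config.batch_probs is not None:
        p = np.array([config.batch_probs[s] for s in sites], float)
    elif len(sites) == 2:
        p = np.array([47 / 81, 34 / 81])  # two-site recruitment split
    else:
        p = np.full(len(sites), 1.0 / len(sites))
    return sites, p / p.sum()


def build_roster(
    config: SimulationConfig,
    exclusion_spec: dict[str, int] | None = None,
) -> list[TwinPairRecord]:
    """Draw a twin-pair roster; flag excluded pairs per the given cascade.

    ``exclusion_spec`` maps reason → number of pairs to exclude; reasons are
    applied sequentially in the order psychiatric → missing_mri →
    low_quality_dti to pairs chosen at random from those still retained.
    """
    config.validate()
    exclusion_spec = dict(exclusion_spec or {})
    for reason, count in exclusion_spec.items():
        if reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {reason!r}")
        if count < 0:
            raise ValueError(f"negative exclusion count for {reason!r}")
    n_total = config.n_mz + config.n_dz
    if sum(exclusion_spec.values()) > n_total:
        raise ValueError("more exclusions than pairs")

    rng = np.random.default_rng(config.seed)
    sites, site_p = _site_probs(config)
    records: list[TwinPairRecord] = []
    for i in range(n_total):
        zyg = "MZ" if i < config.n_mz else "DZ"
        age = float(rng.uniform(*config.age_range))
        if zyg == "MZ":
            s = "M" if rng.random() < 0.5 else "F"
            sex_1 = sex_2 = s
        elif rng.random() < config.opposite_sex_dz_fraction:
            sex_1, sex_2 = ("M", "F") if rng.random() < 0.5 else ("F", "M")
        else:
            sex_1 = sex_2 = "M" if rng.random() < 0.5 else "F"
        scanner = sites[rng.choice(len(sites), p=site_p)] if sites else "site_A"
        records.append(
            TwinPairRecord(
                pair_id=f"pair{i + 1:04d}",
                zygosity=zyg,
                sex_1=sex_1,
                sex_2=sex_2,
                age=age,
                scanner=scanner,
            )
        )

    # sequential exclusion cascade on randomly chosen still-retained pairs
    for reason in EXCLUSION_REASONS:
        count = exclusion_spec.get(reason, 0)
        retained_idx = [i for i, r in enumerate(records) if r.excluded_reason == "none"]
        if count > len(retained_idx):
            raise ValueError(f"cannot exclude {count} pairs for {reason!r}")
        for i in rng.choice(retained_idx, size=count, replace=False):
            records[i] = replace(records[i], excluded_reason=reason)
    return records


def retained_pairs(roster: list[TwinPairRecord]) -> list[TwinPairRecord]:
    """Filter view of the roster: pairs entering analysis."""
    return [r for r in roster if r.excluded_reason == "none"]


def roster_to_frame(roster: list[TwinPairRecord]) -> pd.DataFrame:
    """One row per pair; round-trips through CSV."""
    return pd.DataFrame(
        {
            "pair_id": [r.pair_id for r in roster],
            "zygosity": [r.zygosity for r in roster],
            "sex_1": [r.sex_1 for r in roster],
            "sex_2": [r.sex_2 for r in roster],
            "age": [r.age for r in roster],
            "scanner": [r.scanner for r in roster],
            "excluded_reason": [r.excluded_reason for r in roster],
        }
    )


def roster_from_frame(df: pd.DataFrame) -> list[TwinPairRecord]:
    return [
        TwinPairRecord(
            pair_id=str(row.pair_id),
            zygosity=str(row.zygosity),
            sex_1=str(row.sex_1),
            sex_2=str(row.sex_2),
            age=float(row.age),
            scanner=str(row.scanner),
            excluded_reason=str(getattr(row, "excluded_reason", "none")),
        )
        for row in df.itertuples(index=False)
    ]


def _pair_latent(rng: np.random.Generator, n: int, share: float) -> np.ndarray:
    """(n, 2) latent draws with within-pair correlation ``share``."""
    shared = rng.standard_normal((n, 1))
    unique = rng.standard_normal((n, 2))
    return math.sqrt(share) * shared + math.sqrt(1.0 - share) * unique


def simulate_regional_values(
    roster: list[TwinPairRecord], config: SimulationConfig
) -> pd.DataFrame:
    """Long regional-metric table for the retained pairs of ``roster``.

    Columns: subject_id, pair_id, twin_index, region, metric, value.
    Identical roster + config (seed) give a bit-identical table.
    """
    config.validate()
    pairs = retained_pairs(roster)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    zyg = np.array([p.zygosity for p in pairs])
    n = len(pairs)
    age = np.array([p.age for p in pairs])
    male = np.array([[p.sex_1 == "M", p.sex_2 == "M"] for p in pairs], float)
    shift = np.array([config.batch_effects.get(p.scanner, (0.0, 1.0))[0] for p in pairs])
    scale = np.array([config.batch_effects.get(p.scanner, (0.0, 1.0))[1] for p in pairs])
    age_mid = 0.5 * (config.age_range[0] + config.age_range[1])

    rows: list[pd.DataFrame] = []
    for region in config.components_by_region:
        _, A, C, D, E = config.components_by_region[region]
        for metric in config.metrics:
            mu, sd = METRIC_SCALES[metric]
            a_share = np.where(zyg == "MZ", 1.0, 0.5)
            d_share = np.where(zyg == "MZ", 1.0, 0.25)
            # draw MZ and DZ blocks with their own sharing coefficients
            a_lat = np.empty((n, 2))
            d_lat = np.empty((n, 2))
            for share_arr, lat in ((a_share, a_lat), (d_share, d_lat)):
                for s in np.unique(share_arr):
                    idx = np.where(share_arr == s)[0]
                    lat[idx] = _pair_latent(rng, len(idx), float(s))
            c_lat = np.repeat(rng.standard_normal((n, 1)), 2, axis=1)
            e_lat = rng.standard_normal((n, 2))
            trait = (
                math.sqrt(A) * a_lat
                + math.sqrt(C) * c_lat
                + math.sqrt(D) * d_lat
                + math.sqrt(E) * e_lat
            )
            biological = (
                config.age_effect * (age - age_mid)[:, None] + config.sex_effect * male
            )
            value = mu + sd * (biological + shift[:, None] + scale[:, None] * trait)
            if metric == "FA":
                value = np.clip(value, 0.0, 1.0)
            rows.append(
                pd.DataFrame(
                    {
                        "subject_id": [s for p in pairs for s in p.subject_ids],
                        "pair_id": np.repeat([p.pair_id for p in pairs], 2),
                        "twin_index": np.tile([1, 2], n),
                        "region": region,
                        "metric": metric,
                        "value": value.ravel(),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def simulate_skeleton_volumes(
    atlas_spec: dict[str, int],
    regional_values: pd.DataFrame,
    voxel_noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int, int] | None = None,
):
    """Build 4D skeleton metric maps and a 3D label volume from a regional table.

    ``atlas_spec`` maps region name → voxel count; regions are laid out as
    disjoint voxel runs inside a zero background (voxels outside all labels
    are exactly zero, mimicking a TBSS skeleton).  Per subject and region,
    labelled voxels carry the subject's regional value plus optional i.i.d.
    Gaussian noise.

    Returns ``(maps, labels, label_names, subjects)`` where ``maps`` is a
    dict metric → 4D array (x, y, z, subject).
    """
    if voxel_noise_sd < 0:
        raise ValueError("voxel_noise_sd must be >= 0")
    if any(c < 1 for c in atlas_spec.values()):
        raise ValueError("voxel counts must be >= 1")
    total_vox = sum(atlas_spec.values())
    if shape is None:
        side = max(3, math.ceil((2 * total_vox) ** (1 / 3)) + 1)
        shape = (side, side, side)
    if int(np.prod(shape)) < 2 * total_vox:
        raise ValueError("volume too small for the requested labels plus background")

    labels = np.zeros(shape, dtype=np.int16)
    flat = labels.ravel()
    label_names: dict[int, str] = {}
    # leave a one-voxel zero gap between runs so background always exists
    pos = 1
    for k, (region, count) in enumerate(sorted(atlas_spec.items()), start=1):
        if np.any(flat[pos : pos + count]):
            raise ValueError("overlapping labels in atlas construction")
        flat[pos : pos + count] = k
        label_names[k] = region
        pos += count + 1

    subjects = list(dict.fromkeys(regional_values["subject_id"]))
    metrics = list(dict.fromkeys(regional_values["metric"]))
    rng = np.random.default_rng(seed)
    values = regional_values.set_index(["subject_id", "region", "metric"])["value"]

    maps: dict[str, np.ndarray] = {}
    for metric in metrics:
        vol4 = np.zeros(shape + (len(subjects),), dtype=np.float64)
        for si, subj in enumerate(subjects):
            img = np.zeros(shape)
            for k, region in label_names.items():
                v = values.get((subj, region, metric), np.nan)
                if np.isnan(v):
                    continue
                mask = labels == k
                vox = np.full(int(mask.sum()), float(v))
                if voxel_noise_sd > 0:
                    vox = vox + rng.normal(0.0, voxel_noise_sd, vox.size)
                img[mask] = vox
            vol4[..., si] = img
        maps[metric] = vol4
    return maps, labels, label_names, subjects
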