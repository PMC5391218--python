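"""Two-species synthetic methylation cohorts with planted ground truth.

The generator emulates the statistical structure of a dog/wolf RRBS study:
right-skewed age distributions (dogs 0.5-14 years, mean about 5; wolves
0.5-8 years, mean about 2.7), CpGs whose methylation drifts with age
(shared across species or species-specific), CpGs with a constant
between-species offset, negative-binomial read depth, and random
zero-coverage dropout. Latent per-entry frequencies are built on the
log-odds scale,

    p_ij = invlogit( logit(b_i) + s_i * rate_j * (age_j - age_ref)
                     + d_i * [species_j = dog] + eps_ij ),

so planted effects never push frequencies out of (0, 1); read counts are
binomial draws at the sampled depth. Every site's class, slope, offset and
baseline are recorded so downstream stages can be tested for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import CountRecord, SampleMeta, SiteKey, write_cgmap, write_metadata
from .matrix_builder import CountMatrix

__all__ = [
    "AgeSpec",
    "SimConfig",
    "SimTruth",
    "sample_cohort",
    "simulate_counts",
    "write_cohort",
]

SITE_CLASSES = ("null", "age_shared", "age_dog_only", "age_wolf_only", "species_offset")


@dataclass(frozen=True)
class AgeSpec:
    """Truncated-gamma age distribution (shape/scale in years)."""

    shape: float
    scale: float
    min_age: float
    max_age: float


# Defaults target the study cohort summaries: dogs mean ~5 / median ~4 on
# 0.5-14 years; wolves mean ~2.7 / median ~2 on 0.5-8 years.
DOG_AGES = AgeSpec(shape=2.0, scale=2.5, min_age=0.5, max_age=14.0)
WOLF_AGES = AgeSpec(shape=2.0, scale=1.35, min_age=0.5, max_age=8.0)


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_dog: int = 46
    n_wolf: int = 62
    n_sites: int = 5000
    frac_age_sites: float = 0.04
    frac_shared_age_sites: float = 0.5  # fraction of age sites shared by species
    frac_species_offset_sites: float = 0.02
    # per-year |log-odds| age effect; calibrated so surviving planted sites
    # span the per-CpG |corr(age, meth)| range of the published model tables
    slope_range: tuple[float, float] = (0.02, 0.12)
    offset_size: float = 0.2  # species shift on the frequency scale
    depth_mean: float = 30.0
    depth_dispersion: float = 5.0  # negative-binomial size; larger = less dispersed
    missing_rate: float = 0.03
    noise_sd: float = 0.15  # latent logit-scale noise
    age_ref: float = 4.0  # years; centers planted age effects
    weight_effect: float = 0.0  # aging-rate coupling to standardized breed weight
    dog_age_spec: AgeSpec = DOG_AGES
    wolf_age_spec: AgeSpec = WOLF_AGES
    fixed_depth: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.frac_age_sites <= 1 or not 0 <= self.frac_species_offset_sites <= 1:
            raise ValueError("site-class fractions must be in [0, 1]")
        if self.frac_age_sites + self.frac_species_offset_sites > 1:
            raise ValueError("site-class fractions must jointly be <= 1")
        if not 0 <= self.frac_shared_age_sites <= 1:
            raise ValueError("frac_shared_age_sites must be in [0, 1]")
        if self.depth_mean < 1:
            raise ValueError("depth_mean must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class SimTruth:
    """Planted parameters: per-site classes/effects and per-sample covariates."""

    sites: pd.DataFrame  # columns: chrom, pos, cls, slope, offset, baseline
    samples: pd.DataFrame  # columns: sample_id, species, age, weight, rate
    latent: np.ndarray = field(repr=False, default=None)  # sites x samples p_ij

    def site_classes(self) -> np.ndarray:
        return self.sites["cls"].to_numpy()


def _truncated_gamma(rng: np.random.Generator, spec: AgeSpec, n: int) -> np.ndarray:
    """Rejection-sample a gamma truncated to [min_age, max_age]."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.gamma(spec.shape, spec.scale, size=max(2 * (n - filled), 16))
        ok = draw[(draw >= spec.min_age) & (draw <= spec.max_age)]
        take = min(ok.size, n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def sample_cohort(cfg: SimConfig) -> list[SampleMeta]:
    """Draw a two-species cohort with ages, sexes and dog breed weights.

    Dog breed maximum weights are log-uniform between 3 and 70 kg, spanning
    toy to giant breeds.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    meta: list[SampleMeta] = []
    dog_ages = _truncated_gamma(rng, cfg.dog_age_spec, cfg.n_dog)
    wolf_ages = _truncated_gamma(rng, cfg.wolf_age_spec, cfg.n_wolf)
    dog_weights = np.exp(rng.uniform(np.log(3.0), np.log(70.0), size=cfg.n_dog))
    for i in range(cfg.n_dog):
        meta.append(
            SampleMeta(
                sample_id=f"dog{i + 1:03d}",
                species="dog",
                age_years=round(float(dog_ages[i]), 3),
                sex="F" if rng.random() < 0.5 else "M",
                breed_max_weight=round(float(dog_weights[i]), 1),
            )
        )
    for i in range(cfg.n_wolf):
        meta.append(
            SampleMeta(
                sample_id=f"wolf{i + 1:03d}",
                species="wolf",
                age_years=round(float(wolf_ages[i]), 3),
                sex="F" if rng.random() < 0.5 else "M",
            )
        )
    return meta


def _logit(p):
    return np.log(p / (1 - p))


def _invlogit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _plant_sites(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_sites
    n_age = int(round(cfg.frac_age_sites * n))
    n_shared = int(round(cfg.frac_shared_age_sites * n_age))
    n_dog_only = (n_age - n_shared) // 2
    n_wolf_only = n_age - n_shared - n_dog_only
    n_off = int(round(cfg.frac_species_offset_sites * n))
    cls = np.array(
        ["age_shared"] * n_shared
        + ["age_dog_only"] * n_dog_only
        + ["age_wolf_only"] * n_wolf_only
        + ["species_offset"] * n_off
        + ["null"] * (n - n_age - n_off)
    )
    rng.shuffle(cls)

    baseline = rng.uniform(0.15, 0.85, size=n)
    # keep the frequency-scale species offset achievable without saturation
    off_rows = cls == "species_offset"
    baseline[off_rows] = rng.uniform(
        0.05 + cfg.offset_size, 0.95 - cfg.offset_size, size=off_rows.sum()
    )

    lo, hi = cfg.slope_range
    slope = rng.uniform(lo, hi, size=n) * rng.choice([-1.0, 1.0], size=n)
    slope[(cls == "null") | (cls == "species_offset")] = 0.0

    sign = rng.choice([-1.0, 1.0], size=n)
    offset = np.zeros(n)
    shifted = np.clip(baseline + sign * cfg.offset_size, 1e-3, 1 - 1e-3)
    offset[off_rows] = (_logit(shifted) - _logit(baseline))[off_rows]

    # site coordinates: spread over autosomes, sorted, unique
    chroms = np.array([f"chr{c}" for c in rng.integers(1, 39, size=n)])
    pos = rng.integers(10_000, 60_000_000, size=n)
    df = pd.DataFrame(
        {"chrom": chroms, "pos": pos, "cls": cls, "slope": slope,
         "offset": offset, "baseline": baseline}
    )
    df = df.drop_duplicates(["chrom", "pos"]).sort_values(["chrom", "pos"])
    while len(df) < n:  # top up the rare collision
        extra = n - len(df)
        more = df.iloc[:extra].copy()
        more["pos"] = more["pos"] + 1
        df = (
            pd.concat([df, more])
            .drop_duplicates(["chrom", "pos"])
            .sort_values(["chrom", "pos"])
        )
    return df.reset_index(drop=True)


def simulate_counts(
    meta: list[SampleMeta], cfg: SimConfig, assembly: str = "canFam3"
) -> tuple[CountMatrix, SimTruth]:
    """Simulate the cohort count matrix and its ground truth."""
    rng = np.random.default_rng([cfg.seed, 2])
    sites_df = _plant_sites(cfg, rng)
    n_sites, n_samples = len(sites_df), len(meta)

    ages = np.array([m.age_years for m in meta])
    is_dog = np.array([m.species == "dog" for m in meta])
    weights = np.array(
        [m.breed_max_weight if m.breed_max_weight is not None else np.nan for m in meta]
    )
    rate = np.ones(n_samples)
    if cfg.weight_effect != 0.0 and np.isfinite(weights).sum() >= 2:
        w = weights[np.isfinite(weights)]
        z = (weights - w.mean()) / (w.std() if w.std() > 0 else 1.0)
        rate = np.where(np.isfinite(weights), 1.0 + cfg.weight_effect * z, 1.0)
        rate = np.maximum(rate, 0.1)

    slope = sites_df["slope"].to_numpy()[:, None]
    offset = sites_df["offset"].to_numpy()[:, None]
    cls = sites_df["cls"].to_numpy()
    base_logit = _logit(sites_df["baseline"].to_numpy())[:, None]

    # per-class applicability of the age slope
    slope_applies = np.ones((n_sites, n_samples))
    slope_applies[cls == "age_dog_only"] = is_dog.astype(float)
    slope_applies[cls == "age_wolf_only"] = (~is_dog).astype(float)

    age_term = slope * slope_applies * (rate * (ages - cfg.age_ref))[None, :]
    species_term = offset * is_dog[None, :].astype(float)
    eps = rng.normal(0.0, cfg.noise_sd, size=(n_sites, n_samples))
    latent = _invlogit(base_logit + age_term + species_term + eps)

    if cfg.fixed_depth:
        T = np.full((n_sites, n_samples), int(round(cfg.depth_mean)), dtype=np.int64)
    else:
        size = cfg.depth_dispersion
        p_nb = size / (size + cfg.depth_mean)
        T = rng.negative_binomial(size, p_nb, size=(n_sites, n_samples)).astype(np.int64)
    if cfg.missing_rate > 0:
        T[rng.random((n_sites, n_samples)) < cfg.missing_rate] = 0
    K = rng.binomial(T, latent)

    sites = [
        SiteKey(assembly, str(c), int(p))
        for c, p in zip(sites_df["chrom"], sites_df["pos"])
    ]
    counts = CountMatrix(
        sites=sites, samples=[m.sample_id for m in meta], K=K, T=T
    )
    truth = SimTruth(
        sites=sites_df,
        samples=pd.DataFrame(
            {
                "sample_id": [m.sample_id for m in meta],
                "species": [m.species for m in meta],
                "age": ages,
                "weight": weights,
                "rate": rate,
            }
        ),
        latent=latent,
    )
    return counts, truth


def write_cohort(
    meta: list[SampleMeta],
    counts: CountMatrix,
    truth: SimTruth,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the cohort as CGmap files (one per sample, zero-coverage rows
    omitted), a metadata table and truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for j, sid in enumerate(counts.samples):
        recs = [
            CountRecord(counts.sites[i], int(counts.K[i, j]), int(counts.T[i, j]))
            for i in range(len(counts.sites))
            if counts.T[i, j] > 0
        ]
        p = outdir / f"{sid}.cgmap"
        write_cgmap(recs, p)
        paths[sid] = p
    write_metadata(meta, outdir / "metadata.tsv")
    truth.sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    truth.samples.to_csv(outdir / "truth_samples.tsv", sep="\t", index=False)
    paths["metadata"] = outdir / "metadata.tsv"
    return paths
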