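"""Cross-species conservation of age-correlated methylation.

For each CpG the Pearson correlation r of methylation with chronological age
is converted to the Student-t statistic for testing r = 0,

    z = sqrt(m - 2) * r / sqrt(1 - r^2),

so that tracks computed on cohorts of different sizes are comparable.
Tracks from two species are paired through a syntenic-coordinate map and the
Pearson correlation of the paired z values measures how strongly
age-associated methylation is conserved. Significant sites (BH-adjusted
q <= 0.05) are split by the sign of r into gain- and loss-of-methylation
foregrounds for external annotation tooling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import SiteKey, SyntenyMap
from .matrix_builder import FrequencyMatrix

__all__ = [
    "AgeCorrelationRecord",
    "ConservationReport",
    "z_normalize",
    "age_correlation_track",
    "pair_tracks",
    "conservation_score",
    "benjamini_hochberg",
    "select_foreground",
    "track_to_frame",
]


@dataclass(frozen=True)
class AgeCorrelationRecord:
    site: SiteKey
    r: float
    m: int
    z: float
    p: float
    q: float


@dataclass(frozen=True)
class ConservationReport:
    n_pairs: int
    r_z: float
    p: float
    zero_variance: bool = False


def z_normalize(r, m):
    """Sample-size-normalized correlation statistic sqrt(m-2) r / sqrt(1-r^2).

    Identical to the classical t statistic for testing a Pearson correlation
    against zero with m - 2 degrees of freedom. |r| = 1 maps to +/- inf.
    """
    r = np.asarray(r, dtype=float)
    m = np.asarray(m, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.sqrt(m - 2) * r / np.sqrt(1 - r * r)
    z = np.where(r == 0, 0.0, z)
    return z if z.ndim else float(z)


def _pearson_rows(F: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r of F against y, NaN-aware; returns (r, m)."""
    valid = ~np.isnan(F)
    m = valid.sum(axis=1)
    r = np.zeros(F.shape[0])
    # fast path: rows with no missing values
    full = valid.all(axis=1)
    if full.any():
        X = F[full]
        xc = X - X.mean(axis=1, keepdims=True)
        yc = y - y.mean()
        denom = np.sqrt((xc * xc).sum(axis=1) * (yc * yc).sum())
        num = xc @ yc
        with np.errstate(invalid="ignore", divide="ignore"):
            rr = np.where(denom > 0, num / denom, 0.0)
        r[full] = rr
    for i in np.flatnonzero(~full):
        v = valid[i]
        if v.sum() < 3:
            r[i] = 0.0
            continue
        x = F[i, v]
        yy = y[v]
        if np.std(x) == 0 or np.std(yy) == 0:
            r[i] = 0.0
        else:
            r[i] = float(np.corrcoef(x, yy)[0, 1])
    return np.clip(r, -1.0, 1.0), m


def age_correlation_track(
    freq: FrequencyMatrix, ages: Sequence[float]
) -> list[AgeCorrelationRecord]:
    """Per-site correlation of methylation with chronological age.

    m counts the samples with a defined frequency at the site; p is
    two-sided from the t distribution with m - 2 df; q is the BH-adjusted p
    across all sites in the track. Zero-variance sites get r = 0, z = 0,
    p = 1.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.shape[0] != len(freq.samples):
        raise ValueError("ages must align with freq samples")
    if ages.shape[0] < 3:
        raise ValueError("need at least three samples for a correlation track")
    r, m = _pearson_rows(freq.F, ages)
    z = z_normalize(r, np.maximum(m, 3))
    with np.errstate(invalid="ignore"):
        p = 2 * stats.t.sf(np.abs(z), df=np.maximum(m - 2, 1))
    p = np.where(np.isfinite(z), p, 0.0)
    p = np.where(r == 0, 1.0, p)
    q = benjamini_hochberg(p)
    return [
        AgeCorrelationRecord(site=s, r=float(r[i]), m=int(m[i]), z=float(z[i]),
                             p=float(p[i]), q=float(q[i]))
        for i, s in enumerate(freq.sites)
    ]


def pair_tracks(
    track_a: Sequence[AgeCorrelationRecord],
    track_b: Sequence[AgeCorrelationRecord],
    smap: SyntenyMap,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Pair two z tracks through a synteny map.

    Returns (z_a, z_b, n_unmatched) with one entry per map pair found in
    both tracks. Track assemblies must match the two sides of the map.
    """
    if not smap.pairs:
        return np.array([]), np.array([]), 0
    by_a = {rec.site: rec for rec in track_a}
    by_b = {rec.site: rec for rec in track_b}
    asm_a = {rec.site.assembly for rec in track_a}
    asm_b = {rec.site.assembly for rec in track_b}
    if asm_a and {smap.assembly_a} != asm_a:
        raise ValueError(
            f"track A assembly {sorted(asm_a)} does not match map side A "
            f"({smap.assembly_a})"
        )
    if asm_b and {smap.assembly_b} != asm_b:
        raise ValueError(
            f"track B assembly {sorted(asm_b)} does not match map side B "
            f"({smap.assembly_b})"
        )
    za, zb, miss = [], [], 0
    for sa, sb in smap.pairs:
        ra, rb = by_a.get(sa), by_b.get(sb)
        if ra is None or rb is None:
            miss += 1
            continue
        za.append(ra.z)
        zb.append(rb.z)
    return np.asarray(za), np.asarray(zb), miss


def conservation_score(z_a: np.ndarray, z_b: np.ndarray) -> ConservationReport:
    """Pearson correlation between two paired z tracks, with its p-value."""
    z_a = np.asarray(z_a, dtype=float)
    z_b = np.asarray(z_b, dtype=float)
    if z_a.shape != z_b.shape:
        raise ValueError("paired z tracks must have equal length")
    n = z_a.shape[0]
    if n < 3:
        raise ValueError("need at least three pairs for a conservation score")
    finite = np.isfinite(z_a) & np.isfinite(z_b)
    z_a, z_b = z_a[finite], z_b[finite]
    if np.std(z_a) == 0 or np.std(z_b) == 0:
        return ConservationReport(n_pairs=int(finite.sum()), r_z=0.0, p=1.0,
                                  zero_variance=True)
    res = stats.pearsonr(z_a, z_b)
    return ConservationReport(
        n_pairs=int(finite.sum()), r_z=float(res.statistic), p=float(res.pvalue)
    )


def benjamini_hochberg(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_foreground(
    track: Sequence[AgeCorrelationRecord], q_max: float = 0.05
) -> tuple[list[SiteKey], list[SiteKey], list[SiteKey]]:
    """Split significant age-correlated sites into gain/loss foregrounds.

    gain: q <= q_max and r > 0 (methylation increases with age);
    loss: q <= q_max and r < 0; background: all sites in the track.
    """
    gain = [rec.site for rec in track if rec.q <= q_max and rec.r > 0]
    loss = [rec.site for rec in track if rec.q <= q_max and rec.r < 0]
    background = [rec.site for rec in track]
    return gain, loss, background


def track_to_frame(track: Sequence[AgeCorrelationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "assembly": [t.site.assembly for t in track],
            "chrom": [t.site.chrom for t in track],
            "pos": [t.site.pos for t in track],
            "r": [t.r for t in track],
            "m": [t.m for t in track],
            "z": [t.z for t in track],
            "p": [t.p for t in track],
            "q": [t.q for t in track],
        }
    )
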