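"""Culling of CpGs with species-divergent methylation.

A joint dog+wolf clock must not pick up CpGs whose methylation separates the
species rather than tracking age. Because the dog cohort skews older than the
wolf cohort, the species comparison is run on an age-matched subset: all
wolves, plus dogs no older than the oldest wolf. Sites whose two-sample t
statistic reaches the threshold are excluded from all downstream modelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io_formats import SampleMeta, SiteKey
from .matrix_builder import FrequencyMatrix

__all__ = [
    "DivergenceResult",
    "age_matched_subset",
    "species_t_statistics",
    "cull_divergent_sites",
]


@dataclass(frozen=True)
class DivergenceResult:
    site: SiteKey
    t_stat: float
    n_dog: int
    n_wolf: int
    excluded: bool


def age_matched_subset(meta: Sequence[SampleMeta]) -> list[str]:
    """Sample ids for the species comparison: all wolves, dogs <= max wolf age."""
    wolf_ages = [m.age_years for m in meta if m.species == "wolf"]
    if not wolf_ages:
        raise ValueError("age matching requires at least one wolf sample")
    max_wolf = max(wolf_ages)
    return [
        m.sample_id
        for m in meta
        if m.species == "wolf" or (m.species == "dog" and m.age_years <= max_wolf)
    ]


def species_t_statistics(
    freq: FrequencyMatrix,
    labels: Sequence[str],
    variant: Literal["welch", "pooled"] = "welch",
) -> list[DivergenceResult]:
    """Per-site two-sample t statistic of dog versus wolf methylation.

    ``labels`` gives the species per column of ``freq`` (the age-matched
    subset). Entries that are NaN are ignored per site. A site with fewer
    than two defined values in either group is skipped with a warning; both
    groups constant and equal gives t = 0, constant but different gives an
    infinite t (always excluded).
    """
    labels = np.asarray(labels)
    if labels.shape[0] != len(freq.samples):
        raise ValueError("labels must align with freq samples")
    dog_cols = labels == "dog"
    wolf_cols = labels == "wolf"
    if dog_cols.sum() < 2 or wolf_cols.sum() < 2:
        raise ValueError("need at least two samples of each species")

    results: list[DivergenceResult] = []
    skipped = 0
    Fd, Fw = freq.F[:, dog_cols], freq.F[:, wolf_cols]
    nd = np.sum(~np.isnan(Fd), axis=1)
    nw = np.sum(~np.isnan(Fw), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        md = np.nanmean(Fd, axis=1)
        mw = np.nanmean(Fw, axis=1)
        vd = np.nanvar(Fd, axis=1, ddof=1)
        vw = np.nanvar(Fw, axis=1, ddof=1)
    for i, site in enumerate(freq.sites):
        if nd[i] < 2 or nw[i] < 2:
            skipped += 1
            continue
        diff = md[i] - mw[i]
        if variant == "welch":
            se2 = vd[i] / nd[i] + vw[i] / nw[i]
        else:
            sp2 = ((nd[i] - 1) * vd[i] + (nw[i] - 1) * vw[i]) / (nd[i] + nw[i] - 2)
            se2 = sp2 * (1 / nd[i] + 1 / nw[i])
        if se2 == 0:
            t = 0.0 if diff == 0 else float(np.sign(diff)) * np.inf
        else:
            t = float(diff / np.sqrt(se2))
        results.append(
            DivergenceResult(site=site, t_stat=t, n_dog=int(nd[i]), n_wolf=int(nw[i]), excluded=False)
        )
    if skipped:
        warnings.warn(
            f"skipped {skipped} site(s) with <2 defined values in a species group"
        )
    return results


def cull_divergent_sites(
    freq: FrequencyMatrix,
    results: Sequence[DivergenceResult],
    threshold: float = 2.0,
    mode: Literal["absolute", "signed"] = "absolute",
) -> tuple[FrequencyMatrix, list[DivergenceResult]]:
    """Drop sites whose t statistic reaches the threshold (t >= 2 by default).

    The default excludes on |t| >= threshold, since divergence in either
    direction confounds a joint clock; ``signed`` reproduces the literal
    one-sided reading. Returns the culled matrix and the per-site results
    with the ``excluded`` flag populated; sites without a defined t (skipped
    in the statistics step) are retained.
    """
    by_site = {}
    flagged: list[DivergenceResult] = []
    for res in results:
        stat = abs(res.t_stat) if mode == "absolute" else res.t_stat
        excluded = bool(stat >= threshold)
        flagged.append(DivergenceResult(res.site, res.t_stat, res.n_dog, res.n_wolf, excluded))
        by_site[res.site] = excluded
    keep = np.array([not by_site.get(s, False) for s in freq.sites])
    return freq.subset_sites(np.flatnonzero(keep)), flagged


def divergence_report(results: Sequence[DivergenceResult]) -> pd.DataFrame:
    """Tabular report of the species comparison (one row per tested site)."""
    return pd.DataFrame(
        {
            "assembly": [r.site.assembly for r in results],
            "chrom": [r.site.chrom for r in results],
            "pos": [r.site.pos for r in results],
            "t_stat": [r.t_stat for r in results],
            "n_dog": [r.n_dog for r in results],
            "n_wolf": [r.n_wolf for r in results],
            "excluded": [r.excluded for r in results],
        }
    )
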