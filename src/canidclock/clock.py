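"""Epigenetic age clocks: training, cross-validation, transfer, application.

A clock is a sparse elastic-net regression of ln(age in years) on CpG
methylation fractions. Training pre-selects CpGs by absolute Pearson
correlation with (log) age, fits the penalized model with the mixing
parameter fixed at 0.5 and the penalty strength chosen by internal k-fold
cross-validation, and reports predictions on the age scale by
exponentiation. Accuracy is assessed by leave-one-out cross-validation in
which pre-selection and penalty choice are redone within every fold, so the
held-out sample never influences its own model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from .io_formats import ClockEntry, ClockModel, SampleMeta
from .matrix_builder import FrequencyMatrix

__all__ = [
    "ClockTrainingConfig",
    "PredictionRecord",
    "LoocvSummary",
    "preselect_sites",
    "fit_clock",
    "predict_age",
    "loocv_evaluate",
    "cross_species_transfer",
    "age_acceleration",
    "weight_correlation",
]


@dataclass(frozen=True)
class ClockTrainingConfig:
    """Settings for clock training.

    alpha is the elastic-net mixing parameter (1 = lasso, 0 = ridge); 0.5
    balances the two penalties and is what produced the published models.
    preselect_abs_corr is the |Pearson r| threshold of the univariate
    pre-selection step. corr_transform picks whether pre-selection
    correlates methylation against ln(age) (consistent with the regression
    target) or raw age.
    """

    alpha: float = 0.5
    preselect_abs_corr: float = 0.3
    cv_folds: int = 10
    penalty_rule: Literal["min_cv_error", "one_se"] = "min_cv_error"
    corr_transform: Literal["log", "raw"] = "log"
    n_penalties: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        if not 0 <= self.preselect_abs_corr < 1:
            raise ValueError("preselect_abs_corr must be in [0, 1)")
        if self.cv_folds < 3:
            raise ValueError("cv_folds must be >= 3")


class PredictionRecord(NamedTuple):
    """One sample's chronological age, DNAm age, and their difference."""

    sample_id: str
    chrono_age: float
    dnam_age: float
    age_acceleration: float


@dataclass
class LoocvSummary:
    r: float
    median_abs_error: float
    mean_n_cpgs: float
    n_folds: int
    n_failed: int = 0
    failed_samples: list[str] = field(default_factory=list)
    fold_models: list[ClockModel] | None = None


def _row_correlations(F: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each matrix row against y; 0 for zero-variance rows."""
    xc = F - F.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum(axis=1) * (yc * yc).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, xc @ yc / np.where(denom > 0, denom, 1.0), 0.0)
    return r


def preselect_sites(
    freq: FrequencyMatrix,
    ages: Sequence[float],
    threshold: float = 0.3,
    transform: Literal["log", "raw"] = "log",
) -> np.ndarray:
    """Row indices of sites with |Pearson r(methylation, age)| above threshold.

    Zero-variance sites have r = 0 by convention and are never selected.
    The correlation target defaults to ln(age) for consistency with the
    log-age regression; raw age is available as an option.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.shape[0] != len(freq.samples):
        raise ValueError("ages must align with freq samples")
    if ages.shape[0] < 3:
        raise ValueError("need at least three samples for pre-selection")
    if not freq.complete:
        raise ValueError("pre-selection requires a complete (imputed) matrix")
    y = np.log(ages) if transform == "log" else ages
    r = _row_correlations(freq.F, y)
    return np.flatnonzero(np.abs(r) > threshold)


def _choose_one_se_alpha(enet: ElasticNetCV) -> float:
    """Largest penalty whose CV error is within one SE of the minimum."""
    mse = enet.mse_path_  # (n_alphas, n_folds)
    mean = mse.mean(axis=1)
    se = mse.std(axis=1, ddof=1) / np.sqrt(mse.shape[1])
    best = int(np.argmin(mean))
    limit = mean[best] + se[best]
    ok = np.flatnonzero(mean <= limit)
    # alphas_ are sorted descending: the smallest index is the strongest penalty
    return float(enet.alphas_[ok.min()])


def fit_clock(
    freq: FrequencyMatrix,
    ages: Sequence[float],
    cfg: ClockTrainingConfig | None = None,
    name: str = "clock",
) -> ClockModel:
    """Fit an elastic-net clock of ln(age) on the given methylation matrix.

    Sites are expected to be pre-selected/culled already. Predictors are
    standardized internally; the returned coefficients are on the raw
    frequency scale. Per-entry training diagnostics (mean methylation and
    Pearson correlation with chronological age) mirror the published model
    tables. Sites whose coefficient is shrunk to zero are omitted.
    """
    cfg = cfg or ClockTrainingConfig()
    ages = np.asarray(ages, dtype=float)
    if np.any(ages <= 0):
        raise ValueError("ages must be positive for the log transform")
    n = ages.shape[0]
    if n != len(freq.samples):
        raise ValueError("ages must align with freq samples")
    if n < cfg.cv_folds:
        raise ValueError(
            f"cannot run {cfg.cv_folds}-fold internal CV with only {n} samples"
        )
    if not freq.complete:
        raise ValueError("clock fitting requires a complete (imputed) matrix")

    y = np.log(ages)
    X = freq.F.T  # samples x sites
    assembly = freq.sites[0].assembly if freq.sites else "canFam3"
    if X.shape[1] == 0:
        warnings.warn("no predictor sites; returning intercept-only clock")
        return ClockModel(name=name, assembly=assembly, intercept=float(y.mean()))

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / sd_safe

    cv = KFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        enet = ElasticNetCV(
            l1_ratio=cfg.alpha,
            alphas=cfg.n_penalties,
            cv=cv,
            max_iter=5000,
            random_state=cfg.seed,
        )
        enet.fit(Xs, y)
        if cfg.penalty_rule == "one_se":
            penalty = _choose_one_se_alpha(enet)
            final = ElasticNet(alpha=penalty, l1_ratio=cfg.alpha, max_iter=5000)
            final.fit(Xs, y)
            coef_std, icpt_std = final.coef_, float(final.intercept_)
        else:
            coef_std, icpt_std = enet.coef_, float(enet.intercept_)

    coef = coef_std / sd_safe
    intercept = icpt_std - float(np.sum(coef * mu))
    nz = np.flatnonzero(coef)
    if nz.size == 0:
        warnings.warn("elastic net shrank all coefficients to zero; "
                      "returning intercept-only clock")
    age_corr = _row_correlations(freq.F, ages)
    entries = [
        ClockEntry(
            site=freq.sites[j],
            coef=float(coef[j]),
            train_mean_meth=float(np.clip(mu[j], 0.0, 1.0)),
            train_age_corr=float(np.clip(age_corr[j], -1.0, 1.0)),
        )
        for j in nz
    ]
    return ClockModel(name=name, assembly=assembly, intercept=intercept,
                      entries=entries)


def predict_age(
    model: ClockModel,
    freq: FrequencyMatrix,
    ages: Sequence[float] | None = None,
    missing_sites: Literal["error", "train_mean"] = "error",
) -> list[PredictionRecord]:
    """Apply a clock: dnam_age = exp(intercept + sum(coef * frequency)).

    Extra non-model sites in ``freq`` are ignored and site order is
    irrelevant. Model sites absent from ``freq`` raise an error by default;
    with ``missing_sites="train_mean"`` the model's stored training mean
    methylation is substituted (available for the packaged models). If
    chronological ages are supplied, age acceleration (dnam - chrono) is
    filled in; otherwise it is NaN.
    """
    index = {s: i for i, s in enumerate(freq.sites)}
    absent = [e.site for e in model.entries if e.site not in index]
    if absent and missing_sites == "error":
        raise KeyError(
            f"{len(absent)} model site(s) absent from the matrix, e.g. "
            f"{[str(s) for s in absent[:5]]}"
        )
    n = len(freq.samples)
    lin = np.full(n, model.intercept, dtype=float)
    for e in model.entries:
        i = index.get(e.site)
        if i is None:
            if e.train_mean_meth is None:
                raise KeyError(
                    f"model site {e.site} absent and has no stored training mean"
                )
            lin += e.coef * e.train_mean_meth
        else:
            vals = freq.F[i]
            if np.any(np.isnan(vals)):
                raise ValueError(f"NaN frequency at model site {e.site}")
            lin += e.coef * vals
    dnam = np.exp(lin)
    if ages is None:
        chrono = np.full(n, np.nan)
    else:
        chrono = np.asarray(ages, dtype=float)
    return [
        PredictionRecord(
            sample_id=freq.samples[j],
            chrono_age=float(chrono[j]),
            dnam_age=float(dnam[j]),
            age_acceleration=float(dnam[j] - chrono[j]),
        )
        for j in range(n)
    ]


def age_acceleration(predictions: Sequence[PredictionRecord]) -> np.ndarray:
    """DNAm age minus chronological age, per sample."""
    return np.array([p.age_acceleration for p in predictions])


def loocv_evaluate(
    freq: FrequencyMatrix,
    ages: Sequence[float],
    cfg: ClockTrainingConfig | None = None,
    keep_fold_models: bool = False,
) -> tuple[list[PredictionRecord], LoocvSummary]:
    """Leave-one-out accuracy of the clock-building procedure.

    For every sample, CpG pre-selection and the penalized fit are redone on
    the other n - 1 samples and the held-out sample's age is predicted from
    that fold model. The summary reports Pearson r between predicted and
    chronological age, the median absolute error in years, and the mean
    number of CpGs across fold models. Folds whose fit fails are excluded
    from the summary with a warning.
    """
    cfg = cfg or ClockTrainingConfig()
    ages = np.asarray(ages, dtype=float)
    n = len(freq.samples)
    if n < 10:
        raise ValueError("leave-one-out evaluation needs at least 10 samples")
    predictions: list[PredictionRecord] = []
    sizes: list[int] = []
    failed: list[str] = []
    models: list[ClockModel] = []
    all_cols = np.arange(n)
    for i in range(n):
        rest = np.delete(all_cols, i)
        train = freq.subset_samples(rest)
        try:
            sel = preselect_sites(
                train, ages[rest], cfg.preselect_abs_corr, cfg.corr_transform
            )
            model = fit_clock(train.subset_sites(sel), ages[rest], cfg)
            pred = predict_age(model, freq.subset_samples([i]), ages=[ages[i]])
        except (ValueError, KeyError) as exc:
            warnings.warn(f"LOOCV fold for sample {freq.samples[i]} failed: {exc}")
            failed.append(freq.samples[i])
            continue
        predictions.extend(pred)
        sizes.append(model.n_cpgs)
        if keep_fold_models:
            models.append(model)
    if len(predictions) < 3:
        raise ValueError("too few successful LOOCV folds to summarize")
    dnam = np.array([p.dnam_age for p in predictions])
    chrono = np.array([p.chrono_age for p in predictions])
    r = float(np.corrcoef(dnam, chrono)[0, 1]) if np.std(dnam) > 0 else 0.0
    summary = LoocvSummary(
        r=r,
        median_abs_error=float(np.median(np.abs(dnam - chrono))),
        mean_n_cpgs=float(np.mean(sizes)),
        n_folds=len(predictions),
        n_failed=len(failed),
        failed_samples=failed,
        fold_models=models if keep_fold_models else None,
    )
    return predictions, summary


@dataclass
class TransferResult:
    model: ClockModel
    predictions: list[PredictionRecord]
    transfer_r: float
    n_cpgs: int


def cross_species_transfer(
    freq: FrequencyMatrix,
    meta: Sequence[SampleMeta],
    cfg: ClockTrainingConfig | None = None,
) -> dict[str, TransferResult]:
    """Train on one species, predict the other, in both directions.

    Returns {"dog_to_wolf": ..., "wolf_to_dog": ...}; each result carries
    the single-species model, the other species' predictions, and the
    transfer correlation.
    """
    cfg = cfg or ClockTrainingConfig()
    by_id = {m.sample_id: m for m in meta}
    species = np.array([by_id[s].species for s in freq.samples])
    ages = np.array([by_id[s].age_years for s in freq.samples])
    out: dict[str, TransferResult] = {}
    for train_sp, test_sp in (("dog", "wolf"), ("wolf", "dog")):
        tr = np.flatnonzero(species == train_sp)
        te = np.flatnonzero(species == test_sp)
        if tr.size < 10 or te.size < 10:
            raise ValueError(
                f"cross-species transfer needs >= 10 samples per species; "
                f"got {tr.size} {train_sp}, {te.size} {test_sp}"
            )
        train = freq.subset_samples(tr)
        sel = preselect_sites(train, ages[tr], cfg.preselect_abs_corr,
                              cfg.corr_transform)
        model = fit_clock(train.subset_sites(sel), ages[tr], cfg,
                          name=f"{train_sp}_only")
        preds = predict_age(model, freq.subset_samples(te), ages=ages[te])
        dnam = np.array([p.dnam_age for p in preds])
        chrono = np.array([p.chrono_age for p in preds])
        r = float(np.corrcoef(dnam, chrono)[0, 1]) if np.std(dnam) > 0 else 0.0
        out[f"{train_sp}_to_{test_sp}"] = TransferResult(
            model=model, predictions=preds, transfer_r=r, n_cpgs=model.n_cpgs
        )
    return out


class WeightCorrResult(NamedTuple):
    r: float
    n: int
    zero_variance: bool


def weight_correlation(
    predictions: Sequence[PredictionRecord], meta: Sequence[SampleMeta]
) -> WeightCorrResult:
    """Pearson r between age acceleration and breed maximum weight over dogs.

    Only dog samples with a recorded breed weight enter. Zero variance on
    either axis yields r = 0 with the zero_variance flag set.
    """
    by_id = {m.sample_id: m for m in meta}
    accel, weight = [], []
    for p in predictions:
        m = by_id.get(p.sample_id)
        if m is None or m.species != "dog" or m.breed_max_weight is None:
            continue
        accel.append(p.age_acceleration)
        weight.append(m.breed_max_weight)
    if len(accel) < 3:
        raise ValueError("need at least three dogs with breed weights")
    accel_a, weight_a = np.asarray(accel), np.asarray(weight)
    if np.std(accel_a) == 0 or np.std(weight_a) == 0:
        return WeightCorrResult(r=0.0, n=len(accel), zero_variance=True)
    r = float(np.corrcoef(accel_a, weight_a)[0, 1])
    return WeightCorrResult(r=r, n=len(accel), zero_variance=False)
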