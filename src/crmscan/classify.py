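"""Bootstrap-LASSO (bolasso) classification of enhancers from motif-hit densities.

The model is deliberately simple: each enhancer is represented by the
density (hits per kb) of every motif in a panel, densities are standardized
to zero mean and unit variance over the whole dataset, and an L1-penalized
least-squares regression against +/-1 class targets is fit on bootstrap
resamples. A motif's bootstrap selection frequency — the fraction of
resample fits in which its coefficient is non-zero — is its confidence. The
final classifier keeps the motifs above a confidence threshold chosen by
greedy descent from 95% in 5% steps while leave-one-out AUC improves, refit
by ordinary (unpenalized) least squares. Positive coefficients mean
above-average motif density predicts the positive class.

Density features are used, rather than counts, because enhancer sequences
have different lengths; hit-density features are built with an order-2
Markov background trained on the pooled input sequences and a natural-log
log-odds threshold of 4.6 by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .motifs import (
    ConsensusMotif,
    MarkovBackground,
    Motif,
    PWM,
    hit_density,
    scan_motif,
    train_markov,
)
from .seqio import SequenceRecord

logger = logging.getLogger(__name__)


@dataclass
class EnhancerSet:
    """Labeled enhancer sequences; labels are +1 (positive class) or -1."""

    records: list[tuple[SequenceRecord, int]]
    provenance: str = ""

    def __post_init__(self) -> None:
        labels = {lab for _, lab in self.records}
        if not labels <= {+1, -1}:
            raise ValueError("labels must be +1 or -1")
        if labels != {+1, -1}:
            raise ValueError("both classes must be present")

    @property
    def sequences(self) -> list[SequenceRecord]:
        return [rec for rec, _ in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.array([lab for _, lab in self.records])


@dataclass
class FeatureMatrix:
    """Enhancers x motifs hit-density matrix (per kb), optionally standardized."""

    values: pd.DataFrame
    standardized: bool = False
    col_means: Optional[pd.Series] = None
    col_sds: Optional[pd.Series] = None

    @property
    def motif_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def enhancer_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class LassoFit:
    coefficients: np.ndarray
    intercept: float
    alpha: float

    @property
    def selected(self) -> np.ndarray:
        return self.coefficients != 0


@dataclass
class BolassoResult:
    n_bootstrap: int
    selection_freq: dict[str, float]
    seed: int
    lambda_rule: str = "5-fold CV MSE minimum, capped at max_features non-zero coefficients"
    redraws: int = 0


@dataclass
class FinalClassifier:
    motifs: list[str]
    coefficients: dict[str, float]
    intercept: float
    confidence_threshold: float
    loocv_auc: float


def build_features(
    enhancers: EnhancerSet,
    pwms: Sequence[PWM] = (),
    consensi: Sequence[ConsensusMotif] = (),
    bg: Optional[MarkovBackground] = None,
    bg_order: int = 2,
    threshold: float = 4.6,
    strands: str = "both",
) -> FeatureMatrix:
    """Hit-density matrix: cell (enhancer, motif) = hits per kb.

    The background for PWM log-odds defaults to an order-`bg_order` chain
    trained on the pooled (unmasked) enhancer sequences themselves, making
    the feature build self-contained; pass `bg` to use an external sample.
    """
    motifs: list[Motif] = list(pwms) + list(consensi)
    ids = [m.id for m in motifs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate motif ids in the panel")
    if not motifs:
        raise ValueError("empty motif panel")
    if bg is None and pwms:
        bg = train_markov(enhancers.sequences, bg_order)
    rows = {}
    for rec, _ in enhancers.records:
        rows[rec.id] = [
            hit_density(scan_motif(rec, m, bg=bg, threshold=threshold, strands=strands), len(rec))
            for m in motifs
        ]
    values = pd.DataFrame.from_dict(rows, orient="index", columns=ids)
    return FeatureMatrix(values)


def standardize(fm: FeatureMatrix) -> FeatureMatrix:
    """Column z-scores (population SD) over the whole dataset.

    Zero-variance columns carry no information and are dropped with a
    warning. Column means/SDs are retained so new enhancers can be scored on
    the training scale.
    """
    if fm.standardized:
        raise ValueError("feature matrix is already standardized")
    means = fm.values.mean(axis=0)
    sds = fm.values.std(axis=0, ddof=0)
    keep = sds > 0
    if not keep.any():
        raise ValueError("all feature columns are constant")
    dropped = list(fm.values.columns[~keep])
    if dropped:
        logger.warning("dropping %d constant feature column(s): %s", len(dropped), dropped)
    z = (fm.values.loc[:, keep] - means[keep]) / sds[keep]
    return FeatureMatrix(z, standardized=True, col_means=means[keep], col_sds=sds[keep])


def unstandardize(fm: FeatureMatrix) -> FeatureMatrix:
    if not fm.standardized:
        raise ValueError("feature matrix is not standardized")
    return FeatureMatrix(fm.values * fm.col_sds + fm.col_means)


def _cv_splits(y: np.ndarray, n_splits: int, seed: int):
    """Stratified folds; the fold count shrinks if a class is too small."""
    counts = np.bincount((y > 0).astype(int), minlength=2)
    n_splits = max(2, min(n_splits, counts.min()))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def fit_lasso_once(
    X: np.ndarray,
    y: np.ndarray,
    max_features: int = 50,
    seed: int = 0,
    n_alphas: int = 50,
    cv: int = 5,
    cv_repeats: int = 5,
) -> LassoFit:
    """One LASSO fit: lambda by inner stratified CV (squared error), then
    increased along the path until at most `max_features` coefficients are
    non-zero.

    The CV error curve is averaged over `cv_repeats` independent fold
    splits; with a single split on a few dozen rows the curve is noisy
    enough that its minimum often lands at a spuriously small penalty. The
    objective is L1-penalized least squares against the +/-1 targets; the
    intercept is unpenalized (fit by centering). The path includes the
    smallest penalty giving the empty (intercept-only) model, so nothing is
    selected when no feature reduces the CV error.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if max_features <= 0:
        return LassoFit(np.zeros(X.shape[1]), float(y.mean()), float("inf"))
    alphas, _, _ = lasso_path(X - X.mean(0), y - y.mean(), alphas=n_alphas, eps=1e-3)
    mse = np.zeros(len(alphas))
    for rep in range(cv_repeats):
        for train, test in _cv_splits(y, cv, seed + rep):
            Xtr, ytr = X[train], y[train]
            xm, ym = Xtr.mean(0), ytr.mean()
            _, coefs, _ = lasso_path(Xtr - xm, ytr - ym, alphas=alphas)
            pred = (X[test] - xm) @ coefs + ym  # n_test x n_alphas
            mse += ((pred - y[test][:, None]) ** 2).sum(axis=0)
    best = int(np.argmin(mse))
    xm, ym = X.mean(0), y.mean()
    _, coefs_full, _ = lasso_path(X - xm, y - ym, alphas=alphas)
    # alphas are in decreasing order: move back toward larger penalties
    # until the sparsity cap holds
    idx = best
    while idx > 0 and (coefs_full[:, idx] != 0).sum() > max_features:
        idx -= 1
    coef = coefs_full[:, idx].copy()
    intercept = float(ym - xm @ coef)
    return LassoFit(coef, intercept, float(alphas[idx]))


def bolasso(
    fm: FeatureMatrix,
    labels: np.ndarray,
    n_bootstrap: int = 1000,
    seed: int = 0,
    max_features: int = 50,
    per_resample_cv: bool = False,
) -> BolassoResult:
    """Bootstrap selection frequencies: fraction of resample LASSO fits in
    which each motif's coefficient is non-zero.

    The regularization parameter is picked once, by cross-validation on the
    full dataset (capped so at most `max_features` coefficients are
    non-zero), and every bootstrap fit uses it — the original bolasso
    formulation, which keeps the selection frequencies a measure of support
    stability at a fixed penalty. Set `per_resample_cv` to re-tune the
    penalty inside every resample instead (noisier: bootstrap duplicates
    leak across the inner CV folds and bias the penalty low).

    Resamples are drawn with replacement at full size, unstratified;
    single-class resamples are redrawn (and counted in `redraws`).
    """
    if not fm.standardized:
        raise ValueError("bolasso expects a standardized feature matrix")
    X = fm.values.to_numpy()
    y = np.asarray(labels, dtype=float)
    n = len(y)
    rng = np.random.default_rng(seed)
    base_fit = fit_lasso_once(X, y, max_features=max_features,
                              seed=int(rng.integers(0, 2**31 - 1)))
    selected = np.zeros(X.shape[1])
    redraws = 0
    for _ in range(n_bootstrap):
        while True:
            idx = rng.integers(0, n, n)
            if len(np.unique(y[idx])) > 1:
                break
            redraws += 1
        if per_resample_cv:
            fit = fit_lasso_once(X[idx], y[idx], max_features=max_features,
                                 seed=int(rng.integers(0, 2**31 - 1)))
        else:
            fit = _lasso_at_alpha(X[idx], y[idx], base_fit.alpha)
        selected += fit.selected
    if redraws:
        logger.info("redrew %d single-class bootstrap resample(s)", redraws)
    freq = {m: float(s) / n_bootstrap for m, s in zip(fm.motif_ids, selected)}
    rule = ("per-resample 5-fold CV MSE minimum" if per_resample_cv
            else "5-fold CV MSE minimum on the full dataset, shared across resamples")
    return BolassoResult(n_bootstrap, freq, seed,
                         lambda_rule=rule + f", capped at {max_features} features",
                         redraws=redraws)


def _lasso_at_alpha(X: np.ndarray, y: np.ndarray, alpha: float) -> LassoFit:
    if not np.isfinite(alpha):
        return LassoFit(np.zeros(X.shape[1]), float(y.mean()), alpha)
    xm, ym = X.mean(0), y.mean()
    _, coefs, _ = lasso_path(X - xm, y - ym, alphas=[alpha])
    coef = coefs[:, 0].copy()
    return LassoFit(coef, float(ym - xm @ coef), alpha)


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    A = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return beta[1:], float(beta[0])


def loocv_auc(fm: FeatureMatrix, labels: np.ndarray, feature_subset: Sequence[str]) -> float:
    """Leave-one-out AUC of an unpenalized least-squares fit on a motif subset.

    Each enhancer's decision value comes from a model refit without it; the
    AUC over held-out values uses the Mann-Whitney formulation (ties count
    half). Pooled leave-one-out decision values are centered by the training
    fold's mean fitted value (its label mean): without this, the intercept
    of every fold shifts opposite to the held-out label and the null AUC is
    pessimistically biased well below 0.5.
    """
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2 or min((y > 0).sum(), (y < 0).sum()) < 2:
        raise ValueError("need at least two enhancers per class")
    missing = [m for m in feature_subset if m not in fm.values.columns]
    if missing:
        raise ValueError(f"unknown features {missing}")
    X = fm.values[list(feature_subset)].to_numpy()
    n = len(y)
    decisions = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        coef, intercept = _ols(X[keep], y[keep])
        decisions[i] = intercept + X[i] @ coef - y[keep].mean()
    return float(roc_auc_score(y > 0, decisions))


def select_final(
    bolasso_result: BolassoResult,
    fm: FeatureMatrix,
    labels: np.ndarray,
    start_threshold: float = 0.95,
    step: float = 0.05,
    auc_fn: Optional[Callable[[FeatureMatrix, np.ndarray, Sequence[str]], float]] = None,
) -> Optional[FinalClassifier]:
    """Pick the confidence threshold by greedy descent from `start_threshold`.

    At each threshold the motifs at or above it are refit by ordinary least
    squares and scored by LOOCV AUC; the descent continues while the AUC
    improves and stops at the first non-improvement. Thresholds that do not
    change the feature set are skipped (their AUC is identical by
    construction). Returns None when no motif is selected at any threshold.
    """
    auc_fn = auc_fn or loocv_auc
    y = np.asarray(labels, dtype=float)
    freq = bolasso_result.selection_freq
    best: Optional[tuple[float, list[str], float]] = None  # (auc, feats, threshold)
    threshold = start_threshold
    prev_feats: Optional[list[str]] = None
    while threshold > 1e-9:
        feats = sorted([m for m, f in freq.items() if f >= threshold - 1e-12])
        if feats and feats != prev_feats:
            auc = auc_fn(fm, y, feats)
            if best is None or auc > best[0]:
                best = (auc, feats, threshold)
            else:
                break
            prev_feats = feats
        threshold = round(threshold - step, 10)
    if best is None:
        return None
    auc, feats, thr = best
    coef, intercept = _ols(fm.values[feats].to_numpy(), y)
    return FinalClassifier(
        motifs=feats,
        coefficients={m: float(c) for m, c in zip(feats, coef)},
        intercept=intercept,
        confidence_threshold=thr,
        loocv_auc=auc,
    )


def score_enhancer(clf: FinalClassifier, fm_row: "pd.Series | dict[str, float]") -> float:
    """Decision value: intercept + sum of coefficient x standardized density."""
    score = clf.intercept
    for motif, coef in clf.coefficients.items():
        if motif not in fm_row:
            raise ValueError(f"feature {motif!r} missing from the row")
        score += coef * float(fm_row[motif])
    return score
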