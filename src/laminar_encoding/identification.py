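"""Rank-based sound identification scoring and model comparison.

A trained encoding model is scored by its ability to identify held-out
sounds: the predicted response pattern of test sound k is correlated with
the measured patterns of all test sounds, and the rank r_k of the correct
sound's correlation (1 = highest) is converted to the score

    P_k = 1 - (r_k - 1) / (S_test - 1),

so 1 is perfect identification, 0 consistently wrong, and 0.5 chance.
Scores are averaged over all test sounds (and per sound category), and
two models are compared by a paired t-test after Fisher transformation
z = atanh(2 P - 1), which maps chance to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

FISHER_EPS = 1e-6

__all__ = [
    "IdentificationResult",
    "ComparisonReport",
    "rank_sound",
    "score_from_rank",
    "identification_scores",
    "fisher_transform",
    "compare_models",
]


@dataclass
class IdentificationResult:
    """Per-sound ranks/scores plus overall and per-category means."""

    sound_ids: np.ndarray
    ranks: np.ndarray
    scores: np.ndarray
    fold_of_sound: np.ndarray
    s_test: dict  # fold -> number of test sounds
    overall: float
    per_category: dict
    model_tag: str = ""


@dataclass
class ComparisonReport:
    """Paired test between two models' Fisher-transformed scores."""

    statistic: float
    dof: int
    p_value: float
    p_corrected: float
    sided: str
    correction: int
    mean_difference_z: float


def _cross_correlation(pred: np.ndarray, meas: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix C[k, j] = r(pred row k, meas row j).

    Rows are patterns across voxels; zero-variance rows raise with the
    offending row indices named.
    """
    pc = pred - pred.mean(axis=1, keepdims=True)
    mc = meas - meas.mean(axis=1, keepdims=True)
    p_sd = np.sqrt((pc**2).sum(axis=1))
    m_sd = np.sqrt((mc**2).sum(axis=1))
    for name, sd_ in (("predicted", p_sd), ("measured", m_sd)):
        if np.any(sd_ == 0):
            bad = np.flatnonzero(sd_ == 0).tolist()
            raise ValueError(
                f"{name} pattern(s) {bad} have zero variance across voxels"
            )
    return (pc @ mc.T) / np.outer(p_sd, m_sd)


def _corr_with_rows(pred: np.ndarray, measured: np.ndarray) -> np.ndarray:
    """Pearson r of ``pred`` (V,) with every row of ``measured`` (S, V)."""
    pc = pred - pred.mean()
    mc = measured - measured.mean(axis=1, keepdims=True)
    p_sd = np.sqrt((pc**2).sum())
    m_sd = np.sqrt((mc**2).sum(axis=1))
    if p_sd == 0:
        raise ValueError("predicted pattern has zero variance across voxels")
    if np.any(m_sd == 0):
        bad = np.flatnonzero(m_sd == 0)
        raise ValueError(
            f"measured pattern(s) {bad.tolist()} have zero variance across voxels"
        )
    return (mc @ pc) / (m_sd * p_sd)


def rank_sound(
    predicted_k: np.ndarray, measured_all: np.ndarray, match_index: int
) -> float:
    """Rank of the matching sound's prediction-measurement correlation.

    The predicted voxel pattern is correlated with each measured
    test-sound pattern; the returned value is the rank (1 = highest,
    average rank for ties) of the correlation with the true sound
    ``match_index`` among all test sounds.
    """
    predicted_k = np.asarray(predicted_k, dtype=float)
    measured_all = np.asarray(measured_all, dtype=float)
    if measured_all.ndim != 2 or measured_all.shape[0] < 2:
        raise ValueError("need at least 2 test sounds")
    if measured_all.shape[1] != predicted_k.size or predicted_k.size < 2:
        raise ValueError("need matching voxel dimensions and >= 2 voxels")
    if not (np.all(np.isfinite(predicted_k)) and np.all(np.isfinite(measured_all))):
        raise ValueError("non-finite values in prediction or measurement")
    r = _corr_with_rows(predicted_k, measured_all)
    return float(stats.rankdata(-r, method="average")[match_index])


def score_from_rank(rank: float, s_test: int) -> float:
    """Identification score P = 1 - (rank - 1) / (S_test - 1)."""
    if s_test < 2:
        raise ValueError("S_test must be >= 2")
    if not 1 <= rank <= s_test:
        raise ValueError(f"rank {rank} outside [1, {s_test}]")
    return 1.0 - (rank - 1.0) / (s_test - 1.0)


def _voxel_zscore(mat: np.ndarray) -> np.ndarray:
    """Z-score each voxel's values across the test sounds.

    Voxels with zero variance across sounds carry no identity
    information and are mapped to zero deviation.
    """
    mu = mat.mean(axis=0, keepdims=True)
    sd = mat.std(axis=0, keepdims=True)
    return np.divide(mat - mu, sd, out=np.zeros_like(mat), where=sd > 0)


def identification_scores(
    predicted_by_fold: dict,
    measured_by_fold: dict,
    test_ids_by_fold: dict,
    category_of_sound: dict | None = None,
    model_tag: str = "",
    normalize: str = "zscore",
    expected_sound_ids: np.ndarray | None = None,
) -> IdentificationResult:
    """Identification scores across cross-validation folds.

    ``predicted_by_fold``/``measured_by_fold`` map fold id to
    (S_test x V) matrices with rows following ``test_ids_by_fold``;
    ranks are computed within each fold's test set, then pooled (each
    sound is a test sound in exactly one fold).

    With ``normalize="zscore"`` (the default) each voxel's predicted and
    measured values are z-scored across the fold's test sounds before
    the pattern correlations, so ranks reflect the sound-specific
    response structure rather than between-voxel offset/gain differences
    and are invariant to per-voxel affine rescaling; ``"none"``
    correlates the raw patterns.
    """
    if normalize not in ("zscore", "none"):
        raise ValueError(f"unknown normalization {normalize!r}")
    folds = sorted(predicted_by_fold)
    seen: list[int] = []
    sound_ids, ranks, fold_of = [], [], []
    s_test = {}
    for f in folds:
        pred = np.asarray(predicted_by_fold[f], dtype=float)
        meas = np.asarray(measured_by_fold[f], dtype=float)
        ids = np.asarray(test_ids_by_fold[f])
        if pred.shape != meas.shape or pred.shape[0] != len(ids):
            raise ValueError(f"fold {f}: inconsistent prediction/measurement shapes")
        if normalize == "zscore":
            pred = _voxel_zscore(pred)
            meas = _voxel_zscore(meas)
        s_test[f] = pred.shape[0]
        corr = _cross_correlation(pred, meas)
        fold_ranks = stats.rankdata(-corr, method="average", axis=1)
        ranks.extend(np.diagonal(fold_ranks).tolist())
        sound_ids.extend(int(i) for i in ids)
        fold_of.extend([f] * pred.shape[0])
        seen.extend(ids.tolist())
    if len(set(seen)) != len(seen):
        raise ValueError("a sound appears in more than one fold's test set")
    if expected_sound_ids is not None:
        missing = sorted(set(int(s) for s in expected_sound_ids) - set(seen))
        if missing:
            raise ValueError(f"sound(s) missing from all test sets: {missing[:5]}")

    sound_ids = np.asarray(sound_ids)
    ranks = np.asarray(ranks)
    fold_of = np.asarray(fold_of)
    scores = np.array(
        [score_from_rank(r, s_test[f]) for r, f in zip(ranks, fold_of)]
    )
    per_category: dict = {}
    if category_of_sound is not None:
        missing = [int(s) for s in sound_ids if s not in category_of_sound]
        if missing:
            raise ValueError(f"sounds missing a category label: {missing[:5]}")
        cats = np.array([category_of_sound[int(s)] for s in sound_ids])
        per_category = {
            str(c): float(scores[cats == c].mean()) for c in np.unique(cats)
        }
    order = np.argsort(sound_ids)
    return IdentificationResult(
        sound_ids=sound_ids[order],
        ranks=ranks[order],
        scores=scores[order],
        fold_of_sound=fold_of[order],
        s_test=s_test,
        overall=float(scores.mean()),
        per_category=per_category,
        model_tag=model_tag,
    )


def fisher_transform(
    scores: np.ndarray, convention: str = "centered", eps: float = FISHER_EPS
) -> np.ndarray:
    """Fisher (atanh) transform of identification scores.

    The default ``"centered"`` convention maps scores through
    atanh(2 P - 1), so chance (0.5) maps to 0; ``"plain"`` applies
    atanh(P) directly.  Values are clipped away from the poles by ``eps``.
    """
    p = np.asarray(scores, dtype=float)
    if convention == "centered":
        x = np.clip(2.0 * p - 1.0, -1.0 + eps, 1.0 - eps)
    elif convention == "plain":
        x = np.clip(p, -1.0 + eps, 1.0 - eps)
    else:
        raise ValueError(f"unknown Fisher convention {convention!r}")
    return np.arctanh(x)


def compare_models(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    sided: str = "two-sided",
    correction: int = 1,
    convention: str = "centered",
) -> ComparisonReport:
    """Paired t-test on Fisher-transformed identification scores.

    ``scores_a``/``scores_b`` are paired over analysis units (subjects or
    hemispheres).  ``sided`` is ``"two-sided"`` or ``"greater"`` (A > B);
    ``correction`` is a Bonferroni factor applied to the p-value.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 paired units")
    za = fisher_transform(a, convention)
    zb = fisher_transform(b, convention)
    alt = {"two-sided": "two-sided", "greater": "greater"}[sided]
    res = stats.ttest_rel(za, zb, alternative=alt)
    p = float(res.pvalue)
    if np.isnan(p):  # identical pairs: zero variance of differences
        t_stat, p = 0.0, 1.0
    else:
        t_stat = float(res.statistic)
    return ComparisonReport(
        statistic=t_stat,
        dof=a.size - 1,
        p_value=p,
        p_corrected=min(1.0, p * correction),
        sided=sided,
        correction=correction,
        mean_difference_z=float(np.mean(za - zb)),
    )
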