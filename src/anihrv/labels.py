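"""Multi-rater pain-score harmonization.

Several clinicians score each patient's pain (EAPS, 0-100, one value per
second) retrospectively.  Raters can carry systematic bias, so before the
scores become a regression target the cohort is checked with a one-way
ANOVA across raters (observations: per-patient mean score per rater),
deviating raters are excluded, and the remaining raters are averaged per
second into the consensus label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

__all__ = [
    "RaterScores",
    "AnovaResult",
    "LabelSeries",
    "rater_mean_matrix",
    "rater_anova",
    "select_raters",
    "consensus_label",
]


@dataclass(frozen=True)
class RaterScores:
    """Per-second scores from multiple raters on a shared 1-Hz grid.

    ``scores`` has shape (n_seconds, n_raters), all values in [0, 100].
    """

    time_s: np.ndarray
    scores: np.ndarray
    rater_ids: tuple

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 2 or s.shape[0] != t.size:
            raise ValueError("scores must be (n_seconds, n_raters) aligned with time_s")
        if s.shape[1] != len(self.rater_ids):
            raise ValueError("rater_ids length mismatch")
        if np.any(s < 0) or np.any(s > 100):
            raise ValueError("scores must lie in [0, 100]")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "rater_ids", tuple(self.rater_ids))

    @property
    def n_raters(self) -> int:
        return self.scores.shape[1]


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    group_means: tuple
    rater_ids: tuple
    excluded_raters: tuple = ()


@dataclass(frozen=True)
class LabelSeries:
    """Consensus per-second pain score (the regression target)."""

    time_s: np.ndarray
    eaps: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "time_s", np.asarray(self.time_s, dtype=float))
        object.__setattr__(self, "eaps", np.asarray(self.eaps, dtype=float))
        if self.time_s.shape != self.eaps.shape:
            raise ValueError("time/label length mismatch")

    def __len__(self) -> int:
        return int(self.eaps.size)


def rater_mean_matrix(cohort_scores: list[RaterScores]) -> tuple[np.ndarray, tuple]:
    """Stack per-patient mean score per rater into an (n_patients, n_raters) matrix."""
    if not cohort_scores:
        raise ValueError("empty cohort")
    ids = cohort_scores[0].rater_ids
    for s in cohort_scores:
        if s.rater_ids != ids:
            raise ValueError("raters differ across patients")
    return np.vstack([np.mean(s.scores, axis=0) for s in cohort_scores]), ids


def _as_matrix(obs, rater_ids=None) -> tuple[np.ndarray, tuple]:
    if isinstance(obs, list) and obs and isinstance(obs[0], RaterScores):
        return rater_mean_matrix(obs)
    m = np.asarray(obs, dtype=float)
    if m.ndim != 2:
        raise ValueError("observations must be (n_patients, n_raters)")
    ids = tuple(rater_ids) if rater_ids is not None else tuple(chr(ord("A") + k) for k in range(m.shape[1]))
    return m, ids


def rater_anova(obs, rater_ids=None) -> AnovaResult:
    """One-way ANOVA across raters.

    ``obs`` is either a list of per-patient :class:`RaterScores` (reduced to
    per-patient mean score per rater — per-second values are massively
    autocorrelated and would inflate significance) or an already-built
    (n_patients, n_raters) matrix.  Groups are raters; observations are
    patients.
    """
    m, ids = _as_matrix(obs, rater_ids)
    if m.shape[1] < 2:
        raise ValueError("ANOVA needs at least 2 raters")
    if m.shape[0] < 2:
        raise ValueError("ANOVA needs at least 2 patients")
    groups = [m[:, k] for k in range(m.shape[1])]
    if np.allclose(m, m[:, :1]):  # identical groups: F = 0, p = 1 (guard scipy's constant-input nan)
        f, p = 0.0, 1.0
    else:
        f, p = _stats.f_oneway(*groups)
    return AnovaResult(
        f_statistic=float(f), p_value=float(p),
        group_means=tuple(float(np.mean(g)) for g in groups), rater_ids=ids,
    )


def select_raters(obs, alpha: float = 0.05, rater_ids=None) -> tuple:
    """Iteratively exclude deviating raters; return the included rater ids.

    While the across-rater ANOVA is significant at ``alpha`` and more than
    two raters remain: take the rater whose group mean is farthest from the
    mean of the others, and exclude it if its Tukey-HSD pairwise comparisons
    are significant against the majority of the other raters.  Deterministic
    given the score matrix.
    """
    m, ids = _as_matrix(obs, rater_ids)
    included = list(range(m.shape[1]))
    while len(included) > 2:
        sub = m[:, included]
        res = rater_anova(sub, [ids[k] for k in included])
        if res.p_value >= alpha:
            break
        means = np.asarray(res.group_means)
        grand_others = np.array([np.mean(np.delete(means, j)) for j in range(means.size)])
        cand = int(np.argmax(np.abs(means - grand_others)))
        tukey = _stats.tukey_hsd(*[sub[:, j] for j in range(sub.shape[1])])
        sig_vs_cand = [tukey.pvalue[cand, j] < alpha for j in range(sub.shape[1]) if j != cand]
        if sum(sig_vs_cand) > len(sig_vs_cand) / 2:
            included.pop(cand)
        else:
            break
    return tuple(ids[k] for k in included)


def consensus_label(scores: RaterScores, included: tuple | list) -> LabelSeries:
    """Per-second arithmetic mean over the included raters."""
    if len(included) == 0:
        raise ValueError("at least one rater must be included")
    idx = [scores.rater_ids.index(r) for r in included]
    return LabelSeries(time_s=scores.time_s.copy(), eaps=np.mean(scores.scores[:, idx], axis=1))
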