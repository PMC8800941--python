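"""ReliefF feature relevance and the RadSig signature.

Standard multi-class ReliefF with a full deterministic pass over instances:
for each instance, the k nearest same-class hits and the k nearest misses
per other class (prior-weighted, Kononenko's extension) pull a feature's
weight down/up by the normalized value differences. Features are min–max
scaled to [0, 1] and distances are Manhattan. Weights lie in [-1, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RELEVANCE_TAU = 0.05


@dataclass
class RelieffConfig:
    k_neighbors: int = 10
    n_sample: int | None = None  # None = deterministic full pass
    relevance_threshold: float = RELEVANCE_TAU
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not np.isfinite(self.relevance_threshold):
            raise ValueError("relevance threshold must be finite")


def _minmax(x: np.ndarray) -> np.ndarray:
    lo = x.min(axis=0)
    rng = x.max(axis=0) - lo
    rng[rng == 0] = 1.0
    return (x - lo) / rng


def relieff_rank(
    table: pd.DataFrame, labels: pd.Series, config: RelieffConfig | None = None
) -> pd.Series:
    """ReliefF weight per feature (higher = more class-discriminative)."""
    if config is None:
        config = RelieffConfig()
    x = _minmax(table.to_numpy(dtype=float))
    y = np.asarray(labels.loc[_subject_index(table)])
    n, n_feat = x.shape
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    priors = {c: cnt / n for c, cnt in zip(classes, counts)}

    if config.n_sample is None or config.n_sample >= n:
        sample_idx = np.arange(n)
    else:
        rng = np.random.default_rng(config.seed)
        sample_idx = rng.choice(n, size=config.n_sample, replace=False)

    # pairwise Manhattan distances on the scaled features
    dist = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    np.fill_diagonal(dist, np.inf)

    w = np.zeros(n_feat)
    m = len(sample_idx)
    for i in sample_idx:
        same = np.flatnonzero((y == y[i]))
        same = same[same != i]
        k_hit = min(config.k_neighbors, same.size)
        if k_hit < config.k_neighbors:
            warnings.warn(
                f"class {y[i]!r} has too few members; using k={k_hit} hits"
            )
        if k_hit > 0:
            hits = same[np.argsort(dist[i, same], kind="stable")[:k_hit]]
            w -= np.abs(x[hits] - x[i]).sum(axis=0) / (m * k_hit)
        prior_i = priors[y[i]]
        for c in classes:
            if c == y[i]:
                continue
            other = np.flatnonzero(y == c)
            k_miss = min(config.k_neighbors, other.size)
            if k_miss == 0:
                continue
            misses = other[np.argsort(dist[i, other], kind="stable")[:k_miss]]
            weight_c = priors[c] / (1.0 - prior_i)
            w += weight_c * np.abs(x[misses] - x[i]).sum(axis=0) / (m * k_miss)
    return pd.Series(w, index=table.columns, name="relieff_weight")


def _subject_index(table: pd.DataFrame):
    if isinstance(table.index, pd.MultiIndex):
        return table.index.get_level_values("subject_id")
    return table.index


def rank_importance(
    weights: pd.Series, tau: float = RELEVANCE_TAU, top_n: int = 15
) -> list[str]:
    """Features with weight > tau, sorted by descending weight, truncated at
    ``top_n``. Ties keep the original column order (stable sort)."""
    passing = weights[weights > tau]
    if passing.empty:
        warnings.warn("no feature passes the relevance threshold")
        return []
    ranked = passing.sort_values(ascending=False, kind="stable")
    return list(ranked.index[:top_n])


@dataclass
class RadSig:
    """The radiomic signature: the top-ranked features for one task."""

    task: str  # prediction | assessment
    features: list[str]
    weights: pd.Series
    truncated: bool = False

    def __post_init__(self) -> None:
        w = self.weights.loc[self.features].to_numpy()
        if np.any(np.diff(w) > 1e-12):
            raise ValueError("RadSig weights must be nonincreasing")


def build_radsig(
    shortlist: list[str], weights: pd.Series, task: str = "prediction",
    size: int = 4,
) -> RadSig:
    """Top ``size`` shortlist features; a shorter shortlist is used whole
    and flagged."""
    truncated = len(shortlist) < size
    if truncated:
        warnings.warn(
            f"shortlist has only {len(shortlist)} features (< {size})"
        )
    return RadSig(task, shortlist[:size], weights, truncated)


def select_radsig(
    table: pd.DataFrame,
    labels: pd.Series,
    task: str = "prediction",
    config: RelieffConfig | None = None,
    tau: float = RELEVANCE_TAU,
    top_n: int = 15,
    size: int = 4,
) -> RadSig:
    """ReliefF ranking -> relevance shortlist -> RadSig, in one call."""
    weights = relieff_rank(table, labels, config)
    shortlist = rank_importance(weights, tau, top_n)
    return build_radsig(shortlist, weights, task, size)


def delta_table(bl: pd.DataFrame, ontx: pd.DataFrame) -> pd.DataFrame:
    """On-treatment minus baseline feature differences, paired by subject
    (the assessment-task predictors)."""
    b = bl.copy()
    t = ontx.copy()
    if isinstance(b.index, pd.MultiIndex):
        b.index = b.index.get_level_values("subject_id")
    if isinstance(t.index, pd.MultiIndex):
        t.index = t.index.get_level_values("subject_id")
    if set(b.index) != set(t.index):
        raise ValueError("baseline and on-treatment tables are not paired")
    return t.loc[b.index] - b
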