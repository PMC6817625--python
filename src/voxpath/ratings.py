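"""Aggregation and reliability of rater-by-target attractiveness matrices."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RatingMatrix",
    "cronbach_alpha",
    "aggregate_target_means",
    "cross_sample_agreement",
    "rating_blocks",
    "summarize_ratings",
]

SCALE_MIN, SCALE_MAX = 1, 7


@dataclass(frozen=True)
class RatingMatrix:
    """Complete raters x targets grid of integer attractiveness scores (1..7)."""

    rater_ids: tuple[str, ...]
    target_ids: tuple[str, ...]
    scores: np.ndarray  # shape (n_raters, n_targets)
    rater_country: tuple[str, ...] | None = None
    display: str | None = None

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores)
        if scores.ndim != 2:
            raise ValueError(f"scores must be 2-D, got shape {scores.shape}")
        if scores.shape != (len(self.rater_ids), len(self.target_ids)):
            raise ValueError(
                f"scores shape {scores.shape} does not match "
                f"{len(self.rater_ids)} raters x {len(self.target_ids)} targets"
            )
        if not np.all(np.isfinite(scores)):
            raise ValueError("scores contain missing or non-finite cells")
        if np.any(scores != np.round(scores)):
            raise ValueError("scores must be integers")
        if scores.min() < SCALE_MIN or scores.max() > SCALE_MAX:
            raise ValueError(
                f"scores outside the {SCALE_MIN}..{SCALE_MAX} scale: "
                f"min={scores.min()}, max={scores.max()}"
            )
        if self.rater_country is not None and len(self.rater_country) != len(self.rater_ids):
            raise ValueError("rater_country length does not match rater_ids")
        object.__setattr__(self, "scores", scores.astype(float))

    @property
    def n_raters(self) -> int:
        return len(self.rater_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)


def cronbach_alpha(matrix: RatingMatrix) -> float:
    """Cronbach's alpha with raters as items and targets as observations.

    alpha = k/(k-1) * (1 - sum var(rater_i) / var(sum over raters)),
    sample variances (n-1 denominator). Raises if the target-wise total has
    zero variance (alpha undefined) or with fewer than 2 raters/targets.
    """
    k = matrix.n_raters
    if k < 2 or matrix.n_targets < 2:
        raise ValueError("alpha needs >= 2 raters and >= 2 targets")
    item_vars = matrix.scores.var(axis=1, ddof=1)
    total_var = matrix.scores.sum(axis=0).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total score has zero variance; alpha undefined")
    return k / (k - 1.0) * (1.0 - item_vars.sum() / total_var)


def aggregate_target_means(matrix: RatingMatrix) -> pd.Series:
    """Arithmetic mean score per target across all raters."""
    return pd.Series(matrix.scores.mean(axis=0), index=list(matrix.target_ids), name="mean_rating")


def cross_sample_agreement(
    means_a: pd.Series, means_b: pd.Series, conf: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Pearson correlation between two per-target mean vectors on identical
    targets, with a Fisher-z confidence interval."""
    if list(means_a.index) != list(means_b.index):
        raise ValueError("target lists are not aligned")
    n = len(means_a)
    if n < 4:
        raise ValueError(f"need >= 4 aligned targets, got {n}")
    a = np.asarray(means_a, dtype=float)
    b = np.asarray(means_b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant mean vector; correlation undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    if abs(r) >= 1.0:
        return r, (r, r)
    z = math.atanh(r)
    half = sps.norm.ppf(0.5 + conf / 2.0) / math.sqrt(n - 3)
    return r, (math.tanh(z - half), math.tanh(z + half))


def rating_blocks(ratings: pd.DataFrame) -> list[tuple[str, RatingMatrix]]:
    """Split a long-format ratings table into complete rater x target blocks.

    A block is a (display, rater_country) stratum further split by the exact
    target set each rater saw, so every returned matrix is complete. Block
    labels look like ``"speech x BR"`` (with a numeric suffix when a stratum
    splits into several rater sets).
    """
    blocks: list[tuple[str, RatingMatrix]] = []
    for (display, country), grp in ratings.groupby(["display", "rater_country"], sort=True):
        sets = grp.groupby("rater_id")["target_id"].agg(frozenset)
        variants = sets.groupby(sets).groups  # target-set -> rater ids
        for j, (targets, raters) in enumerate(sorted(variants.items(), key=lambda kv: sorted(kv[0]))):
            sub = grp[grp["rater_id"].isin(raters)]
            wide = sub.pivot(index="rater_id", columns="target_id", values="score").sort_index()
            wide = wide[sorted(wide.columns)]
            if wide.isna().any().any():
                raise ValueError(
                    f"incomplete block {display} x {country}: missing cells detected"
                )
            label = f"{display} x {country}" + (f" #{j + 1}" if len(variants) > 1 else "")
            blocks.append(
                (
                    label,
                    RatingMatrix(
                        rater_ids=tuple(str(i) for i in wide.index),
                        target_ids=tuple(str(c) for c in wide.columns),
                        scores=wide.to_numpy(),
                        rater_country=tuple([str(country)] * len(wide.index)),
                        display=str(display),
                    ),
                )
            )
    return blocks


def summarize_ratings(ratings: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pooled per-target means and per-block reliabilities.

    Returns (attractiveness, reliability): the first has one row per
    target x display with the mean score across all raters pooled over
    countries; the second one row per complete block with Cronbach's alpha.
    """
    attract = (
        ratings.groupby(["target_id", "display"])["score"]
        .agg(mean_rating="mean", n_raters="count")
        .reset_index()
    )
    rows = []
    for label, matrix in rating_blocks(ratings):
        rows.append(
            {
                "block": label,
                "alpha": cronbach_alpha(matrix),
                "k_raters": matrix.n_raters,
                "n_targets": matrix.n_targets,
            }
        )
    return attract, pd.DataFrame(rows)
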