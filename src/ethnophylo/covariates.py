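"""Model covariates: farming propensity, husbandry midpoint, passthroughs.

Ethnographic-atlas subsistence variables come as coarse *percentage
intervals* (e.g. a society may show 76–85% dependence on gathering and 0–5%
on agriculture).  Farming propensity summarises the four subsistence modes
(gathering, hunting, fishing, agriculture) on a single axis: integer values
are sampled uniformly within each interval, a covariance PCA is run on the
sampled table, and the procedure is repeated many times (default 500); the
per-society farming propensity is the mean PC1 score across runs, with PC1
sign-aligned so the agriculture loading is positive.

Animal husbandry dependence, coded on the same interval scale, is
summarised by the interval midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PercentageInterval",
    "FarmingPropensityResult",
    "SUBSISTENCE_MODES",
    "sample_subsistence",
    "pca_pc1",
    "farming_propensity",
    "husbandry_midpoint",
]

#: Order of the four subsistence columns; agriculture last (the axis PC1 is
#: sign-aligned to).
SUBSISTENCE_MODES = ("gathering", "hunting", "fishing", "agriculture")
AGRICULTURE_INDEX = SUBSISTENCE_MODES.index("agriculture")


@dataclass(frozen=True)
class PercentageInterval:
    """Closed integer percentage interval, lower <= upper, both in [0, 100]."""

    lower: int
    upper: int

    def __post_init__(self):
        if not (0 <= self.lower <= self.upper <= 100):
            raise ValueError(f"invalid percentage interval {self.lower}-{self.upper}")

    @property
    def midpoint(self) -> float:
        return (self.lower + self.upper) / 2.0


@dataclass
class FarmingPropensityResult:
    """Per-society farming propensity and across-run PCA summaries."""

    scores: pd.Series
    score_sd: pd.Series        # across-run sd of the per-society PC1 score
    mean_agriculture_loading: float
    sd_agriculture_loading: float
    mean_variance_explained: float
    sd_variance_explained: float
    n_runs: int
    seed: int | None


def sample_subsistence(intervals, rng: np.random.Generator) -> np.ndarray:
    """Draw one integer uniformly (inclusive) from each percentage interval."""
    return np.array(
        [rng.integers(iv.lower, iv.upper + 1) for iv in intervals], dtype=float
    )


def pca_pc1(matrix: np.ndarray, *, align_index: int = AGRICULTURE_INDEX,
            clr_transform: bool = False):
    """First principal component of a covariance PCA.

    Returns ``(scores, loadings, variance_fraction)`` with unit-norm
    loadings sign-aligned so ``loadings[align_index] >= 0``.  Operates on
    the sample covariance of the raw (centred, unstandardised) columns; with
    ``clr_transform`` the rows are first closed to compositions and
    centred-log-ratio transformed (zeros replaced multiplicatively).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 5:
        raise ValueError("pca_pc1 requires a 2-D matrix with at least 5 rows")
    if np.isnan(X).any():
        raise ValueError("pca_pc1 does not accept missing cells")
    if clr_transform:
        from skbio.stats.composition import clr, multi_replace

        comp = X / X.sum(axis=1, keepdims=True)
        X = clr(multi_replace(comp))
    Xc = X - X.mean(axis=0)
    cov = (Xc.T @ Xc) / (X.shape[0] - 1)
    total = np.trace(cov)
    if total <= 0:
        raise ValueError("zero total variance: all columns constant")
    evals, evecs = np.linalg.eigh(cov)
    pc1 = evecs[:, -1]
    if pc1[align_index] < 0:
        pc1 = -pc1
    scores = Xc @ pc1
    return scores, pc1, float(evals[-1] / total)


def farming_propensity(
    intervals: pd.DataFrame,
    n_runs: int = 500,
    rng: np.random.Generator | int | None = None,
    *,
    clr_transform: bool = False,
) -> FarmingPropensityResult:
    """Mean PC1 score over repeated interval sampling + PCA.

    ``intervals`` must carry columns ``dep_<mode>_lo`` / ``dep_<mode>_hi``
    for the four subsistence modes.  Each run samples one integer per
    interval, runs :func:`pca_pc1`, and records the per-society PC1 score,
    the agriculture loading and the PC1 variance fraction; scores are
    averaged across runs.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)

    lows = np.column_stack(
        [intervals[f"dep_{m}_lo"].to_numpy(float) for m in SUBSISTENCE_MODES]
    )
    highs = np.column_stack(
        [intervals[f"dep_{m}_hi"].to_numpy(float) for m in SUBSISTENCE_MODES]
    )
    if np.isnan(lows).any() or np.isnan(highs).any():
        raise ValueError("all societies must have the four subsistence intervals")
    if (lows > highs).any() or (lows < 0).any() or (highs > 100).any():
        raise ValueError("invalid subsistence intervals")

    n = len(intervals)
    run_scores = np.empty((n_runs, n))
    loadings = np.empty(n_runs)
    varfracs = np.empty(n_runs)
    for r in range(n_runs):
        sampled = rng.integers(lows.astype(int), highs.astype(int) + 1).astype(float)
        scores, pc1, vf = pca_pc1(sampled, clr_transform=clr_transform)
        run_scores[r] = scores
        loadings[r] = pc1[AGRICULTURE_INDEX]
        varfracs[r] = vf

    mean = run_scores.mean(axis=0)
    sd = run_scores.std(axis=0, ddof=1) if n_runs > 1 else np.zeros(n)
    return FarmingPropensityResult(
        scores=pd.Series(mean, index=intervals.index, name="farming_propensity"),
        score_sd=pd.Series(sd, index=intervals.index, name="farming_propensity_sd"),
        mean_agriculture_loading=float(loadings.mean()),
        sd_agriculture_loading=float(loadings.std(ddof=1)) if n_runs > 1 else 0.0,
        mean_variance_explained=float(varfracs.mean()),
        sd_variance_explained=float(varfracs.std(ddof=1)) if n_runs > 1 else 0.0,
        n_runs=n_runs,
        seed=seed,
    )


def husbandry_midpoint(interval: PercentageInterval) -> float:
    """Midpoint of the animal-husbandry dependence interval."""
    return interval.midpoint
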