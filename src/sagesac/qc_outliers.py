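"""PCA-based within-day sample outlier screening.

Samples are projected onto the top principal components of the
gene-centered ln-normalized matrix; a sample is flagged when its distance
from its own day's centroid in PC space exceeds ``z_cut`` times the median
within-day distance pooled across days.  The deterministic distance rule
replaces visual inspection of score plots; days with a single sample are
never flagged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_Z_CUT = 3.0


@dataclass
class SampleScore:
    sample_id: str
    day: str
    coords: np.ndarray
    outlier: bool = False


def pca_scores(values: pd.DataFrame, metadata: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Sample scores on the top-``k`` principal components.

    ``values`` is genes x samples; each gene is centered across samples and
    samples are projected onto the leading right singular directions.
    Returns a samples x k DataFrame (columns PC1..PCk) with a ``day``
    column appended.
    """
    n_samples = values.shape[1]
    if n_samples < 3:
        raise ValueError("PCA outlier screening needs at least 3 samples")
    if k >= n_samples:
        raise ValueError(f"k={k} must be < number of samples ({n_samples})")
    X = values.to_numpy(dtype=float).T  # samples x genes
    X = X - X.mean(axis=0)
    # Deterministic SVD with a fixed sign convention (largest-|loading| positive).
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    signs = np.sign(Vt[np.arange(len(S)), np.argmax(np.abs(Vt), axis=1)])
    scores = (U * S) * signs
    out = pd.DataFrame(
        scores[:, :k], index=values.columns, columns=[f"PC{i+1}" for i in range(k)]
    )
    out["day"] = metadata.loc[out.index, "day"].to_numpy()
    return out


def flag_outliers(scores: pd.DataFrame, z_cut: float = DEFAULT_Z_CUT) -> pd.Series:
    """Boolean flag per sample.

    Flagging is iterative: a gross outlier drags its own day's centroid,
    which would make its innocent replicate siblings look distant too, so
    at each round only the single farthest sample exceeding
    z_cut x (median within-day distance) is flagged and distances are
    recomputed without it.  Iteration stops when no sample exceeds the
    cut, which also makes the rule idempotent: re-screening the retained
    samples flags nothing.
    """
    pc_cols = [c for c in scores.columns if c.startswith("PC")]
    coords = scores[pc_cols].to_numpy(dtype=float)
    days = scores["day"].to_numpy()
    flags = np.zeros(len(scores), dtype=bool)

    singleton_days = {
        d for d in pd.unique(days) if (days == d).sum() < 2
    }
    for d in singleton_days:
        warnings.warn(
            f"day {d!r} has a single sample; it cannot be screened",
            stacklevel=2,
        )

    while True:
        dist = np.full(len(scores), np.nan)
        eligible = np.zeros(len(scores), dtype=bool)
        for day in pd.unique(days):
            idx = np.flatnonzero((days == day) & ~flags)
            if len(idx) < 2:
                continue
            centroid = coords[idx].mean(axis=0)
            dist[idx] = np.linalg.norm(coords[idx] - centroid, axis=1)
            eligible[idx] = True
        if not eligible.any():
            break
        median_dist = np.median(dist[eligible])
        # floor the spread at numerical noise relative to the score scale,
        # so exactly-replicated samples are never flagged
        floor = 1e-9 * float(np.sqrt(np.mean(coords**2)) + 1.0)
        exceed = eligible & (dist > z_cut * max(median_dist, floor))
        if not exceed.any():
            break
        worst = np.nanargmax(np.where(exceed, dist, -np.inf))
        flags[worst] = True
        logger.info("flagged outlier sample %s", scores.index[worst])
    return pd.Series(flags, index=scores.index, name="outlier")


def screen_outliers(
    values: pd.DataFrame, metadata: pd.DataFrame, k: int = 2, z_cut: float = DEFAULT_Z_CUT
) -> tuple[pd.DataFrame, list[str]]:
    """Convenience wrapper: scores plus the list of flagged sample ids."""
    scores = pca_scores(values, metadata, k=k)
    flags = flag_outliers(scores, z_cut=z_cut)
    return scores.assign(outlier=flags), list(scores.index[flags])
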