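"""Upper-quartile library-size normalization, ln transform, low-count filter.

Each library is scaled by the 75th percentile of its counts over the genes
with a nonzero total across all libraries, a statistic robust to the few
extremely abundant transcripts (globins) that dominate SAGE libraries.
By default values are reported relative to a fixed reference scale
(``ref_scale``, default 100), i.e. a gene sitting exactly at a library's
upper quartile gets the value 100; this makes each sample's normalized
values strictly invariant to rescaling that sample's raw counts.  An
alternative anchor (``anchor="geomean"``) divides instead by
UQ_s / geometric-mean(UQ), which keeps values on the raw count scale but
is only invariant up to a global constant.  Either way the anchor cancels
in contrasts and standardized profiles.  Normalized counts are ln(x + 1)
transformed; genes whose mean normalized count across samples is below a
threshold (default 8) are excluded from model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tag_alignment import CountMatrix

DEFAULT_MIN_MEAN = 8.0


@dataclass
class NormalizedMatrix:
    """Upper-quartile-scaled expression: raw-scale ``norm_counts`` and
    ln(x+1) ``values``, with the per-sample ``scale_factors`` used."""

    norm_counts: pd.DataFrame
    values: pd.DataFrame
    scale_factors: pd.Series
    metadata: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


DEFAULT_REF_SCALE = 100.0


def upper_quartile_factors(
    counts: CountMatrix,
    ref_scale: float = DEFAULT_REF_SCALE,
    anchor: str = "fixed",
) -> pd.Series:
    """Per-sample scale factors; dividing raw counts by the factor
    equalizes upper quartiles across libraries.

    The 75th percentile is taken over the genes with nonzero total count
    across all samples (linear interpolation between order statistics).
    ``anchor="fixed"`` (default): factor_s = UQ_s / ref_scale, so each
    sample's normalized values depend on that sample alone.
    ``anchor="geomean"``: factor_s = UQ_s / geometric-mean(UQ), keeping
    values near the raw count scale.
    """
    mat = counts.counts
    if (mat.sum(axis=0) == 0).any():
        zero = [s for s in mat.columns if mat[s].sum() == 0]
        raise ValueError(f"all-zero sample(s): {zero}")
    nonzero = mat.index[mat.sum(axis=1) > 0]
    if len(nonzero) == 0:
        raise ValueError("no gene with nonzero total count")
    uq = np.percentile(mat.loc[nonzero].to_numpy(), 75, axis=0)
    if (uq <= 0).any():
        raise ValueError("upper quartile is zero for some sample")
    if anchor == "fixed":
        factors = uq / float(ref_scale)
    elif anchor == "geomean":
        factors = uq / np.exp(np.mean(np.log(uq)))
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    return pd.Series(factors, index=mat.columns, name="scale_factor")


def ln_transform(norm_counts: pd.DataFrame) -> pd.DataFrame:
    """ln(x + 1); the pseudocount handles sampling zeros."""
    if (norm_counts.to_numpy() < 0).any():
        raise ValueError("negative normalized counts")
    return np.log1p(norm_counts)


def normalize(
    counts: CountMatrix,
    ref_scale: float = DEFAULT_REF_SCALE,
    anchor: str = "fixed",
) -> NormalizedMatrix:
    factors = upper_quartile_factors(counts, ref_scale=ref_scale, anchor=anchor)
    norm_counts = counts.counts / factors
    return NormalizedMatrix(norm_counts, ln_transform(norm_counts), factors, counts.metadata)


def low_count_filter(
    norm_counts: pd.DataFrame, threshold: float = DEFAULT_MIN_MEAN
) -> pd.Index:
    """Genes retained for modeling: mean normalized count >= threshold."""
    return norm_counts.index[norm_counts.mean(axis=1) >= threshold]
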