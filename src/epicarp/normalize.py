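"""Cumulative-sum scaling (CSS) of amplicon count tables.

CSS replaces the total-sum scaling denominator with the cumulative sum of each
sample's counts up to a quantile of its *positive* counts, which stabilises
variance when a few dominant taxa would otherwise drive the library-size
estimate. This implementation uses a fixed quantile (default the median of
positive counts) with an explicit convention:

    q_j = the ceil(l * n+)-th smallest positive count of sample j
          (n+ = number of positive counts),
    s_j = sum of all counts of sample j that are <= q_j,
    value_ij = count_ij / s_j * scale_constant.

Zeros stay zero, so presence/absence patterns are unchanged, and scaling a
sample's counts uniformly rescales s_j and leaves normalised values intact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError


@dataclass(frozen=True)
class CssParams:
    """CSS settings: quantile of positive counts, output scale, optional log."""

    quantile_l: float = 0.5
    scale_constant: float = 1000.0
    log_transform: bool = False

    def validate(self) -> "CssParams":
        if not 0 < self.quantile_l < 1:
            raise ParameterError("quantile_l must lie in (0, 1)")
        if not self.scale_constant > 0:
            raise ParameterError("scale_constant must be positive")
        return self


def css_scaling_factor(sample_counts, params: CssParams | None = None) -> float:
    """The CSS denominator s for one sample's count vector.

    Raises :class:`ValidationError` for an all-zero sample (no library-size
    information).
    """
    params = (params or CssParams()).validate()
    counts = np.asarray(sample_counts, dtype=float)
    if counts.ndim != 1:
        raise ParameterError("sample_counts must be one-dimensional")
    if np.any(counts < 0):
        raise ValidationError("negative counts are not allowed")
    positive = np.sort(counts[counts > 0])
    if positive.size == 0:
        raise ValidationError("cannot compute a CSS factor for an all-zero sample")
    k = math.ceil(params.quantile_l * positive.size)
    q = positive[k - 1]
    return float(counts[counts <= q].sum())


def css_normalize(table: pd.DataFrame, params: CssParams | None = None) -> pd.DataFrame:
    """CSS-normalise a phylotype-by-sample count table column-wise.

    Returns a float frame with the same shape and labels; applies
    ``log(x + 1)`` afterwards when ``params.log_transform`` is set.
    """
    params = (params or CssParams()).validate()
    factors = np.array(
        [css_scaling_factor(table[c].to_numpy(), params) for c in table.columns]
    )
    out = table.astype(float) / factors * params.scale_constant
    if params.log_transform:
        out = np.log1p(out)
    return out
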