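"""Alpha diversity and Jaccard-family community dissimilarity.

Three alpha metrics summarise each sample: phylotype richness (the number of
taxa observed), Shannon entropy in nats, and the Gini-Simpson index
``1 - sum(p_i^2)``. Beta diversity uses the two Jaccard variants of the
analysis workflow: binary Jaccard on presence/absence, and the quantitative
(Ruzicka) Jaccard ``1 - sum(min)/sum(max)`` on abundances, which relates to
Bray-Curtis dissimilarity B as ``2B / (1 + B)``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .errors import ParameterError, ValidationError


def alpha_diversity(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample richness, Shannon (nats) and Gini-Simpson indices.

    Accepts raw counts or normalised abundances (phylotypes x samples);
    proportions are formed per sample. All-zero samples are rejected.
    """
    x = table.to_numpy(dtype=float)
    totals = x.sum(axis=0)
    if np.any(totals <= 0):
        sid = table.columns[np.argmax(totals <= 0)]
        raise ValidationError(f"sample {sid!r} has no positive abundance")
    p = x / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    return pd.DataFrame(
        {
            "richness": (x > 0).sum(axis=0),
            "shannon": -plogp.sum(axis=0),
            "simpson": 1.0 - (p**2).sum(axis=0),
        },
        index=pd.Index(table.columns, name="sample_id"),
    )


def jaccard_binary(x, y) -> float:
    """Binary Jaccard dissimilarity: 1 - |shared present| / |union present|."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_pair(x, y)
    xa, ya = x > 0, y > 0
    union = np.count_nonzero(xa | ya)
    if union == 0:
        warnings.warn("both vectors empty; binary Jaccard defined as 0")
        return 0.0
    return 1.0 - np.count_nonzero(xa & ya) / union


def jaccard_abundance(x, y) -> float:
    """Quantitative (Ruzicka) Jaccard: 1 - sum(min) / sum(max)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_pair(x, y)
    denom = np.maximum(x, y).sum()
    if denom == 0:
        warnings.warn("both vectors empty; abundance Jaccard defined as 0")
        return 0.0
    return 1.0 - np.minimum(x, y).sum() / denom


def _check_pair(x, y):
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("inputs must be equal-length one-dimensional vectors")
    if np.any(x < 0) or np.any(y < 0):
        raise ValidationError("abundance vectors must be non-negative")


METRICS = ("jaccard_binary", "jaccard_abundance")
_ALIASES = {
    "binary": "jaccard_binary",
    "abundance": "jaccard_abundance",
    "ruzicka": "jaccard_abundance",
}


def distance_matrix(table: pd.DataFrame, metric: str) -> DistanceMatrix:
    """Pairwise dissimilarity of the samples (columns) of a table.

    ``metric`` is ``"jaccard_binary"``/``"binary"`` or
    ``"jaccard_abundance"``/``"abundance"``/``"ruzicka"``.
    """
    name = _ALIASES.get(metric, metric)
    if name not in METRICS:
        raise ParameterError(f"unknown metric {metric!r}; choose from {METRICS}")
    if table.shape[1] < 2:
        raise ParameterError("need at least 2 samples for a distance matrix")
    x = table.to_numpy(dtype=float).T  # samples x taxa
    if np.any(x < 0):
        raise ValidationError("abundance table must be non-negative")
    n = x.shape[0]
    out = np.zeros((n, n))
    if name == "jaccard_binary":
        b = x > 0
        inter = b.astype(float) @ b.T
        present = b.sum(axis=1).astype(float)
        union = present[:, None] + present[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            out = 1.0 - np.where(union > 0, inter / np.maximum(union, 1e-300), 1.0)
    else:
        for i in range(n):
            mins = np.minimum(x[i], x[i + 1 :]).sum(axis=1)
            maxs = np.maximum(x[i], x[i + 1 :]).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                d = 1.0 - np.where(maxs > 0, mins / np.maximum(maxs, 1e-300), 1.0)
            out[i, i + 1 :] = d
            out[i + 1 :, i] = d
    np.fill_diagonal(out, 0.0)
    # clip tiny negatives from floating error
    out = np.clip((out + out.T) / 2.0, 0.0, 1.0)
    return DistanceMatrix(out, ids=[str(c) for c in table.columns])


def geographic_distance_matrix(metadata: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distance (km) between sample sites on planar coordinates.

    Sites span under 19 km, so planar Euclidean distance is an adequate
    stand-in for great-circle distance.
    """
    coords = metadata[["site_x_km", "site_y_km"]].to_numpy(dtype=float)
    d = squareform(pdist(coords, metric="euclidean"))
    return DistanceMatrix(d, ids=[str(s) for s in metadata.index])
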