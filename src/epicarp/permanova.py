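"""Distance-based permutational multivariate ANOVA and the Mantel test.

The PERMANOVA here follows the classical Gower-centring construction: from a
dissimilarity matrix ``D`` build ``G = J (-D^2 / 2) J`` with ``J`` the
centring matrix; the sum of squares explained by a model term is the trace of
``G`` projected onto the subspace that term adds to the design (sequential,
Type I), and the pseudo-F is the term's mean square over the residual mean
square. Significance comes from freely permuting sample identities, with the
conservative convention

    p = (number of permuted F >= observed F + 1) / (n_permutations + 1),

whose floor at 1 / (n_permutations + 1) is the familiar 9.999e-5 at 10,000
permutations. On a Euclidean distance matrix of a univariate response the
decomposition coincides exactly with classical ANOVA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, permutations as iter_permutations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .errors import ParameterError
from .inference import bh_adjust, round_sig, sequential_projectors

__all__ = ["Permanova", "PermanovaResults", "pairwise_permanova", "mantel", "gower_center"]


def gower_center(d: np.ndarray) -> np.ndarray:
    """Gower-centred inner-product matrix of a squared-dissimilarity matrix."""
    a = -0.5 * d.astype(float) ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


@dataclass
class PermanovaResults:
    """Fitted PERMANOVA: per-term SS, pseudo-F, R-squared and permutation p."""

    table: pd.DataFrame  # rows: terms + Residual + Total
    n_permutations: int
    seed: int | None
    method: str  # "sampled" | "exact"

    def r_squared_ratio(self, term_a: str, term_b: str, sig_figs: int = 2) -> float:
        """Ratio of two terms' R-squared, rounded for reporting."""
        r2 = self.table["R2"]
        if r2[term_b] == 0:
            raise ParameterError(f"term {term_b!r} has zero R2")
        return round_sig(float(r2[term_a] / r2[term_b]), sig_figs)

    def summary(self) -> str:
        head = (
            f"PERMANOVA ({self.method} permutations={self.n_permutations}, "
            f"seed={self.seed})"
        )
        return head + "\n" + self.table.to_string(float_format=lambda v: f"{v:.6g}")


class Permanova:
    """Sequential (Type I) PERMANOVA on a dissimilarity matrix.

    Parameters
    ----------
    dm : skbio.DistanceMatrix
        Pairwise dissimilarities between samples.
    metadata : pandas.DataFrame
        Sample metadata indexed by sample id; must cover all ids in ``dm``.
    factors : sequence of str
        One or two metadata columns, in model order.
    interaction : bool
        Include the A:B interaction (two factors only).
    """

    def __init__(self, dm: DistanceMatrix, metadata: pd.DataFrame, factors, interaction: bool = True):
        ids = list(dm.ids)
        missing = [i for i in ids if i not in metadata.index]
        if missing:
            raise ParameterError(f"metadata missing sample(s) {missing[:3]}")
        factors = list(factors)
        if len(factors) not in (1, 2):
            raise ParameterError("factors must name one or two metadata columns")
        self.dm = dm
        self.ids = ids
        self.factor_values = [
            (name, metadata.loc[ids, name].to_numpy()) for name in factors
        ]
        self.interaction = interaction and len(factors) == 2

    def fit(
        self,
        permutations: int = 10_000,
        seed: int | None = None,
        method: str = "sampled",
    ) -> PermanovaResults:
        """Run the decomposition and permutation test.

        ``method="exact"`` enumerates all ``n!`` sample permutations (only
        feasible for small n; guarded at n <= 9) and reports the exact
        permutation p including the identity rearrangement.
        """
        d = self.dm.data
        n = d.shape[0]
        g = gower_center(d)
        names, delta_hats, dfs, resid_proj, df_resid = sequential_projectors(
            self.factor_values, interaction=self.interaction
        )
        if df_resid <= 0:
            raise ParameterError("saturated design: no residual degrees of freedom")
        ss_total = float(np.trace(g))
        ss_terms = np.array([float(np.sum(dh * g)) for dh in delta_hats])
        ss_resid = float(np.sum(resid_proj * g))
        ms_resid = ss_resid / df_resid
        f_obs = (ss_terms / np.array(dfs)) / ms_resid

        if method == "exact":
            if n > 9:
                raise ParameterError("exact enumeration is limited to n <= 9 samples")
            perms = np.array(list(iter_permutations(range(n))))
            f_perm = self._permuted_f(g, perms, delta_hats, dfs, resid_proj, df_resid)
            p = (f_perm >= f_obs[None, :] - 1e-12).mean(axis=0)
            n_perm = len(perms)
        elif method == "sampled":
            if permutations < 1:
                raise ParameterError("permutations must be >= 1")
            rng = np.random.default_rng(seed)
            p = np.zeros(len(f_obs))
            count = np.zeros(len(f_obs))
            chunk = max(1, min(permutations, int(2e7 / (n * n + 1))))
            done = 0
            while done < permutations:
                m = min(chunk, permutations - done)
                perms = np.array([rng.permutation(n) for _ in range(m)])
                f_perm = self._permuted_f(g, perms, delta_hats, dfs, resid_proj, df_resid)
                count += (f_perm >= f_obs[None, :] - 1e-12).sum(axis=0)
                done += m
            p = (count + 1.0) / (permutations + 1.0)
            n_perm = permutations
        else:
            raise ParameterError(f"unknown method {method!r}")

        rows = []
        for name, df, ss, f, pv in zip(names, dfs, ss_terms, f_obs, p):
            rows.append(
                {"term": name, "df": df, "SS": ss, "pseudo_F": f,
                 "R2": ss / ss_total if ss_total > 0 else np.nan, "p": pv}
            )
        rows.append(
            {"term": "Residual", "df": df_resid, "SS": ss_resid, "pseudo_F": np.nan,
             "R2": ss_resid / ss_total if ss_total > 0 else np.nan, "p": np.nan}
        )
        rows.append(
            {"term": "Total", "df": n - 1, "SS": ss_total, "pseudo_F": np.nan,
             "R2": 1.0, "p": np.nan}
        )
        table = pd.DataFrame(rows).set_index("term")
        return PermanovaResults(
            table=table, n_permutations=n_perm, seed=seed, method=method
        )

    @staticmethod
    def _permuted_f(g, perms, delta_hats, dfs, resid_proj, df_resid):
        """Pseudo-F for a batch of permutations (rows of ``perms``)."""
        gp = g[perms[:, :, None], perms[:, None, :]]  # (m, n, n)
        ss = np.stack(
            [np.einsum("ij,pij->p", dh, gp) for dh in delta_hats], axis=1
        )
        ss_res = np.einsum("ij,pij->p", resid_proj, gp)
        return (ss / np.asarray(dfs)[None, :]) / (ss_res / df_resid)[:, None]


def pairwise_permanova(
    dm: DistanceMatrix,
    metadata: pd.DataFrame,
    factor: str,
    permutations: int = 10_000,
    seed: int | None = None,
    adjust: bool = True,
) -> pd.DataFrame:
    """One-factor PERMANOVA on every pair of factor levels.

    Returns one row per level pair with the pair's pseudo-F, R2 and
    permutation p; BH-adjusted q across pairs unless ``adjust`` is off.
    """
    ids = np.array(dm.ids)
    values = metadata.loc[ids, factor]
    levels = sorted(pd.unique(values))
    if len(levels) < 2:
        raise ParameterError(f"factor {factor!r} needs at least 2 levels")
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in combinations(levels, 2):
        keep = ids[values.isin([a, b]).to_numpy()]
        sub = dm.filter(keep)
        res = Permanova(sub, metadata, [factor], interaction=False).fit(
            permutations=permutations, seed=int(rng.integers(2**31 - 1))
        )
        term = res.table.index[0]
        rows.append(
            {
                "level_1": a,
                "level_2": b,
                "df": int(res.table.loc[term, "df"]),
                "pseudo_F": float(res.table.loc[term, "pseudo_F"]),
                "R2": float(res.table.loc[term, "R2"]),
                "p": float(res.table.loc[term, "p"]),
            }
        )
    out = pd.DataFrame(rows)
    if adjust:
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def mantel(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    permutations: int = 9_999,
    seed: int | None = None,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices over the same samples.

    Pearson r over the lower-triangle entries; the p-value permutes one
    matrix's sample order, with the (b+1)/(m+1) convention. ``alternative``
    is ``"greater"`` (distance-decay style, default), ``"less"`` or
    ``"two-sided"``.
    """
    if set(dm1.ids) != set(dm2.ids):
        raise ParameterError("the two distance matrices must share sample ids")
    if alternative not in ("greater", "less", "two-sided"):
        raise ParameterError(f"unknown alternative {alternative!r}")
    dm2 = dm2.filter(dm1.ids)
    n = dm1.shape[0]
    if n < 3:
        raise ParameterError("Mantel test needs at least 3 samples")
    tri = np.tril_indices(n, k=-1)
    x = dm1.data[tri]
    y0 = dm2.data
    r_obs = _pearson(x, y0[tri])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        r_perm = _pearson(x, y0[perm[:, None], perm[None, :]][tri])
        if alternative == "greater":
            hit = r_perm >= r_obs - 1e-12
        elif alternative == "less":
            hit = r_perm <= r_obs + 1e-12
        else:
            hit = abs(r_perm) >= abs(r_obs) - 1e-12
        count += bool(hit)
    p = (count + 1.0) / (permutations + 1.0)
    return float(r_obs), float(p)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0:
        return 0.0
    return float(xc @ yc) / denom
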