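"""Univariate hypothesis testing for the epicarp workflow.

Implements the decision tree the analysis follows for per-sample summaries
(richness, diversity indices, aggregated abundances):

1. Shapiro-Wilk normality check; if it fails, retest after a square-root
   transform; if that also fails, fall back to Kruskal-Wallis with Dunn's
   post-hoc and Benjamini-Hochberg correction.
2. Two-way factorial ANOVA with sequential (Type I) sums of squares, omega
   squared effect sizes, and Tukey HSD post-hocs.

The ANOVA is computed through explicit design-matrix projections (the same
machinery the distance-based tests use), so its sums of squares agree exactly
with the distance-based decomposition in the Euclidean limit.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError, ValidationError

__all__ = [
    "TwoWayAnova",
    "AnovaResults",
    "omega_squared_ratio",
    "round_sig",
    "normality_gate",
    "GateDecision",
    "kruskal_wallis",
    "dunn_posthoc",
    "bh_adjust",
    "tukey_hsd",
    "sequential_projectors",
]


def round_sig(x: float, sig_figs: int = 2) -> float:
    """Round to a number of significant figures (reporting convention)."""
    if x == 0 or not np.isfinite(x):
        return float(x)
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig_figs - 1))


# ---------------------------------------------------------------------------
# design-matrix machinery (shared with the distance-based tests)
# ---------------------------------------------------------------------------

def _reduced_dummies(factor: np.ndarray) -> np.ndarray:
    """Treatment-coded (first level dropped) indicator columns, full rank."""
    levels = pd.unique(factor)
    return (factor[:, None] == levels[None, 1:]).astype(float)


def sequential_projectors(factors: list, interaction: bool = True):
    """Hat-matrix increments for an intercept + sequential factorial design.

    ``factors`` is a list of (name, values) pairs in model order. Each term is
    treatment-coded so the cumulative design is full rank by construction.
    Returns ``(term_names, delta_hats, dfs, resid_projector, df_resid)`` where
    each ``delta_hats[k]`` is the projection onto the subspace added by term
    ``k`` over the preceding terms. Raises on singular designs (aliased
    factors) and, for the interaction, on empty cells.
    """
    n = len(factors[0][1])
    blocks = [np.ones((n, 1))]
    names = []
    reduced = []
    for name, values in factors:
        arr = np.asarray(values)
        if len(arr) != n:
            raise ParameterError(f"factor {name!r} misaligned with observations")
        if len(pd.unique(arr)) < 2:
            raise ParameterError(f"factor {name!r} needs at least 2 levels")
        reduced.append(_reduced_dummies(arr))
        blocks.append(reduced[-1])
        names.append(name)
    if interaction:
        if len(factors) != 2:
            raise ParameterError("interaction requires exactly two factors")
        a = np.asarray(factors[0][1]).astype(str)
        b = np.asarray(factors[1][1]).astype(str)
        cells = pd.crosstab(a, b)
        if (cells.to_numpy() == 0).any():
            i, j = np.argwhere(cells.to_numpy() == 0)[0]
            raise ValidationError(
                f"empty design cell ({cells.index[i]!r}, {cells.columns[j]!r})"
            )
        # column-wise products of the two reduced codings
        blocks.append(np.einsum("ni,nj->nij", reduced[0], reduced[1]).reshape(n, -1))
        names.append(f"{factors[0][0]}:{factors[1][0]}")

    x = np.empty((n, 0))
    prev_rank = 0
    prev_hat = np.zeros((n, n))
    delta_hats = []
    dfs = []
    for k, block in enumerate(blocks):
        x = np.hstack([x, block])
        q, r = np.linalg.qr(x)
        diag = np.abs(np.diag(r))
        if diag.size and diag.min() <= 1e-8 * max(1.0, diag.max()):
            raise ParameterError(
                f"singular design: term {names[k - 1]!r} is aliased with earlier terms"
            )
        rank = x.shape[1]
        hat = q @ q.T
        if k > 0:
            delta_hats.append(hat - prev_hat)
            dfs.append(rank - prev_rank)
        prev_rank, prev_hat = rank, hat
    df_resid = n - prev_rank
    resid = np.eye(n) - prev_hat
    return names, delta_hats, dfs, resid, df_resid


# ---------------------------------------------------------------------------
# two-way ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaResults:
    """Fitted two-way ANOVA: sequential SS table plus effect-size helpers."""

    table: pd.DataFrame  # rows: factor A, factor B, A:B, Residual
    ss_total: float
    n_obs: int
    transformation: str = "none"

    @property
    def ms_error(self) -> float:
        return float(self.table.loc["Residual", "mean_sq"])

    def omega_squared(self) -> pd.Series:
        """Omega-squared per effect: df_e (MS_e - MS_err) / (SS_total + MS_err)."""
        ms_err = self.ms_error
        effects = self.table.drop(index="Residual")
        omega = (
            effects["df"] * (effects["mean_sq"] - ms_err) / (self.ss_total + ms_err)
        )
        omega.name = "omega_squared"
        return omega

    def effect_ratio(self, effect_a: str, effect_b: str, sig_figs: int = 2) -> float:
        """Ratio of omega-squared effect sizes, rounded for reporting."""
        omega = self.omega_squared()
        if omega[effect_b] == 0:
            raise ParameterError(f"effect {effect_b!r} has zero omega-squared")
        return round_sig(float(omega[effect_a] / omega[effect_b]), sig_figs)

    def summary(self) -> str:
        lines = [f"Two-way ANOVA (sequential SS, transformation={self.transformation})"]
        lines.append(self.table.to_string(float_format=lambda v: f"{v:.6g}"))
        omega = self.omega_squared()
        lines.append("omega^2: " + ", ".join(f"{k}={v:.4g}" for k, v in omega.items()))
        return "\n".join(lines)


class TwoWayAnova:
    """Two-way full-factorial ANOVA with sequential (Type I) sums of squares.

    Term order follows the argument order, matching the convention that the
    first-listed factor absorbs shared variation.
    """

    def __init__(self, response, factor_a, factor_b, names=("A", "B")):
        self.y = np.asarray(response, dtype=float)
        if self.y.ndim != 1:
            raise ParameterError("response must be one-dimensional")
        self.factors = [
            (names[0], np.asarray(factor_a)),
            (names[1], np.asarray(factor_b)),
        ]
        for _, f in self.factors:
            if len(f) != len(self.y):
                raise ParameterError("factors must align with the response")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, response: str, factor_a: str, factor_b: str):
        return cls(
            frame[response].to_numpy(dtype=float),
            frame[factor_a].to_numpy(),
            frame[factor_b].to_numpy(),
            names=(factor_a, factor_b),
        )

    def fit(self, transformation: str = "none") -> AnovaResults:
        y = self.y
        if transformation == "sqrt":
            if np.any(y < 0):
                raise ParameterError("square-root transform needs non-negative data")
            y = np.sqrt(y)
        elif transformation != "none":
            raise ParameterError(f"unknown transformation {transformation!r}")
        names, delta_hats, dfs, resid_proj, df_resid = sequential_projectors(
            self.factors, interaction=True
        )
        yc = y - y.mean()
        ss_total = float(yc @ yc)
        ss_terms = [float(y @ dh @ y) for dh in delta_hats]
        ss_resid = float(y @ resid_proj @ y)
        rows = []
        ms_resid = ss_resid / df_resid if df_resid else np.nan
        degenerate = ss_total <= 1e-12
        for name, df, ss in zip(names, dfs, ss_terms):
            ms = ss / df
            if degenerate or not df_resid or ms_resid <= 0:
                f = p = np.nan
            else:
                f = ms / ms_resid
                p = float(stats.f.sf(f, df, df_resid))
            rows.append({"term": name, "df": df, "sum_sq": ss, "mean_sq": ms, "F": f, "p": p})
        rows.append(
            {
                "term": "Residual",
                "df": df_resid,
                "sum_sq": ss_resid,
                "mean_sq": ms_resid,
                "F": np.nan,
                "p": np.nan,
            }
        )
        table = pd.DataFrame(rows).set_index("term")
        return AnovaResults(
            table=table, ss_total=ss_total, n_obs=len(y), transformation=transformation
        )


def omega_squared_ratio(
    df_a: int, f_a: float, df_b: int, f_b: float, sig_figs: int = 2
) -> float:
    """Omega-squared ratio of two effects sharing one ANOVA error term.

    For effects a and b with a common MS_error and SS_total, the ratio of
    their omega-squared values reduces algebraically to
    ``df_a (F_a - 1) / (df_b (F_b - 1))`` — computable from the printed F
    statistics alone. Rounded to ``sig_figs`` significant figures, the
    reporting convention for "x times greater" statements.
    """
    num = df_a * (f_a - 1.0)
    den = df_b * (f_b - 1.0)
    if den == 0:
        raise ParameterError("reference effect has F = 1 (zero omega-squared)")
    return round_sig(num / den, sig_figs)


# ---------------------------------------------------------------------------
# normality gate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GateDecision:
    branch: str  # "anova" | "sqrt_anova" | "kruskal_wallis"
    shapiro_p_raw: float
    shapiro_p_sqrt: float | None


def normality_gate(values, alpha: float = 0.05) -> GateDecision:
    """Decide the test family: ANOVA, sqrt-transformed ANOVA, or Kruskal-Wallis.

    Shapiro-Wilk on the raw values (or residuals, if the caller passes them);
    on failure the square-root transform is retested; if still non-normal the
    rank-based fallback is chosen.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ParameterError("normality test needs at least 3 observations")
    if np.ptp(x) == 0:
        # constant data: Shapiro is undefined; parametric branch trivially fine
        return GateDecision("anova", 1.0, None)
    p_raw = float(stats.shapiro(x).pvalue)
    if p_raw >= alpha:
        return GateDecision("anova", p_raw, None)
    if np.any(x < 0):
        return GateDecision("kruskal_wallis", p_raw, None)
    p_sqrt = float(stats.shapiro(np.sqrt(x)).pvalue)
    if p_sqrt >= alpha:
        return GateDecision("sqrt_anova", p_raw, p_sqrt)
    return GateDecision("kruskal_wallis", p_raw, p_sqrt)


# ---------------------------------------------------------------------------
# rank-based tests
# ---------------------------------------------------------------------------

def kruskal_wallis(groups) -> tuple[float, int, float]:
    """Kruskal-Wallis H (tie-corrected), its df, and the chi-square p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ParameterError("need at least 2 non-empty groups")
    stat, p = stats.kruskal(*groups)
    return float(stat), len(groups) - 1, float(p)


def dunn_posthoc(groups, labels=None) -> pd.DataFrame:
    """Dunn's pairwise z tests after Kruskal-Wallis, BH-adjusted.

    Uses rank means on the pooled sample with tie-corrected variance:
    ``z = (R_i - R_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j))`` with
    ``T = sum(t^3 - t) / (12 (N - 1))`` over tie groups.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ParameterError("need at least 2 non-empty groups")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    sizes = [len(g) for g in groups]
    bounds = np.cumsum([0] + sizes)
    rank_means = [
        ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(groups))
    ]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    var_unit = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        se = np.sqrt(var_unit * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (rank_means[i] - rank_means[j]) / se if se > 0 else np.nan
        p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append({"group_1": labels[i], "group_2": labels[j], "z": z, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Tukey HSD
# ---------------------------------------------------------------------------

def tukey_hsd(
    groups,
    labels=None,
    ms_error: float | None = None,
    df_error: int | None = None,
) -> pd.DataFrame:
    """Tukey's honestly-significant-difference pairwise comparisons.

    By default the pooled within-group mean square serves as the error term;
    pass ``ms_error``/``df_error`` to reuse the residual of a wider ANOVA
    (e.g. comparing fruit means against the two-way model's error).
    P-values come from the studentized range distribution.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2 or any(len(g) < 1 for g in groups):
        raise ParameterError("need at least 2 non-empty groups")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(k)]
    if (ms_error is None) != (df_error is None):
        raise ParameterError("ms_error and df_error must be given together")
    if ms_error is None:
        df_error = sum(len(g) - 1 for g in groups)
        if df_error <= 0:
            raise ParameterError("no residual degrees of freedom")
        ms_error = sum(((g - g.mean()) ** 2).sum() for g in groups) / df_error
    means = [g.mean() for g in groups]
    rows = []
    for i, j in combinations(range(k), 2):
        diff = means[i] - means[j]
        se = np.sqrt(ms_error / 2.0 * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
        if se == 0:
            q = np.inf if diff else 0.0
        else:
            q = abs(diff) / se
        p = float(stats.studentized_range.sf(q, k, df_error))
        rows.append(
            {"group_1": labels[i], "group_2": labels[j], "mean_diff": diff, "q_stat": q, "p_adj": p}
        )
    return pd.DataFrame(rows)
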