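"""Type-II ANOVA for the unbalanced two-factor incubation design.

The incubation design is a 2 x 2 factorial (site x light, or site x
epiphytes) with unequal cell sizes (4 vials with epiphytes, 3 without), so
type-I sums of squares depend on factor order. Type-II SS are computed by
nested model comparison with sum-to-zero factor coding:

    SS(A | B)     = RSS(B)     - RSS(A + B)
    SS(B | A)     = RSS(A)     - RSS(A + B)
    SS(AB | A, B) = RSS(A + B) - RSS(A + B + AB)

F statistics use the residual mean square of the full model; p values come
from the F distribution. On balanced designs this reduces to the classical
decomposition (type I = type II = type III).

Residual sums of squares are obtained from QR projections, which also gives
a vectorized many-response path (:func:`null_pvalues`) used for type-I
error calibration under a simulated null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError


@dataclass
class AnovaResult:
    """ANOVA table plus model-level summaries.

    ``table`` has one row per term (and ``Residual``) with columns
    ``sum_sq``, ``df``, ``F``, ``p``. ``r_squared`` is the full-model R2.
    """

    table: pd.DataFrame
    r_squared: float
    residual_ss: float
    residual_df: int

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]


def _sum_coded(labels) -> tuple[np.ndarray, list]:
    """Sum-to-zero (deviation) coding: n x (levels-1) matrix."""
    labels = np.asarray(labels)
    levels = list(pd.unique(labels))
    if len(levels) < 2:
        raise DesignError("each factor needs >= 2 levels")
    x = np.zeros((labels.size, len(levels) - 1))
    for j, lev in enumerate(levels[:-1]):
        x[labels == lev, j] = 1.0
    x[labels == levels[-1], :] = -1.0
    return x, levels


def _interaction(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    return np.einsum("ni,nj->nij", xa, xb).reshape(xa.shape[0], -1)


def _q_basis(*blocks: np.ndarray) -> np.ndarray:
    """Orthonormal basis (incl. intercept) of the column space of [1, blocks...]."""
    n = blocks[0].shape[0] if blocks else 0
    x = np.column_stack([np.ones((n, 1))] + [b for b in blocks if b.size])
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
    return q[:, keep]


def _rss(y: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Residual SS of y (n,) or (n, m) projected off the column space of q."""
    proj = q.T @ y
    return (y * y).sum(axis=0) - (proj * proj).sum(axis=0)


def two_way_anova_type2(values, factor_a, factor_b,
                        names: tuple[str, str] = ("A", "B")) -> AnovaResult:
    """Two-factor type-II ANOVA on a possibly unbalanced crossed design.

    Raises :class:`DesignError` for an empty cell, zero residual df, or a
    response with no residual variance (F undefined).
    """
    y = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (y.shape[0] == fa.shape[0] == fb.shape[0]):
        raise DesignError("values and factors must have equal length")
    xa, lev_a = _sum_coded(fa)
    xb, lev_b = _sum_coded(fb)
    cells = pd.crosstab(pd.Series(fa), pd.Series(fb))
    if (cells.values == 0).any() or cells.shape != (len(lev_a), len(lev_b)):
        raise DesignError("every factor-level cell must be non-empty")
    xab = _interaction(xa, xb)

    q_full = _q_basis(xa, xb, xab)
    q_ab_drop = _q_basis(xa, xb)
    q_a = _q_basis(xa)
    q_b = _q_basis(xb)

    n = y.shape[0]
    df_a, df_b = xa.shape[1], xb.shape[1]
    df_ab = df_a * df_b
    df_res = n - (1 + df_a + df_b + df_ab)
    if df_res <= 0:
        raise DesignError("zero residual degrees of freedom")

    ss_total = float(((y - y.mean()) ** 2).sum())
    if ss_total <= 0:
        raise DesignError("constant response: nothing to decompose")
    rss_full = float(_rss(y, q_full))
    ss_a = float(_rss(y, q_b) - _rss(y, q_ab_drop))
    ss_b = float(_rss(y, q_a) - _rss(y, q_ab_drop))
    ss_ab = float(_rss(y, q_ab_drop) - rss_full)
    mse = rss_full / df_res
    if mse <= 0 or not np.isfinite(mse):
        raise DesignError("no residual variance: F statistics are undefined")

    rows = {}
    for term, ss, df in ((names[0], ss_a, df_a), (names[1], ss_b, df_b),
                         (f"{names[0]}:{names[1]}", ss_ab, df_ab)):
        f = (ss / df) / mse
        rows[term] = {"sum_sq": max(ss, 0.0), "df": df, "F": f,
                      "p": float(stats.f.sf(f, df, df_res))}
    rows["Residual"] = {"sum_sq": rss_full, "df": df_res, "F": np.nan, "p": np.nan}
    table = pd.DataFrame(rows).T
    return AnovaResult(table=table, r_squared=1.0 - rss_full / ss_total,
                       residual_ss=rss_full, residual_df=df_res)


def one_way_anova(values, factor, name: str = "group") -> AnovaResult:
    """One-factor ANOVA (between/within decomposition; type II = type I here)."""
    y = np.asarray(values, dtype=float)
    fa = np.asarray(factor)
    if y.shape[0] != fa.shape[0]:
        raise DesignError("values and factor must have equal length")
    levels, counts = np.unique(fa, return_counts=True)
    if len(levels) < 2:
        raise DesignError("need >= 2 groups")
    if (counts < 2).any():
        raise DesignError("every group needs n >= 2")
    xg, _ = _sum_coded(fa)
    q = _q_basis(xg)
    rss = float(_rss(y, q))
    ss_total = float(((y - y.mean()) ** 2).sum())
    ss_between = ss_total - rss
    df_b = len(levels) - 1
    df_res = y.shape[0] - len(levels)
    mse = rss / df_res
    if mse <= 0 or not np.isfinite(mse):
        raise DesignError("no residual variance: F statistic is undefined")
    f = (ss_between / df_b) / mse
    table = pd.DataFrame({
        name: {"sum_sq": ss_between, "df": df_b, "F": f,
               "p": float(stats.f.sf(f, df_b, df_res))},
        "Residual": {"sum_sq": rss, "df": df_res, "F": np.nan, "p": np.nan},
    }).T
    return AnovaResult(table=table, r_squared=ss_between / ss_total,
                       residual_ss=rss, residual_df=df_res)


def null_pvalues(factor_a, factor_b, n_sim: int, seed: int, term: str = "a") -> np.ndarray:
    """p values for one term over ``n_sim`` pure-noise responses on a fixed design.

    Shares the projection machinery of :func:`two_way_anova_type2`; used to
    check that the type-I error rate matches the nominal alpha.
    """
    xa, _ = _sum_coded(np.asarray(factor_a))
    xb, _ = _sum_coded(np.asarray(factor_b))
    xab = _interaction(xa, xb)
    n = xa.shape[0]
    df_a, df_b = xa.shape[1], xb.shape[1]
    df_ab = df_a * df_b
    df_res = n - (1 + df_a + df_b + df_ab)
    if df_res <= 0:
        raise DesignError("zero residual degrees of freedom")
    q_full = _q_basis(xa, xb, xab)
    q_ab_drop = _q_basis(xa, xb)
    rng = np.random.default_rng(seed)
    y = rng.standard_normal((n, n_sim))
    rss_full = _rss(y, q_full)
    if term == "a":
        ss, df = _rss(y, _q_basis(xb)) - _rss(y, q_ab_drop), df_a
    elif term == "b":
        ss, df = _rss(y, _q_basis(xa)) - _rss(y, q_ab_drop), df_b
    elif term == "ab":
        ss, df = _rss(y, q_ab_drop) - rss_full, df_ab
    else:
        raise ValueError(f"unknown term {term!r}")
    f = (ss / df) / (rss_full / df_res)
    return stats.f.sf(f, df, df_res)
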