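"""Compositional statistics for the amplicon (ASV) count table.

Counts are treated as compositions: each sample is mapped to Euclidean
space with the centered log-ratio (CLR) after adding a pseudocount, the
sample-by-sample distance is plain Euclidean on CLR rows (the Aitchison
distance), and group differences are tested with PERMANOVA on that
distance matrix. Relative-abundance summaries aggregate ASVs at a chosen
taxonomic rank.

PERMANOVA p values use the (b+1)/(m+1) permutation estimator (never 0);
when the number of distinct label arrangements is small the sampler is
replaced by exact enumeration.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skbio.stats.composition import clr as _skbio_clr

from .errors import DesignError

RANKS = ["domain", "phylum", "class", "order", "family", "genus"]


@dataclass
class AsvTable:
    """Samples x ASVs count matrix with per-ASV taxonomy and sample metadata.

    ``counts``: DataFrame (samples x ASVs, non-negative integers);
    ``taxonomy``: DataFrame indexed by ASV with rank columns (subset of
    :data:`RANKS`); ``sample_meta``: DataFrame indexed like ``counts`` with
    grouping columns such as ``site`` and ``compartment``.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.counts.empty:
            raise ValueError("empty count table")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.counts.columns.equals(self.taxonomy.index):
            if set(self.counts.columns) != set(self.taxonomy.index):
                raise ValueError("taxonomy must cover exactly the ASVs in counts")
            self.taxonomy = self.taxonomy.loc[self.counts.columns]
        if len(self.sample_meta) and len(self.sample_meta) != len(self.counts):
            raise ValueError("sample_meta length must match the number of samples")


@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: Optional[int]
    method: str = "sampled"  # or "exact"

    def __post_init__(self) -> None:
        if self.method == "sampled" and self.p_value < 1.0 / (self.n_permutations + 1) - 1e-12:
            raise ValueError("p below the permutation floor 1/(n_perm+1)")


def clr_transform(table, pseudocount: float = 0.5) -> np.ndarray:
    """Centered log-ratio of ``counts + pseudocount``, one row per sample.

    Every output row sums to zero and is invariant to the sample's total
    count (compositional closure). A zero pseudocount is allowed only when
    every entry is already positive (then the transform is exactly
    scale-invariant per row).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    counts = table.counts if isinstance(table, AsvTable) else pd.DataFrame(table)
    if counts.size == 0:
        raise ValueError("empty count table")
    x = counts.to_numpy(dtype=float) + pseudocount
    if (x <= 0).any():
        raise ValueError("zero counts require a positive pseudocount")
    return _skbio_clr(x)


def aitchison_distance(table, pseudocount: float = 0.5) -> np.ndarray:
    """Euclidean distance matrix between CLR-transformed samples."""
    z = clr_transform(table, pseudocount)
    diff = z[:, None, :] - z[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))


def _check_distance(dist: np.ndarray) -> np.ndarray:
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-8):
        raise ValueError("distance matrix must have a zero diagonal")
    return d


def _pseudo_f_terms(d2: np.ndarray, masks: np.ndarray, sizes: np.ndarray,
                    ss_total: float, df_between: int, df_within: int) -> np.ndarray:
    """Pseudo-F for each row of boolean group masks (n_arrangements x groups x n)."""
    ss_within = np.zeros(masks.shape[0])
    for g in range(masks.shape[1]):
        m = masks[:, g, :].astype(float)
        ss_within += np.einsum("ai,ij,aj->a", m, d2, m) / (2.0 * sizes[g])
    ss_between = ss_total - ss_within
    return (ss_between / df_between) / (ss_within / df_within)


def _enumerate_arrangements(groups: np.ndarray, levels: Sequence) -> np.ndarray:
    """All distinct assignments of the multiset of labels to positions."""
    n = groups.size
    counts = [int((groups == lev).sum()) for lev in levels]
    out = []

    def rec(free: tuple, gi: int, current: list):
        if gi == len(levels) - 1:
            out.append(current + [free])
            return
        for combo in itertools.combinations(free, counts[gi]):
            remaining = tuple(p for p in free if p not in combo)
            rec(remaining, gi + 1, current + [combo])

    rec(tuple(range(n)), 0, [])
    masks = np.zeros((len(out), len(levels), n), dtype=bool)
    for a, assignment in enumerate(out):
        for g, positions in enumerate(assignment):
            masks[a, g, list(positions)] = True
    return masks


def n_distinct_arrangements(groups) -> int:
    """Multinomial count of distinct label-to-position assignments."""
    groups = np.asarray(groups)
    _, counts = np.unique(groups, return_counts=True)
    total = math.factorial(groups.size)
    for c in counts:
        total //= math.factorial(int(c))
    return total


def permanova(dist, groups, n_perm: int = 999, seed: Optional[int] = None,
              method: str = "auto", max_exact: int = 20000) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    ``method`` is ``"auto"`` (exact enumeration when the number of distinct
    label arrangements is at most ``max_exact``, else label sampling),
    ``"exact"``, or ``"sampled"``. Sampled p values use (b+1)/(m+1) with
    the supplied seed; results are deterministic given the seed.
    """
    d = _check_distance(dist)
    groups = np.asarray(groups)
    if groups.size != d.shape[0]:
        raise DesignError("group labels must match the distance matrix size")
    levels, counts = np.unique(groups, return_counts=True)
    if len(levels) < 2:
        raise DesignError("PERMANOVA needs >= 2 groups")
    if (counts < 2).any():
        raise DesignError("every group needs >= 2 samples")
    n = groups.size
    a = len(levels)
    df_between, df_within = a - 1, n - a
    d2 = d ** 2
    ss_total = d2.sum() / (2.0 * n)

    obs_mask = np.stack([groups == lev for lev in levels])[None, :, :]
    f_obs = float(_pseudo_f_terms(d2, obs_mask, counts, ss_total, df_between, df_within)[0])
    m = obs_mask[0].astype(float)
    ssw = sum(np.einsum("i,ij,j->", m[g], d2, m[g]) / (2.0 * counts[g]) for g in range(a))
    r2 = (ss_total - ssw) / ss_total

    n_exact = n_distinct_arrangements(groups)
    if method == "auto":
        method = "exact" if n_exact <= max_exact else "sampled"

    if method == "exact":
        masks = _enumerate_arrangements(groups, levels)
        f_all = _pseudo_f_terms(d2, masks, counts, ss_total, df_between, df_within)
        p = float((f_all >= f_obs - 1e-12).sum()) / masks.shape[0]
        return PermanovaResult(f_obs, float(r2), p, masks.shape[0], seed, "exact")

    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(groups) for _ in range(n_perm)])
    masks = np.stack([perms == lev for lev in levels], axis=1)
    f_perm = _pseudo_f_terms(d2, masks, counts, ss_total, df_between, df_within)
    b = int((f_perm >= f_obs - 1e-12).sum())
    p = (b + 1.0) / (n_perm + 1.0)
    return PermanovaResult(f_obs, float(r2), p, n_perm, seed, "sampled")


def relative_abundance(table: AsvTable, rank: str) -> pd.DataFrame:
    """Per-sample percentages aggregated at a taxonomic rank (rows sum to 100).

    ASVs with missing or empty taxonomy at the rank pool into
    ``"Unclassified"``.
    """
    if rank not in table.taxonomy.columns:
        raise ValueError(f"rank {rank!r} not in taxonomy columns {list(table.taxonomy.columns)}")
    tax = table.taxonomy[rank].fillna("Unclassified").replace("", "Unclassified")
    grouped = table.counts.T.groupby(tax.values).sum().T
    totals = grouped.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("cannot compute relative abundance for all-zero samples")
    return grouped.div(totals, axis=0) * 100.0
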