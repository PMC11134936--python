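"""Distance matrices and permutational multivariate ANOVA.

Implements sequential (Type I) variance partitioning on an arbitrary
distance matrix: Gower-centred inner-product matrix, projector-based
sums of squares for an ordered series of categorical terms (including
two-factor interactions), pseudo-F statistics, and permutation p-values
obtained by relabelling samples.  Small designs are tested exhaustively
over all ``n!`` permutations; larger ones by seeded Monte-Carlo sampling
with the "observed counts as one permutation" convention.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DistanceMatrix",
    "PermanovaResult",
    "euclidean_distance",
    "bray_curtis",
    "jaccard",
    "permanova_sequential",
    "pairwise_permanova_bh",
]

#: relative tolerance used for rank decisions and tie counting
RANK_RTOL = 1e-8
_TIE_EPS = 1e-10


@dataclass
class DistanceMatrix:
    """A square symmetric distance matrix with sample identifiers.

    Parameters
    ----------
    ids:
        Sample identifiers, one per row/column.
    data:
        ``(n, n)`` symmetric non-negative array with a zero diagonal.
    metric:
        Label of the metric that produced the matrix
        (``euclidean``, ``bray-curtis`` or ``jaccard``).
    """

    ids: list = field(default_factory=list)
    data: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError(
                f"distance matrix shape {self.data.shape} does not match "
                f"{n} sample ids"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("distance matrix contains non-finite entries")
        if np.any(self.data < 0):
            raise ValueError("distances must be non-negative")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.data), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if self.metric in ("bray-curtis", "jaccard") and np.any(self.data > 1 + 1e-12):
            raise ValueError(f"{self.metric} distances must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.ids)

    def submatrix(self, keep_ids: Iterable) -> "DistanceMatrix":
        """Return the sub-matrix for ``keep_ids`` (order preserved)."""
        keep = list(keep_ids)
        pos = {s: i for i, s in enumerate(self.ids)}
        missing = [s for s in keep if s not in pos]
        if missing:
            raise KeyError(f"ids not in distance matrix: {missing[:5]}")
        idx = np.array([pos[s] for s in keep])
        return DistanceMatrix(keep, self.data[np.ix_(idx, idx)], self.metric)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)


def _as_matrix(table: pd.DataFrame) -> tuple[list, np.ndarray]:
    x = np.asarray(table.values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("abundance table contains non-finite values")
    return list(table.index), x


def euclidean_distance(table: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distances between the rows of ``table``."""
    ids, x = _as_matrix(table)
    return DistanceMatrix(ids, squareform(pdist(x, metric="euclidean")), "euclidean")


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Bray–Curtis dissimilarity ``sum|x-y| / sum(x+y)`` between rows.

    Rows must be non-negative and each row must contain at least one
    positive entry (an all-zero sample has no defined dissimilarity).
    """
    ids, x = _as_matrix(table)
    if np.any(x < 0):
        raise ValueError("Bray-Curtis requires non-negative abundances")
    zero = np.asarray(x.sum(axis=1) == 0)
    if zero.any():
        bad = [ids[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"all-zero sample(s) in Bray-Curtis input: {bad[:5]}")
    return DistanceMatrix(ids, squareform(pdist(x, metric="braycurtis")), "bray-curtis")


def jaccard(table: pd.DataFrame) -> DistanceMatrix:
    """Jaccard distance ``1 - |intersection| / |union|`` between binary rows."""
    ids, x = _as_matrix(table)
    if not np.all(np.isin(x, (0.0, 1.0))):
        raise ValueError("Jaccard requires binary (0/1) rows")
    zero = np.asarray(x.sum(axis=1) == 0)
    if zero.any():
        bad = [ids[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"all-zero sample(s) in Jaccard input: {bad[:5]}")
    d = squareform(pdist(x.astype(bool), metric="jaccard"))
    return DistanceMatrix(ids, d, "jaccard")


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


@dataclass
class PermanovaResult:
    """Sequential PERMANOVA table.

    ``table`` holds one row per model term plus ``Residual`` and ``Total``
    with columns ``df``, ``SS``, ``R2``, ``pseudo_F`` and ``p_perm``.
    """

    table: pd.DataFrame
    terms: tuple
    n_permutations: int
    seed: int | None
    exhaustive: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        head = f"PERMANOVA (sequential SS, {self.n_permutations} permutations"
        head += ", exhaustive)" if self.exhaustive else ")"
        return head + "\n" + self.table.to_string(float_format=lambda v: f"{v:.4f}")


def _term_columns(design: pd.DataFrame, term: str) -> np.ndarray:
    """Full-indicator design columns for a factor or ``a:b`` interaction."""
    if ":" in term:
        a, b = (t.strip() for t in term.split(":", 1))
        for f in (a, b):
            if f not in design.columns:
                raise KeyError(f"factor {f!r} missing from design")
        cells = design[a].astype(str) + "\x1f" + design[b].astype(str)
        return pd.get_dummies(cells, dtype=float).values
    if term not in design.columns:
        raise KeyError(f"factor {term!r} missing from design")
    return pd.get_dummies(design[term].astype(str), dtype=float).values


def _projector(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthogonal projector onto the column space of ``x`` and its rank."""
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        return np.zeros((x.shape[0], x.shape[0])), 0
    rank = int(np.sum(s > RANK_RTOL * s[0]))
    ur = u[:, :rank]
    return ur @ ur.T, rank


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    a = -0.5 * d * d
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return j @ a @ j


def permanova_sequential(
    dm: DistanceMatrix,
    design: pd.DataFrame,
    terms: Sequence[str],
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Partition the variation in ``dm`` among ordered categorical terms.

    Sums of squares are sequential (Type I): each term is charged with
    the increment in explained inertia over the cumulative design built
    from all preceding terms.  Significance is assessed by free
    permutation of sample labels; when ``n!`` does not exceed
    ``n_permutations + 1`` the whole permutation group is enumerated and
    the p-value is the exact tail probability.

    Parameters
    ----------
    dm:
        Distance matrix over the samples.
    design:
        DataFrame of categorical factors indexed like ``dm.ids`` (or
        positionally aligned).
    terms:
        Ordered term names; interactions are written ``"a:b"``.
    n_permutations:
        Number of label permutations (0 skips the test, p = NaN).
    seed:
        Seed for the permutation sampler.
    """
    n = len(dm)
    if n < 3:
        raise ValueError("PERMANOVA requires at least 3 samples")
    if not terms:
        raise ValueError("at least one model term is required")
    design = design.copy()
    if isinstance(design.index, pd.Index) and set(dm.ids).issubset(design.index):
        design = design.loc[dm.ids]
    elif len(design) != n:
        raise ValueError("design does not align with the distance matrix")

    g = _gower_center(dm.data)
    ss_total = float(np.trace(g))
    if ss_total <= RANK_RTOL:
        raise ValueError("all samples identical: total sum of squares is zero")

    blocks: list[np.ndarray] = []
    dfs: list[int] = []
    cols = [np.ones((n, 1))]
    h_prev = np.full((n, n), 1.0 / n)
    rank_prev = 1
    for term in terms:
        cols.append(_term_columns(design, term))
        h, rank = _projector(np.hstack(cols))
        df = rank - rank_prev
        if df <= 0:
            raise ValueError(
                f"term {term!r} adds no degrees of freedom (rank-deficient)"
            )
        blocks.append(h - h_prev)
        dfs.append(df)
        h_prev, rank_prev = h, rank
    resid = np.eye(n) - h_prev
    df_res = n - rank_prev
    if df_res <= 0:
        raise ValueError("saturated model: no residual degrees of freedom")

    dfs_arr = np.asarray(dfs, dtype=float)

    def _stats(gp: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
        ss = np.array([float(np.sum(b * gp)) for b in blocks])
        ss_res = float(np.sum(resid * gp))
        f = (ss / dfs_arr) / (ss_res / df_res)
        return ss, ss_res, f

    ss_obs, ss_res_obs, f_obs = _stats(g)
    if np.any(ss_obs < -1e-8 * ss_total) or ss_res_obs < -1e-8 * ss_total:
        raise ValueError("negative sum of squares: numerical fault in projection")

    exhaustive = False
    if n_permutations > 0:
        thresh = f_obs - _TIE_EPS * np.maximum(1.0, np.abs(f_obs))
        exceed = np.zeros(len(blocks))
        if math.factorial(n) <= n_permutations + 1:
            exhaustive = True
            total = math.factorial(n)
            for perm in itertools.permutations(range(n)):
                idx = np.asarray(perm)
                _, _, f_star = _stats(g[np.ix_(idx, idx)])
                exceed += f_star >= thresh
            pvals = exceed / total
            n_done = total - 1
        else:
            rng = np.random.default_rng(seed)
            for _ in range(n_permutations):
                idx = rng.permutation(n)
                _, _, f_star = _stats(g[np.ix_(idx, idx)])
                exceed += f_star >= thresh
            pvals = (1.0 + exceed) / (1.0 + n_permutations)
            n_done = n_permutations
    else:
        pvals = np.full(len(blocks), np.nan)
        n_done = 0

    rows = []
    for k, term in enumerate(terms):
        rows.append(
            {
                "term": term,
                "df": dfs[k],
                "SS": ss_obs[k],
                "R2": ss_obs[k] / ss_total,
                "pseudo_F": f_obs[k],
                "p_perm": pvals[k],
            }
        )
    rows.append(
        {
            "term": "Residual",
            "df": df_res,
            "SS": ss_res_obs,
            "R2": ss_res_obs / ss_total,
            "pseudo_F": np.nan,
            "p_perm": np.nan,
        }
    )
    rows.append(
        {
            "term": "Total",
            "df": n - 1,
            "SS": ss_total,
            "R2": 1.0,
            "pseudo_F": np.nan,
            "p_perm": np.nan,
        }
    )
    table = pd.DataFrame(rows).set_index("term")
    return PermanovaResult(table, tuple(terms), n_done, seed, exhaustive)


def pairwise_permanova_bh(
    dm: DistanceMatrix,
    factor: pd.Series,
    n_permutations: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """One-term PERMANOVA for every pair of factor levels, BH-adjusted.

    Each level pair is tested on the corresponding sub-matrix; the raw
    permutation p-values are corrected with the Benjamini–Hochberg
    step-up procedure over all pairs.
    """
    factor = pd.Series(factor)
    if set(dm.ids).issubset(factor.index):
        factor = factor.loc[dm.ids]
    elif len(factor) != len(dm):
        raise ValueError("factor does not align with the distance matrix")
    factor.index = dm.ids
    levels = sorted(factor.dropna().unique())
    if len(levels) < 2:
        raise ValueError("pairwise comparisons need at least 2 factor levels")
    counts = factor.value_counts()
    small = [lv for lv in levels if counts.get(lv, 0) < 2]
    if small:
        raise ValueError(f"factor level(s) with < 2 samples: {small}")

    pairs = list(itertools.combinations(levels, 2))
    child_seeds = np.random.SeedSequence(seed).spawn(len(pairs))
    rows = []
    for (a, b), ss in zip(pairs, child_seeds):
        keep = factor.index[factor.isin([a, b])]
        sub = dm.submatrix(keep)
        res = permanova_sequential(
            sub,
            pd.DataFrame({"group": factor.loc[keep]}),
            ["group"],
            n_permutations=n_permutations,
            seed=int(ss.generate_state(1)[0] % (2**31)),
        )
        row = res.table.loc["group"]
        rows.append(
            {
                "level_a": a,
                "level_b": b,
                "n": len(sub),
                "df": int(row["df"]),
                "R2": row["R2"],
                "pseudo_F": row["pseudo_F"],
                "p_perm": row["p_perm"],
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p_perm"].values, method="fdr_bh")[1]
    return out
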