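"""Community statistics: dissimilarity, NMDS, PerMANOVA, coverage-based
rarefaction/extrapolation of Shannon diversity, and the Steel-Dwass test.

These are the analyses a seasonal diet comparison runs on the sample x
taxon table: Bray-Curtis (relative read abundance) and Jaccard (binary
presence) dissimilarities; non-metric multidimensional scaling minimizing
Kruskal stress-1, with the convention that a stress above 0.2 means the
configuration should not be interpreted; a distance-based permutational
MANOVA for group differences; Hill-number (order 1, the exponential of
Shannon entropy) rarefaction and extrapolation reported against sample
coverage with bootstrap confidence bands; and the Steel-Dwass all-pairs
nonparametric comparison of per-sample richness between seasons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln
from scipy.stats import studentized_range

from ._util import child_rng

METRICS = ("bray_curtis", "jaccard")


class StatsError(ValueError):
    pass


# -- dissimilarity ---------------------------------------------------------


@dataclass
class DissimilarityMatrix:
    ids: list[str]
    matrix: np.ndarray  # symmetric, zero diagonal, values in [0, 1]
    metric: str

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise StatsError("matrix shape does not match ids")
        self.matrix = m

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.matrix, index=self.ids, columns=self.ids).to_csv(path, sep="\t")


def dissimilarity(table: pd.DataFrame, metric: str = "bray_curtis") -> DissimilarityMatrix:
    """Pairwise sample dissimilarity from a sample x taxon table.

    ``bray_curtis`` first converts each row to relative abundances and
    uses ``sum|x - y| / sum(x + y)``; ``jaccard`` binarizes the table and
    uses ``1 - |intersection| / |union|``.
    """
    if metric not in METRICS:
        raise StatsError(f"metric must be one of {METRICS}")
    X = table.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise StatsError("need at least two samples")
    if metric == "bray_curtis":
        totals = X.sum(axis=1, keepdims=True)
        if np.any(totals <= 0):
            raise StatsError("every sample needs a positive total for Bray-Curtis")
        vec = pdist(X / totals, metric="braycurtis")
    else:
        vec = pdist(X > 0, metric="jaccard")
    return DissimilarityMatrix(list(table.index), squareform(vec), metric)


# -- NMDS ------------------------------------------------------------------


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x k
    stress: float
    k: int
    converged: bool
    n_restarts: int


def _isotonic_fit(x: np.ndarray) -> np.ndarray:
    """Non-decreasing least-squares fit by pool-adjacent-violators."""
    n = len(x)
    level = x.astype(float).copy()
    weight = np.ones(n)
    # blocks as (value, weight) merged right-to-left
    values: list[float] = []
    weights: list[float] = []
    for v, w in zip(level, weight):
        values.append(v)
        weights.append(w)
        while len(values) > 1 and values[-2] > values[-1]:
            wv = weights[-1] + weights[-2]
            values[-2] = (values[-1] * weights[-1] + values[-2] * weights[-2]) / wv
            weights[-2] = wv
            values.pop()
            weights.pop()
    out = np.empty(n)
    i = 0
    for v, w in zip(values, weights):
        out[i : i + int(w)] = v
        i += int(w)
    return out


def nmds(
    dmat: DissimilarityMatrix,
    k: int = 3,
    restarts: int = 20,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> OrdinationResult:
    """Kruskal non-metric MDS by iterative majorization.

    Each iteration fits monotone disparities to the configuration
    distances in the rank order of the observed dissimilarities (ties
    pooled by the primary approach: tied dissimilarities are free to take
    different disparities) and applies a Guttman transform.  Stress-1 is
    ``sqrt(sum (d - dhat)^2 / sum d^2)``; the best of ``restarts`` random
    starts wins.  Deterministic given ``seed``.
    """
    n = dmat.n
    if k >= n:
        raise StatsError(f"cannot embed {n} samples in {k} dimensions")
    delta = dmat.condensed()
    m = len(delta)
    iu = np.triu_indices(n, 1)

    def _pcoa_start() -> np.ndarray:
        # classical scaling of the dissimilarities: a strong, deterministic
        # first start that is exact whenever the matrix is Euclidean in k dims
        D2 = dmat.matrix**2
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ D2 @ J
        vals, vecs = np.linalg.eigh(B)
        idx = np.argsort(vals)[::-1][:k]
        lam = np.clip(vals[idx], 0.0, None)
        return vecs[:, idx] * np.sqrt(lam)

    best_stress, best_X, best_conv = np.inf, None, False
    for r in range(restarts):
        rng = child_rng(seed, 10, r)
        X = _pcoa_start() if r == 0 else rng.normal(size=(n, k))
        last = np.inf
        converged = False
        for _ in range(max_iter):
            d = np.sqrt(((X[iu[0]] - X[iu[1]]) ** 2).sum(axis=1))
            # primary tie approach: within tied delta, order by current d
            order = np.lexsort((d, delta))
            dhat = np.empty(m)
            dhat[order] = _isotonic_fit(d[order])
            denom = float((d**2).sum())
            if denom <= 0:
                break
            stress = np.sqrt(((d - dhat) ** 2).sum() / denom)
            if abs(last - stress) < tol:
                converged = True
                last = stress
                break
            last = stress
            # Guttman transform with weights 1
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(d > 0, dhat / d, 0.0)
            B = np.zeros((n, n))
            B[iu] = -ratio
            B[(iu[1], iu[0])] = -ratio
            np.fill_diagonal(B, -B.sum(axis=1))
            X = B @ X / n
        if last < best_stress:
            best_stress, best_X, best_conv = last, X.copy(), converged
    coords = pd.DataFrame(
        best_X, index=dmat.ids, columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return OrdinationResult(
        coordinates=coords, stress=float(best_stress), k=k,
        converged=best_conv, n_restarts=restarts,
    )


# -- PerMANOVA -------------------------------------------------------------


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    permutations: int


def permanova(
    dmat: DissimilarityMatrix,
    labels: Sequence[str],
    permutations: int = 10000,
    seed: int = 0,
) -> PermanovaResult:
    """Distance-based permutational MANOVA.

    ``SS_total = sum_{i<j} d_ij^2 / N``; ``SS_within`` sums within-group
    pair terms scaled by group size; the pseudo-F compares among- to
    within-group mean squares and the p-value is the +1-corrected
    permutation tail probability of F under random relabeling.
    """
    labels = np.asarray(labels)
    n = dmat.n
    if len(labels) != n:
        raise StatsError("labels length does not match matrix")
    groups, counts = np.unique(labels, return_counts=True)
    g = len(groups)
    if g < 2:
        raise StatsError("PerMANOVA needs at least two groups")
    if g >= n:
        raise StatsError("PerMANOVA needs residual degrees of freedom")
    D2 = dmat.matrix**2
    ss_total = D2[np.triu_indices(n, 1)].sum() / n

    onehot = np.stack([labels == grp for grp in groups]).astype(float)  # g x n

    def ss_within(memb: np.ndarray) -> np.ndarray:
        # memb: g x P x n indicator; returns per-permutation SS_within
        within = np.einsum("gpi,ij,gpj->gp", memb, D2, memb) / 2.0
        return (within / counts[:, None]).sum(axis=0)

    obs_within = float(ss_within(onehot[:, None, :])[0])
    ss_among = ss_total - obs_within
    with np.errstate(divide="ignore", invalid="ignore"):
        f_obs = (ss_among / (g - 1)) / (obs_within / (n - g))
    r2 = ss_among / ss_total

    rng = child_rng(seed, 20)
    perm_labels = np.tile(np.arange(n), (permutations, 1))
    perm_labels = rng.permuted(perm_labels, axis=1)
    # map observed group memberships through permuted index order
    group_idx = np.searchsorted(groups, labels)
    permuted_groups = group_idx[perm_labels]  # P x n
    memb = np.stack([(permuted_groups == gi).astype(float) for gi in range(g)])
    within_perm = ss_within(memb)
    among_perm = ss_total - within_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = (among_perm / (g - 1)) / (within_perm / (n - g))
    p = (1 + int((f_perm >= f_obs).sum())) / (1 + permutations)
    return PermanovaResult(
        pseudo_f=float(f_obs), r2=float(r2), p_value=float(p), permutations=permutations
    )


# -- coverage and Hill-number rarefaction/extrapolation --------------------


def coverage_estimate(counts: Sequence[int]) -> float:
    """Estimated sample coverage of an abundance vector.

    ``C = 1 - (f1/n) * [(n-1) f1 / ((n-1) f1 + 2 f2)]`` with f1/f2 the
    singleton and doubleton counts; the probability that the next read
    belongs to an already-seen taxon.
    """
    x = np.asarray([c for c in counts if c > 0], dtype=np.int64)
    n = int(x.sum())
    if n == 0:
        raise StatsError("empty count vector")
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if f1 == 0:
        return 1.0
    denom = (n - 1) * f1 + 2 * f2
    if denom == 0:  # n == 1: fall back to the simple Turing estimate
        return float(1.0 - f1 / n)
    return float(1.0 - (f1 / n) * ((n - 1) * f1 / denom))


def _log_comb(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def _interpolated_entropy(x: np.ndarray, m: int) -> float:
    """Expected Shannon entropy of a size-m subsample without replacement.

    ``H(m) = sum_k (k/m) ln(m/k) E[f_k(m)]`` with the hypergeometric
    expectation ``E[f_k(m)] = sum_i C(n_i,k) C(n-n_i,m-k) / C(n,m)``.
    """
    n = int(x.sum())
    k = np.arange(1, m + 1)
    # S x m matrix of log C(n_i, k) + log C(n - n_i, m - k) - log C(n, m)
    xi = x[:, None]
    valid = (k[None, :] <= xi) & ((m - k)[None, :] <= (n - xi))
    with np.errstate(invalid="ignore"):
        logs = (
            _log_comb(xi, np.broadcast_to(k, (len(x), m)))
            + _log_comb(n - xi, np.broadcast_to(m - k, (len(x), m)))
            - _log_comb(np.float64(n), np.float64(m))
        )
    ef = np.where(valid, np.exp(logs), 0.0).sum(axis=0)  # E[f_k(m)]
    w = (k / m) * np.log(m / k)
    return float((w * ef).sum())


def _asymptotic_entropy(x: np.ndarray) -> float:
    """Low-bias asymptotic Shannon entropy (singleton/doubleton corrected)."""
    n = int(x.sum())
    if n <= 1:
        return 0.0
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    # sum_i (x_i/n) * sum_{k=x_i}^{n-1} 1/k
    inv = 1.0 / np.arange(1, n)
    tail = np.concatenate([np.cumsum(inv[::-1])[::-1], [0.0]])  # tail[j] = sum_{k=j+1..n-1} 1/k
    first = float(np.sum((x / n) * tail[x - 1]))
    if f1 == 0:
        return first
    if f2 > 0:
        A = 2 * f2 / ((n - 1) * f1 + 2 * f2)
    elif f1 > 1:
        A = 2 / ((n - 1) * (f1 - 1) + 2)
    else:
        return first
    r = np.arange(1, n)
    correction = (f1 / n) * (1 - A) ** (1 - n) * (
        -np.log(A) - np.sum((1.0 / r) * (1 - A) ** r)
    )
    return first + float(correction)


def _coverage_at_size(x: np.ndarray, m: int) -> float:
    """Expected coverage of a subsample (m < n), the observed coverage at
    m = n, or the extrapolated coverage beyond."""
    n = int(x.sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if m < n:
        keep = (n - x) >= m
        terms = np.zeros(len(x))
        if keep.any():
            terms[keep] = np.exp(
                _log_comb(n - x[keep], np.float64(m)) - _log_comb(np.float64(n - 1), np.float64(m))
            )
        return float(1.0 - np.sum((x / n) * terms))
    if f1 == 0:
        return 1.0
    A = (n - 1) * f1 / ((n - 1) * f1 + 2 * f2)
    return float(1.0 - (f1 / n) * A ** (m - n + 1))


def _hill1_at_size(x: np.ndarray, m: int) -> float:
    n = int(x.sum())
    if m <= n:
        return float(np.exp(_interpolated_entropy(x, m)))
    h_obs = _interpolated_entropy(x, n)
    h_asy = max(_asymptotic_entropy(x), h_obs)
    # anchored hyperbolic approach to the asymptote: exact at m = n,
    # tends to the asymptotic entropy as m grows
    h = h_asy - (h_asy - h_obs) * (n / m)
    return float(np.exp(h))


@dataclass
class RECurve:
    sizes: np.ndarray
    coverages: np.ndarray
    estimates: np.ndarray  # Hill number of order 1
    lcl: np.ndarray
    ucl: np.ndarray
    observed_size: int
    observed_coverage: float
    observed_hill1: float
    bootstrap_reps: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "size": self.sizes,
                "coverage": self.coverages,
                "estimate": self.estimates,
                "lcl": self.lcl,
                "ucl": self.ucl,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def shannon_re_curve(
    counts: Sequence[int],
    grid: Sequence[int] | None = None,
    bootstrap_reps: int = 1000,
    seed: int = 0,
) -> RECurve:
    """Rarefaction/extrapolation of Shannon diversity (Hill order 1).

    Interpolation uses the exact hypergeometric expectation of subsample
    entropy; extrapolation approaches a singleton/doubleton-corrected
    asymptotic entropy along a hyperbolic path anchored at the observed
    point.  Confidence bands are percentile bootstrap (2.5/97.5) over
    multinomial resamples of the count vector; the band is widened, if
    needed, to bracket the point estimate.  The curve is reported against
    both subsample size and estimated coverage.
    """
    x = np.asarray([c for c in counts if c > 0], dtype=np.int64)
    if x.size == 0:
        raise StatsError("empty count vector")
    n = int(x.sum())
    if grid is None:
        lo = np.unique(np.linspace(1, n, 10, dtype=int))
        hi = np.unique(np.linspace(n, 2 * n, 6, dtype=int))[1:]
        grid = np.concatenate([lo, hi])
    grid = np.asarray(sorted(set(int(g) for g in grid)), dtype=int)
    if np.any(grid < 1):
        raise StatsError("grid sizes must be >= 1")

    estimates = np.array([_hill1_at_size(x, int(m)) for m in grid])
    coverages = np.array([_coverage_at_size(x, int(m)) for m in grid])

    if bootstrap_reps > 0:
        rng = child_rng(seed, 30)
        p = x / n
        boot = np.empty((bootstrap_reps, len(grid)))
        for b in range(bootstrap_reps):
            xb = rng.multinomial(n, p)
            xb = xb[xb > 0]
            boot[b] = [_hill1_at_size(xb, int(m)) for m in grid]
        lcl = np.percentile(boot, 2.5, axis=0)
        ucl = np.percentile(boot, 97.5, axis=0)
        lcl = np.minimum(lcl, estimates)
        ucl = np.maximum(ucl, estimates)
    else:
        lcl = estimates.copy()
        ucl = estimates.copy()

    return RECurve(
        sizes=grid,
        coverages=coverages,
        estimates=estimates,
        lcl=lcl,
        ucl=ucl,
        observed_size=n,
        observed_coverage=coverage_estimate(x),
        observed_hill1=float(_hill1_at_size(x, n)),
        bootstrap_reps=bootstrap_reps,
    )


# -- Steel-Dwass all-pairs comparison --------------------------------------


def _rankdata(values: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    return rankdata(values)


def steel_dwass(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """All-pairs nonparametric comparison with a studentized-range reference.

    For each pair of groups the pooled two-sample rank sum is standardized
    with the tie-corrected variance and referred to the studentized-range
    distribution with k = total number of groups (infinite df), the usual
    large-sample Steel-Dwass-Critchlow-Fligner procedure.
    """
    names = list(groups)
    k = len(names)
    if k < 2:
        raise StatsError("need at least two groups")
    arrays = {name: np.asarray(list(groups[name]), dtype=float) for name in names}
    for name, arr in arrays.items():
        if arr.size == 0:
            raise StatsError(f"group {name} is empty")
    rows = []
    for a, b in combinations(names, 2):
        xa, xb = arrays[a], arrays[b]
        na, nb = len(xa), len(xb)
        pooled = np.concatenate([xa, xb])
        ranks = _rankdata(pooled)
        nn = na + nb
        w = float(ranks[:na].sum())
        expect = na * (nn + 1) / 2.0
        var = na * nb / (nn * (nn - 1.0)) * (float((ranks**2).sum()) - nn * (nn + 1) ** 2 / 4.0)
        if var <= 0:
            stat, p = 0.0, 1.0
        else:
            stat = (w - expect) / np.sqrt(var)
            p = float(studentized_range.sf(abs(stat) * np.sqrt(2.0), k, np.inf))
        rows.append({"group1": a, "group2": b, "statistic": float(stat), "p_value": p})
    return pd.DataFrame(rows)


def significance_letters(pairwise: pd.DataFrame, groups: Sequence[str], alpha: float = 0.05) -> dict[str, str]:
    """Compact letter display: groups sharing a letter do not differ at alpha."""
    differ = {
        frozenset((r.group1, r.group2)) for r in pairwise.itertuples() if r.p_value < alpha
    }
    letters: dict[str, str] = {g: "" for g in groups}
    cliques: list[set[str]] = []
    for g in groups:
        placed = False
        for clique in cliques:
            if all(frozenset((g, other)) not in differ for other in clique):
                clique.add(g)
                placed = True
        if not placed:
            cliques.append({g})
    for i, clique in enumerate(cliques):
        letter = chr(ord("a") + i)
        for g in clique:
            letters[g] += letter
    return letters
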