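"""Beta-diversity statistics for compositional sample tables.

Implements the ecological toolbox used to compare mutant populations:
Bray-Curtis dissimilarity, principal coordinates analysis (PCoA), non-metric
multidimensional scaling (NMDS, Kruskal stress-1 with isotonic disparities),
distance-based PERMANOVA with optionally restricted (strata-aware)
permutations for repeated-measures designs, and homogeneity-of-dispersion
tests (distance to group centroid in full PCoA space).

Bray-Curtis between abundance rows x and y is
``1 - 2 * sum_g min(x_g, y_g) / (sum_g x_g + sum_g y_g)``; on rows that each
sum to one this lies in [0, 1] and is 0 iff the compositions coincide.
Because Bray-Curtis is non-Euclidean, the PCoA of its squared form has
negative eigenvalues; dispersion distances subtract the corresponding
imaginary-axis contribution (floored at zero) instead of ignoring it.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

from .barcode_quant import AbundanceTable
from .selection_enrichment import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.sample_ids)
        if d.shape != (n, n):
            raise ValueError(f"distance matrix shape {d.shape} != ({n}, {n})")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if (d < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.d = (d + d.T) / 2.0
        np.fill_diagonal(self.d, 0.0)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class Ordination:
    method: str  # "NMDS" | "PCoA"
    sample_ids: list[str]
    coordinates: np.ndarray
    stress: float | None = None
    eigenvalues: np.ndarray | None = None
    seed: int | None = None
    n_restarts: int | None = None
    converged: bool = True
    stress_trace: np.ndarray | None = None
    all_stress_traces: list[np.ndarray] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        k = self.coordinates.shape[1]
        return pd.DataFrame(
            self.coordinates,
            index=self.sample_ids,
            columns=[f"axis{i + 1}" for i in range(k)],
        )


@dataclass(frozen=True)
class PermanovaResult:
    term: str
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    strata: str | None = None


@dataclass
class DispersionResult:
    sample_ids: list[str]
    groups: list[str]
    distances: np.ndarray
    group_means: dict[str, float]
    anova_F: float
    anova_p: float
    permutation_p: float
    pairwise: list[tuple[str, str, float, float]]  # (A, B, p_perm, q_BH)
    excluded_groups: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

def bray_curtis(table: AbundanceTable | pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between sample rows."""
    if isinstance(table, AbundanceTable):
        frame = table.abundance
    else:
        frame = table
    X = frame.to_numpy(dtype=float)
    ids = list(frame.index)
    totals = X.sum(axis=1)
    if (totals <= 0).any():
        bad = [ids[i] for i in np.flatnonzero(totals <= 0)]
        raise ValueError(f"rows summing to zero: {bad}")
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n - 1):
        shared = np.minimum(X[i], X[i + 1 :]).sum(axis=1)
        D[i, i + 1 :] = 1.0 - 2.0 * shared / (totals[i] + totals[i + 1 :])
    D = D + D.T
    np.clip(D, 0.0, 1.0, out=D)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(sample_ids=ids, d=D)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D**2
    row = A.mean(axis=1, keepdims=True)
    col = A.mean(axis=0, keepdims=True)
    return A - row - col + A.mean()


def _full_pcoa_axes(
    D: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All real and imaginary PCoA axes of a (possibly non-Euclidean) D.

    Returns (real_coords, imag_coords, eigenvalues_desc). Imaginary axes
    correspond to negative eigenvalues; their coordinates are scaled by
    sqrt(-lambda) and contribute *negatively* to squared distances.
    """
    B = _gower_center(D)
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-9 * max(1.0, float(np.abs(evals).max(initial=0.0)))
    pos = evals > tol
    neg = evals < -tol
    real = evecs[:, pos] * np.sqrt(evals[pos])
    imag = evecs[:, neg] * np.sqrt(-evals[neg])
    return real, imag, evals


def pcoa(D: DistanceMatrix, k: int) -> Ordination:
    """Classical (metric) scaling via Gower-centered eigendecomposition.

    Coordinates come from the top-k non-negative eigenvalues; if fewer
    positive axes exist the remainder are zero-padded with a log notice.
    """
    if k >= D.n:
        raise ValueError(f"k={k} must be < n_samples={D.n}")
    real, _, evals = _full_pcoa_axes(D.d)
    n_pos = real.shape[1]
    coords = np.zeros((D.n, k))
    usable = min(k, n_pos)
    coords[:, :usable] = real[:, :usable]
    if usable < k:
        logger.info("pcoa: only %d positive axes for k=%d; padding", n_pos, k)
    return Ordination(
        method="PCoA",
        sample_ids=list(D.sample_ids),
        coordinates=coords,
        eigenvalues=evals,
    )


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = float((d**2).sum())
    if denom == 0.0:
        return 0.0
    return math.sqrt(float(((d - dhat) ** 2).sum()) / denom)


def _disparities(d: np.ndarray, delta: np.ndarray) -> np.ndarray:
    # Primary tie treatment: within blocks of equal observed dissimilarity the
    # configuration distances are free to order themselves, so sort by
    # (delta, d) before pooling adjacent violators.
    order = np.lexsort((d, delta))
    dhat = np.empty_like(d)
    dhat[order] = isotonic_regression(d[order]).x
    return dhat


def _guttman_step(X: np.ndarray, d: np.ndarray, dhat: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d > 0, dhat / np.where(d > 0, d, 1.0), 0.0)
    B = -squareform(ratio, checks=False)
    np.fill_diagonal(B, -B.sum(axis=1))
    return (B @ X) / n


def _nmds_single(
    X0: np.ndarray, delta: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, bool]:
    X = X0.copy()

    def stress_of(Xc: np.ndarray) -> float:
        d = pdist(Xc)
        return _stress1(d, _disparities(d, delta))

    s_cur = stress_of(X)
    trace = [s_cur]
    converged = False
    for _ in range(max_iter):
        d = pdist(X)
        dhat = _disparities(d, delta)
        X_new = _guttman_step(X, d, dhat)
        s_new = stress_of(X_new)
        if s_new > s_cur:
            # Backtrack toward the current configuration; accept only a
            # non-increasing move so the stress trace is monotone.
            accepted = False
            alpha = 0.5
            while alpha > 1e-4:
                X_try = X + alpha * (X_new - X)
                s_try = stress_of(X_try)
                if s_try <= s_cur:
                    X_new, s_new, accepted = X_try, s_try, True
                    break
                alpha /= 2.0
            if not accepted:
                converged = True
                break
        improvement = s_cur - s_new
        X, s_cur = X_new, s_new
        trace.append(s_cur)
        if improvement < tol:
            converged = True
            break
    return X, np.asarray(trace), converged


def nmds(
    D: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    seed: int | None = None,
    tol: float = 1e-7,
) -> Ordination:
    """Non-metric MDS minimizing Kruskal stress-1.

    Disparities are the isotonic (pool-adjacent-violators) regression of the
    configuration distances on the rank order of the observed dissimilarities
    (primary tie treatment). One start uses the k-dimensional PCoA
    configuration; the remaining ``n_restarts - 1`` starts are random. The
    best final configuration is returned; per-restart stress traces are kept
    and each trace is non-increasing by construction. Deterministic for a
    given seed.
    """
    if D.n < k + 2:
        raise ValueError(f"NMDS needs n_samples >= k + 2 (n={D.n}, k={k})")
    rng = np.random.default_rng(seed)
    delta = D.condensed()
    scale = float(delta.mean()) or 1.0

    starts = [pcoa(D, k).coordinates]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(rng.normal(scale=scale, size=(D.n, k)))

    best: tuple[float, np.ndarray, np.ndarray, bool] | None = None
    traces: list[np.ndarray] = []
    for X0 in starts:
        X, trace, conv = _nmds_single(X0, delta, max_iter, tol)
        traces.append(trace)
        final = float(trace[-1])
        if best is None or final < best[0]:
            best = (final, X, trace, conv)
    assert best is not None
    stress, X, trace, conv = best
    # Stress-1 is scale-invariant; rescale and center the winning
    # configuration so its distances live on the scale of the data.
    X = X - X.mean(axis=0)
    d_final = pdist(X)
    if d_final.sum() > 0:
        X = X * (delta.mean() / d_final.mean())
    if not conv:
        logger.warning("nmds: best restart hit max_iter without converging")
    logger.info(
        "nmds: stress per restart: %s",
        ", ".join(f"{t[-1]:.4f}" for t in traces),
    )
    return Ordination(
        method="NMDS",
        sample_ids=list(D.sample_ids),
        coordinates=X,
        stress=stress,
        seed=seed,
        n_restarts=n_restarts,
        converged=conv,
        stress_trace=trace,
        all_stress_traces=traces,
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _pseudo_f(
    d2: np.ndarray, labels: np.ndarray, uniq: np.ndarray
) -> tuple[float, float, float]:
    """Anderson's distance-based decomposition: (F, SS_between, SS_total)."""
    n = len(labels)
    a = len(uniq)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in uniq:
        mask = labels == g
        n_g = int(mask.sum())
        ss_within += d2[np.ix_(mask, mask)].sum() / (2.0 * n_g)
    ss_between = ss_total - ss_within
    df_b, df_w = a - 1, n - a
    if df_w <= 0 or ss_within <= 0:
        return math.inf, ss_between, ss_total
    return (ss_between / df_b) / (ss_within / df_w), ss_between, ss_total


def restricted_permutations(
    labels: Sequence,
    strata: Sequence | None,
    seed: int | None,
    n: int,
) -> Iterator[np.ndarray]:
    """Yield ``n`` permuted label vectors honoring the exchangeability design.

    Without strata, labels shuffle freely. With strata there are two regimes:
    if the labels are constant within every stratum (e.g. feeding regime per
    reactor) the strata themselves are the exchangeable units and whole-block
    labels are shuffled across strata; otherwise (e.g. time within reactor)
    labels shuffle only within each stratum. In both regimes a stratum's
    samples are never split apart.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    if strata is None:
        for _ in range(n):
            yield rng.permutation(labels)
        return
    strata = np.asarray(strata)
    stratum_ids = pd.unique(strata)
    members = [np.flatnonzero(strata == s) for s in stratum_ids]
    constant = all(len(set(labels[m])) == 1 for m in members)
    if constant:
        block_labels = np.array([labels[m[0]] for m in members])
        for _ in range(n):
            shuffled = rng.permutation(block_labels)
            out = labels.copy()
            for lab, m in zip(shuffled, members):
                out[m] = lab
            yield out
    else:
        for _ in range(n):
            out = labels.copy()
            for m in members:
                out[m] = labels[m][rng.permutation(len(m))]
            yield out


def _distinct_label_arrangements(labels: np.ndarray) -> Iterator[np.ndarray]:
    """All distinct arrangements of a label multiset (exhaustive testing)."""
    seen: set[tuple] = set()
    for perm in itertools.permutations(labels):
        if perm not in seen:
            seen.add(perm)
            yield np.asarray(perm)


def permanova(
    D: DistanceMatrix,
    labels: Sequence,
    n_permutations: int | str = 999,
    strata: Sequence | None = None,
    seed: int | None = None,
    term: str = "group",
) -> PermanovaResult:
    """Distance-based one-factor PERMANOVA.

    ``pseudo_F = (SS_between / (a - 1)) / (SS_within / (n - a))`` with sums of
    squares computed from squared distances; ``p = (1 + #{F_perm >= F_obs}) /
    (1 + n_permutations)``. Pass ``n_permutations="exhaustive"`` to enumerate
    every distinct label arrangement (small designs only), in which case the
    p-value is exact. ``strata`` restricts permutations for repeated-measures
    designs (see :func:`restricted_permutations`).
    """
    labels = np.asarray(labels)
    if len(labels) != D.n:
        raise ValueError("labels length must match the distance matrix")
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs >=2 groups")
    counts = {g: int((labels == g).sum()) for g in uniq}
    empty = [g for g, c in counts.items() if c == 0]
    if empty:
        raise ValueError(f"degenerate design: empty group(s) {empty}")
    d2 = D.d**2
    f_obs, ss_b, ss_t = _pseudo_f(d2, labels, uniq)
    r2 = ss_b / ss_t if ss_t > 0 else 0.0
    ftol = 1e-12 * max(1.0, abs(f_obs)) if math.isfinite(f_obs) else 0.0

    if n_permutations == "exhaustive":
        if strata is not None:
            raise ValueError("exhaustive enumeration does not support strata")
        total = 0
        at_least = 0
        for perm in _distinct_label_arrangements(labels):
            total += 1
            f_p, _, _ = _pseudo_f(d2, perm, uniq)
            if f_p >= f_obs - ftol:
                at_least += 1
        p = at_least / total
        n_perm = total - 1  # arrangements other than the observed one
    else:
        n_perm = int(n_permutations)
        exceed = 0
        for perm in restricted_permutations(labels, strata, seed, n_perm):
            f_p, _, _ = _pseudo_f(d2, perm, uniq)
            if f_p >= f_obs - ftol:
                exceed += 1
        p = (1 + exceed) / (1 + n_perm)

    return PermanovaResult(
        term=term,
        pseudo_F=f_obs,
        R2=r2,
        p_value=p,
        n_permutations=n_perm,
        strata=None if strata is None else "restricted",
    )


# ---------------------------------------------------------------------------
# Beta dispersion (homogeneity of group dispersions)
# ---------------------------------------------------------------------------

def _anova_f(values: np.ndarray, labels: np.ndarray, uniq: Sequence) -> float:
    n = len(values)
    a = len(uniq)
    grand = values.mean()
    ss_b = 0.0
    ss_w = 0.0
    for g in uniq:
        v = values[labels == g]
        ss_b += len(v) * (v.mean() - grand) ** 2
        ss_w += ((v - v.mean()) ** 2).sum()
    if n - a <= 0 or ss_w <= 0:
        return math.inf if ss_b > 0 else 0.0
    return (ss_b / (a - 1)) / (ss_w / (n - a))


def beta_dispersion(
    D: DistanceMatrix,
    groups: Sequence,
    n_permutations: int = 999,
    seed: int | None = None,
) -> DispersionResult:
    """Within-group spread as distance to the group centroid in PCoA space.

    All PCoA axes are used; squared distances on imaginary axes (negative
    eigenvalues of the non-Euclidean embedding) are subtracted from the real
    part and the result floored at zero before taking the square root. Group
    differences are tested with a classical one-way ANOVA F on the distances
    (plus a label-permutation p for the same F) and pairwise permutation
    tests with Benjamini-Hochberg adjustment. Groups of size 1 are excluded
    from testing but their distances are still reported.
    """
    groups = np.asarray([str(g) for g in groups])
    if len(groups) != D.n:
        raise ValueError("groups length must match the distance matrix")
    real, imag, _ = _full_pcoa_axes(D.d)
    uniq = list(pd.unique(groups))
    dist = np.zeros(D.n)
    for g in uniq:
        mask = groups == g
        cr = real[mask].mean(axis=0)
        ci = imag[mask].mean(axis=0) if imag.size else np.zeros(0)
        sq = ((real[mask] - cr) ** 2).sum(axis=1)
        if imag.size:
            sq = sq - ((imag[mask] - ci) ** 2).sum(axis=1)
        dist[mask] = np.sqrt(np.maximum(sq, 0.0))

    group_means = {g: float(dist[groups == g].mean()) for g in uniq}
    testable = [g for g in uniq if (groups == g).sum() >= 2]
    excluded = [g for g in uniq if g not in testable]
    if len(testable) < 2:
        raise ValueError("beta dispersion test needs >=2 groups of size >=2")
    test_mask = np.isin(groups, testable)
    tv, tl = dist[test_mask], groups[test_mask]

    f_obs = _anova_f(tv, tl, testable)
    _, anova_p = sps.f_oneway(*[tv[tl == g] for g in testable])
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        f_p = _anova_f(tv, rng.permutation(tl), testable)
        if f_p >= f_obs - 1e-12:
            exceed += 1
    perm_p = (1 + exceed) / (1 + n_permutations)

    pairwise: list[tuple[str, str, float, float]] = []
    raw_ps: list[float] = []
    pairs = list(itertools.combinations(testable, 2))
    for ga, gb in pairs:
        va, vb = tv[tl == ga], tv[tl == gb]
        obs = abs(va.mean() - vb.mean())
        pooled = np.concatenate([va, vb])
        na = len(va)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            if abs(perm[:na].mean() - perm[na:].mean()) >= obs - 1e-12:
                count += 1
        raw_ps.append((1 + count) / (1 + n_permutations))
    qs = bh_adjust(raw_ps) if raw_ps else []
    for (ga, gb), p, q in zip(pairs, raw_ps, qs):
        pairwise.append((ga, gb, float(p), float(q)))

    return DispersionResult(
        sample_ids=list(D.sample_ids),
        groups=list(groups),
        distances=dist,
        group_means=group_means,
        anova_F=f_obs,
        anova_p=float(anova_p),
        permutation_p=perm_p,
        pairwise=pairwise,
        excluded_groups=excluded,
    )
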