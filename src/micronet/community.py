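"""Community diversity and composition statistics for ASV count tables.

Covers the standard amplicon downstream stack: per-sample rarefaction
(subsampling reads without replacement to a common depth), alpha diversity
(observed species and Shannon index, natural log by default), Bray-Curtis
dissimilarity, classical principal-coordinates analysis, and one-factor
PERMANOVA with a seeded (or exhaustive) permutation null.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .synthetic_data import AsvCounts


@dataclass(frozen=True)
class AlphaDiversity:
    observed_species: int
    shannon: float


@dataclass
class DissimilarityMatrix:
    """Square symmetric dissimilarities in [0, 1] with a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if v.shape[0] != len(self.labels):
            raise ValueError("labels do not match matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        self.values = v

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame       # sites x retained axes
    eigenvalues: np.ndarray         # all, descending (negatives retained)
    proportion_explained: np.ndarray  # positive-eigenvalue axes, sums to 1


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    method: str = "random"  # random | exhaustive


@dataclass
class RarefactionResult:
    counts: AsvCounts
    dropped: list[str]  # sample ids below the requested depth


def rarefy(counts: AsvCounts, depth: int, seed: int) -> RarefactionResult:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped and reported.  Uses a
    multivariate hypergeometric draw per sample, seeded.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    totals = counts.matrix.sum(axis=1)
    keep = totals >= depth
    dropped = [s for s, k in zip(counts.sample_ids, keep) if not k]
    rows = []
    for i in np.flatnonzero(keep):
        row = counts.matrix[i]
        if totals[i] == depth:
            rows.append(row.copy())
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth))
    mat = np.vstack(rows) if rows else np.zeros((0, len(counts.taxa_ids)), dtype=np.int64)
    new = dataclasses.replace(
        counts,
        matrix=mat,
        sample_ids=[s for s, k in zip(counts.sample_ids, keep) if k],
    )
    return RarefactionResult(new, dropped)


def alpha_diversity(sample_counts: np.ndarray, *, base: float | None = None) -> AlphaDiversity:
    """Observed species and Shannon index for one count vector.

    Shannon H = -Σ pᵢ log pᵢ over positive abundances, natural log unless
    ``base`` is given.
    """
    x = np.asarray(sample_counts, float)
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero sample has no diversity")
    p = x[x > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return AlphaDiversity(int((x > 0).sum()), h)


def alpha_diversity_table(counts: AsvCounts, *, base: float | None = None) -> pd.DataFrame:
    rows = [alpha_diversity(counts.matrix[i], base=base) for i in range(len(counts.sample_ids))]
    return pd.DataFrame(
        {
            "observed_species": [r.observed_species for r in rows],
            "shannon": [r.shannon for r in rows],
        },
        index=pd.Index(counts.sample_ids, name="site_id"),
    )


def bray_curtis(counts: AsvCounts) -> DissimilarityMatrix:
    """Bray-Curtis dissimilarity: 1 - 2 Σ min(xᵢ, yᵢ) / (Σx + Σy)."""
    if len(counts.sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    mat = counts.matrix.astype(float)
    if np.any(mat.sum(axis=1) == 0):
        raise ValueError("zero-sum sample in count table")
    d = squareform(pdist(mat, metric="braycurtis"))
    return DissimilarityMatrix(list(counts.sample_ids), d)


def pcoa(d: DissimilarityMatrix, n_axes: int = 2, *, cailliez: bool = False) -> OrdinationResult:
    """Classical scaling (principal coordinates) of a dissimilarity matrix.

    Double-centers -D²/2, eigendecomposes, and orders axes by descending
    eigenvalue.  Negative eigenvalues are retained in the report but no
    coordinates are produced for them; variance proportions are taken over
    the positive eigenvalues.  ``cailliez=True`` adds the smallest constant
    to the off-diagonal dissimilarities that makes the configuration
    Euclidean before scaling.
    """
    D = d.values
    if cailliez:
        D = D + _cailliez_constant(D) * (1.0 - np.eye(len(D)))
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    pos = eigvals > max(1e-12 * max(abs(eigvals[0]), 1.0), 0.0)
    n_pos = int(pos.sum())
    n_keep = min(n_axes, n_pos)
    coords = eigvecs[:, :n_keep] * np.sqrt(eigvals[:n_keep])
    if n_keep == 0:
        coords = np.zeros((n, n_axes))
        n_keep = n_axes
    prop = eigvals[:n_pos] / eigvals[:n_pos].sum() if n_pos else np.zeros(0)
    frame = pd.DataFrame(
        coords, index=d.labels, columns=[f"PCo{i + 1}" for i in range(coords.shape[1])]
    )
    return OrdinationResult(frame, eigvals, prop)


def _cailliez_constant(D: np.ndarray) -> float:
    """Smallest additive constant making D + c (off-diagonal) Euclidean."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B1 = -0.5 * J @ (D**2) @ J
    B2 = -0.5 * J @ D @ J
    upper = np.block([[np.zeros((n, n)), 2.0 * B1], [-np.eye(n), -4.0 * B2]])
    eigs = np.linalg.eigvals(upper)
    c = float(np.max(eigs.real))
    return max(c, 0.0)


def _ss_within(d2: np.ndarray, labels: np.ndarray) -> float:
    ss = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        ss += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ss


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, n_groups: int) -> float:
    n = len(labels)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = _ss_within(d2, labels)
    ss_among = ss_total - ss_within
    if ss_within <= 0:
        return math.inf if ss_among > 0 else 0.0
    return (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))


def _distinct_labelings(labels: np.ndarray):
    """All distinct arrangements of a label multiset (small n only)."""
    uniq, counts = np.unique(labels, return_counts=True)
    n = len(labels)
    results = []

    def build(avail: tuple[int, ...], k: int, current: dict[int, object]):
        if k == len(uniq) - 1:
            arr = np.empty(n, dtype=labels.dtype)
            for pos, lab in current.items():
                arr[pos] = lab
            for pos in avail:
                arr[pos] = uniq[k]
            results.append(arr)
            return
        for combo in itertools.combinations(avail, counts[k]):
            nxt = dict(current)
            for pos in combo:
                nxt[pos] = uniq[k]
            remaining = tuple(p for p in avail if p not in combo)
            build(remaining, k + 1, nxt)

    build(tuple(range(n)), 0, {})
    return results


def permanova(
    d: DissimilarityMatrix,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
    *,
    exhaustive: bool = False,
) -> PermanovaResult:
    """One-factor PERMANOVA on a dissimilarity matrix.

    Pseudo-F partitions the squared dissimilarities into among- and
    within-group sums of squares.  The null is built by permuting group
    labels; p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations).  With
    ``exhaustive=True`` all distinct labelings are enumerated instead and
    p = #{F >= F_obs} / #labelings (the identity included) — feasible for
    small designs only.

    Degenerate case: if all dissimilarities are zero (identical samples),
    F is reported as 0 and p as 1.
    """
    labels = np.asarray(groups)
    if len(labels) != len(d.labels):
        raise ValueError("group labels do not match the dissimilarity matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if np.any(counts < 2):
        raise ValueError("every group needs at least 2 members")
    d2 = d.values**2
    n = len(labels)
    a = len(uniq)
    f_obs = _pseudo_f(d2, labels, a)
    if d2.max() == 0.0:
        return PermanovaResult(0.0, 1.0, 0, "degenerate")

    if exhaustive:
        arrangements = _distinct_labelings(labels)
        n_total = len(arrangements)
        if n_total > 100_000:
            raise ValueError(f"{n_total} labelings is too many for exhaustive enumeration")
        ge = sum(1 for arr in arrangements if _pseudo_f(d2, arr, a) >= f_obs - 1e-12)
        return PermanovaResult(float(f_obs), ge / n_total, n_total - 1, "exhaustive")

    rng = np.random.default_rng(seed)
    # vectorize the permutation null over group-indicator matrices
    perm_idx = np.array([rng.permutation(n) for _ in range(n_permutations)])
    perm_labels = labels[perm_idx]  # (P, n)
    ss_total = d2.sum() / (2.0 * n)
    ss_w = np.zeros(n_permutations)
    for g, ng in zip(uniq, counts):
        mask = (perm_labels == g).astype(float)
        ss_w += np.einsum("pi,pj,ij->p", mask, mask, d2) / (2.0 * ng)
    ss_a = ss_total - ss_w
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = (ss_a / (a - 1)) / (ss_w / (n - a))
    ge = int(np.sum(f_perm >= f_obs - 1e-12))
    p = (1 + ge) / (1 + n_permutations)
    return PermanovaResult(float(f_obs), p, n_permutations, "random")
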