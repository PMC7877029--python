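"""Post-cleaning processing and ecological statistics.

Rarefaction to a common depth, removal of rare taxa, relativization, core
taxon detection, Bray-Curtis dissimilarity, principal coordinates analysis,
PERMANOVA and univariable redundancy analysis with permutation tests.

Permutation p-values follow the add-one convention
p = (1 + #{permuted statistic >= observed}) / (1 + n_permutations) and every
source of randomness takes an explicit seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .feature_table import FeatureTable, prevalence, relative_abundance

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# table processing
# ---------------------------------------------------------------------------

def rarefy(
    table: FeatureTable, depth: int = 8000, seed: int | np.random.Generator = 0
) -> tuple[FeatureTable, list[str]]:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped and returned
    as the second element.  Draws are multivariate hypergeometric, so
    per-taxon counts never exceed the originals; a fixed seed reproduces
    the draw exactly.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    totals = table.counts.sum(axis=0)
    keep_mask = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep_mask) if not k]
    if dropped:
        logger.info("rarefy: dropping %d samples below depth %d", len(dropped), depth)
    kept = [s for s, k in zip(table.sample_ids, keep_mask) if k]
    out = np.empty((table.n_taxa, len(kept)), dtype=np.int64)
    for j, col_idx in enumerate(np.flatnonzero(keep_mask)):
        col = table.counts[:, col_idx]
        if col.sum() == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth, method="marginals")
    return FeatureTable(list(table.taxon_ids), kept, out), dropped


def filter_low_count(
    table: FeatureTable, min_total: int = 60
) -> tuple[FeatureTable, dict]:
    """Drop taxa with grand total below ``min_total`` reads (strict).

    Returns the filtered table and a report with the removed taxa, the
    fraction of taxa removed, and the per-sample fraction of reads lost.
    """
    totals = table.counts.sum(axis=1)
    keep_mask = totals >= min_total
    removed = [t for t, k in zip(table.taxon_ids, keep_mask) if not k]
    kept = [t for t, k in zip(table.taxon_ids, keep_mask) if k]
    sample_totals = table.counts.sum(axis=0).astype(float)
    removed_reads = table.counts[~keep_mask, :].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_reads = np.where(sample_totals > 0, removed_reads / sample_totals, 0.0)
    report = {
        "removed_taxa": removed,
        "fraction_taxa_removed": len(removed) / table.n_taxa if table.n_taxa else 0.0,
        "fraction_reads_removed_per_sample": pd.Series(frac_reads, index=table.sample_ids),
    }
    return table.subset_taxa(kept), report


def relativize(table: FeatureTable, total: float = 8000.0) -> pd.DataFrame:
    """Scale each sample to a fixed total (default 8000)."""
    sums = table.counts.sum(axis=0)
    if (sums == 0).any():
        zero = [s for s, t in zip(table.sample_ids, sums) if t == 0]
        raise ValueError(f"zero-total samples cannot be relativized: {zero[:5]}")
    return pd.DataFrame(
        table.counts * (total / sums), index=table.taxon_ids, columns=table.sample_ids
    )


def core_taxa(
    table: FeatureTable,
    prevalence_min: float = 0.95,
    mean_abundance_min: float = 0.01,
) -> set[str]:
    """Taxa meeting BOTH a prevalence floor and a mean relative-abundance floor."""
    prev = prevalence(table)
    mean_ab = relative_abundance(table).mean(axis=1).reindex(table.taxon_ids).fillna(0.0)
    return {
        t for t in table.taxon_ids
        if prev[t] >= prevalence_min and mean_ab[t] >= mean_abundance_min
    }


# ---------------------------------------------------------------------------
# dissimilarity and ordination
# ---------------------------------------------------------------------------

def bray_curtis(abundances: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Bray-Curtis dissimilarity between rows (samples x taxa).

    d(i, j) = 1 - 2 sum_t min(x_it, x_jt) / (sum_t x_it + sum_t x_jt).
    """
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    if (x.sum(axis=1) == 0).any():
        raise ValueError("zero-sum rows are not allowed")
    return squareform(pdist(x, metric="braycurtis"))


@dataclass
class OrdinationResult:
    """PCoA embedding: coordinates, eigenvalues (all, descending) and the
    proportion of positive-eigenvalue inertia explained per retained axis."""

    coordinates: np.ndarray       # samples x positive axes
    eigenvalues: np.ndarray       # all eigenvalues, descending (negatives reported)
    proportion_explained: np.ndarray


def pcoa(d: np.ndarray | pd.DataFrame) -> OrdinationResult:
    """Principal coordinates of a symmetric dissimilarity matrix.

    Gower double-centering of -d^2/2 followed by a symmetric
    eigendecomposition; coordinates are eigenvectors scaled by the square
    root of their (positive) eigenvalues.  Negative eigenvalues — possible
    for semimetric input such as Bray-Curtis — are reported but contribute
    no axes.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("d must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("d must be symmetric")
    n = d.shape[0]
    a = -0.5 * d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals[0]), 1.0) * 1e-12
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    total_pos = evals[pos].sum()
    prop = evals[pos] / total_pos if total_pos > 0 else np.zeros(0)
    return OrdinationResult(coords, evals, prop)


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

@dataclass
class PermutationTestResult:
    statistic: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int


def _group_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Within-group sum of squared distances / group size, summed over groups."""
    ss_w = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        sub = d2[np.ix_(idx, idx)]
        ss_w += sub.sum() / (2.0 * idx.size)
    return ss_w


def permanova(
    d: np.ndarray | pd.DataFrame,
    grouping,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """One-way PERMANOVA on a distance matrix.

    Partitions the total sum of squared distances (SS_T = sum of squared
    pairwise distances / n) into between- and within-group parts and forms
    the pseudo-F; significance by free label permutation with the add-one
    convention.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    codes, uniques = pd.factorize(pd.Series(list(grouping)))
    if len(codes) != n:
        raise ValueError("grouping length must match distance matrix")
    a = len(uniques)
    if a < 2:
        raise ValueError("need >= 2 groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        raise ValueError("every group needs >= 2 samples")
    d2 = d ** 2
    ss_t = d2.sum() / (2.0 * n)
    ss_w = _group_ss(d2, codes, a)
    ss_b = ss_t - ss_w
    f_obs = (ss_b / (a - 1)) / (ss_w / (n - a))
    r2 = ss_b / ss_t if ss_t > 0 else 0.0
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        ss_w_p = _group_ss(d2, perm, a)
        ss_b_p = ss_t - ss_w_p
        f_p = (ss_b_p / (a - 1)) / (ss_w_p / (n - a))
        if f_p >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return PermutationTestResult(float(f_obs), float(r2), float(p), n_permutations, seed)


def _hellinger(y: np.ndarray) -> np.ndarray:
    row_sums = y.sum(axis=1, keepdims=True)
    return np.sqrt(y / np.where(row_sums > 0, row_sums, 1.0))


def _design_basis(x: pd.Series | np.ndarray) -> np.ndarray:
    """Orthonormal basis of the centered design column space for one variable."""
    if isinstance(x, pd.Series) and (x.dtype == object or isinstance(x.dtype, pd.CategoricalDtype)):
        xmat = pd.get_dummies(x).to_numpy(dtype=float)
    else:
        arr = np.asarray(x)
        if arr.dtype.kind in "OUS":
            xmat = pd.get_dummies(pd.Series(arr)).to_numpy(dtype=float)
        else:
            xmat = arr.reshape(len(arr), -1).astype(float)
    xc = xmat - xmat.mean(axis=0)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size and s[0] > 0 else 0
    if rank == 0:
        raise ValueError("explanatory variable is constant")
    return u[:, :rank]


def rda_univariable(
    y: np.ndarray | pd.DataFrame,
    x,
    n_permutations: int = 999,
    seed: int = 0,
    hellinger: bool = False,
) -> PermutationTestResult:
    """Univariable redundancy analysis with a permutation test.

    Column-centers the response (samples x taxa; optionally Hellinger-
    transformed first), projects it onto the centered design of one
    explanatory variable (categorical dummy-coded or numeric) and forms the
    pseudo-F from the fitted/residual trace ratio scaled by degrees of
    freedom.  ``r_squared`` is the constrained fraction of total variance.
    Significance by permuting the rows of the design.
    """
    y = np.asarray(y, dtype=float)
    if hellinger:
        y = _hellinger(y)
    yc = y - y.mean(axis=0)
    n = yc.shape[0]
    q = _design_basis(x)
    if q.shape[0] != n:
        raise ValueError("x length must match the number of samples")
    rank = q.shape[1]
    if n - rank - 1 <= 0:
        raise ValueError("not enough residual degrees of freedom")
    ss_tot = float(np.sum(yc ** 2))
    if ss_tot == 0:
        raise ValueError("response is constant")

    def _ss_fit(qmat: np.ndarray) -> float:
        proj = qmat.T @ yc
        return float(np.sum(proj ** 2))

    ss_fit = _ss_fit(q)
    ss_res = ss_tot - ss_fit
    f_obs = (ss_fit / rank) / (ss_res / (n - rank - 1))
    r2 = ss_fit / ss_tot
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        qp = q[rng.permutation(n), :]
        ss_fit_p = _ss_fit(qp)
        ss_res_p = ss_tot - ss_fit_p
        f_p = (ss_fit_p / rank) / (ss_res_p / (n - rank - 1))
        if f_p >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return PermutationTestResult(float(f_obs), float(r2), float(p), n_permutations, seed)
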