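"""Downstream diet-composition statistics.

Covers DNA-recovery-rate summaries, aggregation of per-individual detections
into landscape x sampling-round composition rows, the Hellinger transform,
Euclidean distances, one-factor PERMANOVA with permutations restricted
within strata, a multivariate homogeneity-of-dispersion test, and
non-metric multidimensional scaling (Kruskal stress-1).

All permutation procedures are seeded and reproducible; p-values follow the
conservative ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)`` convention, which
counts the observed labelling as one permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform


# --------------------------------------------------------------------------
# Recovery rates and count arithmetic


def recovery_rates(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum DNA recovery percentages from positives/total counts.

    ``counts`` needs columns ``positives`` and ``total``; any other columns
    are carried through.  Percentages are reported to 0.1.  Zero-total strata
    yield NaN (not estimable) rather than an error.
    """
    if (counts["positives"] > counts["total"]).any():
        raise ValueError("positives exceed totals")
    out = counts.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = 100.0 * counts["positives"] / counts["total"]
    out["rate_percent"] = rate.replace([np.inf, -np.inf], np.nan).round(1)
    return out


def recovery_ratio(counts: pd.DataFrame, numerator: str, denominator: str) -> float:
    """Ratio of recovery rates between two named strata (index labels)."""
    rates = recovery_rates(counts)["rate_percent"]
    return float(rates.loc[numerator] / rates.loc[denominator])


def complementary_trap_share(
    species_total: int, n_focal_trap: int, n_other_trap: int, other_share_percent: float
) -> float:
    """Share (%) of a species in one trap type from its share in the other.

    With ``species_total`` individuals of the species over both trap types,
    ``n_other_trap`` individuals (all species) in the other trap type of
    which ``other_share_percent`` belong to the species, the remainder of
    the species must sit in the focal trap type.
    """
    in_other = other_share_percent / 100.0 * n_other_trap
    return 100.0 * (species_total - in_other) / n_focal_trap


def taxon_frequencies(
    presence: pd.DataFrame, groups: pd.Series | None = None
) -> pd.DataFrame:
    """Percent of positive individuals containing each taxon.

    Rows of ``presence`` are individuals, columns taxa, cells 0/1.  Only
    individuals positive for at least one taxon enter the denominator.
    With ``groups`` (per-individual labels) a column per group is added.
    """
    pos = presence[presence.sum(axis=1) > 0]
    out = pd.DataFrame({"overall": 100.0 * pos.mean(axis=0)})
    if groups is not None:
        for g, idx in pos.groupby(groups.reindex(pos.index)).groups.items():
            out[g] = 100.0 * pos.loc[idx].mean(axis=0)
    return out


# --------------------------------------------------------------------------
# Composition matrix


@dataclass
class CompositionMatrix:
    """Proportions of detected taxa per landscape x sampling-round unit."""

    proportions: pd.DataFrame  # rows = units, columns = taxa
    units: pd.DataFrame  # per-row factor labels (landscape, round, species, ...)
    excluded: list[str]  # individuals dropped for missing metadata


def composition_matrix(
    presence: pd.DataFrame,
    metadata: pd.DataFrame,
    factors: Sequence[str] = ("landscape", "round", "species"),
) -> CompositionMatrix:
    """Aggregate per-individual detections into per-unit detection proportions.

    ``presence`` rows are individuals (0/1 per taxon); ``metadata`` is
    indexed by individual with the factor columns.  Detections are summed
    per unit and converted to within-row proportions; all-zero units are
    retained as zero rows.
    """
    known = presence.index.intersection(metadata.dropna(subset=list(factors)).index)
    excluded = [str(i) for i in presence.index.difference(known)]
    counts = presence.loc[known].groupby(
        [metadata.loc[known, f] for f in factors]
    ).sum()
    row_sums = counts.sum(axis=1)
    props = counts.div(row_sums.replace(0, 1), axis=0)
    units = pd.DataFrame(
        list(counts.index), columns=list(factors), index=range(len(counts))
    )
    props.index = units.index
    return CompositionMatrix(props, units, excluded)


def hellinger(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Hellinger transform: sqrt of within-row proportions; zero rows stay zero."""
    arr = np.asarray(matrix, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative cells are not allowed")
    row_sums = arr.sum(axis=1, keepdims=True)
    out = np.sqrt(np.divide(arr, np.where(row_sums == 0, 1.0, row_sums)))
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def euclidean_distances(matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Square symmetric Euclidean distance matrix between rows."""
    return squareform(pdist(np.asarray(matrix, dtype=float), metric="euclidean"))


# --------------------------------------------------------------------------
# PERMANOVA


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    strata: str = ""


def _pseudo_f(d2: np.ndarray, inv: np.ndarray, n_groups: int) -> float:
    """One-factor adonis pseudo-F from squared distances and group codes."""
    n = len(inv)
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = inv == g
        ng = int(idx.sum())
        if ng > 1:
            ss_within += d2[np.ix_(idx, idx)].sum() / (2 * ng)
    ss_among = ss_total - ss_within
    return (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))


def _strata_permutation(
    inv: np.ndarray, strata: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    out = inv.copy()
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        out[idx] = inv[idx[rng.permutation(len(idx))]]
    return out


def permanova(
    dist: np.ndarray,
    groups: Sequence,
    strata: Sequence | None = None,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix, permuting within strata.

    The pseudo-F comes from the among/within partition of squared
    distances; permutations shuffle group labels only within each stratum so
    stratum-level differences cannot masquerade as group effects.
    """
    dist = np.asarray(dist, dtype=float)
    groups = np.asarray(groups)
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise ValueError("distance matrix must be square")
    labels, inv = np.unique(groups, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    strata_arr = (
        np.zeros(n, dtype=int) if strata is None else np.unique(strata, return_inverse=True)[1]
    )
    for s in np.unique(strata_arr):
        if len(np.unique(inv[strata_arr == s])) < 2:
            warnings.warn(
                f"stratum {s} holds a single group level; it contributes no "
                "permutation freedom"
            )
    d2 = dist**2
    f_obs = _pseudo_f(d2, inv, len(labels))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = _strata_permutation(inv, strata_arr, rng)
        if _pseudo_f(d2, perm, len(labels)) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(
        float(f_obs), float(p), n_perm, "" if strata is None else "stratified"
    )


# --------------------------------------------------------------------------
# Multivariate dispersion (betadisper-style)


@dataclass(frozen=True)
class DispersionResult:
    f_stat: float
    p_value: float
    n_permutations: int
    group_distances: dict  # group label -> mean distance to centroid


def _pcoa(dist: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate axes split into real and imaginary parts.

    Negative eigenvalues of the Gower-centered matrix yield imaginary axes
    whose squared contributions are subtracted from distances (the standard
    correction for semi-metric dissimilarities).
    """
    n = dist.shape[0]
    a = -0.5 * dist**2
    row = a.mean(axis=1, keepdims=True)
    g = a - row - row.T + a.mean()
    w, v = np.linalg.eigh(g)
    tol = 1e-8 * max(abs(w).max(), 1.0)
    pos, neg = w > tol, w < -tol
    real = v[:, pos] * np.sqrt(w[pos])
    imag = v[:, neg] * np.sqrt(-w[neg])
    return real, imag


def _dists_to_centroids(
    real: np.ndarray, imag: np.ndarray, groups: np.ndarray
) -> np.ndarray:
    z = np.empty(len(groups))
    for g in np.unique(groups):
        idx = groups == g
        dr = real[idx] - real[idx].mean(axis=0)
        d2 = (dr**2).sum(axis=1)
        if imag.size:
            di = imag[idx] - imag[idx].mean(axis=0)
            d2 = d2 - (di**2).sum(axis=1)
        z[idx] = np.sqrt(np.maximum(d2, 0.0))
    return z


def centroid_distances(dist: np.ndarray, groups: Sequence) -> np.ndarray:
    """Per-row distance to its group centroid in principal-coordinate space."""
    real, imag = _pcoa(np.asarray(dist, dtype=float))
    return _dists_to_centroids(real, imag, np.asarray(groups))


def _anova_f(z: np.ndarray, inv: np.ndarray, n_groups: int) -> float:
    n = len(z)
    grand = z.mean()
    ss_among = ss_within = 0.0
    for g in range(n_groups):
        zg = z[inv == g]
        ss_among += len(zg) * (zg.mean() - grand) ** 2
        ss_within += ((zg - zg.mean()) ** 2).sum()
    return (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))


def dispersion_test(
    dist: np.ndarray,
    groups: Sequence,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> DispersionResult:
    """Permutation test for homogeneity of multivariate dispersions.

    Rows are embedded by principal coordinates; each row's distance to its
    group centroid is compared across groups with a one-way F statistic, and
    the null distribution is built by permuting group labels and recomputing
    centroid distances.  Groups of size 1 are excluded with a warning.
    """
    dist = np.asarray(dist, dtype=float)
    groups = np.asarray(groups)
    sizes = pd.Series(groups).value_counts()
    singletons = sizes[sizes < 2].index.tolist()
    if singletons:
        warnings.warn(f"excluding single-member groups: {singletons}")
        keep = ~np.isin(groups, singletons)
        dist, groups = dist[np.ix_(keep, keep)], groups[keep]
    labels, inv = np.unique(groups, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups of size >= 2")
    real, imag = _pcoa(dist)
    z_obs = _dists_to_centroids(real, imag, inv)
    f_obs = _anova_f(z_obs, inv, len(labels))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = inv[rng.permutation(len(inv))]
        z = _dists_to_centroids(real, imag, perm)
        if _anova_f(z, perm, len(labels)) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    means = {
        str(lab): float(z_obs[inv == g].mean()) for g, lab in enumerate(labels)
    }
    return DispersionResult(float(f_obs), float(p), n_perm, means)


# --------------------------------------------------------------------------
# NMDS


@dataclass
class NmdsResult:
    coordinates: np.ndarray  # n x k, centered
    stress: float  # Kruskal stress-1
    converged: bool
    degenerate: bool = False


def _stress1(e: np.ndarray, dhat: np.ndarray) -> float:
    denom = (e**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((e - dhat) ** 2).sum() / denom))


def nmds(
    dist: np.ndarray,
    k: int = 2,
    n_starts: int = 20,
    seed: int | np.random.Generator | None = None,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> NmdsResult:
    """Non-metric MDS minimizing Kruskal stress-1.

    Alternates monotone (isotonic) regression of embedded distances on the
    input dissimilarity order with Guttman-transform configuration updates;
    the first start is seeded from principal coordinates, the rest are
    random, and the lowest-stress solution wins.
    """
    from sklearn.isotonic import IsotonicRegression

    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if n < k + 1:
        raise ValueError("need at least k+1 rows")
    iu = np.triu_indices(n, 1)
    d = dist[iu]
    if np.allclose(d, d[0]):
        real, _ = _pcoa(dist)
        coords = real[:, :k] if real.shape[1] >= k else np.zeros((n, k))
        return NmdsResult(coords - coords.mean(axis=0), 0.0, True, degenerate=True)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = np.argsort(d, kind="stable")
    iso = IsotonicRegression(increasing=True)
    ranks = np.arange(len(d), dtype=float)

    best: NmdsResult | None = None
    for s in range(n_starts):
        if s == 0:
            real, _ = _pcoa(dist)
            x = real[:, :k] if real.shape[1] >= k else rng.normal(size=(n, k))
            if x.shape[1] < k:
                x = np.hstack([x, rng.normal(size=(n, k - x.shape[1]))])
        else:
            x = rng.normal(size=(n, k))
        prev = np.inf
        converged = False
        for _ in range(max_iter):
            e_mat = squareform(pdist(x))
            e = e_mat[iu]
            dhat = np.empty_like(e)
            dhat[order] = iso.fit(ranks, e[order]).predict(ranks)
            stress = _stress1(e, dhat)
            if stress > prev + 1e-12:
                break
            if prev - stress < tol:
                prev = stress
                converged = True
                break
            prev = stress
            # Guttman transform with target distances dhat
            dhat_mat = np.zeros((n, n))
            dhat_mat[iu] = dhat
            dhat_mat += dhat_mat.T
            with np.errstate(divide="ignore", invalid="ignore"):
                b = np.where(e_mat > 0, -dhat_mat / e_mat, 0.0)
            np.fill_diagonal(b, 0.0)
            np.fill_diagonal(b, -b.sum(axis=1))
            x = (b @ x) / n
        if best is None or prev < best.stress:
            coords = x - x.mean(axis=0)
            best = NmdsResult(coords, float(prev), converged)
    return best
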