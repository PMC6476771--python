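"""Habitat x trait ordination and seasonal dissimilarity tests.

Correspondence analysis (CA) decomposes the Pearson chi-square structure
of a contingency table: with relative frequencies P = X/n, row masses r
and column masses c, the matrix of standardised residuals

    S = D_r^{-1/2} (P - r c^T) D_c^{-1/2}

is factored by SVD; squared singular values are the principal inertias
(summing to chi^2/n) and principal coordinates place habitats and traits
in a common space.  The deviation table (observed minus expected counts,
both margins summing to zero) shows which habitat-trait combinations
drive the inertia.

Seasonal differences in availability (FAP) and consumption (MCS)
profiles are tested with PERMANOVA on Bray-Curtis dissimilarities
(months as replicates, seasons as groups), backed by a permutation test
of multivariate dispersion homogeneity (distances to group centroids in
the principal-coordinate embedding).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from scipy.spatial.distance import pdist

from .core import ValidationError


# ---------------------------------------------------------------- contingency


def build_contingency(
    plots: pd.DataFrame,
    assignment: pd.DataFrame | None = None,
    by: str = "trait",
) -> tuple[pd.DataFrame, int]:
    """Habitat x trait (or habitat x taxon) stem-count table.

    With ``by="trait"`` each cell sums stems of all taxa carrying that
    consumption trait in plots of that habitat; taxa with trait "none"
    are excluded.  Plots left without a single stem of an included taxon
    are dropped; their number is returned alongside the table.
    """
    if by not in ("trait", "taxon"):
        raise ValidationError(f"by must be 'trait' or 'taxon', got {by!r}")
    df = plots.copy()
    if by == "trait":
        if assignment is None:
            raise ValidationError("trait contingency needs a trait assignment")
        trait_of = assignment["trait"]
        df["unit"] = df["taxon"].map(trait_of)
        df = df[df["unit"].notna() & (df["unit"] != "none")]
    else:
        if assignment is not None:
            keep = assignment.index[assignment["trait"] != "none"]
            df = df[df["taxon"].isin(keep)]
        df["unit"] = df["taxon"]

    per_plot = df.groupby("plot_id")["stems"].sum()
    nonempty = set(per_plot[per_plot > 0].index)
    n_excluded = plots["plot_id"].nunique() - len(nonempty)
    df = df[df["plot_id"].isin(nonempty)]

    table = (
        df.groupby(["habitat", "unit"])["stems"].sum().unstack(fill_value=0)
    )
    if table.size == 0 or table.to_numpy().sum() == 0:
        raise ValidationError("contingency table has no nonzero cells")
    return table, n_excluded


# ------------------------------------------------------------------------ CA


@dataclass
class CAResult:
    """Correspondence analysis of a two-way contingency table."""

    row_coords: pd.DataFrame      # principal coordinates, rows
    col_coords: pd.DataFrame      # principal coordinates, columns
    singular_values: np.ndarray
    inertia: np.ndarray           # per-axis principal inertias
    inertia_pct: np.ndarray       # percent of total inertia per axis
    total_inertia: float          # = Pearson chi2 / n
    deviations: pd.DataFrame      # observed - expected counts


def correspondence_analysis(table: pd.DataFrame, tol: float = 1e-12) -> CAResult:
    """SVD-based correspondence analysis in symmetric (principal) scaling."""
    X = table.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValidationError("CA needs at least a 2 x 2 table")
    if (X < 0).any():
        raise ValidationError("CA input must be nonnegative")
    n = X.sum()
    if n <= 0:
        raise ValidationError("CA input has zero grand total")
    r = X.sum(axis=1) / n
    c = X.sum(axis=0) / n
    if (r == 0).any() or (c == 0).any():
        raise ValidationError("CA input has an all-zero row or column")

    P = X / n
    E = np.outer(r, c)
    S = (P - E) / np.sqrt(E)
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)

    keep = sv > np.sqrt(tol)
    k = min(int(keep.sum()), min(X.shape) - 1)
    sv = sv[:k]
    U, Vt = U[:, :k], Vt[:k, :]

    inertia = sv**2
    total = float(inertia.sum())
    pct = 100.0 * inertia / total if total > 0 else np.zeros(k)

    axes = [f"axis{i + 1}" for i in range(k)]
    F = (U * sv) / np.sqrt(r)[:, None]
    G = (Vt.T * sv) / np.sqrt(c)[:, None]
    row_coords = pd.DataFrame(F, index=table.index, columns=axes)
    col_coords = pd.DataFrame(G, index=table.columns, columns=axes)

    deviations = pd.DataFrame(
        X - n * E, index=table.index, columns=table.columns
    )
    return CAResult(
        row_coords=row_coords,
        col_coords=col_coords,
        singular_values=sv,
        inertia=inertia,
        inertia_pct=pct,
        total_inertia=total,
        deviations=deviations,
    )


# ------------------------------------------------------------- dissimilarity


def bray_curtis(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between the rows of *profiles*.

    d(j, k) = sum_i |x_ij - x_ik| / sum_i (x_ij + x_ik), in [0, 1] for
    nonnegative data.  A pair of all-zero rows has an undefined ratio;
    it is reported as 0 with a warning.
    """
    X = profiles.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValidationError("Bray-Curtis input must be nonnegative")
    with np.errstate(invalid="ignore"):
        d = pdist(X, metric="braycurtis")
    if np.isnan(d).any():
        warnings.warn(
            "zero-sum row pair(s): Bray-Curtis undefined, reported as 0",
            stacklevel=2,
        )
        d = np.nan_to_num(d, nan=0.0)
    return pd.DataFrame(
        squareform(d), index=profiles.index, columns=profiles.index
    )


# ----------------------------------------------------------------- PERMANOVA


@dataclass
class DistanceTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    method: str


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    """Pseudo-F from squared distances and integer group labels."""
    N = d2.shape[0]
    a = len(groups)
    ss_total = d2[np.triu_indices(N, k=1)].sum() / N
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        n_g = len(idx)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(n_g, k=1)].sum() / n_g
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / (a - 1)) / (ss_within / (N - a))


def _check_groups(dist: pd.DataFrame | np.ndarray, groups) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    labels, counts = np.unique(np.asarray(groups), return_counts=True)
    if len(labels) < 2:
        raise ValidationError("need at least two groups")
    if (counts < 2).any():
        bad = labels[counts < 2].tolist()
        raise ValidationError(f"singleton group(s): {bad}")
    if len(groups) != d.shape[0]:
        raise ValidationError("groups length must match distance matrix")
    codes = np.searchsorted(labels, np.asarray(groups))
    return d, codes, np.arange(len(labels))


def permanova(
    dist: pd.DataFrame | np.ndarray,
    groups,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
    method: str = "permutation",
) -> DistanceTestResult:
    """One-factor PERMANOVA on a distance matrix.

    ``method="permutation"`` draws *n_perm* random label permutations and
    reports p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    ``method="exact"`` enumerates every distinct assignment of the label
    multiset (feasible only for small N) and reports the exact
    proportion of assignments with F >= F_obs.
    """
    d, codes, group_ids = _check_groups(dist, groups)
    d2 = d**2
    f_obs = _pseudo_f(d2, codes, group_ids)
    eps = 1e-12

    if method == "exact":
        n_ge = 0
        total = 0
        seen_count: dict[tuple, None] = {}
        for perm in set(itertools.permutations(codes.tolist())):
            total += 1
            if _pseudo_f(d2, np.array(perm), group_ids) >= f_obs - eps:
                n_ge += 1
        return DistanceTestResult(f_obs, n_ge / total, total, "exact")
    if method != "permutation":
        raise ValidationError(f"unknown method {method!r}")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    f_perm = _pseudo_f_batch(d2, codes, group_ids, n_perm, rng)
    n_ge = int((f_perm >= f_obs - eps).sum())
    p = (1 + n_ge) / (1 + n_perm)
    return DistanceTestResult(f_obs, p, n_perm, "permutation")


def _pseudo_f_batch(
    d2: np.ndarray,
    codes: np.ndarray,
    group_ids: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pseudo-F for *n_perm* random label permutations, vectorised."""
    N = d2.shape[0]
    a = len(group_ids)
    ss_total = d2[np.triu_indices(N, k=1)].sum() / N
    perms = np.argsort(rng.random((n_perm, N)), axis=1)
    labels = codes[perms]                              # (n_perm, N)
    onehot = (labels[:, :, None] == group_ids).astype(float)
    # per-group sum of all ordered within-group pairs, halved
    pair = np.einsum("pia,pja,ij->pa", onehot, onehot, d2) / 2.0
    sizes = np.bincount(codes, minlength=a).astype(float)
    ss_within = (pair / sizes).sum(axis=1)
    ss_between = ss_total - ss_within
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / (a - 1)) / (ss_within / (N - a))
    f[np.isnan(f)] = 0.0
    return f


# ------------------------------------------------------- dispersion (PERMDISP)


def _pcoa_embedding(d: np.ndarray, tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate embedding split into real and imaginary parts.

    Returns (real axes scaled by sqrt(lambda), imaginary axes scaled by
    sqrt(-lambda)); squared distances in the embedding are
    ||dx_real||^2 - ||dx_imag||^2, the standard correction for
    non-Euclidean dissimilarities.
    """
    N = d.shape[0]
    A = -0.5 * d**2
    J = np.eye(N) - np.ones((N, N)) / N
    B = J @ A @ J
    B = (B + B.T) / 2
    lam, V = np.linalg.eigh(B)
    scale = np.max(np.abs(lam)) if N else 1.0
    pos = lam > tol * max(scale, 1.0)
    neg = lam < -tol * max(scale, 1.0)
    real = V[:, pos] * np.sqrt(lam[pos])
    imag = V[:, neg] * np.sqrt(-lam[neg])
    return real, imag


def centroid_distances(dist: pd.DataFrame | np.ndarray, groups) -> np.ndarray:
    """Each observation's distance to its own group centroid (PERMDISP z)."""
    d, codes, group_ids = _check_groups(dist, groups)
    real, imag = _pcoa_embedding(d)
    z = np.empty(d.shape[0])
    for g in group_ids:
        idx = np.flatnonzero(codes == g)
        cr = real[idx].mean(axis=0)
        ci = imag[idx].mean(axis=0) if imag.size else np.zeros(0)
        dr2 = ((real[idx] - cr) ** 2).sum(axis=1)
        di2 = ((imag[idx] - ci) ** 2).sum(axis=1) if imag.size else 0.0
        z[idx] = np.sqrt(np.maximum(dr2 - di2, 0.0))
    return z


def _anova_f(z: np.ndarray, codes: np.ndarray, group_ids: np.ndarray) -> float:
    grand = z.mean()
    ssb = sum(
        len(np.flatnonzero(codes == g)) * (z[codes == g].mean() - grand) ** 2
        for g in group_ids
    )
    ssw = sum(((z[codes == g] - z[codes == g].mean()) ** 2).sum() for g in group_ids)
    a, N = len(group_ids), len(z)
    if ssw <= 0:
        return np.inf if ssb > 1e-12 else 0.0
    return (ssb / (a - 1)) / (ssw / (N - a))


def dispersion_homogeneity(
    dist: pd.DataFrame | np.ndarray,
    groups,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> DistanceTestResult:
    """Permutation test of homogeneity of multivariate dispersions.

    The one-way ANOVA F on distances-to-centroid is recomputed under
    random permutations of those distances across groups.  Degenerate
    input with zero between- and within-group spread yields F = 0, p = 1.
    """
    d, codes, group_ids = _check_groups(dist, groups)
    z = centroid_distances(dist, groups)
    f_obs = _anova_f(z, codes, group_ids)
    if f_obs == 0.0:
        return DistanceTestResult(0.0, 1.0, n_perm, "permutation")
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        if _anova_f(z, rng.permutation(codes), group_ids) >= f_obs - 1e-12:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_perm)
    return DistanceTestResult(f_obs, p, n_perm, "permutation")
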