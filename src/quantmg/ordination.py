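"""Community ordination and permutation tests, implemented first-party.

The composition workflow mirrors the standard compositional recipe for
spike-in family tables: percent composition per sample, restriction to the
top-N families, zero replacement with a small constant (0.001, in percent
units, so the log floor is -3), log10 transform, then a centered and scaled
principal component analysis.  Group structure is tested with a one-way
PERMANOVA on square-root-transformed proportions under Bray–Curtis
dissimilarity, guarded by a homogeneity-of-dispersion permutation test in
principal-coordinate space (with the usual negative-eigenvalue correction
for semimetric distances).

All of PCA, Bray–Curtis, PERMANOVA and the PCoA-based dispersion test are
computed here with numpy/scipy linear algebra rather than delegated, so the
algorithms are inspectable and deterministic under a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import relative_abundance, top_n_families

__all__ = [
    "CompositionMatrix",
    "OrdinationResult",
    "PermanovaResult",
    "DispersionResult",
    "composition_matrix",
    "pca",
    "bray_curtis",
    "pcoa",
    "permanova",
    "permanova_from_distance",
    "dispersion_test",
]


@dataclass
class CompositionMatrix:
    """Samples × families matrix of log10 percent composition."""

    data: pd.DataFrame                 # samples x families, log10 percent
    top_families: list = field(default_factory=list)
    zero_sub: float = 0.001            # percent units
    dropped_samples: list = field(default_factory=list)


@dataclass
class OrdinationResult:
    scores: pd.DataFrame               # samples x components
    loadings: pd.DataFrame             # variables x components
    variance_explained: np.ndarray     # fraction per component, sums to 1
    dropped_variables: list = field(default_factory=list)


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    seed: int | None


@dataclass
class DispersionResult:
    F: float
    p_value: float
    deviations: pd.Series              # per-sample distance to group centroid
    group_means: pd.Series
    n_permutations: int
    seed: int | None


def composition_matrix(
    family_table: pd.DataFrame,
    top_n: int = 100,
    zero_sub: float = 0.001,
) -> CompositionMatrix:
    """Log10 percent-composition matrix restricted to the top-N families.

    Percentages are computed on the *full* family table (so the restricted
    columns keep their community-wide proportions), zeros are replaced by
    ``zero_sub`` percent, and log10 is applied.  Samples whose column total
    is zero are dropped with a warning.
    """
    totals = family_table.sum(axis=0)
    zero_cols = list(family_table.columns[totals == 0])
    if zero_cols:
        warnings.warn(f"dropping zero-total samples: {zero_cols}", stacklevel=2)
        family_table = family_table.drop(columns=zero_cols)
    pct = relative_abundance(family_table)
    top, _ = top_n_families(family_table, top_n)
    pct = pct.loc[top]
    pct = pct.where(pct > 0, zero_sub)
    logged = np.log10(pct).T  # samples x families
    return CompositionMatrix(
        data=logged, top_families=top, zero_sub=zero_sub, dropped_samples=zero_cols
    )


def pca(
    matrix: pd.DataFrame | CompositionMatrix,
    center: bool = True,
    scale: bool = True,
) -> OrdinationResult:
    """Principal component analysis by SVD of the standardized matrix.

    With ``scale=True`` every variable is normalized to unit standard
    deviation so all families weigh equally; zero-variance columns cannot be
    scaled and are dropped with a warning.  The sign of each component is
    fixed so its largest-magnitude loading is positive.  Variance-explained
    fractions come from the squared singular values and sum to 1 over the
    retained components (at most min(n_samples − 1, n_variables)).
    """
    X = matrix.data if isinstance(matrix, CompositionMatrix) else matrix
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 samples")
    Xv = X.to_numpy(dtype=float)
    dropped: list = []
    if scale:
        sd = Xv.std(axis=0, ddof=1)
        keep = sd > 0
        dropped = list(X.columns[~keep])
        if dropped:
            warnings.warn(f"dropping zero-variance variables: {dropped}", stacklevel=2)
        Xv = Xv[:, keep]
        cols = X.columns[keep]
    else:
        cols = X.columns
    if center:
        Xv = Xv - Xv.mean(axis=0)
    if scale:
        Xv = Xv / Xv.std(axis=0, ddof=1)
    n, p = Xv.shape
    U, s, Vt = np.linalg.svd(Xv, full_matrices=False)
    k = min(n - 1, p)
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(k):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    comp = [f"PC{j + 1}" for j in range(k)]
    scores = pd.DataFrame(U * s, index=X.index, columns=comp)
    loadings = pd.DataFrame(Vt.T, index=cols, columns=comp)
    var = s**2
    return OrdinationResult(
        scores=scores,
        loadings=loadings,
        variance_explained=var / var.sum(),
        dropped_variables=dropped,
    )


def bray_curtis(matrix) -> np.ndarray:
    """Bray–Curtis dissimilarity matrix of non-negative sample rows.

    d(i,j) = Σ_k |x_ik − x_jk| / Σ_k (x_ik + x_jk) ∈ [0, 1]; symmetric with a
    zero diagonal.  A pair of all-zero samples has an undefined numerator and
    denominator and is assigned distance 0 with a warning.  Bray–Curtis is a
    semimetric: the triangle inequality is not guaranteed.
    """
    X = np.asarray(matrix, dtype=float)
    if (X < 0).any():
        raise ValueError("Bray–Curtis requires non-negative values")
    diff = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    denom = (X[:, None, :] + X[None, :, :]).sum(axis=2)
    zero_pairs = denom == 0
    if zero_pairs.sum() > X.shape[0]:  # off-diagonal zeros
        warnings.warn(
            "all-zero sample pair(s): Bray–Curtis defined as 0", stacklevel=2
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(zero_pairs, 0.0, diff / np.where(zero_pairs, 1.0, denom))
    np.fill_diagonal(d, 0.0)
    return d


def _group_indicator(groups) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(groups)
    levels, codes = np.unique(labels, return_inverse=True)
    return levels, codes


def _permanova_stats(D2: np.ndarray, codes: np.ndarray, n_groups: int):
    """Pseudo-F and R² from a squared-distance matrix and group codes.

    SS_total = Σ_{i<j} d²_ij / n ; SS_within = Σ_g Σ_{i<j∈g} d²_ij / n_g ;
    F = (SS_between/(g−1)) / (SS_within/(n−g)).
    """
    n = D2.shape[0]
    ss_total = D2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = codes == g
        ng = idx.sum()
        ss_within += D2[np.ix_(idx, idx)].sum() / (2.0 * ng)
    ss_between = ss_total - ss_within
    F = (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))
    return F, ss_between / ss_total


def _permuted_F(D2: np.ndarray, codes: np.ndarray, n_groups: int, perms: np.ndarray):
    """Pseudo-F for each row of permuted codes, vectorized over permutations."""
    n = D2.shape[0]
    ss_total = D2.sum() / (2.0 * n)
    ss_within = np.zeros(perms.shape[0])
    for g in range(n_groups):
        M = (perms == g).astype(float)          # n_perm x n
        ng = M.sum(axis=1)
        quad = np.einsum("pi,ij,pj->p", M, D2, M)
        ss_within += quad / (2.0 * ng)
    ss_between = ss_total - ss_within
    return (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova_from_distance(
    D: np.ndarray,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a precomputed dissimilarity matrix.

    The permutation null relabels samples (group labels permuted, not rows of
    the distance matrix) with ``numpy.random.default_rng(seed)``; the p-value
    uses the standard add-one rule p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm),
    so p ≥ 1/(n_perm + 1).
    """
    D = np.asarray(D, dtype=float)
    levels, codes = _group_indicator(groups)
    if len(levels) < 2:
        raise ValueError("PERMANOVA requires at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        raise ValueError(f"every group needs >= 2 samples, sizes: {dict(zip(levels, sizes))}")
    D2 = D**2
    F_obs, R2 = _permanova_stats(D2, codes, len(levels))
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(codes) for _ in range(n_perm)])
    F_perm = _permuted_F(D2, codes, len(levels), perms)
    p = (1.0 + np.sum(F_perm >= F_obs)) / (1.0 + n_perm)
    return PermanovaResult(
        pseudo_F=float(F_obs), R2=float(R2), p_value=float(p),
        n_permutations=n_perm, seed=seed,
    )


def permanova(
    proportions: pd.DataFrame,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    sqrt_transform: bool = True,
) -> PermanovaResult:
    """PERMANOVA on sample compositions: square-root transform, Bray–Curtis
    dissimilarity, then the permutation test of
    :func:`permanova_from_distance`.

    ``proportions`` is samples × families, non-negative (proportions or
    percentages; Bray–Curtis on sqrt values is scale-dependent, so supply the
    same units for every sample).
    """
    X = np.asarray(proportions, dtype=float)
    if sqrt_transform:
        X = np.sqrt(X)
    return permanova_from_distance(bray_curtis(X), groups, n_perm=n_perm, seed=seed)


def pcoa(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinates of a dissimilarity matrix.

    Eigendecomposition of the Gower-centered matrix −½ J D² J.  Returns
    ``(coordinates, eigenvalues)`` with eigenvalues sorted descending;
    *negative* eigenvalues — expected for semimetric inputs like Bray–Curtis
    — are retained, their axes scaled by √|λ| ("imaginary" axes used for the
    dispersion correction).  Zero eigenvalues are dropped.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J
    G = (G + G.T) / 2.0
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = np.abs(evals) > max(1e-10 * np.abs(evals).max(), 1e-14)
    evals, evecs = evals[keep], evecs[:, keep]
    coords = evecs * np.sqrt(np.abs(evals))
    return coords, evals


def dispersion_test(
    D: np.ndarray,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    sample_ids=None,
) -> DispersionResult:
    """Homogeneity of multivariate dispersion (betadisper-style).

    Samples are embedded by principal coordinates; each sample's deviation is
    its distance to its group centroid, with squared deviations on the
    negative-eigenvalue ("imaginary") axes *subtracted* from those on the
    positive axes — the standard correction for semimetric distances — and
    floored at 0 before the square root.  The test statistic is the one-way
    ANOVA F on the deviations; the null distribution permutes group labels
    over the fixed deviations.
    """
    D = np.asarray(D, dtype=float)
    levels, codes = _group_indicator(groups)
    if len(levels) < 2:
        raise ValueError("dispersion test requires at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        raise ValueError(f"every group needs >= 2 samples, sizes: {dict(zip(levels, sizes))}")
    coords, evals = pcoa(D)
    pos = evals > 0
    dev2 = np.zeros(D.shape[0])
    for g in range(len(levels)):
        idx = codes == g
        centroid = coords[idx].mean(axis=0)
        diff2 = (coords[idx] - centroid) ** 2
        dev2[idx] = diff2[:, pos].sum(axis=1) - diff2[:, ~pos].sum(axis=1)
    dev = np.sqrt(np.maximum(dev2, 0.0))

    def anova_F(codes_: np.ndarray) -> float:
        grand = dev.mean()
        ssb = ssw = 0.0
        for g in range(len(levels)):
            x = dev[codes_ == g]
            ssb += x.size * (x.mean() - grand) ** 2
            ssw += ((x - x.mean()) ** 2).sum()
        dfb = len(levels) - 1
        dfw = dev.size - len(levels)
        if ssw == 0:
            return 0.0 if ssb == 0 else np.inf
        return (ssb / dfb) / (ssw / dfw)

    F_obs = anova_F(codes)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if anova_F(rng.permutation(codes)) >= F_obs:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    index = sample_ids if sample_ids is not None else np.arange(D.shape[0])
    deviations = pd.Series(dev, index=index, name="deviation")
    group_means = pd.Series(
        [dev[codes == g].mean() for g in range(len(levels))], index=levels
    )
    return DispersionResult(
        F=float(F_obs), p_value=float(p), deviations=deviations,
        group_means=group_means, n_permutations=n_perm, seed=seed,
    )
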