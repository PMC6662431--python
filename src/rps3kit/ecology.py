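"""Community dissimilarity, ordination, and environmental statistics.

Implements the downstream ecological toolkit applied to the marker-based
abundance matrix: Bray–Curtis and (un)weighted UniFrac dissimilarities,
principal-coordinates analysis and non-metric multidimensional scaling,
BIOENV selection of the environmental-variable subset whose Euclidean
distances best correlate with community dissimilarity, the Mantel
permutation test, and simple covariate correlation/regression.

Distance matrices are :class:`skbio.DistanceMatrix` objects throughout;
trees are :class:`skbio.TreeNode`. Permutation p-values use the add-one
convention, ``p = (1 + #{permuted >= observed}) / (1 + n_perm)``, and are
one-sided (greater) as is standard for Mantel.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from sklearn.manifold import smacof

from .errors import ConfigError, InputError
from .quant import AbundanceMatrix

logger = logging.getLogger(__name__)


@dataclass
class StatResult:
    """A single statistic with its p-value and sample size."""

    name: str
    estimate: float
    p_value: float | None
    n: int
    extra: dict = field(default_factory=dict)


@dataclass
class CovariateStats:
    """Pearson correlation and OLS regression of abundance on a covariate."""

    r: float
    r_p_value: float
    slope: float
    intercept: float
    r_squared: float
    slope_p_value: float
    n: int


@dataclass
class BioenvResult:
    """Best environmental subset and the full evaluation trace."""

    best_subset: tuple[str, ...]
    correlation: float
    scores: list[tuple[tuple[str, ...], float]]
    method: str


@dataclass
class OrdinationResult:
    """Sample coordinates plus method-specific fit diagnostics."""

    method: str
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray | None = None
    stress: float | None = None
    seed: int | None = None
    converged: bool = True


def _abundance_frame(matrix: AbundanceMatrix | pd.DataFrame) -> pd.DataFrame:
    if isinstance(matrix, AbundanceMatrix):
        return matrix.data
    return matrix


def bray_curtis(matrix: AbundanceMatrix | pd.DataFrame) -> DistanceMatrix:
    """Bray–Curtis dissimilarity between samples (columns).

    ``d(i, j) = sum |x_i - x_j| / sum (x_i + x_j)`` over taxa. A pair of
    all-zero samples gets distance 0 with a warning.
    """
    df = _abundance_frame(matrix)
    if (df.values < 0).any():
        raise InputError("Bray-Curtis requires non-negative abundances")
    X = df.T.values.astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        condensed = pdist(X, metric="braycurtis")
    if np.isnan(condensed).any():
        logger.warning("all-zero sample pair(s): distance set to 0")
        condensed = np.nan_to_num(condensed, nan=0.0)
    return DistanceMatrix(squareform(condensed), ids=list(df.columns))


def _branch_table(
    tree: TreeNode, df: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Per-branch lengths and descendant abundance proportions.

    Returns ``(lengths, props)`` with one row per non-root branch and one
    column per sample in ``props``.
    """
    leaf_names = {leaf.name for leaf in tree.tips()}
    missing = [t for t in df.index if t not in leaf_names]
    if missing:
        raise InputError(f"abundance rows absent from tree: {missing}")
    totals = df.sum(axis=0).values.astype(float)
    safe_totals = np.where(totals > 0, totals, 1.0)
    lengths = []
    props = []
    # postorder accumulation of descendant-leaf abundance per node
    sums: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            if node.name in df.index:
                s = df.loc[node.name].values.astype(float)
            else:
                s = np.zeros(df.shape[1])
        else:
            s = np.zeros(df.shape[1])
            for child in node.children:
                s = s + sums[id(child)]
        sums[id(node)] = s
        if node.parent is not None:  # root branch excluded
            lengths.append(float(node.length or 0.0))
            props.append(s / safe_totals)
    return np.array(lengths), np.array(props)


def unifrac(
    tree: TreeNode,
    matrix: AbundanceMatrix | pd.DataFrame,
    weighted: bool = False,
    normalized: bool = True,
) -> DistanceMatrix:
    """UniFrac distance between samples on a rooted tree.

    Unweighted: branch length unique to either sample's taxa divided by the
    branch length covered by either. Weighted raw: ``sum_b l_b |p_A - p_B|``
    with ``p`` the descendant relative-abundance fraction; the normalized
    variant divides by ``sum_b l_b (p_A + p_B)``, the value attained by two
    completely disjoint communities.
    """
    df = _abundance_frame(matrix)
    lengths, props = _branch_table(tree, df)
    samples = list(df.columns)
    n = len(samples)
    out = np.zeros((n, n))
    present = props > 0
    for i in range(n):
        for j in range(i + 1, n):
            if weighted:
                raw = float(np.sum(lengths * np.abs(props[:, i] - props[:, j])))
                if normalized:
                    denom = float(np.sum(lengths * (props[:, i] + props[:, j])))
                    d = raw / denom if denom > 0 else 0.0
                else:
                    d = raw
            else:
                either = present[:, i] | present[:, j]
                unique = present[:, i] ^ present[:, j]
                covered = float(np.sum(lengths[either]))
                d = float(np.sum(lengths[unique])) / covered if covered > 0 else 0.0
            out[i, j] = out[j, i] = d
    return DistanceMatrix(out, ids=samples)


def pcoa(d: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Principal-coordinates analysis (Gower double centering + eigh).

    Coordinates are eigenvectors scaled by the square root of their
    eigenvalues; axes with non-positive eigenvalues get zero coordinates.
    All eigenvalues (including negatives, which arise for non-Euclidean
    dissimilarities such as Bray–Curtis) are reported in decreasing order.
    """
    n = d.shape[0]
    if k >= n:
        raise InputError(f"k = {k} must be smaller than the number of samples {n}")
    D2 = np.asarray(d.data, dtype=float) ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    coords = np.zeros((n, k))
    for axis in range(k):
        if eigvals[axis] > 0:
            coords[:, axis] = eigvecs[:, axis] * np.sqrt(eigvals[axis])
    frame = pd.DataFrame(
        coords, index=list(d.ids), columns=[f"PC{i+1}" for i in range(k)]
    )
    return OrdinationResult("pcoa", frame, eigenvalues=eigvals)


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    n_starts: int = 4,
    seed: int = 0,
    max_iter: int = 500,
) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1.

    Runs SMACOF with monotone regression from a PCoA initialization plus
    ``n_starts - 1`` seeded random starts and keeps the lowest-stress
    solution. Deterministic given the seed.
    """
    n = d.shape[0]
    if n < k + 1:
        raise InputError(f"need at least k + 1 = {k + 1} samples, got {n}")
    dissim = np.asarray(d.data, dtype=float)
    rng = np.random.default_rng(seed)
    inits = [pcoa(d, k).coordinates.values]
    for _ in range(max(0, n_starts - 1)):
        inits.append(rng.normal(size=(n, k)))
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for init in inits:
            coords, stress, n_iter = smacof(
                dissim,
                metric=False,
                n_components=k,
                init=init,
                n_init=1,
                max_iter=max_iter,
                eps=1e-9,
                normalized_stress=True,
                return_n_iter=True,
            )
            if best is None or stress < best[1]:
                best = (coords, stress, n_iter)
    coords, stress, n_iter = best
    frame = pd.DataFrame(
        coords, index=list(d.ids), columns=[f"NMDS{i+1}" for i in range(k)]
    )
    return OrdinationResult(
        "nmds",
        frame,
        stress=float(stress),
        seed=seed,
        converged=n_iter < max_iter,
    )


def _condensed(d: DistanceMatrix) -> np.ndarray:
    return squareform(np.asarray(d.data, dtype=float), checks=False)


def _correlate(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "pearson":
        return float(np.corrcoef(x, y)[0, 1])
    if method == "spearman":
        return float(
            np.corrcoef(scipy.stats.rankdata(x), scipy.stats.rankdata(y))[0, 1]
        )
    raise ConfigError(f"unknown correlation method {method!r}")


def bioenv(
    community_d: DistanceMatrix,
    env: pd.DataFrame,
    method: str = "pearson",
    max_subset_size: int | None = None,
    strategy: str = "exhaustive",
) -> BioenvResult:
    """Select the environmental-variable subset best matching community structure.

    Variables are standardized (zero mean, unit variance, ddof = 1); for
    every non-empty subset up to ``max_subset_size`` the Euclidean distance
    matrix on the standardized subset is correlated with ``community_d``
    over the lower triangle, and the maximizing subset is returned together
    with all evaluated scores. ``strategy="stepwise"`` replaces exhaustive
    enumeration with best-first forward expansion (for many variables).
    Constant variables are excluded with a warning.
    """
    labels = list(community_d.ids)
    missing = [s for s in labels if s not in env.index]
    if missing:
        raise InputError(f"environment table missing samples: {missing}")
    env = env.loc[labels]
    stds = env.std(axis=0, ddof=1)
    constant = list(env.columns[(stds == 0) | stds.isna()])
    if constant:
        logger.warning("excluding constant environmental variables: %s", constant)
        env = env.drop(columns=constant)
    if env.shape[1] == 0:
        raise InputError("no usable (non-constant) environmental variables")
    z = (env - env.mean(axis=0)) / env.std(axis=0, ddof=1)
    variables = list(env.columns)
    if max_subset_size is None:
        max_subset_size = len(variables)
    max_subset_size = min(max_subset_size, len(variables))
    target = _condensed(community_d)

    # squared pairwise differences per variable; subset distance is the
    # square root of their sum
    sq = {
        v: pdist(z[[v]].values, metric="sqeuclidean") for v in variables
    }

    def score(subset: tuple[str, ...]) -> float:
        dist = np.sqrt(sum(sq[v] for v in subset))
        return _correlate(dist, target, method)

    scores: list[tuple[tuple[str, ...], float]] = []
    if strategy == "exhaustive":
        for size in range(1, max_subset_size + 1):
            for subset in itertools.combinations(variables, size):
                scores.append((subset, score(subset)))
    elif strategy == "stepwise":
        current: tuple[str, ...] = ()
        current_score = -np.inf
        while len(current) < max_subset_size:
            candidates = [
                tuple(sorted(current + (v,)))
                for v in variables
                if v not in current
            ]
            evaluated = [(c, score(c)) for c in candidates]
            scores.extend(evaluated)
            best_c, best_s = max(evaluated, key=lambda t: t[1])
            if best_s <= current_score:
                break
            current, current_score = best_c, best_s
    else:
        raise ConfigError(f"unknown strategy {strategy!r}")

    best_subset, best_score = max(scores, key=lambda t: t[1])
    return BioenvResult(best_subset, best_score, scores, method)


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "pearson",
    n_perm: int = 999,
    seed: int = 0,
) -> StatResult:
    """Mantel permutation test of association between two distance matrices.

    ``r`` is the correlation of the lower triangles; the p-value counts
    permutations of d2's labels whose correlation reaches the observed one,
    with the add-one convention (one-sided, greater).
    """
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    if set(d1.ids) != set(d2.ids):
        raise InputError("distance matrices have different labels")
    d2 = d2.filter(d1.ids)  # align label order
    x = _condensed(d1)
    m2 = np.asarray(d2.data, dtype=float)
    y = squareform(m2, checks=False)
    r_obs = _correlate(x, y, method)
    n = len(d1.ids)
    rng = np.random.default_rng(seed)
    if method == "pearson":
        xz = (x - x.mean()) / x.std()
    else:
        rx = scipy.stats.rankdata(x)
        xz = (rx - rx.mean()) / rx.std()
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        yp = squareform(m2[np.ix_(idx, idx)], checks=False)
        if method == "spearman":
            yp = scipy.stats.rankdata(yp)
        yz = (yp - yp.mean()) / yp.std()
        r_perm = float(np.mean(xz * yz))
        if r_perm >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return StatResult(
        name=f"mantel_{method}",
        estimate=r_obs,
        p_value=p,
        n=n,
        extra={"permutations": n_perm, "seed": seed},
    )


def covariate_stats(
    abundance: Sequence[float] | pd.Series,
    covariate: Sequence[float] | pd.Series,
) -> CovariateStats:
    """Pearson r (two-sided parametric p) and OLS of abundance on covariate."""
    y = np.asarray(abundance, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if len(x) != len(y):
        raise InputError("abundance and covariate lengths differ")
    if len(x) < 3:
        raise InputError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise InputError("covariate is constant")
    if np.ptp(y) == 0:
        raise InputError("abundance is constant; correlation undefined")
    r, r_p = scipy.stats.pearsonr(x, y)
    reg = scipy.stats.linregress(x, y)
    return CovariateStats(
        r=float(r),
        r_p_value=float(r_p),
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        r_squared=float(reg.rvalue**2),
        slope_p_value=float(reg.pvalue),
        n=len(x),
    )


def read_distance_tsv(path) -> DistanceMatrix:
    """Read a labeled square distance matrix from TSV."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return DistanceMatrix(df.values, ids=[str(c) for c in df.columns])


def write_distance_tsv(d: DistanceMatrix, path, header_comment: str | None = None) -> None:
    df = pd.DataFrame(np.asarray(d.data), index=list(d.ids), columns=list(d.ids))
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t")
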