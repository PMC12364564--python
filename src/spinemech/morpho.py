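"""Geometric-morphometric shape space for landmark configurations.

Implements the standard landmark pipeline for spine shapes: generalized
Procrustes analysis (GPA: centering, unit-centroid-size scaling, optimal
rotation to a consensus), principal component analysis of the aligned
coordinates, permutation linear models on shape (residual-randomization
F tests), and a phylomorphospace (PC scores of the tips of a phylogeny
with internal-node scores estimated by branch-length-weighted
squared-change parsimony, equivalent to maximum-likelihood Brownian
ancestral states).

Landmark correspondence across specimens is assumed given (e.g. produced
by an automated alignment tool); :func:`pseudo_landmarks` offers a simple
deterministic farthest-point sampler for desk-scale tests on meshes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
import trimesh

from .errors import ConvergenceError, ParameterError

__all__ = [
    "LandmarkSet",
    "GPAResult",
    "PCAResult",
    "ProcrustesLMResult",
    "read_landmarks",
    "pseudo_landmarks",
    "gpa",
    "shape_pca",
    "procrustes_lm",
    "load_tree",
    "phylomorphospace",
]


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LandmarkSet:
    """Landmark configurations: ``coords[i]`` is the (k, 3) configuration of
    specimen ``ids[i]``; landmark j corresponds across specimens."""

    ids: tuple[str, ...]
    coords: np.ndarray  # (n, k, 3)

    def __post_init__(self) -> None:
        arr = np.asarray(self.coords, dtype=float)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ParameterError("coords must have shape (n, k, 3)")
        if arr.shape[1] < 4:
            raise ParameterError("need at least k = 4 landmarks")
        if len(self.ids) != arr.shape[0]:
            raise ParameterError("ids and coords disagree on specimen count")
        if len(set(self.ids)) != len(self.ids):
            raise ParameterError("duplicated specimen ids")
        sizes = np.linalg.norm(arr - arr.mean(axis=1, keepdims=True), axis=(1, 2))
        if np.any(sizes <= 0):
            raise ParameterError("zero-size (degenerate) configuration present")
        object.__setattr__(self, "coords", arr)
        object.__setattr__(self, "ids", tuple(self.ids))

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]


@dataclass(frozen=True)
class GPAResult:
    """Aligned configurations (centered, unit centroid size, rotated to the
    consensus), the consensus itself, and Procrustes distances to it."""

    ids: tuple[str, ...]
    aligned: np.ndarray            # (n, k, 3)
    consensus: np.ndarray          # (k, 3)
    distances: np.ndarray          # (n,)
    n_iterations: int


@dataclass(frozen=True)
class PCAResult:
    """Shape PCA: specimen scores, per-axis variance fractions, loadings."""

    ids: tuple[str, ...]
    scores: np.ndarray              # (n, c)
    variance_fraction: np.ndarray   # (c,)
    components: np.ndarray          # (c, k*3)
    mean: np.ndarray                # (k*3,)

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=list(self.ids), columns=cols)


@dataclass(frozen=True)
class ProcrustesLMResult:
    """Permutation (residual-randomization) linear model on shape."""

    ss_effect: float
    ss_residual: float
    df_effect: int
    df_residual: int
    f_statistic: float
    p_value: float
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        if self.ss_effect < 0 or self.ss_residual < 0:
            raise ParameterError("sums of squares must be >= 0")
        lo = 1.0 / (self.n_permutations + 1)
        if not lo - 1e-12 <= self.p_value <= 1.0 + 1e-12:
            raise ParameterError("p-value outside its attainable range")


# ---------------------------------------------------------------------------
# landmark IO and sampling
# ---------------------------------------------------------------------------


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read landmark configurations from CSV.

    Long format: columns ``specimen, landmark, x, y, z`` (one row per
    landmark).  Wide format: one row per specimen, first column the
    specimen id, then 3k numeric columns in landmark-major order
    (x1, y1, z1, x2, ...).
    """
    df = pd.read_csv(path)
    lower = {c.lower(): c for c in df.columns}
    if {"specimen", "landmark", "x", "y", "z"} <= set(lower):
        spec = lower["specimen"]
        lm = lower["landmark"]
        ids = []
        configs = []
        k_ref = None
        for sid, g in df.groupby(spec, sort=False):
            g = g.sort_values(lm)
            arr = g[[lower["x"], lower["y"], lower["z"]]].to_numpy(float)
            if k_ref is None:
                k_ref = len(arr)
            elif len(arr) != k_ref:
                raise ParameterError(
                    f"specimen {sid!r} has {len(arr)} landmarks, expected {k_ref}"
                )
            ids.append(str(sid))
            configs.append(arr)
        return LandmarkSet(ids=tuple(ids), coords=np.stack(configs))
    # wide: id column + 3k numeric columns
    id_col = df.columns[0]
    rest = df.columns[1:]
    if len(rest) % 3 != 0:
        raise ParameterError("wide landmark CSV needs 3k coordinate columns")
    coords = df[rest].to_numpy(float).reshape(len(df), -1, 3)
    ids = tuple(str(v) for v in df[id_col])
    return LandmarkSet(ids=ids, coords=coords)


def pseudo_landmarks(mesh: trimesh.Trimesh, k: int, seed: int = 0) -> np.ndarray:
    """Deterministic farthest-point sampling of ``k`` mesh vertices.

    The start vertex is drawn from the seeded generator; each further point
    maximises the minimum Euclidean distance to those already chosen (ties
    broken by smallest vertex index).  A cheap stand-in for automated
    correspondence sampling in tests; distances are Euclidean, not
    geodesic.
    """
    verts = np.asarray(mesh.vertices, dtype=float)
    if k < 1 or k > len(verts):
        raise ParameterError(f"k must be in [1, {len(verts)}]")
    rng = np.random.default_rng(seed)
    start = int(rng.integers(0, len(verts)))
    chosen = [start]
    dmin = np.linalg.norm(verts - verts[start], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(dmin))
        chosen.append(nxt)
        dmin = np.minimum(dmin, np.linalg.norm(verts - verts[nxt], axis=1))
    return verts[chosen]


# ---------------------------------------------------------------------------
# GPA
# ---------------------------------------------------------------------------


def _optimal_rotation(a: np.ndarray, b: np.ndarray, allow_reflection: bool) -> np.ndarray:
    """Orthogonal R minimising ||a R − b||_F (proper rotation by default)."""
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    r = u @ vt
    if not allow_reflection and np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


def gpa(
    landmarks: LandmarkSet,
    max_iter: int = 100,
    tol: float = 1e-10,
    allow_reflection: bool = False,
) -> GPAResult:
    """Generalized Procrustes analysis.

    Each configuration is centered and scaled to unit centroid size, then
    iteratively rotated to the running consensus (mean configuration,
    itself renormalised to unit size) until the consensus stops moving.
    By default only proper rotations are allowed, preserving chirality —
    left and right organs are mirror images and should not be superimposed.

    Raises
    ------
    ConvergenceError
        If the consensus has not stabilised after ``max_iter`` iterations.
    """
    if landmarks.n_specimens < 2:
        raise ParameterError("GPA needs at least two specimens")
    X = landmarks.coords.copy()
    X -= X.mean(axis=1, keepdims=True)
    sizes = np.linalg.norm(X, axis=(1, 2), keepdims=True)
    X /= sizes

    consensus = X[0].copy()
    consensus /= np.linalg.norm(consensus)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for i in range(len(X)):
            X[i] = X[i] @ _optimal_rotation(X[i], consensus, allow_reflection)
        new_consensus = X.mean(axis=0)
        new_consensus /= np.linalg.norm(new_consensus)
        change = np.sqrt(np.mean((new_consensus - consensus) ** 2))
        consensus = new_consensus
        if change < tol:
            break
    else:
        raise ConvergenceError(
            f"GPA did not converge in {max_iter} iterations "
            f"(last consensus rms change {change:.3e})"
        )
    distances = np.linalg.norm(X - consensus, axis=(1, 2))
    return GPAResult(
        ids=landmarks.ids,
        aligned=X,
        consensus=consensus,
        distances=distances,
        n_iterations=n_iter,
    )


def procrustes_distance(
    a: np.ndarray, b: np.ndarray, allow_reflection: bool = False
) -> float:
    """Ordinary (two-shape) Procrustes distance after centering, unit
    scaling and optimal rotation of ``a`` onto ``b``."""
    a = np.asarray(a, float) - np.asarray(a, float).mean(axis=0)
    b = np.asarray(b, float) - np.asarray(b, float).mean(axis=0)
    a /= np.linalg.norm(a)
    b /= np.linalg.norm(b)
    r = _optimal_rotation(a, b, allow_reflection)
    return float(np.linalg.norm(a @ r - b))


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def shape_pca(g: GPAResult) -> PCAResult:
    """PCA of the vectorised aligned coordinates.

    Axes are the eigenvectors of the specimen covariance; scores are the
    centered data projected on them.  Each axis is oriented so that its
    largest-magnitude loading is positive (a deterministic sign
    convention).  Variance fractions sum to 1 over the returned axes.
    """
    n = g.aligned.shape[0]
    if n < 2:
        raise ParameterError("shape PCA needs at least two specimens")
    Y = g.aligned.reshape(n, -1)
    mean = Y.mean(axis=0)
    Yc = Y - mean
    u, s, vt = np.linalg.svd(Yc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 0:
        raise ParameterError("no shape variation among specimens")
    scores = u * s
    for j in range(vt.shape[0]):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            vt[j] *= -1
            scores[:, j] *= -1
    return PCAResult(
        ids=g.ids,
        scores=scores,
        variance_fraction=var / total,
        components=vt,
        mean=mean,
    )


# ---------------------------------------------------------------------------
# permutation linear model (RRPP)
# ---------------------------------------------------------------------------


def _design_matrix(covariate, n: int) -> np.ndarray:
    cov = np.asarray(covariate)
    if cov.shape[0] != n:
        raise ParameterError("covariate length does not match specimen count")
    if cov.dtype.kind in "OUSb":  # factor
        levels = pd.unique(cov)
        if len(levels) < 2:
            raise ParameterError("covariate is constant")
        cols = [(cov == lv).astype(float) for lv in levels[1:]]
        Z = np.column_stack(cols)
    else:
        cov = cov.astype(float)
        if np.isnan(cov).any():
            raise ParameterError("covariate contains missing values")
        if np.ptp(cov) == 0:
            raise ParameterError("covariate is constant")
        Z = cov.reshape(n, -1)
    return Z


def procrustes_lm(
    g: GPAResult,
    covariate,
    n_permutations: int = 999,
    seed: int = 0,
) -> ProcrustesLMResult:
    """Linear model on shape with a residual-randomization permutation test.

    The vectorised aligned shapes are regressed on the covariate (numeric,
    or a factor which is dummy-coded).  Effect and residual Procrustes sums
    of squares give ``F = (SS_eff/df_eff)/(SS_res/df_res)``.  The null
    distribution permutes the rows of the residuals of the reduced
    (intercept-only) model; the observed arrangement counts toward the
    null, so the smallest attainable p is ``1/(n_permutations + 1)``.
    """
    n = g.aligned.shape[0]
    Y = g.aligned.reshape(n, -1)
    Yc = Y - Y.mean(axis=0)
    Z = _design_matrix(covariate, n)
    Zc = Z - Z.mean(axis=0)
    df_eff = Zc.shape[1]
    df_res = n - df_eff - 1
    if df_res < 1:
        raise ParameterError("not enough specimens for the model")

    # hat matrix of the centered design; SS_eff = ||P Yc||^2
    q, _ = np.linalg.qr(Zc)
    ss_total = float((Yc**2).sum())

    def ss_effect_of(Ymat: np.ndarray) -> float:
        proj = q.T @ Ymat
        return float((proj**2).sum())

    ss_eff = ss_effect_of(Yc)
    ss_res = ss_total - ss_eff

    def f_of(ss_e: float) -> float:
        ss_r = ss_total - ss_e
        return (ss_e / df_eff) / (ss_r / df_res) if ss_r > 0 else np.inf

    f_obs = f_of(ss_eff)
    rng = np.random.default_rng(seed)
    count = 1  # the observed arrangement
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        f_perm = f_of(ss_effect_of(Yc[perm]))
        if f_perm >= f_obs:
            count += 1
    return ProcrustesLMResult(
        ss_effect=ss_eff,
        ss_residual=ss_res,
        df_effect=df_eff,
        df_residual=df_res,
        f_statistic=f_obs,
        p_value=count / (n_permutations + 1),
        n_permutations=n_permutations,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# phylomorphospace
# ---------------------------------------------------------------------------


def load_tree(source: str | Path) -> dendropy.Tree:
    """Load a rooted newick tree from a path or a newick string."""
    src = str(source)
    if "(" in src:
        return dendropy.Tree.get(data=src, schema="newick")
    return dendropy.Tree.get(path=src, schema="newick")


def phylomorphospace(
    tree: dendropy.Tree,
    tip_scores: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Project a phylogeny into a morphospace.

    ``tip_scores`` is indexed by tip label with one column per score axis
    (e.g. PC1, PC2).  Internal-node scores minimise the sum over edges of
    (Δscore)²/branch-length — weighted squared-change parsimony, the
    maximum-likelihood Brownian ancestral states.  Tips absent from the
    score table are pruned; score labels absent from the tree are an error.
    Zero or missing branch lengths are replaced by 1e−8 × tree height.

    Returns
    -------
    nodes, edges
        ``nodes``: one row per node (tips and internals) with the score
        columns and ``is_tip``; ``edges``: parent/child node ids with
        branch lengths — everything needed to draw the tree in score space.
    """
    tree = tree.clone(depth=1)
    labels = set(tip_scores.index.astype(str))
    tip_labels = {t.label for t in tree.taxon_namespace if t.label is not None}
    missing = labels - tip_labels
    if missing:
        raise ParameterError(f"score table rows not in the tree: {sorted(missing)}")
    keep = [t for t in tree.taxon_namespace if t.label in labels]
    if len(keep) < 2:
        raise ParameterError("need at least two scored tips")
    if len(keep) < len(tip_labels):
        tree.retain_taxa(keep)

    heights = [
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    ]
    height = max(heights) if heights else 1.0
    eps = 1e-8 * (height if height > 0 else 1.0)

    nodes = list(tree.preorder_node_iter())
    node_ids: dict[int, str] = {}
    internal_index: dict[int, int] = {}
    n_internal = 0
    for i, nd in enumerate(nodes):
        if nd.is_leaf():
            node_ids[id(nd)] = str(nd.taxon.label)
        else:
            node_ids[id(nd)] = f"node{n_internal}"
            internal_index[id(nd)] = n_internal
            n_internal += 1

    cols = list(tip_scores.columns)
    m = n_internal
    A = np.zeros((m, m))
    B = np.zeros((m, len(cols)))
    tip_vals = tip_scores.astype(float)

    def edge_weight(child) -> float:
        bl = child.edge.length
        if bl is None or bl <= 0:
            bl = eps
        return 1.0 / bl

    for nd in nodes:
        if nd.is_leaf():
            continue
        ui = internal_index[id(nd)]
        neighbours = list(nd.child_nodes())
        if nd.parent_node is not None:
            w = edge_weight(nd)
            A[ui, ui] += w
            A[ui, internal_index[id(nd.parent_node)]] -= w
        for ch in neighbours:
            w = edge_weight(ch)
            A[ui, ui] += w
            if ch.is_leaf():
                B[ui] += w * tip_vals.loc[str(ch.taxon.label)].to_numpy()
            else:
                A[ui, internal_index[id(ch)]] -= w
    states = np.linalg.solve(A, B)

    node_rows = []
    for nd in nodes:
        nid = node_ids[id(nd)]
        if nd.is_leaf():
            vals = tip_vals.loc[nid].to_numpy()
        else:
            vals = states[internal_index[id(nd)]]
        row = {"node_id": nid, "is_tip": nd.is_leaf()}
        row.update({c: float(v) for c, v in zip(cols, vals)})
        node_rows.append(row)
    edge_rows = []
    for nd in nodes:
        if nd.parent_node is not None:
            edge_rows.append(
                {
                    "parent": node_ids[id(nd.parent_node)],
                    "child": node_ids[id(nd)],
                    "length": nd.edge.length if nd.edge.length else eps,
                }
            )
    return pd.DataFrame(node_rows), pd.DataFrame(edge_rows)
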