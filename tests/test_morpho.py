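"""GPA, shape PCA, permutation shape models and phylomorphospace."""

import numpy as np
import pandas as pd
import pytest
import trimesh

from spinemech import morpho, synth
from spinemech.errors import ParameterError
from spinemech.morpho import (
    LandmarkSet,
    gpa,
    load_tree,
    phylomorphospace,
    procrustes_distance,
    procrustes_lm,
    pseudo_landmarks,
    read_landmarks,
    shape_pca,
)


def random_similarity(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q, float(rng.uniform(0.5, 2.0)), rng.normal(size=3) * 5.0


# ---------------------------------------------------------------------------
# landmark IO
# ---------------------------------------------------------------------------


class TestReadLandmarks:
    def _long_csv(self, tmp_path, k=10, n=3):
        rng = np.random.default_rng(1)
        rows = []
        coords = rng.normal(size=(n, k, 3))
        for i in range(n):
            for j in range(k):
                rows.append(
                    {"specimen": f"s{i}", "landmark": j, "x": coords[i, j, 0],
                     "y": coords[i, j, 1], "z": coords[i, j, 2]}
                )
        p = tmp_path / "long.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        return p, coords

    def test_long_format(self, tmp_path):
        p, coords = self._long_csv(tmp_path)
        lms = read_landmarks(p)
        assert lms.k == 10 and lms.n_specimens == 3
        assert np.allclose(lms.coords, coords)

    def test_wide_format_identical_to_long(self, tmp_path):
        p, coords = self._long_csv(tmp_path)
        long = read_landmarks(p)
        wide_rows = []
        for i, sid in enumerate(long.ids):
            row = {"specimen": sid}
            for j in range(long.k):
                for a, ax in enumerate("xyz"):
                    row[f"{ax}{j + 1}"] = coords[i, j, a]
            wide_rows.append(row)
        wp = tmp_path / "wide.csv"
        pd.DataFrame(wide_rows).to_csv(wp, index=False)
        wide = read_landmarks(wp)
        assert wide.ids == long.ids
        assert np.allclose(wide.coords, long.coords)

    def test_ragged_landmark_counts_rejected(self, tmp_path):
        p, _ = self._long_csv(tmp_path)
        df = pd.read_csv(p).iloc[:-1]  # drop one landmark of the last specimen
        p2 = tmp_path / "ragged.csv"
        df.to_csv(p2, index=False)
        with pytest.raises(ParameterError, match="landmarks"):
            read_landmarks(p2)


# ---------------------------------------------------------------------------
# pseudo-landmarks
# ---------------------------------------------------------------------------


class TestPseudoLandmarks:
    def test_k1_is_seeded_start_vertex(self):
        mesh = trimesh.creation.icosphere(subdivisions=1)
        pts = pseudo_landmarks(mesh, k=1, seed=3)
        start = np.random.default_rng(3).integers(0, len(mesh.vertices))
        assert np.allclose(pts[0], mesh.vertices[start])

    def test_tetrahedron_selects_all_four_corners(self):
        verts = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        )
        faces = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        pts = pseudo_landmarks(mesh, k=4, seed=0)
        # brute-force max-min-distance subset of size 4 is the corner set
        assert {tuple(p) for p in pts} == {tuple(v) for v in verts}

    def test_deterministic_given_seed(self):
        mesh = trimesh.creation.icosphere(subdivisions=2)
        a = pseudo_landmarks(mesh, k=12, seed=9)
        b = pseudo_landmarks(mesh, k=12, seed=9)
        assert np.array_equal(a, b)

    def test_k_too_large_rejected(self):
        mesh = trimesh.creation.icosphere(subdivisions=0)
        with pytest.raises(ParameterError):
            pseudo_landmarks(mesh, k=10_000)


# ---------------------------------------------------------------------------
# GPA
# ---------------------------------------------------------------------------


class TestGPA:
    def test_duplicate_configurations_have_zero_distances(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(6, 3))
        lms = LandmarkSet(
            ids=("a", "b", "c"), coords=np.stack([base, base, base])
        )
        res = gpa(lms)
        assert np.all(res.distances < 1e-12)

    def test_similarity_transformed_copy_at_zero_distance(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(8, 3))
        q, s, t = random_similarity(rng)
        lms = LandmarkSet(ids=("a", "b"), coords=np.stack([base, (base @ q) * s + t]))
        res = gpa(lms)
        assert np.all(res.distances < 1e-8)

    def test_two_shape_distance_matches_closed_form_superimposition(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(5, 3))
        b = rng.normal(size=(5, 3))
        lms = LandmarkSet(ids=("a", "b"), coords=np.stack([a, b]))
        res = gpa(lms)
        d_gpa = float(np.linalg.norm(res.aligned[0] - res.aligned[1]))

        # independent closed form: center, unit-scale, optimal rotation of
        # a onto b; distance = sqrt(2 - 2 * sum of singular values)
        ac = a - a.mean(0)
        bc = b - b.mean(0)
        ac /= np.linalg.norm(ac)
        bc /= np.linalg.norm(bc)
        u, s, vt = np.linalg.svd(ac.T @ bc)
        if np.linalg.det(u @ vt) < 0:
            s[-1] *= -1
        d_opa = np.sqrt(max(2.0 - 2.0 * s.sum(), 0.0))
        assert d_gpa == pytest.approx(d_opa, abs=1e-6)

    def test_consensus_is_fixed_point(self):
        lms, _ = synth.generate_landmark_set(n_specimens=10, k=6, seed=11)
        res = gpa(lms)
        assert np.linalg.norm(res.consensus) == pytest.approx(1.0, abs=1e-10)
        realigned = np.stack(
            [
                x @ morpho._optimal_rotation(x, res.consensus, False)
                for x in res.aligned
            ]
        )
        new_consensus = realigned.mean(axis=0)
        new_consensus /= np.linalg.norm(new_consensus)
        assert np.abs(new_consensus - res.consensus).max() < 1e-6

    def test_alignment_invariant_under_similarity_of_any_input(self):
        lms, _ = synth.generate_landmark_set(n_specimens=8, k=6, seed=12)
        res0 = gpa(lms)
        rng = np.random.default_rng(77)
        coords = lms.coords.copy()
        for i in (1, 4):
            q, s, t = random_similarity(rng)
            coords[i] = (coords[i] @ q) * s + t
        res1 = gpa(LandmarkSet(ids=lms.ids, coords=coords))
        assert np.abs(res0.distances - res1.distances).max() < 1e-8
        v0 = shape_pca(res0).variance_fraction
        v1 = shape_pca(res1).variance_fraction
        assert np.abs(v0 - v1).max() < 1e-8

    def test_procrustes_distance_triangle_inequality(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            a, b, c = rng.normal(size=(3, 5, 3))
            dab = procrustes_distance(a, b)
            dbc = procrustes_distance(b, c)
            dac = procrustes_distance(a, c)
            assert dac <= dab + dbc + 1e-9
            assert dab == pytest.approx(procrustes_distance(b, a), abs=1e-9)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


class TestShapePCA:
    def test_single_shape_direction_gives_pc1_everything(self):
        lms, _ = synth.generate_landmark_set(
            n_specimens=10, k=6, noise_sd=0.0, seed=5
        )
        pca = shape_pca(gpa(lms))
        assert pca.variance_fraction[0] > 0.999
        assert pca.variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_covariance_eigen_oracle(self):
        lms, _ = synth.generate_landmark_set(n_specimens=5, k=4, seed=6)
        res = gpa(lms)
        pca = shape_pca(res)
        Y = res.aligned.reshape(5, -1)
        Yc = Y - Y.mean(axis=0)
        evals, evecs = np.linalg.eigh(Yc.T @ Yc)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0, None)
        assert np.allclose(
            pca.variance_fraction[:4], (evals / evals.sum())[:4], atol=1e-9
        )
        for j in range(2):  # leading axes against eigenvector oracle, up to sign
            v = evecs[:, order[j]]
            dot = abs(float(np.dot(v, pca.components[j])))
            assert dot == pytest.approx(1.0, abs=1e-8)


# ---------------------------------------------------------------------------
# permutation linear model
# ---------------------------------------------------------------------------


class TestProcrustesLM:
    def test_perfect_covariate_attains_minimum_p(self):
        lms, _ = synth.generate_landmark_set(n_specimens=12, k=6, seed=7)
        res = gpa(lms)
        pc1 = shape_pca(res).scores[:, 0]
        out = procrustes_lm(res, pc1, n_permutations=999, seed=0)
        assert out.p_value == pytest.approx(1.0 / 1000.0, abs=1e-15)

    def test_tiny_example_matches_normal_equation_oracle(self):
        lms, _ = synth.generate_landmark_set(n_specimens=4, k=4, seed=8)
        res = gpa(lms)
        x = np.array([0.3, -1.2, 0.5, 1.9])
        out = procrustes_lm(res, x, n_permutations=99, seed=0)
        Y = res.aligned.reshape(4, -1)
        Yc = Y - Y.mean(axis=0)
        X = np.column_stack([np.ones(4), x])
        beta = np.linalg.lstsq(X, Yc, rcond=None)[0]
        fitted = X @ beta
        ss_eff = float(((fitted - fitted.mean(axis=0)) ** 2).sum())
        ss_res = float(((Yc - fitted) ** 2).sum())
        assert out.ss_effect == pytest.approx(ss_eff, rel=1e-10)
        assert out.ss_residual == pytest.approx(ss_res, rel=1e-10)
        f_oracle = (ss_eff / 1) / (ss_res / 2)
        assert out.f_statistic == pytest.approx(f_oracle, rel=1e-10)

    def test_reproducible_given_seed(self):
        lms, _ = synth.generate_landmark_set(n_specimens=10, k=5, seed=9)
        res = gpa(lms)
        cov = np.random.default_rng(1).normal(size=10)
        a = procrustes_lm(res, cov, n_permutations=499, seed=42)
        b = procrustes_lm(res, cov, n_permutations=499, seed=42)
        assert a.p_value == b.p_value and a.f_statistic == b.f_statistic

    def test_factor_covariate(self):
        lms, _ = synth.generate_landmark_set(n_specimens=10, k=5, seed=10)
        res = gpa(lms)
        fam = np.array(["x"] * 5 + ["y"] * 5)
        out = procrustes_lm(res, fam, n_permutations=99, seed=0)
        assert out.df_effect == 1
        assert 0 < out.p_value <= 1

    def test_constant_covariate_rejected(self):
        lms, _ = synth.generate_landmark_set(n_specimens=6, k=5, seed=11)
        res = gpa(lms)
        with pytest.raises(ParameterError, match="constant"):
            procrustes_lm(res, np.ones(6), n_permutations=9, seed=0)


# ---------------------------------------------------------------------------
# phylomorphospace
# ---------------------------------------------------------------------------


def brute_force_states(tree, tip_scores):
    """Numeric minimisation of sum((delta score)^2 / branch length)."""
    from scipy.optimize import minimize

    nodes = list(tree.preorder_node_iter())
    internal = [nd for nd in nodes if not nd.is_leaf()]
    idx = {id(nd): i for i, nd in enumerate(internal)}
    heights = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
    eps = 1e-8 * max(max(heights), 1.0)

    def objective(x):
        total = 0.0
        for nd in nodes:
            if nd.parent_node is None:
                continue
            bl = nd.edge.length if nd.edge.length and nd.edge.length > 0 else eps
            parent_val = x[idx[id(nd.parent_node)]]
            child_val = (
                tip_scores[nd.taxon.label] if nd.is_leaf() else x[idx[id(nd)]]
            )
            total += (parent_val - child_val) ** 2 / bl
        return total

    x0 = np.full(len(internal), np.mean(list(tip_scores.values())))
    res = minimize(objective, x0, method="BFGS", options={"gtol": 1e-12})
    return {i: v for i, v in enumerate(res.x)}, internal


class TestPhylomorphospace:
    def test_two_tip_symmetric_root(self):
        tree = load_tree("(A:1,B:1);")
        nodes, _ = phylomorphospace(
            tree, pd.DataFrame({"PC1": [0.0, 2.0]}, index=["A", "B"])
        )
        root = nodes[~nodes.is_tip].iloc[0]
        assert root.PC1 == pytest.approx(1.0, abs=1e-10)

    def test_star_tree_root_is_tip_mean(self):
        tree = load_tree("(A:1,B:1,C:1,D:1,E:1);")
        vals = [1.0, 2.0, 3.0, 4.0, 10.0]
        nodes, _ = phylomorphospace(
            tree,
            pd.DataFrame({"PC1": vals}, index=list("ABCDE")),
        )
        root = nodes[~nodes.is_tip].iloc[0]
        assert root.PC1 == pytest.approx(np.mean(vals), abs=1e-10)

    @pytest.mark.parametrize(
        "newick,scores",
        [
            ("((A:1,B:2):0.5,(C:1.5,(D:0.7,E:0.3):1):2);",
             {"A": 0.0, "B": 1.0, "C": -2.0, "D": 3.5, "E": 1.2}),
            ("(((A:1,B:1):1,C:2):1,(D:3,E:1,F:2):0.5);",
             {"A": 2.0, "B": -1.0, "C": 0.5, "D": 4.0, "E": -3.0, "F": 0.0}),
            ("((A:0.2,B:0.2):3,C:0.1);", {"A": 1.0, "B": 5.0, "C": -2.0}),
        ],
    )
    def test_matches_numeric_minimiser_on_small_trees(self, newick, scores):
        tree = load_tree(newick)
        nodes, edges = phylomorphospace(
            tree, pd.DataFrame({"PC1": pd.Series(scores)})
        )
        oracle, internal = brute_force_states(
            load_tree(newick), scores
        )
        got = nodes[~nodes.is_tip].PC1.to_numpy()
        want = np.array([oracle[i] for i in range(len(internal))])
        assert np.abs(got - want).max() < 1e-6
        # edges connect every non-root node to its parent
        assert len(edges) == len(nodes) - 1

    def test_zero_length_branch_handled_by_epsilon(self):
        tree = load_tree("((A:0,B:1):1,C:2);")
        nodes, _ = phylomorphospace(
            tree, pd.DataFrame({"PC1": [1.0, 2.0, 3.0]}, index=["A", "B", "C"])
        )
        inner = nodes[~nodes.is_tip]
        assert np.isfinite(inner.PC1).all()
        # a zero-length branch pins the inner node to its tip value
        child_node = inner.PC1.iloc[-1]
        assert child_node == pytest.approx(1.0, abs=1e-4)

    def test_missing_tip_rejected(self):
        tree = load_tree("(A:1,B:1);")
        with pytest.raises(ParameterError, match="not in the tree"):
            phylomorphospace(
                tree, pd.DataFrame({"PC1": [1.0, 2.0]}, index=["A", "Z"])
            )

    def test_extra_tips_pruned(self):
        tree = load_tree("((A:1,B:1):1,(C:1,D:1):1);")
        nodes, _ = phylomorphospace(
            tree, pd.DataFrame({"PC1": [0.0, 2.0, 4.0]}, index=["A", "B", "C"])
        )
        assert "D" not in set(nodes.node_id)
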