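"""Alignment, grid geometry, Gaussian similarity fields, PLS diagnostics,
and contour maps."""

import numpy as np
import pytest

from glioqsar.comsia import (
    DEFAULT_ALPHA,
    AlignedMolecule,
    FieldGrid,
    FieldMatrix,
    align_to_template,
    assemble_field_matrix,
    build_grid,
    compute_field,
    contour_maps,
    fit_pls,
    kabsch_rotation,
    molecule_field_row,
    write_dx,
)
from glioqsar.synthetic import FieldPlantSpec, generate_aligned_molecules


def _mol(coords, **overrides):
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = len(coords)
    defaults = dict(
        id="m",
        elements=["C"] * n,
        coords=coords,
        charges=np.full(n, 0.1),
        radii=np.ones(n),
        hydrophobicity=np.full(n, 0.5),
        donor=np.zeros(n, dtype=bool),
        acceptor=np.ones(n, dtype=bool),
    )
    defaults.update(overrides)
    return AlignedMolecule(**defaults)


def _rot_z(deg):
    t = np.deg2rad(deg)
    return np.array([
        [np.cos(t), -np.sin(t), 0.0],
        [np.sin(t), np.cos(t), 0.0],
        [0.0, 0.0, 1.0],
    ])


class TestAlignment:
    base = np.array([[0.0, 0, 0], [1.5, 0, 0], [0, 1.5, 0], [0.7, 0.7, 1.0]])

    def test_self_alignment_rmsd_zero(self):
        m = _mol(self.base)
        _, rmsd = align_to_template(m, m, [(i, i) for i in range(4)])
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_translated_copy_rmsd_zero(self):
        m = _mol(self.base)
        shifted = m.translated([3.0, -2.0, 5.0])
        aligned, rmsd = align_to_template(shifted, m,
                                          [(i, i) for i in range(4)])
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(aligned.coords, m.coords, atol=1e-10)

    def test_rotation_recovered(self):
        m = _mol(self.base)
        R = _rot_z(90)
        rotated = _mol(self.base @ R.T)
        aligned, rmsd = align_to_template(rotated, m,
                                          [(i, i) for i in range(4)])
        assert rmsd < 1e-6
        np.testing.assert_allclose(aligned.coords, m.coords, atol=1e-6)

    def test_kabsch_returns_proper_rotation(self, rng):
        P = rng.normal(size=(6, 3))
        R = kabsch_rotation(P - P.mean(0), (P @ _rot_z(37).T) - P.mean(0))
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_map_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        m = _mol(line)
        with pytest.raises(ValueError, match="collinear"):
            align_to_template(m, m, [(i, i) for i in range(3)])

    def test_fewer_than_three_pairs_rejected(self):
        m = _mol(self.base)
        with pytest.raises(ValueError, match="3"):
            align_to_template(m, m, [(0, 0), (1, 1)])


class TestGrid:
    def test_point_molecule_default_box(self):
        g = build_grid([_mol([[0.0, 0, 0]])])
        assert g.counts == (5, 5, 5)
        assert g.n_points == 125
        assert g.origin == (-4.0, -4.0, -4.0)

    def test_halved_pitch(self):
        g = build_grid([_mol([[0.0, 0, 0]])], spacing=1.0)
        assert g.n_points == 9**3

    def test_reorder_invariance(self):
        a = _mol([[0.0, 0, 0], [2, 1, 0]])
        b = _mol([[-1.0, 3, 2]])
        assert build_grid([a, b]) == build_grid([b, a])

    def test_points_cover_box(self):
        g = build_grid([_mol([[0.0, 0, 0]])])
        pts = g.points()
        assert pts.shape == (125, 3)
        assert pts.min() == -4.0 and pts.max() == 4.0


class TestField:
    def test_probe_at_atom_gives_unit_gaussian(self):
        # single C atom with radius 1 at the only grid point: steric value
        # -(1^3 * exp(0)) = -1
        m = _mol([[0.0, 0, 0]])
        g = FieldGrid(origin=(0.0, 0.0, 0.0), spacing=1.0, counts=(1, 1, 1))
        assert compute_field(m, g, "S")[0] == pytest.approx(-1.0)

    def test_gaussian_at_one_angstrom(self):
        m = _mol([[1.0, 0, 0]])
        g = FieldGrid(origin=(0.0, 0.0, 0.0), spacing=1.0, counts=(1, 1, 1))
        assert compute_field(m, g, "S")[0] == pytest.approx(
            -np.exp(-DEFAULT_ALPHA), abs=1e-12
        )
        assert np.exp(-DEFAULT_ALPHA) == pytest.approx(0.74082, abs=1e-5)

    def test_translation_invariance(self):
        m = _mol([[0.5, -0.5, 1.0], [1.0, 2.0, 0.0]])
        g = build_grid([m])
        shift = np.array([10.0, -3.0, 4.0])
        m2 = m.translated(shift)
        g2 = FieldGrid(
            origin=tuple(np.array(g.origin) + shift),
            spacing=g.spacing, counts=g.counts,
        )
        for f in "SEHDA":
            np.testing.assert_allclose(
                compute_field(m, g, f), compute_field(m2, g2, f), atol=1e-12
            )

    def test_joint_rotation_invariance(self):
        # rotating molecules by 90° about z maps the axis-aligned grid onto
        # itself up to relabeling: field values agree as multisets
        m = _mol([[1.0, 0.0, 0.0], [-1.0, 0.0, 0.5]])
        m_rot = _mol(m.coords @ _rot_z(90).T)
        v1 = np.sort(molecule_field_row(m, build_grid([m])))
        v2 = np.sort(molecule_field_row(m_rot, build_grid([m_rot])))
        np.testing.assert_allclose(v1, v2, atol=1e-10)

    def test_unknown_field_label(self):
        m = _mol([[0.0, 0, 0]])
        with pytest.raises(KeyError, match="field"):
            compute_field(m, build_grid([m]), "X")


class TestFieldMatrix:
    def test_identical_molecules_fully_masked(self):
        m = _mol([[0.0, 0, 0], [1, 1, 0]])
        fm = assemble_field_matrix([m, m.translated(np.zeros(3)),
                                    m.translated(np.zeros(3))])
        assert fm.active_mask.sum() == 0

    def test_localized_difference_localized_contrast(self):
        a = _mol([[0.0, 0, 0], [1.5, 0, 0]])
        b = _mol([[0.0, 0, 0], [1.5, 0, 0], [2.0, 0, 0]])
        grid = build_grid([a, b])
        fm = assemble_field_matrix([a, b], grid, min_sigma=0.0)
        diff = np.abs(fm.values[0] - fm.values[1])
        pts = grid.points()
        d_new_atom = np.linalg.norm(pts - np.array([2.0, 0, 0]), axis=1)
        far = np.tile(d_new_atom > 6.0, len(fm.field_labels))
        assert diff[far].max() < np.exp(-DEFAULT_ALPHA * 36.0) * 10

    def test_masking_idempotent(self):
        res = generate_aligned_molecules(FieldPlantSpec(n_molecules=5, seed=1))
        fm = res.field_matrix
        again = assemble_field_matrix(res.molecules, fm.grid)
        np.testing.assert_array_equal(fm.active_mask, again.active_mask)

    def test_column_bookkeeping(self):
        m = _mol([[0.0, 0, 0]])
        fm = assemble_field_matrix([m, m.translated([1.0, 0, 0])])
        npts = fm.grid.n_points
        assert fm.values.shape[1] == 5 * npts
        assert fm.column_field(0) == "S"
        assert fm.column_field(npts) == "E"
        assert fm.column_point(npts + 3) == 3


def nipals_pls1(X, y, n_components):
    """Independent PLS1 reference (classic NIPALS with deflation)."""
    X = X.astype(float).copy()
    y = y.astype(float).copy()
    x_mean, y_mean = X.mean(0), y.mean()
    Xc, yc = X - x_mean, y - y_mean
    W, P, Q = [], [], []
    for _ in range(n_components):
        w = Xc.T @ yc
        w /= np.linalg.norm(w)
        t = Xc @ w
        tt = t @ t
        p = Xc.T @ t / tt
        q = (yc @ t) / tt
        Xc = Xc - np.outer(t, p)
        yc = yc - q * t
        W.append(w); P.append(p); Q.append(q)
    W, P, Q = np.array(W).T, np.array(P).T, np.array(Q)
    B = W @ np.linalg.solve(P.T @ W, Q)
    return B, x_mean, y_mean


def _matrix_from_X(X, min_sigma=0.0):
    """Wrap a plain matrix as a one-field FieldMatrix for fit_pls."""
    n, p = X.shape
    grid = FieldGrid(origin=(0.0, 0.0, 0.0), spacing=1.0, counts=(p, 1, 1))
    return FieldMatrix(
        compound_ids=[f"c{i}" for i in range(n)],
        grid=grid,
        field_labels=("S",),
        values=X.astype(float),
        active_mask=X.std(axis=0) >= min_sigma,
    )


class TestPls:
    def test_univariate_one_component_equals_simple_regression(self, rng):
        x = rng.normal(size=12)
        y = 2.0 * x + 0.5 + 0.2 * rng.normal(size=12)
        X = np.column_stack([x])
        model = fit_pls(_matrix_from_X(X), y, max_components=1)
        slope = np.cov(x, y, bias=True)[0, 1] / x.var()
        pred_ls = y.mean() + slope * (x - x.mean())
        np.testing.assert_allclose(
            model.predict_rows(X), pred_ls, atol=1e-8
        )

    def test_coefficients_match_independent_nipals(self, rng):
        X = rng.normal(size=(15, 8))
        y = X[:, 0] - 0.5 * X[:, 3] + 0.1 * rng.normal(size=15)
        for c in (1, 2, 3):
            B, xm, ym = nipals_pls1(X, y, c)
            from sklearn.cross_decomposition import PLSRegression

            m = PLSRegression(n_components=c, scale=False).fit(X, y)
            np.testing.assert_allclose(np.ravel(m.coef_), B, atol=1e-8)

    def test_loo_q2_matches_brute_force_with_oracle(self, rng):
        X = rng.normal(size=(10, 5))
        y = X[:, 0] + 0.3 * rng.normal(size=10)
        model = fit_pls(_matrix_from_X(X), y, max_components=2)
        tss = np.sum((y - y.mean()) ** 2)
        for c in (1, 2):
            press = 0.0
            for i in range(10):
                keep = np.arange(10) != i
                B, xm, ym = nipals_pls1(X[keep], y[keep], c)
                pred = (X[i] - xm) @ B + ym
                press += (y[i] - pred) ** 2
            assert model.q2_per_component[c - 1] == pytest.approx(
                1.0 - press / tss, abs=1e-8
            )

    def test_noiseless_planted_model_recovered(self):
        res = generate_aligned_molecules(
            FieldPlantSpec(n_molecules=25, noise_sd=0.0, seed=2)
        )
        model = fit_pls(res.field_matrix, res.y, max_components=20)
        assert model.r2 >= 0.999

    def test_fractions_sum_to_one(self):
        res = generate_aligned_molecules(
            FieldPlantSpec(n_molecules=15, noise_fraction=0.2, seed=3)
        )
        model = fit_pls(res.field_matrix, res.y, max_components=4)
        assert sum(model.fractions.values()) == pytest.approx(1.0, abs=1e-9)
        assert set(model.fractions) == set("SEHDA")

    def test_onc_maximizes_q2(self):
        res = generate_aligned_molecules(
            FieldPlantSpec(n_molecules=20, noise_fraction=0.3, seed=4)
        )
        model = fit_pls(res.field_matrix, res.y, max_components=6)
        assert model.q2 == max(model.q2_per_component)
        assert model.q2_per_component[model.n_components - 1] == model.q2

    def test_degenerate_response_rejected(self):
        res = generate_aligned_molecules(FieldPlantSpec(n_molecules=6, seed=5))
        with pytest.raises(ValueError, match="degenerate"):
            fit_pls(res.field_matrix, np.ones(6), max_components=2)

    def test_empty_active_set_rejected(self):
        m = _mol([[0.0, 0, 0]])
        fm = assemble_field_matrix([m, m.translated(np.zeros(3)),
                                    m.translated(np.zeros(3)),
                                    m.translated(np.zeros(3))])
        with pytest.raises(ValueError, match="active"):
            fit_pls(fm, np.arange(4.0), max_components=2)


class TestContours:
    def _toy_model_matrix(self, coef_pattern):
        n_cols = len(coef_pattern)
        grid = FieldGrid(origin=(0.0, 0.0, 0.0), spacing=1.0,
                         counts=(n_cols, 1, 1))
        fm = FieldMatrix(
            compound_ids=["a", "b", "c", "d"],
            grid=grid,
            field_labels=("S",),
            values=np.random.default_rng(0).normal(size=(4, n_cols)),
            active_mask=np.ones(n_cols, dtype=bool),
        )
        from glioqsar.comsia import PlsQsarModel

        model = PlsQsarModel(
            n_components=1,
            coefficients=np.asarray(coef_pattern, dtype=float),
            x_mean=np.zeros(n_cols),
            y_mean=0.0,
            column_sd=np.ones(n_cols),
            q2=0.5, q2_per_component=[0.5], r2=0.9, see=0.1, f_value=5.0,
            fractions={"S": 1.0},
            active_mask=fm.active_mask,
            field_labels=("S",),
            grid=grid,
        )
        return model, fm

    def test_symmetric_pair_one_favored_one_disfavored(self):
        model, fm = self._toy_model_matrix([1.0, -1.0, 0.0, 0.0, 0.0])
        cs = contour_maps(model, fm, upper_pct=80, lower_pct=20)
        assert list(cs.per_field["S"].favored_points) == [0]
        assert list(cs.per_field["S"].disfavored_points) == [1]

    def test_raising_upper_pct_shrinks_favored(self):
        model, fm = self._toy_model_matrix(
            [3.0, 2.0, 1.0, 0.5, -0.5, -1.0, -2.0, -3.0]
        )
        small = contour_maps(model, fm, upper_pct=90, lower_pct=5)
        big = contour_maps(model, fm, upper_pct=60, lower_pct=5)
        assert set(small.per_field["S"].favored_points) <= set(
            big.per_field["S"].favored_points
        )

    def test_single_hot_column_is_unique_favored(self):
        model, fm = self._toy_model_matrix([0.0, 0.0, 5.0, 0.0, 0.0, 0.0])
        cs = contour_maps(model, fm, upper_pct=80, lower_pct=10)
        assert list(cs.per_field["S"].favored_points) == [2]

    def test_sparse_field_warns_and_empties(self):
        model, fm = self._toy_model_matrix([1.0, -1.0])
        fm.active_mask = np.array([True, False])
        model.active_mask = fm.active_mask
        model.coefficients = model.coefficients[:1]
        model.column_sd = model.column_sd[:1]
        with pytest.warns(UserWarning, match="fewer than 2"):
            cs = contour_maps(model, fm)
        assert len(cs.per_field["S"].favored_points) == 0


def test_dx_export_roundtrip(tmp_path):
    grid = FieldGrid(origin=(-1.0, -1.0, -1.0), spacing=1.0, counts=(2, 2, 2))
    vals = np.arange(8.0)
    p = tmp_path / "field.dx"
    write_dx(grid, vals, p)
    text = p.read_text()
    assert "counts 2 2 2" in text
    data = []
    for line in text.splitlines():
        parts = line.split()
        if parts and all(_is_float(x) for x in parts) and len(parts) <= 3:
            data.extend(float(x) for x in parts)
    # first 3 header lines contain origin/deltas; values appear after the
    # "data follows" marker — reparse robustly instead
    marker = text.index("data follows")
    tail = text[marker + len("data follows"):].split("attribute")[0].split()
    np.testing.assert_allclose([float(v) for v in tail], vals)


def _is_float(s):
    try:
        float(s)
        return True
    except ValueError:
        return False
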