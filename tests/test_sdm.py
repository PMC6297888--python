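import numpy as np
import pytest

from wildcons import sdm
from wildcons.core_grid import GridSpec, RasterLayer, cell_center, haversine_km
from wildcons.synthgen import NicheSpec, WorldConfig, generate_world, sample_species_occurrences


@pytest.fixture(scope="module")
def world():
    return generate_world(
        WorldConfig(n_rows=30, n_cols=30, n_species=1, predictor_style="independent", seed=5)
    )


def _niche(world, q=40, frac=10):
    vals = world.stack.layer("wc2.0_bio_2.5m_01").values[world.land_mask.values == 1]
    return NicheSpec(
        "wc2.0_bio_2.5m_01", float(np.percentile(vals, q)), float(np.ptp(vals) / frac)
    )


def _presences(world, niche, n, seed):
    cells = sample_species_occurrences(niche, world.stack, world.land_mask, 0, n, seed=seed)
    return [cell_center(world.grid, r, c) for r, c in cells], set(cells)


class TestPseudoAbsences:
    def test_counting(self, world):
        mask = world.land_mask
        pres = set(list(zip(*np.nonzero(mask.values == 1)))[:10])
        pres = {(int(r), int(c)) for r, c in pres}
        pts = sdm.sample_pseudo_absences(mask, pres, 50, seed=0)
        assert len(pts) == len(set(pts)) == 50
        for lon, lat in pts:
            r = int((mask.grid.origin_lat - lat) / mask.grid.cell_size_deg)
            c = int((lon - mask.grid.origin_lon) / mask.grid.cell_size_deg)
            assert mask.values[r, c] == 1
            assert (r, c) not in pres

    def test_determinism(self, world):
        a = sdm.sample_pseudo_absences(world.land_mask, set(), 100, seed=7)
        b = sdm.sample_pseudo_absences(world.land_mask, set(), 100, seed=7)
        assert a == b
        c = sdm.sample_pseudo_absences(world.land_mask, set(), 100, seed=8)
        assert a != c

    def test_fallback_when_too_few(self):
        g = GridSpec(cell_size_deg=1.0, origin_lon=0, origin_lat=5, n_rows=5, n_cols=5)
        vals = np.zeros(g.shape)
        vals[0, :3] = 1
        mask = RasterLayer(g, vals, "binary")
        with pytest.warns(UserWarning):
            pts = sdm.sample_pseudo_absences(mask, {(0, 0)}, 10, seed=0)
        assert len(pts) == 2

    def test_n_validation(self, world):
        with pytest.raises(ValueError):
            sdm.sample_pseudo_absences(world.land_mask, set(), 0, seed=0)


class TestFitOccurrenceModel:
    def test_niche_center_exceeds_edge(self, world):
        niche = _niche(world)
        pts, cells = _presences(world, niche, 80, seed=1)
        bg = sdm.sample_pseudo_absences(world.land_mask, cells, 400, seed=1)
        prob, _ = sdm.fit_occurrence_model(pts, bg, world.stack, world.land_mask, seed=1)
        vals = world.stack.layer(niche.predictor).values
        land = world.land_mask.values == 1
        dev = np.abs(vals - niche.optimum)
        center = land & (dev < niche.breadth)
        edge = land & (dev > 3 * niche.breadth)
        assert prob.values[center].mean() > prob.values[edge].mean()

    def test_uniform_presences_near_flat(self, world):
        rng = np.random.default_rng(2)
        rows, cols = np.nonzero(world.land_mask.values == 1)
        idx = rng.choice(len(rows), 80, replace=False)
        pts = [cell_center(world.grid, int(rows[i]), int(cols[i])) for i in idx]
        bg = sdm.sample_pseudo_absences(world.land_mask, set(), 400, seed=2)
        prob, _ = sdm.fit_occurrence_model(pts, bg, world.stack, world.land_mask, reg=8.0, seed=2)
        land = world.land_mask.values == 1
        null_spread = prob.values[land].std()

        niche = _niche(world, frac=20)
        sig_pts, sig_cells = _presences(world, niche, 80, seed=2)
        sig_bg = sdm.sample_pseudo_absences(world.land_mask, sig_cells, 400, seed=2)
        sig_prob, _ = sdm.fit_occurrence_model(
            sig_pts, sig_bg, world.stack, world.land_mask, reg=8.0, seed=2
        )
        sig_spread = sig_prob.values[land].std()
        assert null_spread < 0.5 * sig_spread  # no-signal prediction is much flatter

    def test_l1_path_never_gains_features(self, world):
        niche = _niche(world)
        pts, cells = _presences(world, niche, 60, seed=3)
        bg = sdm.sample_pseudo_absences(world.land_mask, cells, 300, seed=3)
        counts = []
        for reg in (0.5, 1.0, 2.0, 4.0, 8.0):
            _, model = sdm.fit_occurrence_model(pts, bg, world.stack, world.land_mask, reg=reg, seed=3)
            coefs = np.array(list(model.coefficients().values()))
            counts.append(int(np.sum(np.abs(coefs) > 1e-10)))
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_too_few_presences(self, world):
        with pytest.raises(sdm.TooFewPresencesError):
            sdm.fit_occurrence_model(
                [(0.0, 0.0)] * 5, [(1.0, 1.0)], world.stack, world.land_mask
            )

    def test_determinism_bit_identical(self, world):
        niche = _niche(world)
        pts, cells = _presences(world, niche, 40, seed=4)
        bg = sdm.sample_pseudo_absences(world.land_mask, cells, 200, seed=4)
        p1, _ = sdm.fit_occurrence_model(pts, bg, world.stack, world.land_mask, seed=4)
        p2, _ = sdm.fit_occurrence_model(pts, bg, world.stack, world.land_mask, seed=4)
        assert np.array_equal(p1.values, p2.values)


class TestValidateKfold:
    def test_strong_signal_high_auc(self, world):
        niche = _niche(world, frac=20)
        pts, cells = _presences(world, niche, 100, seed=5)
        bg = sdm.sample_pseudo_absences(world.land_mask, cells, 500, seed=5)
        m = sdm.validate_kfold(pts, bg, world.stack, world.land_mask, k=5, seed=5)
        assert m.mean_test_auc > 0.9
        assert m.fold_count == 5
        assert m.n_presence == 100

    def test_null_signal_auc_near_half(self, world):
        rng = np.random.default_rng(6)
        rows, cols = np.nonzero(world.land_mask.values == 1)
        idx = rng.choice(len(rows), 100, replace=False)
        pts = [cell_center(world.grid, int(rows[i]), int(cols[i])) for i in idx]
        bg = sdm.sample_pseudo_absences(world.land_mask, set(), 500, seed=6)
        m = sdm.validate_kfold(pts, bg, world.stack, world.land_mask, k=5, seed=6)
        assert 0.35 < m.mean_test_auc < 0.65

    def test_fold_partition_arithmetic(self):
        from sklearn.model_selection import KFold

        sizes = [len(test) for _, test in KFold(5, shuffle=True, random_state=0).split(range(50))]
        assert sizes == [10] * 5

    def test_too_few_for_folds(self, world):
        with pytest.raises(sdm.TooFewPresencesError):
            sdm.validate_kfold([(0.0, 0.0)] * 4, [(1.0, 1.0)], world.stack, world.land_mask, k=5)

    def test_pass_rule(self):
        good = sdm.ValidationMetrics(mean_test_auc=0.8, sd_test_auc=0.05)
        assert good.passed()
        assert not sdm.ValidationMetrics(mean_test_auc=0.65, sd_test_auc=0.05).passed()
        assert not sdm.ValidationMetrics(mean_test_auc=0.9, sd_test_auc=0.3).passed()


class TestThreshold:
    def test_separable(self, world):
        grid = world.grid
        vals = np.full(grid.shape, 0.1)
        pres_cells = [(2, 10), (5, 12), (9, 20)]
        for r, c in pres_cells:
            vals[r, c] = 0.9
        prob = RasterLayer(grid, vals, "continuous")
        pts = [cell_center(grid, r, c) for r, c in pres_cells]
        binary, thr = sdm.threshold_presence(prob, pts)
        assert thr == pytest.approx(0.9)
        expect = np.zeros(grid.shape)
        for r, c in pres_cells:
            expect[r, c] = 1
        np.testing.assert_array_equal(binary.values, expect)

    def test_matches_brute_force_scan(self, world):
        rng = np.random.default_rng(7)
        grid = world.grid
        vals = rng.uniform(size=grid.shape)
        prob = RasterLayer(grid, vals, "continuous")
        cells = [(int(r), int(c)) for r, c in rng.integers(0, 30, size=(15, 2))]
        pts = [cell_center(grid, r, c) for r, c in cells]
        _, thr = sdm.threshold_presence(prob, pts)
        p_pres = np.array([vals[r, c] for r, c in cells])
        b_vals = vals.ravel()
        best, best_t = -np.inf, None
        for t in np.unique(np.concatenate([p_pres, b_vals])):
            j = (p_pres >= t).mean() + (b_vals < t).mean()
            if j > best:
                best, best_t = j, t
        assert thr == pytest.approx(best_t)

    def test_constant_surface_tie_rule(self, world):
        grid = world.grid
        prob = RasterLayer(grid, np.full(grid.shape, 0.5), "continuous")
        binary, thr = sdm.threshold_presence(prob, [cell_center(grid, 1, 1)])
        assert thr == 0.5
        assert np.all(binary.values == 1)  # >= tie rule


class TestCA50:
    def test_single_point_disk(self, world):
        grid, mask = world.grid, world.land_mask
        pt = cell_center(grid, 15, 15)
        buf = sdm.ca50([pt], grid, mask)
        for r in range(grid.n_rows):
            for c in range(grid.n_cols):
                lon, lat = cell_center(grid, r, c)
                expected = (
                    haversine_km(pt[0], pt[1], lon, lat) <= 50.0 and mask.values[r, c] == 1
                )
                assert buf.values[r, c] == float(expected)

    def test_equator_radius_closed_form(self):
        g = GridSpec(cell_size_deg=0.5, origin_lon=0.0, origin_lat=2.5, n_rows=10, n_cols=10)
        mask = RasterLayer(g, np.ones(g.shape), "binary")
        pt = cell_center(g, 4, 4)  # near equator
        buf = sdm.ca50([pt], g, mask)
        # 50 km / 111.19 km/deg = 0.45 deg arc radius: neighbouring centres
        # sit 0.5 deg away, so only the point's own cell qualifies
        r, c = 4, 4
        assert buf.values[r, c] == 1
        assert buf.values[r, c - 1] == 0 and buf.values[r, c + 1] == 0
        assert buf.values.sum() == 1

        # at 0.25-deg cells the 0.45-deg radius reaches the neighbours
        g2 = GridSpec(cell_size_deg=0.25, origin_lon=0.0, origin_lat=1.25, n_rows=10, n_cols=10)
        mask2 = RasterLayer(g2, np.ones(g2.shape), "binary")
        pt2 = cell_center(g2, 4, 4)
        buf2 = sdm.ca50([pt2], g2, mask2)
        assert buf2.values[4, 3] == 1 and buf2.values[4, 5] == 1
        assert buf2.values[4, 6] == 0

    def test_union_property(self, world):
        grid, mask = world.grid, world.land_mask
        a = [cell_center(grid, 3, 10)]
        b = [cell_center(grid, 20, 25)]
        both = sdm.ca50(a + b, grid, mask)
        union = np.maximum(sdm.ca50(a, grid, mask).values, sdm.ca50(b, grid, mask).values)
        np.testing.assert_array_equal(both.values, union)

    def test_zero_points(self, world):
        with pytest.raises(ValueError):
            sdm.ca50([], world.grid, world.land_mask)


class TestRunSpeciesSDM:
    def test_fallback_to_ca50(self, world):
        pts = [cell_center(world.grid, 10, 10 + i) for i in range(3)]
        out = sdm.run_species_sdm("spX", pts, world.stack, world.land_mask, seed=0, n_background=100)
        assert out.model_kind == "ca50"
        assert not out.passed
        assert out.probability is None
        assert out.presence.semantics == "binary"

    def test_model_pathway(self, world):
        niche = _niche(world, frac=20)
        pts, _ = _presences(world, niche, 100, seed=9)
        out = sdm.run_species_sdm("spY", pts, world.stack, world.land_mask, seed=9, n_background=400)
        assert out.model_kind == "maxent_like"
        assert out.passed
        # presence=1 implies probability >= threshold
        on = out.presence.values == 1
        assert np.all(out.probability.values[on] >= out.metrics.threshold)
        # presence cells within the mask
        assert np.all(world.land_mask.values[on] == 1)
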