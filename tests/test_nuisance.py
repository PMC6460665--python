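"""Localized nuisance regression: WM regressors, detrending, residuals."""

import numpy as np
import pytest

from cerefc.grids import BinaryMask, VolumeGrid, VolumeSeries
from cerefc.nuisance import (LocalWMOperator, NuisanceDesign,
                             detrend_polynomial, legendre_basis,
                             local_wm_regressor, percent_signal_change,
                             regress_nuisance, regress_nuisance_matrix)


def _series_with(grid, assignments, t_len=20, fill=0.0):
    data = np.full(grid.dims + (t_len,), fill)
    for vox, ts in assignments.items():
        data[vox] = ts
    return VolumeSeries(grid, data)


def _mask_of(grid, voxels, label="white"):
    m = np.zeros(grid.dims, bool)
    for v in voxels:
        m[v] = True
    return BinaryMask(grid, m, label)


class TestLocalWM:
    def test_single_wm_voxel_returns_its_series(self, grid, rng):
        ts = rng.standard_normal(20)
        series = _series_with(grid, {(3, 3, 3): ts})
        wm = _mask_of(grid, [(3, 3, 3)])
        out = local_wm_regressor(series, wm, (4, 3, 3), radius_mm=15.0)
        assert np.allclose(out, ts)

    def test_opposite_series_cancel(self, grid, rng):
        ts = rng.standard_normal(20)
        series = _series_with(grid, {(3, 3, 3): ts, (3, 3, 4): -ts})
        wm = _mask_of(grid, [(3, 3, 3), (3, 3, 4)])
        out = local_wm_regressor(series, wm, (3, 3, 3), radius_mm=15.0)
        assert np.allclose(out, 0.0)

    def test_matches_brute_force_everywhere(self, rng):
        """5x5x5 toy image: per-voxel sphere average vs direct enumeration."""
        grid = VolumeGrid((5, 5, 5), (3.0, 3.0, 3.0))
        data = rng.standard_normal(grid.dims + (10,))
        series = VolumeSeries(grid, data)
        wm = BinaryMask(grid, rng.random(grid.dims) > 0.5, "white")
        radius = 7.0
        wm_idx = np.argwhere(wm.membership)
        for voxel in [(0, 0, 0), (2, 2, 2), (4, 1, 3)]:
            got = local_wm_regressor(series, wm, voxel, radius)
            d = np.linalg.norm((wm_idx - np.array(voxel)) * 3.0, axis=1)
            sel = wm_idx[d <= radius]
            expect = (np.mean([data[tuple(v)] for v in sel], axis=0)
                      if len(sel) else data[wm.membership].mean(axis=0))
            assert np.allclose(got, expect)

    def test_operator_agrees_with_per_voxel_calls(self, rng):
        grid = VolumeGrid((6, 6, 6), (3.0, 3.0, 3.0))
        series = VolumeSeries(grid, rng.standard_normal(grid.dims + (8,)))
        wm = BinaryMask(grid, rng.random(grid.dims) > 0.6, "white")
        gray = BinaryMask(grid, rng.random(grid.dims) > 0.5, "gray")
        op = LocalWMOperator(gray, wm, 7.0)
        out = op.apply(series)
        for row, vox in enumerate(np.argwhere(gray.membership)):
            assert np.allclose(out[row],
                               local_wm_regressor(series, wm, vox, 7.0))

    def test_empty_wm_mask_errors(self, grid, random_series):
        with pytest.raises(ValueError, match="empty white-matter"):
            local_wm_regressor(random_series, _mask_of(grid, []), (0, 0, 0))


class TestDetrend:
    def test_quartic_removed_to_machine_precision(self):
        t = np.linspace(-1, 1, 50)
        y = 3 - 2 * t + 0.5 * t ** 2 - t ** 3 + 2 * t ** 4
        assert np.allclose(detrend_polynomial(y, 4), 0.0, atol=1e-10)

    def test_order_zero_demeans(self, rng):
        y = rng.standard_normal(40)
        assert np.allclose(detrend_polynomial(y, 0), y - y.mean())

    def test_matches_projection_oracle(self, rng):
        """Cubic plus noise, order 4: identical to explicit hat-matrix LS."""
        t = np.linspace(-1, 1, 60)
        y = 1 + t ** 3 + 0.3 * rng.standard_normal(60)
        basis = legendre_basis(60, 4)
        hat = basis @ np.linalg.solve(basis.T @ basis, basis.T)
        assert np.allclose(detrend_polynomial(y, 4), y - hat @ y, atol=1e-10)

    def test_residual_orthogonal_to_basis(self, rng):
        y = rng.standard_normal(30)
        resid = detrend_polynomial(y, 3)
        basis = legendre_basis(30, 3)
        assert np.abs(basis.T @ resid).max() < 1e-10
        assert abs(resid.mean()) < 1e-12

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="too short"):
            detrend_polynomial(np.arange(4.0), 4)


class TestPSC:
    def test_scales_to_percent_of_mean(self, grid):
        data = np.full(grid.dims + (10,), 200.0)
        data[2, 2, 2] = 100.0 + np.arange(10)
        mask = BinaryMask(grid, np.ones(grid.dims, bool), "gray")
        out, ok = percent_signal_change(VolumeSeries(grid, data), mask)
        assert np.allclose(out.values[3, 3, 3], 100.0)
        expected = (100.0 + np.arange(10)) / (100.0 + 4.5) * 100.0
        assert np.allclose(out.values[2, 2, 2], expected)
        assert ok.n_voxels == mask.n_voxels

    def test_near_zero_mean_voxels_dropped(self, grid):
        data = np.zeros(grid.dims + (10,))
        data[1, 1, 1] = 50.0
        mask = BinaryMask(grid, np.ones(grid.dims, bool), "gray")
        _, ok = percent_signal_change(VolumeSeries(grid, data), mask)
        assert ok.n_voxels == 1


class TestRegression:
    def _design(self, rng, t_len=40, order=2):
        return NuisanceDesign(
            ventricle_series=rng.standard_normal(t_len),
            motion_series=rng.standard_normal((t_len, 6)),
            polynomial_order=order,
        )

    def test_design_span_input_gives_zero_residual(self, rng):
        design = self._design(rng)
        basis = np.column_stack([
            legendre_basis(40, 2),
            design.ventricle_series,
            design.motion_series,
        ])
        y = basis @ rng.standard_normal(basis.shape[1])
        resid = regress_nuisance_matrix(y[None, :], design)
        assert np.allclose(resid, 0.0, atol=1e-9)

    def test_constant_only_design_demeans(self, rng):
        y = rng.standard_normal((3, 30))
        design = NuisanceDesign(
            ventricle_series=np.zeros(30),
            motion_series=np.zeros((30, 6)),
            polynomial_order=0,
        )
        resid = regress_nuisance_matrix(y, design)
        assert np.allclose(resid, y - y.mean(axis=1, keepdims=True))

    def test_residuals_orthogonal_to_all_columns(self, rng):
        """Every voxel's residual is orthogonal to every design column,
        including its private localized WM regressor."""
        t_len = 50
        n_vox = 20
        design = NuisanceDesign(
            ventricle_series=rng.standard_normal(t_len),
            motion_series=rng.standard_normal((t_len, 6)),
            local_wm=rng.standard_normal((n_vox, t_len)),
            physio_series=rng.standard_normal((t_len, 3)),
            polynomial_order=4,
        )
        y = rng.standard_normal((n_vox, t_len))
        resid = regress_nuisance_matrix(y, design)
        basis = legendre_basis(t_len, 4)
        cols = np.column_stack([basis, design.ventricle_series,
                                design.motion_series, design.physio_series])
        for v in range(n_vox):
            r = resid[v]
            for c in cols.T:
                assert abs(r @ c) < 1e-8 * np.linalg.norm(r) * np.linalg.norm(c)
            w = design.local_wm[v]
            assert abs(r @ w) < 1e-8 * np.linalg.norm(r) * np.linalg.norm(w)

    def test_4d_wrapper_zero_outside_mask(self, grid, rng):
        series = VolumeSeries(grid, rng.standard_normal(grid.dims + (30,)))
        gray = _mask_of(grid, [(1, 1, 1), (2, 2, 2)], "gray")
        design = NuisanceDesign(
            ventricle_series=rng.standard_normal(30),
            motion_series=rng.standard_normal((30, 6)),
            polynomial_order=1,
        )
        resid = regress_nuisance(series, design, gray)
        assert np.all(resid.values[~gray.membership] == 0)
        assert not np.allclose(resid.values[1, 1, 1], 0)

    def test_length_mismatch_errors(self, rng):
        design = self._design(rng, t_len=40)
        with pytest.raises(ValueError, match="length"):
            regress_nuisance_matrix(rng.standard_normal((2, 30)), design)

    def test_rank_deficient_columns_dropped_with_warning(self, rng, caplog):
        t_len = 40
        vent = rng.standard_normal(t_len)
        motion = np.tile(vent[:, None], (1, 6))  # duplicated columns
        design = NuisanceDesign(ventricle_series=vent, motion_series=motion,
                                polynomial_order=1)
        import logging

        with caplog.at_level(logging.WARNING, logger="cerefc.nuisance"):
            resid = regress_nuisance_matrix(rng.standard_normal((2, t_len)),
                                            design)
        assert "rank-deficient" in caplog.text
        assert np.abs(resid @ vent).max() < 1e-8


class TestOnSyntheticSubject:
    def test_planted_nuisance_suppressed_and_coupling_kept(self):
        """After nuisance regression the residuals decorrelate from the
        planted drift/global components, drift removal lowers lag-1
        autocorrelation, and planted coupling survives within 0.05 z."""
        from cerefc.config import PipelineConfig
        from cerefc.masks import erode_mask
        from cerefc.nuisance import LocalWMOperator
        from cerefc.pipeline import preprocess_subject, _psc_rows
        from cerefc.simulate import CohortSimulation, SimulationDesign
        from cerefc.connectivity import fisher_z

        design = SimulationDesign(
            n_volumes=120,
            group_sizes={"ASD_F": 2, "ASD_M": 2, "TD_F": 2, "TD_M": 2},
            interaction_delta=0.0,
            global_signal_sd=0.1,   # moderate nuisance amplitudes
            rng_seed=5,
        )
        sim = CohortSimulation(design)
        wm_op = LocalWMOperator(sim.masks.gray,
                                erode_mask(sim.masks.white, 1), 15.0)
        cfg = PipelineConfig()
        subj = sim.subject(0)
        resid = preprocess_subject(subj, sim.masks, wm_op, cfg)

        drift = sim._drift_basis @ sim.truth.drift_coeffs[subj.subject]
        raw = _psc_rows(subj.series_smoothed.values,
                        sim.masks.gray.membership)
        for v in range(0, resid.shape[0], 97):
            c = np.corrcoef(resid[v], drift)[0, 1]
            assert abs(c) < 0.05

        def lag1(rows):
            a = rows - rows.mean(1, keepdims=True)
            num = (a[:, 1:] * a[:, :-1]).sum(1)
            den = (a ** 2).sum(1)
            return num / den

        assert lag1(resid).mean() < lag1(raw).mean()

        # planted coupling preserved after regression (region-mean series),
        # averaged over the planted cerebellar-cortical pairs
        rows = {rid: m.membership[sim.masks.gray.membership]
                for rid, m in zip(sim.masks.regions.ids,
                                  sim.masks.regions.masks)}

        def mean_pair_z(rows_a, rows_b, data):
            a = data[rows_a].mean(axis=0)
            b = data[rows_b].mean(axis=0)
            return fisher_z(np.corrcoef(a, b)[0, 1])

        ids = sim.truth.region_ids
        zs = [mean_pair_z(rows[a], rows[b], resid)
              - sim.truth.coupling_z["TD_M"][ids.index(a), ids.index(b)]
              for a, b in sim.truth.interaction_pairs]
        assert abs(np.mean(zs)) < 0.05
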