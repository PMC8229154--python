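import hashlib

import numpy as np
import pytest
import statsmodels.api as sm

from cognet.errors import ParameterError, SizingError, ValidationError
from cognet.metadata import MOCA_DOMAINS
from cognet.synthetic import (CohortConfig, PlantedModel, calibrate_residual_sd,
                              simulate_cohort, simulate_sources,
                              simulate_subject_bold, simulate_timecourses)

GRID = (20, 20, 10)


class TestSources:
    def test_compact_near_orthogonal_maps(self):
        maps, mask = simulate_sources(GRID, 6, seed=1)
        assert maps.shape == (6, int(mask.sum()))
        np.testing.assert_allclose(np.linalg.norm(maps, axis=1), 1.0, atol=1e-12)
        cos = maps @ maps.T
        off = np.abs(cos[~np.eye(6, dtype=bool)])
        assert off.max() < 0.2
        for m in maps:
            z = (m - m.mean()) / m.std()
            assert (np.abs(z) >= 1.0).sum() >= 50

    def test_seed_determinism(self):
        a, _ = simulate_sources(GRID, 6, seed=1)
        b, _ = simulate_sources(GRID, 6, seed=1)
        np.testing.assert_array_equal(a, b)
        c, _ = simulate_sources(GRID, 6, seed=2)
        assert not np.array_equal(a, c)

    def test_grid_too_small(self):
        with pytest.raises(SizingError):
            simulate_sources((6, 6, 4), 6, seed=0)
        with pytest.raises(ParameterError):
            simulate_sources(GRID, 0, seed=0)


@pytest.fixture(scope="module")
def truth():
    return simulate_cohort(CohortConfig(n_pd=3, n_ctr=2, noise_sd=0.0,
                                        group_effect={}), seed=4).truth


class TestSubjectBold:

    def test_noise_free_rank_equals_active_components(self, truth):
        b = simulate_subject_bold(truth, 0, seed=4)
        s = np.linalg.svd(b.data, compute_uv=False)
        assert int((s > s[0] * 1e-8).sum()) == truth.n_components

    def test_band_limited_power(self, truth):
        b = simulate_subject_bold(truth, 1, seed=4)
        # recover per-component time courses by projecting on the known maps
        tc, *_ = np.linalg.lstsq(truth.source_maps.T, b.data, rcond=None)
        freqs = np.fft.rfftfreq(b.n_timepoints, d=b.tr_seconds)
        for row in tc:
            p = np.abs(np.fft.rfft(row - row.mean())) ** 2
            assert p[(freqs > 0) & (freqs < 0.1)].sum() / p[freqs > 0].sum() >= 0.90

    def test_too_few_timepoints(self, truth):
        with pytest.raises(ParameterError):
            simulate_subject_bold(truth, 0, n_timepoints=10, seed=4)

    def test_band_at_nyquist_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ParameterError):
            simulate_timecourses(2, 100, 2.0, (0.01, 0.25), rng)


class TestCohort:
    def test_default_cohort_sizes_and_moca_administration(self):
        cfg = CohortConfig()
        assert (cfg.n_pd, cfg.n_ctr) == (40, 15)
        bundle = simulate_cohort(CohortConfig(grid_shape=(16, 16, 10),
                                              n_components=3, n_timepoints=40,
                                              n_pd=5, n_ctr=3), seed=6)
        md = bundle.metadata
        assert (md["group"] == "PD").sum() == 5 and (md["group"] == "Ctr").sum() == 3
        moca_cols = [c for c in md.columns if c.startswith("moca_") and c != "moca_total"]
        assert len(moca_cols) == 7
        assert md.loc[md.group == "Ctr", moca_cols].isna().all().all()
        assert md.loc[md.group == "PD", moca_cols].notna().all().all()
        for c in moca_cols:
            lo, hi = MOCA_DOMAINS[c.removeprefix("moca_")]
            vals = md.loc[md.group == "PD", c]
            assert vals.between(lo, hi).all()
            assert (vals == vals.round()).all()

    def test_written_files_deterministic(self, tmp_path):
        cfg = CohortConfig(grid_shape=(14, 14, 8), n_components=2, n_pd=2,
                           n_ctr=2, n_timepoints=30)
        def digest(d):
            h = hashlib.sha256()
            for p in sorted(d.glob("*")):
                h.update(p.name.encode())
                h.update(p.read_bytes())
            return h.hexdigest()
        simulate_cohort(cfg, seed=7, out_dir=tmp_path / "a")
        simulate_cohort(cfg, seed=7, out_dir=tmp_path / "b")
        assert digest(tmp_path / "a") == digest(tmp_path / "b")

    def test_unknown_planted_component_rejected(self):
        cfg = CohortConfig(n_components=3, planted_models={
            "attention": PlantedModel(components=(7,), betas=(1.0,))})
        with pytest.raises(ValidationError):
            simulate_cohort(cfg, seed=0)
        with pytest.raises(ValidationError):
            simulate_cohort(CohortConfig(n_pd=1), seed=0)

    def test_zero_residual_unrounded_scores_are_exact(self):
        cfg = CohortConfig(grid_shape=(16, 16, 10), n_components=3,
                           n_timepoints=40, n_pd=8, n_ctr=2, round_scores=False,
                           planted_models={
                               "attention": PlantedModel(components=(0, 2),
                                                         betas=(2.0, -1.5),
                                                         residual_sd=0.0)})
        b = simulate_cohort(cfg, seed=8)
        pd_mask = b.truth.groups == "PD"
        X = b.truth.subject_loadings[pd_mask][:, [0, 2]]
        y = b.metadata.loc[pd_mask, "moca_attention"].to_numpy(float)
        fit = sm.OLS(y, sm.add_constant(X)).fit()
        assert fit.rsquared == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(fit.params[1:], [2.0, -1.5], atol=1e-8)

    def test_r2_calibration_on_realized_samples(self):
        """Mean realized generating-model R² tracks the target within ±0.05.

        Measured with the true (planted) coefficients on the realized
        metadata of replicate cohorts, exactly as a user of the generator
        would check the calibration before running the pipeline.
        """
        cfg = CohortConfig(grid_shape=(14, 14, 10), n_components=3,
                           n_timepoints=30, n_pd=40, n_ctr=2,
                           planted_models={
                               "attention": PlantedModel(
                                   components=(0, 1, 2),
                                   betas=(1.925, -1.925, 1.925),
                                   r2_target=0.6),
                               "delayed_recall": PlantedModel((), ())})
        r2s = []
        for rep in range(60):
            b = simulate_cohort(cfg, seed=100 + rep)
            pm = b.truth.planted_models["attention"]
            pd_mask = b.truth.groups == "PD"
            L = b.truth.subject_loadings[pd_mask][:, list(pm.components)]
            lin = 3.0 + (L - cfg.loading_mean) @ np.array(pm.betas)
            y = b.metadata.loc[pd_mask, "moca_attention"].to_numpy(float)
            r2s.append(1.0 - np.mean((y - lin) ** 2) / np.var(y))
        assert abs(np.mean(r2s) - 0.6) <= 0.05

    def test_calibrate_residual_sd(self):
        # closed form: signal var 1.0, target 0.6 -> noise var 2/3 minus rounding 1/12
        sd = calibrate_residual_sd([1.925, -1.925, 1.925], 0.3, 0.6)
        assert sd == pytest.approx(np.sqrt(1.0 * (0.4 / 0.6) - 1 / 12), abs=2e-3)
        with pytest.raises(ParameterError):
            calibrate_residual_sd([1.0], 0.3, 1.5)
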