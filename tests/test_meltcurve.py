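"""Melting-curve preprocessing, sigmoid fitting and the nested F test."""

import numpy as np
import pandas as pd
import pytest

from targetdecon import meltcurve as mc
from targetdecon import synthetic as syn

TEMPS = np.array([37.3, 42.7, 46.2, 49.4, 52.7, 55.9, 59.4, 62.3])


def _long(protein, cond, rep, temps, abund):
    return pd.DataFrame(
        {
            "protein": protein,
            "condition": cond,
            "replicate": rep,
            "temperature": temps,
            "abundance": abund,
        }
    )


class TestSumTotalNormalize:
    def test_equal_totals_unchanged(self):
        df = pd.concat(
            [
                _long("p1", "vehicle", 1, [37.0, 50.0], [10.0, 5.0]),
                _long("p1", "treatment", 1, [37.0, 50.0], [10.0, 5.0]),
            ]
        )
        ds = mc.sum_total_normalize(mc.TppDataset(df))
        key = ["protein", "condition", "replicate", "temperature"]
        got = ds.data.sort_values(key).reset_index(drop=True)
        want = df.sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(got, want)

    def test_totals_rescaled_to_mean(self):
        # totals 100 and 300 at one temperature -> both rescaled to 200
        df = pd.concat(
            [
                _long("p1", "vehicle", 1, [37.0], [100.0]),
                _long("p1", "treatment", 1, [37.0], [300.0]),
            ]
        )
        ds = mc.sum_total_normalize(mc.TppDataset(df))
        assert sorted(ds.data.abundance) == [200.0, 200.0]

    def test_per_temperature_totals_equal_after(self):
        ds, _ = syn.gen_tpp(n_proteins=20, n_shifted=3, noise_cv=0.1, seed=0)
        norm = mc.sum_total_normalize(ds)
        g = norm.data.groupby(["temperature", "condition", "replicate"])["abundance"].sum()
        for temp, sub in g.groupby(level=0):
            np.testing.assert_allclose(sub, sub.mean(), rtol=1e-9)


class TestPsmFilter:
    def _ds(self, psm_pairs):
        rows = []
        psm = []
        for i, (v, t) in enumerate(psm_pairs):
            rows.append(_long(f"p{i}", "vehicle", 1, [37.0], [1.0]))
            psm.append((f"p{i}", "vehicle", v))
            psm.append((f"p{i}", "treatment", t))
        return mc.TppDataset(
            pd.concat(rows), pd.DataFrame(psm, columns=["protein", "condition", "psm"])
        )

    def test_all_below_threshold_empty(self):
        assert mc.psm_filter(self._ds([(1, 1)] * 3)).data.empty

    def test_boundary_inclusive(self):
        out = mc.psm_filter(self._ds([(2, 2)]))
        assert list(out.data.protein.unique()) == ["p0"]

    def test_mixed_table_counts(self):
        pairs = [(5, 5)] * 7 + [(1, 5), (5, 1), (1, 1)]
        out = mc.psm_filter(self._ds(pairs))
        assert out.data.protein.nunique() == 7


class TestScaleToReference:
    def test_division_and_idempotence(self):
        df = _long("p1", "vehicle", 1, [37.0, 50.0, 60.0], [200.0, 100.0, 50.0])
        fc = mc.scale_to_reference(mc.TppDataset(df))
        np.testing.assert_allclose(sorted(fc.data.abundance, reverse=True), [1.0, 0.5, 0.25])
        fc2 = mc.scale_to_reference(fc)
        pd.testing.assert_frame_equal(fc.data, fc2.data)

    def test_zero_reference_series_excluded(self):
        df = pd.concat(
            [
                _long("p1", "vehicle", 1, [37.0, 50.0], [0.0, 5.0]),
                _long("p2", "vehicle", 1, [37.0, 50.0], [10.0, 5.0]),
            ]
        )
        fc = mc.scale_to_reference(mc.TppDataset(df))
        assert set(fc.data.protein) == {"p2"}


class TestFitMeltCurve:
    def test_closed_form_tm_at_zero_plateau(self):
        y = mc.melt_curve(TEMPS, 550.0, 10.0, 0.0)
        fit = mc.fit_melt_curve(TEMPS, y)
        assert fit.tm == pytest.approx(55.0, abs=1e-6)

    @pytest.mark.parametrize(
        "a,b,plateau",
        [(550.0, 10.0, 0.0), (700.0, 14.0, 0.1), (900.0, 18.5, 0.25)],
    )
    def test_noise_free_parameter_recovery(self, a, b, plateau):
        y = mc.melt_curve(TEMPS, a, b, plateau)
        fit = mc.fit_melt_curve(TEMPS, y)
        assert fit.a == pytest.approx(a, rel=1e-6)
        assert fit.b == pytest.approx(b, rel=1e-6)
        assert fit.plateau == pytest.approx(plateau, abs=1e-6)
        # Tm closed form consistency
        assert fit.tm == pytest.approx(mc.melt_tm(fit.a, fit.b, fit.plateau), abs=1e-9)

    def test_constant_curve_has_no_tm(self):
        fit = mc.fit_melt_curve(TEMPS, np.ones_like(TEMPS))
        assert fit.tm is None

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            mc.fit_melt_curve(TEMPS[:4], np.ones(4))


class TestNparc:
    def test_identical_conditions_give_f_zero_p_one(self):
        rng = np.random.default_rng(0)
        y = mc.melt_curve(TEMPS, 650.0, 13.0, 0.05) + rng.normal(0, 0.03, len(TEMPS))
        res = mc.nparc_test((TEMPS, y), (TEMPS, y.copy()))
        assert res.f_stat == 0.0
        assert res.p == 1.0

    def test_noise_free_shift_exact_on_model_curves(self):
        # fold-change curves drawn exactly from the model: delta Tm is
        # recovered to numerical precision
        tt = np.tile(TEMPS, 2)
        for tm_v, b, plateau in [(49.0, 12.0, 0.1), (52.0, 18.0, 0.0)]:
            ell = np.log(0.5 / (0.5 - plateau))
            a_v = tm_v * (b - ell)
            a_t = (tm_v + 3.0) * (b - ell)
            y_v = np.tile(mc.melt_curve(TEMPS, a_v, b, plateau), 2)
            y_t = np.tile(mc.melt_curve(TEMPS, a_t, b, plateau), 2)
            res = mc.nparc_test((tt, y_v), (tt, y_t))
            assert res.delta_tm == pytest.approx(3.0, abs=1e-3)

    def test_noise_free_shift_through_full_pipeline(self, small_tpp):
        # scaling to the reference point divides by f(T0) (0.95-1.0), which
        # takes curves slightly out of the model family; the residual
        # delta-Tm bias stays well below the 1 degC hit threshold
        ds, truth = small_tpp
        fc = mc.scale_to_reference(ds)
        res = mc.run_nparc(fc)
        for prot, rec in truth.truth.items():
            got = res.loc[res.protein == prot, "delta_tm"].item()
            assert got == pytest.approx(rec["delta_tm"], abs=0.2)

    def test_nestedness_rss_alt_le_rss_null(self, noisy_tpp_results):
        res, _ = noisy_tpp_results
        ok = res[res.tested]
        assert (ok.rss_alt <= ok.rss_null + 1e-12).all()

    def test_too_few_points_raise(self):
        t = TEMPS[:3]
        y = mc.melt_curve(t, 550.0, 10.0, 0.0)
        with pytest.raises(ValueError):
            mc.nparc_test((t, y), (t, y))


class TestCallHits:
    def _results(self, pvals, dtms):
        return pd.DataFrame(
            {
                "protein": [f"p{i}" for i in range(len(pvals))],
                "tested": True,
                "p": pvals,
                "delta_tm": dtms,
                "f_stat": 1.0,
                "rss_null": 1.0,
                "rss_alt": 0.5,
            }
        )

    def test_all_p_one_no_hits(self):
        out = mc.call_hits(self._results([1.0] * 5, [5.0] * 5))
        assert not out.hit.any()

    def test_delta_tm_boundary_strict(self):
        out = mc.call_hits(self._results([1e-9, 1e-9], [1.0, 1.0001]))
        assert out.hit.tolist() == [False, True]

    def test_undefined_delta_tm_cannot_be_hit(self):
        out = mc.call_hits(self._results([1e-9], [np.nan]))
        assert not out.hit.any()

    def test_direction_labels(self):
        out = mc.call_hits(self._results([1e-9, 1e-9], [3.0, -3.0]))
        assert out.direction.tolist() == ["stabilized", "destabilized"]

    def test_bh_adjustment_monotone_in_p(self, noisy_tpp_results):
        res, _ = noisy_tpp_results
        out = mc.call_hits(res).sort_values("p")
        padj = out.loc[out.tested, "p_adj"].to_numpy()
        assert (np.diff(padj) >= -1e-12).all()
        assert (out.loc[out.tested, "p_adj"] >= out.loc[out.tested, "p"] - 1e-12).all()

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            mc.call_hits(pd.DataFrame())

    def test_spiked_proteins_recovered(self, noisy_tpp_results):
        res, truth = noisy_tpp_results
        out = mc.call_hits(res, alpha=0.01, min_abs_dtm=1.0)
        called = set(out.loc[out.hit, "protein"])
        spiked = set(truth.truth)
        assert len(called & spiked) >= 5  # of 6
        assert (out.loc[out.hit & out.protein.isin(spiked), "direction"] == "stabilized").all()


class TestEmpiricalDf:
    def test_rescore_preserves_ranking_and_tightens_tail(self, noisy_tpp_results):
        res, _ = noisy_tpp_results
        rese = mc.rescore_empirical(res)
        ok = res.tested
        # same ordering of evidence
        r1 = res.loc[ok, "f_stat"].rank()
        r2 = rese.loc[ok, "f_stat"].rank()
        assert (r1 == r2).all()
        assert rese.attrs["d2_eff"] < res.loc[ok].shape[0] * 32


class TestCetsa:
    def test_reference_normalization_and_gain_invariance(self):
        y = mc.melt_curve(TEMPS, 700.0, 14.0, 0.05) * 5e4
        fit1 = mc.cetsa_melt(TEMPS, y)
        fit2 = mc.cetsa_melt(TEMPS, y * 3.7)
        assert fit1.tm == pytest.approx(fit2.tm, abs=1e-6)

    def test_noise_free_recovery(self):
        # normalizing to the lowest-temperature signal (f(T0) ~ 0.97, not 1)
        # rescales the curve slightly, so Tm is recovered to ~0.1 degC
        y = mc.melt_curve(TEMPS, 820.0, 16.0, 0.12) * 1234.5
        fit = mc.cetsa_melt(TEMPS, y)
        assert fit.tm == pytest.approx(mc.melt_tm(820.0, 16.0, 0.12), abs=0.1)

    def test_replicates_averaged(self):
        t = np.repeat(TEMPS, 2)
        y = np.repeat(mc.melt_curve(TEMPS, 700.0, 14.0, 0.0), 2)
        fit = mc.cetsa_melt(t, y)
        assert fit.n_points == len(TEMPS)
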