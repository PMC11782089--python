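"""Generator contracts: determinism, ground-truth completeness, and the
constructions each downstream stage relies on."""

import numpy as np
import pandas as pd
import pytest

from targetdecon import meltcurve as mc
from targetdecon import synthetic as syn


@pytest.mark.parametrize(
    "gen, kwargs",
    [
        (syn.gen_tpp, dict(n_proteins=8, n_shifted=2, noise_cv=0.05)),
        (syn.gen_featuretable, dict(n_compound_wells=6, n_dmso_wells=4, n_features=30)),
        (syn.gen_crispr, dict(n_genes=20, n_resistance=3)),
        (syn.gen_expression, dict(n_entities=50, n_regulated=5)),
    ],
)
def test_generators_deterministic_under_seed(gen, kwargs):
    out1, truth1 = gen(seed=123, **kwargs)
    out2, truth2 = gen(seed=123, **kwargs)
    df1 = out1.data if hasattr(out1, "data") else out1
    df2 = out2.data if hasattr(out2, "data") else out2
    pd.testing.assert_frame_equal(df1, df2)
    assert truth1.to_json() == truth2.to_json()


def test_ppi_and_doseresp_deterministic():
    pd.testing.assert_frame_equal(
        syn.gen_ppi(n_nodes=30, mean_degree=3, seed=9),
        syn.gen_ppi(n_nodes=30, mean_degree=3, seed=9),
    )
    pd.testing.assert_frame_equal(
        syn.gen_doseresp(noise_cv=0.1, seed=9), syn.gen_doseresp(noise_cv=0.1, seed=9)
    )


def test_truth_lists_exactly_the_affected_entities():
    _, truth = syn.gen_tpp(n_proteins=15, n_shifted=4, noise_cv=0.0, seed=0)
    assert len(truth.truth) == 4
    _, truth = syn.gen_crispr(n_genes=30, n_resistance=7, seed=0)
    assert len(truth.truth) == 7
    _, truth = syn.gen_expression(n_entities=40, n_regulated=0, seed=0)
    assert truth.truth == {}


class TestGenTpp:
    def test_zero_noise_null_gives_identical_conditions(self):
        ds, _ = syn.gen_tpp(n_proteins=6, n_shifted=0, noise_cv=0.0, seed=3)
        wide = ds.data.pivot_table(
            index=["protein", "replicate", "temperature"],
            columns="condition",
            values="abundance",
        )
        np.testing.assert_allclose(wide["treatment"], wide["vehicle"], rtol=1e-12)

    def test_spiked_delta_tm_exact_in_closed_form(self):
        _, truth = syn.gen_tpp(n_proteins=5, n_shifted=1, delta_tm=3.0, noise_cv=0.0, seed=1)
        rec = truth.truth["P00000"]
        tm_v = mc.melt_tm(rec["a_vehicle"], rec["b"], rec["plateau"])
        tm_t = mc.melt_tm(rec["a_treatment"], rec["b"], rec["plateau"])
        assert tm_t - tm_v == pytest.approx(3.0, abs=1e-9)

    def test_curves_informative_across_gradient(self):
        ds, _ = syn.gen_tpp(n_proteins=40, n_shifted=0, noise_cv=0.0, seed=7)
        fc = mc.scale_to_reference(ds)
        lo = fc.data[fc.data.temperature == fc.temperatures[0]]
        hi = fc.data[fc.data.temperature == fc.temperatures[-1]]
        assert (hi.abundance < 0.3).all()
        assert (lo.abundance == 1.0).all()

    def test_non_monotone_temps_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_tpp(n_proteins=3, temps=[40, 39, 50, 55, 60], seed=0)

    def test_shift_outside_gradient_warns_but_generates(self):
        with pytest.warns(UserWarning):
            ds, _ = syn.gen_tpp(n_proteins=3, n_shifted=1, delta_tm=30.0, noise_cv=0.0, seed=0)
        assert len(ds.data) > 0


class TestGenPpi:
    def test_zero_mean_degree_gives_no_edges(self):
        assert len(syn.gen_ppi(n_nodes=10, mean_degree=0, seed=0)) == 0

    def test_complete_graph_option(self):
        edges = syn.gen_ppi(n_nodes=4, mean_degree=2, model="complete", seed=0)
        assert len(edges) == 6

    def test_annotations_pass_default_filter(self):
        from targetdecon import permnet as pn

        edges = syn.gen_ppi(n_nodes=30, mean_degree=4, seed=1)
        db = pn.filter_interactions(edges)
        assert db.n_edges == len(edges)


class TestGenFeatureTable:
    def test_zero_effect_wells_exchangeable_with_dmso(self):
        table, truth = syn.gen_featuretable(
            n_compound_wells=10, n_dmso_wells=10, n_features=50, effect_size=0.0, seed=2
        )
        feats = table.drop(columns="role")
        cpd = feats[table.role == "compound"].to_numpy().ravel()
        dmso = feats[table.role == "DMSO"].to_numpy().ravel()
        from scipy import stats

        assert stats.ks_2samp(cpd, dmso).pvalue > 0.01
        assert truth.truth == {}

    def test_same_axis_wells_biosimilar_in_noiseless_limit(self):
        from targetdecon import morphoprofile as mp

        table, truth = syn.gen_featuretable(
            n_compound_wells=6, n_dmso_wells=6, n_features=100,
            phenotype_axes=2, effect_size=10.0, noise_sd=1e-4, seed=4,
        )
        feats = table.drop(columns="role")
        dmso = table.index[table.role == "DMSO"].tolist()
        profiles = mp.robust_z(feats, dmso)
        wells = [w for w in table.index if w.startswith("CPD")]
        for i in range(len(wells)):
            for j in range(i + 1, len(wells)):
                sim = mp.biosimilarity(profiles[wells[i]], profiles[wells[j]])
                same = truth.truth[wells[i]]["axis"] == truth.truth[wells[j]]["axis"]
                if same:
                    assert sim > 0.999
                else:
                    assert sim < 0.9


class TestGenCrispr:
    def test_zero_effect_no_truth_and_exchangeable_counts(self):
        counts, truth = syn.gen_crispr(n_genes=50, n_resistance=5, effect_lfc=0.0, seed=6)
        assert truth.truth == {}
        # same expected counts: totals within a few percent
        assert counts["treatment"].sum() == pytest.approx(counts["control"].sum(), rel=0.05)

    def test_active_guide_lfc_matches_effect_at_high_depth(self):
        # Monte-Carlo mean over many active guides at high depth
        counts, truth = syn.gen_crispr(
            n_genes=2500, n_resistance=1250, guides_per_gene=4, effect_lfc=2.0,
            frac_active_guides=1.0, depth=2000, dispersion=0.01, seed=8,
        )
        active = counts.gene.isin(truth.truth.keys())
        lfc = np.log2(counts.treatment + 1) - np.log2(counts.control + 1)
        # renormalization by total depth shifts all guides by a constant;
        # compare active vs inactive difference
        diff = lfc[active].mean() - lfc[~active].mean()
        assert diff == pytest.approx(2.0, abs=0.1)


class TestGenDoseresp:
    def test_noise_free_values_lie_on_the_4pl(self):
        from targetdecon.doseresp import four_pl

        plate = syn.gen_doseresp(ec50=0.2, hill=2.0, top=1.0, bottom=0.1, noise_cv=0.0, seed=0)
        s = plate[plate.role == "sample"]
        expected = four_pl(s.concentration.to_numpy(), 0.2, 2.0, 1.0, 0.1)
        np.testing.assert_allclose(s.signal.to_numpy() / 1e5, expected, rtol=1e-12)

    def test_asymptotes(self):
        plate = syn.gen_doseresp(
            ec50=0.1, hill=2.0, top=1.0, bottom=0.0,
            concs=[1e-6, 1e6, 1e-5, 1e5], noise_cv=0.0, seed=0,
        )
        s = plate[plate.role == "sample"].set_index("concentration")["signal"] / 1e5
        assert s[1e-6] == pytest.approx(1.0, abs=1e-6)
        assert s[1e6] == pytest.approx(0.0, abs=1e-6)


class TestGenExpression:
    def test_regulated_set_recovers_spiked_truth_exactly(self):
        from targetdecon import permnet as pn

        table, truth = syn.gen_expression(n_entities=200, n_regulated=30, seed=10)
        reg = pn.regulated_set(table.rename(columns={"entity": "protein"}))
        assert reg.proteins == {k.upper() for k in truth.truth}
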