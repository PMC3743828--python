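"""Generator contracts: planted structure, determinism, and count moments."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, mannwhitneyu

import devscreen as ds
from devscreen.simulate import DesignError, expected_mean_matrix


def small_design():
    return ds.default_design(n_normal=2, n_delayed=1, n_no_development=1)


class TestDesignAndParams:
    def test_default_design_matches_panel_structure(self):
        d = ds.default_design()
        assert len(d.strain_ids) == 36
        assert len(d.strains_in_category("normal")) == 30
        assert len(d.strains_in_category("delayed")) == 4
        assert len(d.strains_in_category("no_development")) == 1
        assert d.time_points_h == (0.0, 6.0, 12.0, 18.0)
        assert d.replicates == 2
        assert d.wildtype == "WT"

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(strain_ids=("A", "B"), category_of_strain={"A": "normal", "B": "normal"}),
            dict(
                strain_ids=("A", "B"),
                category_of_strain={"A": "wildtype", "B": "normal"},
                time_points_h=(6.0, 6.0),
            ),
            dict(
                strain_ids=("A", "B"),
                category_of_strain={"A": "wildtype", "B": "weird"},
            ),
        ],
    )
    def test_invalid_designs_rejected(self, kwargs):
        with pytest.raises(DesignError):
            ds.PanelDesign(**kwargs)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(frac_core=0.7, frac_perturbable=0.5),
            dict(nb_dispersion=0.0),
            dict(enrichment_of_dev_labels_in_core=0.5),
            dict(n_genes=0),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(DesignError):
            ds.SimulationParams(**kwargs)


class TestCatalogGeneration:
    def test_zero_core_fraction_gives_empty_core(self):
        params = ds.SimulationParams(n_genes=200, frac_core=0.0, seed=3)
        _, truth = ds.generate_catalog(params, small_design())
        assert truth.core_gene_ids == frozenset()

    def test_core_count_is_deterministic_rounding(self):
        params = ds.SimulationParams(n_genes=1000, frac_core=0.1, seed=3)
        _, truth = ds.generate_catalog(params, small_design())
        assert len(truth.core_gene_ids) == 100

    def test_unit_enrichment_leaves_core_label_rate_at_background(self):
        # with odds multiplier 1, the developmental-label frequency among
        # core genes must sit inside the exact binomial interval around the
        # background rate
        params = ds.SimulationParams(
            n_genes=20_000, enrichment_of_dev_labels_in_core=1.0, seed=11
        )
        catalog, truth = ds.generate_catalog(params, small_design())
        core = sorted(truth.core_gene_ids)
        k = int(catalog.table.loc[core, "dev_flag"].sum())
        n = len(core)
        lo, hi = binom.ppf([0.0005, 0.9995], n, params.frac_dev_labels)
        assert lo <= k <= hi

    def test_enriched_core_exceeds_background(self):
        params = ds.SimulationParams(n_genes=20_000, seed=11)
        catalog, truth = ds.generate_catalog(params, small_design())
        core = sorted(truth.core_gene_ids)
        rate_core = catalog.table.loc[core, "dev_flag"].mean()
        rate_bg = catalog.table["dev_flag"].mean()
        assert rate_core > 1.5 * rate_bg

    def test_catalog_invariants(self):
        catalog, truth = ds.generate_catalog(
            ds.SimulationParams(n_genes=500, seed=5), small_design()
        )
        t = catalog.table
        assert (t["mappable_exon_length_nt"] > 0).all()
        assert not (t["dev_flag"] & t["nondev_flag"]).any()
        assert set(t["celltype_label"]) <= {"prespore", "prestalk", "none"}
        # conserved flag is a biased superset around the core
        core = sorted(truth.core_gene_ids)
        assert t.loc[core, "conserved_flag"].mean() > t["conserved_flag"].mean()

    def test_peak_time_is_profile_argmax(self):
        _, truth = ds.generate_catalog(
            ds.SimulationParams(n_genes=400, seed=5), small_design()
        )
        argmax = truth.wt_profile.idxmax(axis=1).astype(float)
        assert (argmax == truth.peak_time_h.astype(float)).all()

    def test_core_never_perturbed_in_normal_strains(self):
        design = small_design()
        _, truth = ds.generate_catalog(ds.SimulationParams(n_genes=500, seed=5), design)
        normal = set(design.strains_in_category("normal"))
        for g in truth.core_gene_ids:
            assert not (truth.perturbed_in.get(g, frozenset()) & normal)


class TestCountGeneration:
    def test_same_seed_is_byte_identical(self):
        design = small_design()
        params = ds.SimulationParams(n_genes=200, seed=9)
        catalog, truth = ds.generate_catalog(params, design)
        a = ds.generate_counts(design, params, truth, catalog)
        b = ds.generate_counts(design, params, truth, catalog)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_count_redraw_changes_counts_not_truth(self):
        design = small_design()
        params = ds.SimulationParams(n_genes=200, seed=9)
        catalog, truth = ds.generate_catalog(params, design)
        a = ds.generate_counts(design, params, truth, catalog)
        b = ds.generate_counts(design, params, truth, catalog, count_seed=12345)
        assert not a.counts.equals(b.counts)

    def test_counts_are_nonneg_integers_with_expected_totals(self, small_panel):
        panel, _, _ = small_panel
        vals = panel.counts.to_numpy()
        assert (vals >= 0).all()
        assert np.issubdtype(vals.dtype, np.integer)
        params = ds.SimulationParams(n_genes=300, seed=7)
        totals = panel.counts.sum(axis=0)
        tol = 5 * params.library_size_cv * params.library_size_mean
        assert ((totals - params.library_size_mean).abs() < tol).all()

    def test_null_effect_size_makes_strains_exchangeable(self):
        # with no planted fold change, pooled mutant counts and WT counts
        # are draws from the same NB at each (gene, time)
        design = small_design()
        params = ds.SimulationParams(
            n_genes=100, frac_core=0.0, frac_perturbable=0.3,
            effect_size_logfc=0.0, seed=21,
        )
        catalog, truth = ds.generate_catalog(params, design)
        panel = ds.generate_counts(design, params, truth, catalog)
        wt = panel.samples_for(strain="WT", time_h=12.0)
        mut = panel.samples_for(category="normal", time_h=12.0)
        pvals = [
            mannwhitneyu(row[wt], row[mut]).pvalue
            for _, row in panel.counts.iterrows()
        ]
        assert np.mean(np.asarray(pvals) > 0.01) >= 0.95

    def test_large_dispersion_reaches_poisson_limit(self):
        # NB closed form: var = mu + mu^2/size, so size -> large gives
        # var/mean -> 1
        design = ds.PanelDesign(
            strain_ids=("WT",),
            category_of_strain={"WT": "wildtype"},
            time_points_h=(0.0,),
            replicates=50,
        )
        params = ds.SimulationParams(
            n_genes=10_000, nb_dispersion=1e6, frac_core=0.0,
            frac_perturbable=0.0, library_size_cv=1e-6, seed=13,
        )
        catalog, truth = ds.generate_catalog(params, design)
        panel = ds.generate_counts(design, params, truth, catalog)
        x = panel.counts.to_numpy(dtype=float)
        m = x.mean(axis=1)
        v = x.var(axis=1, ddof=1)
        keep = m > 20
        ratio = (v[keep] / m[keep]).mean()
        assert abs(ratio - 1.0) < 0.05

    def test_core_expected_means_match_wildtype_in_normal_strains(self):
        # counts are compositional (fixed depth), so unperturbed genes in
        # normal strains keep the WT relative abundance up to one
        # composition scalar per (strain, time) column
        design = small_design()
        params = ds.SimulationParams(n_genes=300, seed=7)
        catalog, truth = ds.generate_catalog(params, design)
        mu = expected_mean_matrix(design, params, truth, catalog)
        core = sorted(truth.core_gene_ids)
        for s in design.strains_in_category("normal"):
            for t in design.time_points_h:
                ratio = mu.loc[core, (s, t)] / mu.loc[core, ("WT", t)]
                np.testing.assert_allclose(ratio, ratio.iloc[0], rtol=1e-9)

    def test_expected_columns_sum_to_one(self):
        design = small_design()
        params = ds.SimulationParams(n_genes=300, seed=7)
        catalog, truth = ds.generate_catalog(params, design)
        mu = expected_mean_matrix(design, params, truth, catalog)
        np.testing.assert_allclose(mu.sum(axis=0), 1.0)

    def test_delayed_strains_use_lagged_profile(self):
        design = small_design()
        params = ds.SimulationParams(n_genes=100, frac_perturbable=0.0, seed=7)
        catalog, truth = ds.generate_catalog(params, design)
        mu = expected_mean_matrix(design, params, truth, catalog)
        noncore = [g for g in mu.index if g not in truth.core_gene_ids]
        # the delayed strain's 12-h column is the WT 6-h column up to the
        # per-time normalization scalar
        ratio = mu.loc[noncore, ("D01", 12.0)] / mu.loc[noncore, ("WT", 6.0)]
        np.testing.assert_allclose(ratio, ratio.iloc[0], rtol=1e-9)


def test_calibration_panel_plants_exact_fraction():
    panel, catalog, truth = ds.calibration_panel(n_genes=1000, de_fraction=0.1, seed=2)
    planted = truth.perturbed_genes_of("N01")
    assert len(planted) == 100
    assert truth.core_gene_ids == frozenset()
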