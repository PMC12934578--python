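"""Generator: determinism, digestion rules, methylome structure, spectra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import methylworm as mw
from methylworm.constants import FORM_LOSSES, PROTON_MASS
from methylworm.synthetic import ConfigurationError, _peptide_for_site
from methylworm.types import Mod


class TestProteome:
    def test_deterministic_for_fixed_seed(self):
        cfg = mw.SimConfig(seed=1, n_proteins=10)
        assert mw.generate_proteome(cfg) == mw.generate_proteome(cfg)

    def test_different_seed_differs(self):
        a = mw.generate_proteome(mw.SimConfig(seed=1, n_proteins=10))
        b = mw.generate_proteome(mw.SimConfig(seed=2, n_proteins=10))
        assert a != b

    def test_empty_proteome(self):
        assert mw.generate_proteome(mw.SimConfig(n_proteins=0)) == {}

    def test_standard_residues_only(self, small_study):
        for seq in small_study["proteome"].values():
            assert set(seq) <= set("ACDEFGHIKLMNPQRSTVWY")

    def test_invalid_length_range_rejected(self):
        with pytest.raises(ConfigurationError):
            mw.SimConfig(protein_length_range=(50, 10))


class TestDigest:
    @pytest.mark.parametrize(
        "max_missed,expected",
        [
            (0, {"AAGK", "FFRPGGK", "LLR"}),
            (1, {"AAGK", "FFRPGGK", "LLR", "AAGKFFRPGGK", "FFRPGGKLLR"}),
        ],
    )
    def test_classic_trypsin_skips_proline(self, max_missed, expected):
        peps = mw.digest("AAGKFFRPGGKLLR", max_missed=max_missed, length_range=(1, 50))
        assert {p["peptide"] for p in peps} == expected

    def test_trypsin_p_cleaves_before_proline(self):
        peps = mw.digest("AAGKFFRPGGKLLR", max_missed=0, length_range=(1, 50),
                         trypsin_p=True)
        assert "FFR" in {p["peptide"] for p in peps}

    def test_coordinates_are_one_based_and_consistent(self):
        seq = "AAGKFFRPGGKLLR"
        for p in mw.digest(seq, 2, (1, 50)):
            assert seq[p["start"] - 1 : p["end"]] == p["peptide"]

    @given(st.text(alphabet="ACDKRGPLS", min_size=1, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_length_filter_contract(self, seq):
        for p in mw.digest(seq, 4, (7, 50)):
            assert 7 <= len(p["peptide"]) <= 50


class TestMethylome:
    def test_form_proportions_reproducible(self, small_config):
        proteome = mw.generate_proteome(small_config)
        t1 = mw.simulate_methylome(proteome, small_config)
        t2 = mw.simulate_methylome(proteome, small_config)
        assert t1.sites.equals(t2.sites)
        k_frac = (t1.sites.residue == "K").mean()
        assert abs(k_frac - 0.74) < 0.15  # binomial noise around the target

    def test_rg_bias_one_places_all_r_sites_in_rg_context(self):
        cfg = mw.SimConfig(seed=3, n_proteins=30, rg_motif_bias=1.0,
                           rgg_protein_fraction=1.0, n_sites=60)
        proteome = mw.generate_proteome(cfg)
        truth = mw.simulate_methylome(proteome, cfg)
        r_sites = truth.sites[truth.sites.residue == "R"]
        assert len(r_sites) > 0
        for _, s in r_sites.iterrows():
            seq = proteome[s.protein]
            assert seq[s.position] == "G"  # the residue after the R

    def test_no_substrate_sites_when_zero(self):
        cfg = mw.SimConfig(seed=1, n_proteins=20, n_sites=40, n_substrate_sites=0)
        truth = mw.simulate_methylome(mw.generate_proteome(cfg), cfg)
        assert not truth.sites.ko1_dependent.any()

    def test_too_many_sites_rejected(self):
        cfg = mw.SimConfig(seed=1, n_proteins=2, protein_length_range=(30, 40),
                           n_sites=500)
        with pytest.raises(ConfigurationError):
            mw.simulate_methylome(mw.generate_proteome(cfg), cfg)

    def test_ablation_range_respected(self, small_study):
        dep = small_study["truth"].sites.query("ko1_dependent")
        assert ((dep.ablation_log2fc >= -9) & (dep.ablation_log2fc <= -5)).all()


class TestPsmTable:
    def test_decoy_fraction(self, small_study):
        frac = small_study["psms"]["is_decoy"].mean()
        assert 0.2 < frac < 0.4  # configured 0.3

    def test_reproducible(self, small_config):
        proteome = mw.generate_proteome(small_config)
        truth = mw.simulate_methylome(proteome, small_config)
        a = mw.simulate_psm_table(truth.sites, proteome, small_config)
        b = mw.simulate_psm_table(truth.sites, proteome, small_config)
        assert a.drop(columns="mods").equals(b.drop(columns="mods"))
        assert list(a["mods"]) == list(b["mods"])

    def test_separable_scores_keep_every_target(self, small_config):
        cfg = mw.SimConfig(seed=1, n_proteins=30, n_sites=60,
                           target_score_mean=100.0, decoy_score_mean=0.0,
                           score_sd=0.01, false_target_rate=0.0)
        proteome = mw.generate_proteome(cfg)
        truth = mw.simulate_methylome(proteome, cfg)
        psms = mw.simulate_psm_table(truth.sites, proteome, cfg)
        _, retained, fdr = mw.compute_methyl_fdr_threshold(psms, 0.01)
        assert len(retained) == (~psms["is_decoy"]).sum()
        assert fdr == 0


class TestSpectrum:
    CFG = mw.SimConfig(seed=1)

    def test_ladder_size_without_losses(self):
        pep = "AGSTVLK"
        spec = mw.simulate_spectrum(pep, (), 2, self.CFG, mass_sigma=0.0)
        assert len(spec.mz) == 2 * (len(pep) - 1)
        assert len(spec.annotations) == 2 * (len(pep) - 1)

    def test_adma_loss_displacement_exact_at_zero_sigma(self):
        pep = "AGSRVLK"
        mods = (Mod(4, "R", "ADMA", 1.0),)
        spec = mw.simulate_spectrum(pep, mods, 2, self.CFG, mass_sigma=0.0)
        # precursor companion sits exactly loss/z below the precursor
        deltas = (spec.precursor_mz - spec.mz) * 2
        assert np.any(np.abs(deltas - FORM_LOSSES["ADMA"]) < 1e-9)

    def test_combined_adma_sdma_precursor_loss(self):
        pep = "AGRSRVLK"
        mods = (Mod(3, "R", "ADMA", 1.0), Mod(5, "R", "SDMA", 1.0))
        spec = mw.simulate_spectrum(pep, mods, 2, self.CFG, mass_sigma=0.0)
        deltas = (spec.precursor_mz - spec.mz) * 2
        combined = FORM_LOSSES["ADMA"] + FORM_LOSSES["SDMA"]
        assert abs(combined - 76.100) < 1e-3
        assert np.any(np.abs(deltas - combined) < 1e-9)

    def test_methyl_form_on_wrong_residue_rejected(self):
        with pytest.raises(ValueError):
            mw.simulate_spectrum("AGSKVLK", (Mod(4, "K", "ADMA", 1.0),), 2, self.CFG)

    def test_mgf_round_trip(self, tmp_path):
        pep = "AGSRVLK"
        spec = mw.simulate_spectrum(pep, (Mod(4, "R", "ADMA", 1.0),), 2, self.CFG,
                                    spectrum_id="s1")
        from methylworm import io as mwio

        mwio.write_mgf([spec], tmp_path / "x.mgf", tmp_path / "x.ann.tsv")
        back = mwio.read_mgf(tmp_path / "x.mgf", tmp_path / "x.ann.tsv")
        assert len(back) == 1
        np.testing.assert_allclose(back[0].mz, spec.mz, atol=1e-5)
        np.testing.assert_allclose(back[0].intensity, spec.intensity, rtol=1e-6)
        assert [tuple(a) for a in back[0].annotations] == [tuple(a) for a in spec.annotations]


class TestAbundance:
    def test_noise_free_matrix_equals_linear_model(self):
        cfg = mw.SimConfig(seed=1, n_proteins=20, n_sites=40, noise_sd=0.0,
                           mnar_quantile=0.0, mar_rate=0.0, n_substrate_sites=10)
        proteome = mw.generate_proteome(cfg)
        truth = mw.simulate_methylome(proteome, cfg)
        pep, prot, gt = mw.simulate_abundance(truth, proteome, cfg)
        # replicates within a genotype are exactly equal without noise
        for g in ("WT", "KO1", "KO2"):
            cols = pep.samples_for(g)
            assert np.allclose(pep.values[cols[0]], pep.values[cols[1]])
        # ablated peptide KO1-WT difference equals protein effect + ablation
        dep = gt.sites.query("ko1_dependent").iloc[0]
        row = pep.values.loc[dep.site_id]
        diff = row[pep.samples_for("KO1")[0]] - row[pep.samples_for("WT")[0]]
        expected = gt.true_peptide_effects.loc[dep.site_id, "KO1"]
        assert abs(diff - expected) < 1e-9

    def test_missingness_labels_partition_cells(self, small_study):
        labels = small_study["truth"].missingness_labels
        assert set(np.unique(labels.values)) <= {
            "observed", "MAR-censored", "MNAR-censored"}
        obs = small_study["peptide_matrix"].values.notna()
        assert ((labels == "observed") == obs).all().all()

    def test_mnar_whole_group_pattern_for_ablated(self, default_study):
        """Deep ablation produces the complete-in-two-groups / all-missing-in-
        one signature on at least some knockout-dependent peptides."""
        truth = default_study["truth"]
        mat = default_study["peptide_matrix"]
        ko1 = mat.samples_for("KO1")
        wt = mat.samples_for("WT")
        dep = truth.sites.query("ko1_dependent and ablation_log2fc <= -5")
        hit = 0
        for sid in dep.site_id:
            row = mat.values.loc[sid]
            if row[ko1].isna().all() and row[wt].notna().all():
                hit += 1
        assert hit >= 1
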