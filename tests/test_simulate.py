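"""Generative model of endpoint signals and CNV estimates."""
import collections

import numpy as np
import pandas as pd
import pytest

from cyp2d6dup.simulate import (
    SimConfig,
    allele_fraction,
    simulate_run,
    truth_record,
)

from conftest import noise_free_config


class TestAlleleFraction:
    @pytest.mark.parametrize(
        "n_ref,n_alt,expected", [(1, 1, 0.5), (1, 2, 2 / 3), (2, 1, 1 / 3)]
    )
    def test_forced_by_counts(self, n_ref, n_alt, expected):
        assert allele_fraction(n_ref, n_alt) == pytest.approx(expected)

    def test_no_copies_is_an_error(self):
        with pytest.raises(ValueError):
            allele_fraction(0, 0)


class TestSimConfigValidation:
    def test_fraction_noise_bounded(self):
        with pytest.raises(ValueError):
            SimConfig(sigma_f=0.2)

    def test_dropout_eta_bounded(self):
        with pytest.raises(ValueError):
            SimConfig(dropout={"c.886C>T": ("ref", 1.5)})


class TestSimulateRun:
    def test_noise_free_duplicated_het_lands_at_two_thirds(self):
        rec = truth_record("Q1", "*1/*4×2")
        run = simulate_run([rec], noise_free_config())
        q = run.genotyper.query("sample_id == 'Q1' and call == 'het'")
        fractions = q["fam"] / (q["vic"] + q["fam"])
        assert np.allclose(fractions, 2 / 3)
        assert len(q) == 2 * 3  # two replicates at each informative assay

    def test_every_sample_assay_has_two_replicates(self, noise_free_main_run):
        sizes = noise_free_main_run.genotyper.groupby(["sample_id", "assay_id"]).size()
        assert (sizes == 2).all()

    def test_same_seed_is_byte_identical(self, tmp_path):
        rec = truth_record("Q1", "*1×2/*41")
        cfg = SimConfig(seed=11)
        a = simulate_run([rec], cfg)
        b = simulate_run([rec], SimConfig(seed=11))
        pd.testing.assert_frame_equal(a.genotyper, b.genotyper)
        pd.testing.assert_frame_equal(a.cnv, b.cnv)

    def test_control_gene_interference_plateau(self):
        """Two copies with a suppressed control-gene copy read exactly 2.5."""
        rec = truth_record("Q1", "*9/*35", interference=True)
        cfg = noise_free_config(eta_ctrl=0.6)
        run = simulate_run([rec], cfg)
        assert set(run.cnv["copy_estimate"]) == {2.5}

    def test_cnv_unbiased_without_interference(self):
        """Mean copy estimate over many replicates matches true copies."""
        rec = truth_record("Q1", "*1/*4×2")
        vals = []
        for seed in range(250):
            run = simulate_run([rec], SimConfig(seed=seed, sigma_c=0.1,
                                                n_concurrent_het=0,
                                                n_controls_per_class=2))
            vals.extend(run.cnv["copy_estimate"])
        vals = np.asarray(vals)
        assert abs(vals.mean() - 3.0) < 3 * 0.1 / np.sqrt(len(vals))

    def test_no_negative_signal_or_copies_under_extreme_noise(self):
        rec = truth_record("Q1", "*1/*4×2")
        run = simulate_run([rec], SimConfig(seed=3, sigma_f=0.14, sigma_c=2.0))
        assert (run.genotyper[["vic", "fam"]] >= 0).all().all()
        assert (run.cnv["copy_estimate"] >= 0).all()
        # extreme CNV noise actually exercises the floor
        assert (run.cnv["copy_estimate"] == 0).any()

    def test_dropout_shifts_mean_fraction(self):
        rec = truth_record("Q1", "*1×2/*41")
        cfg = noise_free_config(dropout={"c.886C>T": ("ref", 0.2)})
        run = simulate_run([rec], cfg)
        q = run.genotyper.query("sample_id == 'Q1' and assay_id == 'c.886C>T'")
        f = (q["fam"] / (q["vic"] + q["fam"])).mean()
        # effective counts 0.4 ref : 1 alt
        assert f == pytest.approx(1 / 1.4, abs=1e-6)

    def test_mean_fraction_converges_to_truth_at_tiny_noise(self):
        rec = truth_record("Q1", "*1/*4×2")
        run = simulate_run([rec], noise_free_config(sigma_f=1e-6, seed=13))
        q = run.genotyper.query("sample_id == 'Q1' and call == 'het'")
        f = (q["fam"] / (q["vic"] + q["fam"])).mean()
        assert f == pytest.approx(2 / 3, abs=1e-5)

    def test_unknown_assay_rejected(self):
        rec = truth_record("Q1", "*1/*4×2")
        rec.assay_counts["c.999G>A"] = (1, 1)
        with pytest.raises(ValueError, match="c.999G>A"):
            simulate_run([rec], SimConfig())

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            simulate_run([], SimConfig())


class TestCohortFixture:
    def test_main_dataset_composition(self, cohort):
        assert len(cohort.main) == 73
        counts = collections.Counter(r.diplotype for r in cohort.main)
        assert len(counts) == 30
        assert counts.most_common(1)[0] == ("*1/*4×2", 11)

    def test_exploratory_and_ambiguous_sizes(self, cohort):
        assert len(cohort.exploratory) == 11
        assert len(cohort.ambiguous) == 3
        assert all(r.interference for r in cohort.ambiguous)

    def test_exploratory_probe_truth(self, cohort):
        rec = next(r for r in cohort.exploratory if r.diplotype == "*68+4/*41×2")
        assert rec.probe_copies == (4, 3, 3)

    def test_counts_consistent_with_diplotypes(self, cohort, registry):
        """Every truth record's per-assay counts follow from its diplotype."""
        from cyp2d6dup.alleles import allele_counts_by_assay, parse_diplotype

        for rec in cohort.main:
            expected = allele_counts_by_assay(parse_diplotype(rec.diplotype), registry)
            assert rec.assay_counts == expected
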