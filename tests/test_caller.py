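"""Cluster fitting, shift statistics, voting and evaluation."""
import numpy as np
import pandas as pd
import pytest

from cyp2d6dup.caller import (
    DEFER,
    CalibrationError,
    CallerConfig,
    ClusterModel,
    NoInformativeSnvError,
    call_duplicated_allele,
    cohen_kappa,
    evaluate_calls,
    fit_clusters,
    fraction_coordinate,
    infer_allele_pair,
    shift_statistic,
)
from cyp2d6dup.report import run_pipeline
from cyp2d6dup.simulate import SimConfig, simulate_run, truth_record

from conftest import noise_free_config


def _points(fractions_by_class):
    rows = []
    for cls, fracs in fractions_by_class.items():
        rows += [{"call": cls, "fraction": f} for f in fracs]
    return pd.DataFrame(rows)


def _model(center=0.5, spread=0.02, count=10):
    return ClusterModel(
        assay_id="c.886C>T",
        run_id="R1",
        centers={"het": center},
        spreads={"het": spread},
        counts={"hom_ref": 4, "het": count, "hom_var": 4},
        zones={"het": (center - 0.12, center + 0.12)},
    )


class TestFractionCoordinate:
    def test_equal_signals(self):
        assert fraction_coordinate(1000, 1000) == 0.5

    def test_pure_variant_signal(self):
        assert fraction_coordinate(0, 500) == 1.0

    def test_non_amplification(self):
        with pytest.raises(ValueError):
            fraction_coordinate(0, 0)


class TestFitClusters:
    def test_degenerate_spread_floors(self):
        m = fit_clusters(_points({"het": [0.5] * 10}), "a")
        assert m.het_center == 0.5
        assert m.het_spread == CallerConfig().floor_sd

    def test_single_het_point_cannot_calibrate(self):
        with pytest.raises(CalibrationError):
            fit_clusters(_points({"het": [0.5], "hom_ref": [0.1, 0.1]}), "a")

    def test_het_class_required(self):
        with pytest.raises(CalibrationError, match="heterozygous"):
            fit_clusters(
                _points({"hom_ref": [0.1, 0.1], "hom_var": [0.9, 0.9]}), "a"
            )

    def test_centers_recovered_from_seeded_run(self, registry):
        cfg = SimConfig(seed=7, lot_sd=0.0, n_controls_per_class=10,
                        n_concurrent_het=20)
        run = simulate_run([truth_record("Q1", "*1/*4×2")], cfg)
        df = run.genotyper
        df = df[df["role"].isin(["control", "concurrent"])].copy()
        df["fraction"] = df["fam"] / (df["vic"] + df["fam"])
        truth_centers = {"hom_ref": cfg.f_hom_ref, "het": 0.5, "hom_var": cfg.f_hom_var}
        # sampling error of a median of n points: ~1.25 sigma/sqrt(n)
        se = {"hom_ref": 1.25 * cfg.sigma_f / np.sqrt(2 * 10),
              "het": 1.25 * cfg.sigma_f / np.sqrt(2 * 30),
              "hom_var": 1.25 * cfg.sigma_f / np.sqrt(2 * 10)}
        centers = {cls: [] for cls in truth_centers}
        for assay_id, adf in df.groupby("assay_id"):
            m = fit_clusters(adf, assay_id)
            for cls, mu in truth_centers.items():
                assert m.centers[cls] == pytest.approx(mu, abs=3.5 * se[cls])
                centers[cls].append(m.centers[cls])
        for cls, mu in truth_centers.items():
            assert np.mean(centers[cls]) == pytest.approx(mu, abs=0.01)

    def test_zone_ordering_invariant(self):
        m = fit_clusters(
            _points(
                {"hom_ref": [0.08, 0.09], "het": [0.49, 0.51], "hom_var": [0.9, 0.92]}
            ),
            "a",
        )
        zs = [m.zones[c] for c in ("hom_ref", "het", "hom_var")]
        assert zs == sorted(zs)


class TestShiftStatistic:
    def test_strong_shift_toward_variant(self):
        sc = shift_statistic([0.667, 0.665], _model())
        assert sc.z == pytest.approx((0.666 - 0.5) / 0.02, abs=0.01)
        assert sc.direction == "toward_var"
        assert sc.confident

    def test_centered_sample_has_no_direction(self):
        sc = shift_statistic([0.5, 0.5], _model())
        assert sc.z == 0
        assert sc.direction == "none"
        assert not sc.confident

    def test_opposite_replicates_are_discordant(self):
        sc = shift_statistic([0.56, 0.44], _model())
        assert sc.discordant
        assert not sc.confident

    def test_both_replicates_must_clear_threshold(self):
        # mean clears 3 sd but one replicate does not
        sc = shift_statistic([0.70, 0.52], _model())
        assert not sc.confident


def _calls_and_shifts(genotype, registry, dropout=None, config=None):
    cfg = noise_free_config(dropout=dropout or {})
    run = simulate_run([truth_record("Q1", genotype)], cfg)
    df = run.genotyper
    df["fraction"] = df["fam"] / (df["vic"] + df["fam"])
    comp = df[df["role"] != "query"]
    models = {a: fit_clusters(adf, a) for a, adf in comp.groupby("assay_id")}
    q = df[df["role"] == "query"]
    calls = {a: adf["call"].iloc[0] for a, adf in q.groupby("assay_id")}
    shifts = [
        shift_statistic(
            adf.sort_values("replicate")["fraction"].tolist(), models[a], config
        )
        for a, adf in q.groupby("assay_id")
        if calls[a] == "het"
    ]
    return calls, shifts


class TestCallDuplicatedAllele:
    def test_unanimous_votes_name_the_duplicated_allele(self, registry):
        calls, shifts = _calls_and_shifts("*1/*4×2", registry)
        dc = call_duplicated_allele("Q1", calls, shifts, registry, cnv_total=3)
        assert dc.result == "*4"
        assert set(dc.votes.values()) == {"*4"}
        assert len(dc.votes) == 3

    def test_shift_toward_reference_votes_for_reference_haplotype(self, registry):
        # duplicated *1: at *41-tagging sites the query shifts toward ref
        calls, shifts = _calls_and_shifts("*1×2/*41", registry)
        dc = call_duplicated_allele("Q1", calls, shifts, registry, cnv_total=3)
        assert dc.result == "*1"

    def test_single_informative_snv_defers(self, registry):
        calls, shifts = _calls_and_shifts("*1×2/*9", registry)
        dc = call_duplicated_allele("Q1", calls, shifts, registry, cnv_total=3)
        assert dc.result == DEFER
        assert "too_few_informative_snvs" in dc.defer_reasons

    def test_dropout_conflict_defers_never_miscalls(self, registry):
        calls, shifts = _calls_and_shifts(
            "*1×2/*41", registry, dropout={"c.886C>T": ("ref", 0.2)}
        )
        dc = call_duplicated_allele("Q1", calls, shifts, registry, cnv_total=3)
        assert dc.result == DEFER
        assert dc.defer_reasons == ["conflicting_votes"]

    def test_cnv_total_other_than_three_defers(self, registry):
        calls, shifts = _calls_and_shifts("*1/*4×2", registry)
        dc = call_duplicated_allele("Q1", calls, shifts, registry, cnv_total=None)
        assert dc.result == DEFER
        assert "cnv_inconsistent" in dc.defer_reasons

    def test_hom_everywhere_is_an_error(self, registry):
        calls = {a: "hom_ref" for a in registry.panel}
        with pytest.raises(NoInformativeSnvError):
            call_duplicated_allele("Q1", calls, [], registry, cnv_total=3)

    def test_raising_z_min_never_converts_defer_to_call(self, registry):
        """Monotonicity: a stricter confidence threshold can only defer more."""
        calls, _ = _calls_and_shifts("*1/*4×2", registry)
        results = []
        for z_min in (1.0, 3.0, 6.0, 1e9):
            cfg = CallerConfig(z_min=z_min)
            _, shifts = _calls_and_shifts("*1/*4×2", registry, config=cfg)
            dc = call_duplicated_allele(
                "Q1", calls, shifts, registry, cnv_total=3, config=cfg
            )
            results.append(dc.result)
        deferred = [r == DEFER for r in results]
        assert deferred == sorted(deferred)  # once deferred, stays deferred

    def test_balanced_two_copy_samples_rarely_shift(self, registry):
        """2-copy heterozygotes should not look duplicated at default noise."""
        rng = np.random.default_rng(0)
        model = _model(center=0.5, spread=0.02)
        confident = 0
        n = 1000
        for _ in range(n):
            fr = rng.normal(0.5, 0.02, size=2)
            sc = shift_statistic(fr, model)
            confident += sc.confident
        assert confident / n <= 0.01


class TestInferAllelePair:
    def test_unique_pair_from_call_pattern(self, registry):
        calls = {a: "hom_ref" for a in registry.panel}
        calls.update({"c.886C>T": "het", "c.985+39G>A": "het", "c.1457G>C": "het"})
        assert infer_allele_pair(calls, registry) == [("*1", "*41")]

    def test_shared_variant_seen_as_homozygous(self, registry):
        calls = {a: "hom_ref" for a in registry.panel}
        calls.update(
            {
                "c.100C>T": "het",
                "c.506-1G>A": "het",
                "c.320C>T": "het",
                "c.886C>T": "het",
                "c.1457G>C": "hom_var",
            }
        )
        assert infer_allele_pair(calls, registry) == [("*4", "*17")]


class TestEvaluation:
    def test_identical_raters_have_perfect_agreement(self):
        truth = ["*4", "*1", "*41"]
        calls = {"r1": ["*4", "*1", DEFER], "r2": ["*4", "*1", DEFER]}
        ev = evaluate_calls(calls, truth)
        assert ev.kappa_correctness == 1.0
        assert ev.kappa_reporting == 1.0
        assert ev.accuracy == {"r1": 1.0, "r2": 1.0}

    def test_hand_computed_zero_kappa(self):
        a = ["call", "call", "defer", "defer"]
        b = ["call", "defer", "call", "defer"]
        assert cohen_kappa(a, b) == pytest.approx(0.0)

    def test_kappa_matches_sklearn_on_nondegenerate_input(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(1)
        a = list(rng.choice(["x", "y", "z"], size=60))
        b = list(rng.choice(["x", "y", "z"], size=60))
        assert cohen_kappa(a, b) == pytest.approx(
            sklearn_metrics.cohen_kappa_score(a, b)
        )

    def test_accuracy_excludes_deferred_cases(self):
        ev = evaluate_calls({"r": ["*4", DEFER, "*1"]}, ["*4", "*1", "*2"])
        assert ev.n_attempted["r"] == 2
        assert ev.accuracy["r"] == 0.5

    def test_all_correct_none_deferred_is_full_accuracy(self):
        ev = evaluate_calls({"r": ["*4", "*1"]}, ["*4", "*1"])
        assert ev.accuracy["r"] == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            evaluate_calls({}, [])


class TestSymmetry:
    def test_vic_fam_and_ref_alt_relabeling_leaves_calls_invariant(self, registry):
        """Swapping the two fluorescence channels together with the ref/alt
        sense of every assay mirrors the geometry and must not change any
        duplication call."""
        rec = truth_record("Q1", "*1/*4×2")
        run = simulate_run([rec], SimConfig(seed=21))
        reports = run_pipeline(run.genotyper, run.cnv, registry=registry)

        flipped = run.genotyper.rename(columns={"vic": "fam", "fam": "vic"})
        flip_call = {"hom_ref": "hom_var", "hom_var": "hom_ref", "het": "het"}
        flipped["call"] = [flip_call[c] for c in flipped["call"]]
        import cyp2d6dup.alleles as am

        mirrored_alleles = [
            am.StarAllele(
                name=a.name,
                defining_variants=frozenset(
                    v for v in registry.panel if registry.covers(a.name, v)
                )
                - a.defining_variants,
                activity_value=a.activity_value,
                structure_class=a.structure_class,
                probe_vector=a.probe_vector,
            )
            for a in registry.alleles.values()
        ]
        mirrored = am.AlleleRegistry(registry.panel.values(), mirrored_alleles)
        reports_m = run_pipeline(flipped, run.cnv, registry=mirrored)
        assert [(r.sample_id, r.status) for r in reports] == [
            (r.sample_id, r.status) for r in reports_m
        ]
        votes = reports[0].evidence["votes"]
        votes_m = reports_m[0].evidence["votes"]
        assert votes == votes_m
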