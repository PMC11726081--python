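"""Model/results surface, sensitivity analyses, and the full report."""

import json

import pytest

import snpmeta as sm


class TestFit:
    def test_fixed_effect_fit_on_bundled_corpus(self, corpus):
        res = sm.GenotypeMetaAnalysis(corpus, "rs3731217", "allelic").fit()
        assert res.effect_model == "fixed"
        assert res.k == 14
        assert res.pooled_or == pytest.approx(0.735, abs=5e-4)
        assert (res.ci_low, res.ci_high) == pytest.approx((0.683, 0.790), abs=5e-4)

    def test_random_effects_selected_for_heterozygote(self, corpus):
        res = sm.GenotypeMetaAnalysis(corpus, "rs3731217", "heterozygote").fit()
        assert res.effect_model == "random"
        assert res.heterogeneity.I2 == pytest.approx(42.76, abs=0.1)

    def test_mantel_haenszel_option(self, corpus):
        cfg = sm.MetaConfig(fixed_method="mh")
        res = sm.GenotypeMetaAnalysis(corpus, "rs3731217", "allelic", cfg).fit()
        assert res.pool.method == "mh"
        assert res.pooled_or == pytest.approx(0.733, abs=5e-4)

    def test_degenerate_studies_excluded_and_logged(self, corpus):
        # two studies have no minor-allele homozygote in either arm
        res = sm.GenotypeMetaAnalysis(corpus, "rs3731217", "homozygote").fit()
        assert res.k == 12
        assert res.pool.excluded_study_ids == ("kreile2016", "bardsiri2022_rs3731217")

    def test_absent_variant_errors(self):
        corpus = sm.simulate_corpus(sm.SimulationConfig(k_studies=3, seed=1))
        with pytest.raises(ValueError, match="absent"):
            sm.GenotypeMetaAnalysis(corpus, "rs3731249")

    def test_summary_carries_key_numbers(self, corpus):
        text = sm.GenotypeMetaAnalysis(corpus, "rs3731217", "allelic").fit().summary()
        assert "0.735" in text and "fixed" in text and "rs3731217" in text


class TestLeaveOneOut:
    def test_one_result_per_omitted_study(self, corpus):
        runs = sm.leave_one_out(corpus, "rs3731217", "allelic")
        assert len(runs) == 14
        assert sorted(sid for sid, _ in runs) == sorted(
            corpus.subset("rs3731217").study_ids())
        for _, pool in runs:
            assert pool.k == 13

    def test_two_studies_yield_single_study_pools(self):
        corpus = sm.simulate_corpus(sm.SimulationConfig(k_studies=2, seed=5))
        runs = sm.leave_one_out(corpus, "rs3731217", "allelic")
        assert all(pool.single_study for _, pool in runs)

    def test_identical_studies_give_identical_reruns(self):
        base = sm.simulate_corpus(sm.SimulationConfig(k_studies=1, seed=9)).records[0]
        clones = [sm.StudyRecord(**{**base.__dict__, "study_id": f"c{i}"})
                  for i in range(4)]
        runs = sm.leave_one_out(sm.StudyCorpus(clones), "rs3731217", "allelic")
        ors = {round(p.pooled_or, 12) for _, p in runs}
        assert len(ors) == 1


class TestSubgroups:
    def test_ethnicity_strata_of_bundled_corpus(self, corpus):
        strata = sm.subgroup_analysis(corpus, "rs3731217", "allelic", "ethnicity")
        ks = {level: pool.k for level, pool in strata.items()}
        assert ks == {"Asian": 4, "Caucasian": 7, "African": 2, "Hispanic": 1}
        assert strata["Hispanic"].single_study

    def test_strata_agree_with_overall_on_global_orientation(self, corpus):
        # on the single global allele orientation every ethnic stratum sits on
        # the protective side of the overall estimate and is homogeneous
        strata = sm.subgroup_analysis(corpus, "rs3731217", "allelic", "ethnicity")
        for level, pool in strata.items():
            assert pool.pooled_or < 1.0, level
            if pool.heterogeneity is not None:
                assert pool.heterogeneity.I2 < 50.0, level

    def test_genotyping_method_factor_supported(self, corpus):
        strata = sm.subgroup_analysis(corpus, "rs3731249", "allelic", "genotyping_method")
        assert sum(p.k for p in strata.values()) == 8

    def test_single_level_factor_equals_overall(self, corpus):
        caucasian = sm.StudyCorpus([r for r in corpus.subset("rs3731249")
                                    if r.ethnicity == "Caucasian"])
        only = sm.subgroup_analysis(caucasian, "rs3731249", "allelic", "ethnicity")
        overall = sm.GenotypeMetaAnalysis(caucasian, "rs3731249", "allelic").fit()
        assert list(only) == ["Caucasian"]
        assert only["Caucasian"].pooled_or == pytest.approx(overall.pooled_or, rel=1e-12)

    def test_unpopulated_factor_errors(self, corpus):
        with pytest.raises(ValueError, match="not populated"):
            sm.subgroup_analysis(corpus, "rs3731217", "allelic", "source")


@pytest.fixture(scope="module")
def report(corpus):
    return sm.run_full_analysis(corpus)


class TestFullReport:
    def test_ten_overall_rows(self, report):
        overall = [r for r in report.rows if r.stratum == "overall"]
        assert len(overall) == 10

    def test_effect_model_labels_match_publication(self, report):
        labels = {(r.variant, r.contrast): r.pool.effect_model
                  for r in report.rows if r.stratum == "overall"}
        expect_random = {("rs3731217", "heterozygote")}
        for key, label in labels.items():
            assert label == ("random" if key in expect_random else "fixed"), key

    def test_hwe_rerun_is_noop_on_bundled_corpus(self, report):
        for r in report.rows:
            if r.stratum == "overall":
                assert r.hwe_rerun.pooled_or == pytest.approx(r.pool.pooled_or, rel=1e-12)

    def test_direction_diagnostic_note_emitted(self, report):
        assert any("opposite side of 1" in n for n in report.notes)

    def test_empty_corpus_errors(self):
        with pytest.raises(ValueError, match="empty corpus"):
            sm.run_full_analysis(sm.StudyCorpus([]))

    def test_requested_absent_variant_recorded_not_fatal(self, corpus):
        only17 = sm.StudyCorpus(list(corpus.subset("rs3731217")))
        rep = sm.run_full_analysis(only17, variants=["rs3731217", "rs3731249"])
        assert "rs3731249" in rep.errors
        assert any(r.variant == "rs3731217" for r in rep.rows)

    def test_json_round_trip(self, report):
        payload = json.loads(json.dumps(sm.report_to_dict(report)))
        again = sm.report_from_dict(payload)
        assert again == report

    def test_written_reports_are_deterministic(self, corpus, report, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        sm.write_report(report, d1)
        sm.write_report(sm.run_full_analysis(corpus), d2)
        for f1 in sorted(d1.iterdir()):
            assert f1.read_bytes() == (d2 / f1.name).read_bytes()

    def test_rounding_contract_in_tsv(self, report, tmp_path):
        sm.write_report(report, tmp_path)
        lines = (tmp_path / "report.tsv").read_text().splitlines()
        header = lines[0].split("\t")
        rows = [dict(zip(header, ln.split("\t"))) for ln in lines[1:]]
        target = next(r for r in rows if r["variant"] == "rs3731217"
                      and r["contrast"] == "heterozygote" and r["stratum"] == "overall")
        assert target["OR"] == "0.763"
        assert target["I2"] == "42.77"
        assert target["effect_model"] == "random"
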