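import math

import numpy as np
import pytest

from prostaging.consistency_validator import validate_record
from prostaging.record_model import MissingKind, TnmCode, is_missing
from prostaging.staging_engine import stage_record
from prostaging.synthetic_data import (
    CorruptionSpec,
    GeneratorConfig,
    InjectionError,
    corrupt_corpus,
    generate_corpus,
    inject_inconsistency,
    merge_patient_reports,
    read_corpus_jsonl,
    render_report,
    sample_record,
    write_corpus_jsonl,
)
from .conftest import make_record


class TestConfigValidation:
    def test_bad_dialect_mix(self):
        with pytest.raises(ValueError):
            GeneratorConfig(dialect_mix={"narrative": 0.5, "synoptic": 0.2})

    def test_bad_noise_rate(self):
        with pytest.raises(ValueError):
            GeneratorConfig(noise_rate=1.5)

    def test_bad_marginal(self):
        with pytest.raises(ValueError):
            GeneratorConfig(marginals={"T-Stage": {"T2c": -1}})

    def test_bad_corruption_code(self):
        with pytest.raises(ValueError):
            CorruptionSpec("No_such_code")


class TestDeterminism:
    def test_same_seed_identical_corpora(self):
        a = generate_corpus(GeneratorConfig(n_patients=50, seed=9))
        b = generate_corpus(GeneratorConfig(n_patients=50, seed=9))
        assert a.records == b.records and a.texts == b.texts

    def test_different_seed_differs(self):
        a = generate_corpus(GeneratorConfig(n_patients=50, seed=9))
        b = generate_corpus(GeneratorConfig(n_patients=50, seed=10))
        assert a.records != b.records


class TestCoherence:
    def test_validator_clean_over_1000(self):
        bundle = generate_corpus(GeneratorConfig(n_patients=1000, seed=21))
        assert all(validate_record(r) == [] for r in bundle.records)

    def test_no_unknown_without_missingness(self, coherent_records):
        for r in coherent_records:
            assert stage_record(r).stage != "Unknown"

    def test_degenerate_marginals_all_stage_iib(self):
        cfg = GeneratorConfig(
            n_patients=50, seed=3, missing_rates={},
            marginals={
                "T-Stage": {"T2c": 1.0},
                "N-Stage": {"N0": 1.0},
                "M-Stage": {"M0": 1.0},
                "WHO Grade Group": {2: 1.0},
                "Perineural Invasion": {"Present": 1.0},
                "Histologic Subtype": {"Acinar adenocarcinoma": 1.0},
                "Resection Margins": {"Negative": 1.0},
            },
            psa_median=6.0, psa_sigma=0.3,
        )
        bundle = generate_corpus(cfg)
        for r in bundle.records:
            if r.psa_ng_ml < 20:  # lognormal tail can cross the IIIA cut
                assert stage_record(r).stage == "IIB"

    def test_epe_svi_coupled_to_t(self, coherent_records):
        for r in coherent_records:
            t = r.t_stage.code
            assert (r.epe == "Present") == (t in ("T3a", "T3b", "T4"))
            assert (r.svi == "Present") == (t in ("T3b", "T4"))

    def test_reported_gg_matches_patterns(self, coherent_records):
        from prostaging.record_model import grade_group_from_patterns

        for r in coherent_records:
            g = r.gleason
            assert g.reported_grade_group == grade_group_from_patterns(
                g.primary_pattern, g.secondary_pattern
            )


class TestMarginalFidelity:
    def test_t_stage_within_3_se(self):
        n = 10_000
        cfg = GeneratorConfig(n_patients=n, seed=33, missing_rates={})
        records = generate_corpus(cfg).records
        weights = cfg.marginals["T-Stage"]
        total = sum(weights.values())
        counts: dict[str, int] = {}
        for r in records:
            counts[r.t_stage.code] = counts.get(r.t_stage.code, 0) + 1
        for code, w in weights.items():
            p = w / total
            se = math.sqrt(p * (1 - p) / n)
            assert abs(counts.get(code, 0) / n - p) <= 3 * se + 1e-12, code

    def test_psa_median_near_configured_center(self):
        cfg = GeneratorConfig(n_patients=5000, seed=4, missing_rates={}, psa_median=8.0)
        psa = np.array([r.psa_ng_ml for r in generate_corpus(cfg).records])
        assert 7.0 < np.median(psa) < 9.0


class TestRendering:
    def test_tabulated_gg_grid_marked(self, rng):
        record = make_record(gg=2, primary=3, secondary=4)
        text = render_report(record, "tabulated", rng)
        assert "GG2 | 3+4=7 | X" in text
        assert "GG3 | 4+3=7 | " in text and "GG3 | 4+3=7 | X" not in text

    def test_synoptic_svi_line(self, rng):
        record = make_record(svi="Present")
        text = render_report(record, "synoptic", rng)
        assert "Seminal vesicle invasion: present" in text

    def test_unknown_dialect(self, rng):
        with pytest.raises(ValueError):
            render_report(make_record(), "telegram", rng)

    def test_noise_rewords_epe_implicitly(self):
        rng = np.random.default_rng(0)
        record = make_record(t="T3a", epe="Present")
        texts = {render_report(record, "synoptic", rng, noise_rate=1.0) for _ in range(3)}
        for text in texts:
            assert "Extraprostatic extension" not in text
            assert "capsular defect" in text


class TestMergeRule:
    def test_later_report_wins(self):
        old = make_record(report_id="R1", psa=4.0, t="T2a")
        new = make_record(report_id="R2", psa=9.0)
        merged = merge_patient_reports([old, new])
        assert merged.psa_ng_ml == 9.0  # newest value kept
        assert merged.t_stage.code == "T2a"  # gap filled from the older report
        assert merged.report_id == "R2"

    def test_x_code_not_overwritten(self):
        from prostaging.record_model import MissingValue

        old = make_record(report_id="R1", n="N0")
        new = make_record(report_id="R2", n=MissingValue(MissingKind.X_CODE, "pNx"))
        merged = merge_patient_reports([old, new])
        assert merged.n_stage == MissingValue(MissingKind.X_CODE, "pNx")

    def test_single_report_identity(self):
        r = make_record(report_id="R1", psa=5.0)
        assert merge_patient_reports([r]) == r


class TestInjection:
    def test_t3a_epe_flip(self, rng):
        record = make_record(t="T3a", epe="Present", svi="Absent")
        out = inject_inconsistency(record, CorruptionSpec("T3a_stage_but_no_EPE"), rng)
        assert out.epe == "Absent"
        assert [e.code for e in validate_record(out)] == ["T3a_stage_but_no_EPE"]

    def test_impossible_target_signals(self, rng):
        record = make_record(t="T2a", epe="Absent")
        with pytest.raises(InjectionError):
            inject_inconsistency(record, CorruptionSpec("T3a_stage_but_no_EPE"), rng)

    def test_rate_zero_leaves_corpus_unchanged(self, coherent_records, rng):
        spec = CorruptionSpec("T3a_stage_but_no_EPE", rate=0.0)
        out, notes = corrupt_corpus(coherent_records, spec, rng)
        assert out == list(coherent_records) and notes == []

    def test_corrupt_corpus_annotates(self, coherent_records, rng):
        spec = CorruptionSpec("N1_stage_but_no_positive_lymph_nodes", rate=1.0)
        out, notes = corrupt_corpus(coherent_records, spec, rng)
        assert notes
        for i, code in notes:
            assert [e.code for e in validate_record(out[i])] == [code]


class TestCorpusIO:
    def test_jsonl_round_trip(self, small_bundle, tmp_path):
        path = tmp_path / "corpus.jsonl"
        write_corpus_jsonl(small_bundle, path, tmp_path / "manifest.json")
        back = read_corpus_jsonl(path)
        assert list(back.records) == list(small_bundle.records)
        assert list(back.texts) == list(small_bundle.texts)

    def test_manifest_contains_seed(self, small_bundle, tmp_path):
        import json

        write_corpus_jsonl(small_bundle, tmp_path / "c.jsonl", tmp_path / "m.json")
        manifest = json.loads((tmp_path / "m.json").read_text())
        assert manifest["config"]["seed"] == 11
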