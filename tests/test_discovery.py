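"""Prevalence boundary, novelty criteria audit, validation, annotation."""

import numpy as np
import pandas as pd
import pytest

from lncforge.classify import classify_catalog
from lncforge.discovery import (
    DiscoveryConfig,
    annotate_against_databases,
    apply_novelty_criteria,
    cross_platform_validate,
    prevalence_filter,
)
from lncforge.models import AnnotationCatalog, GenomicInterval, TranscriptModel
from lncforge.simulate import (
    generate_coding_sequence,
    generate_noncoding_sequence,
    rng_stream,
)

CRITERIA = ["length", "multi_exonic", "class_code", "noncoding", "chromosome"]


def iv(start, end, chrom="chr1", strand="+"):
    return GenomicInterval(chrom, start, end, strand)


def make_t(tid, exons, **kw):
    return TranscriptModel(transcript_id=tid, gene_id=tid + "g", exons=exons, **kw)


def multi_exon(tid, chrom, start, widths, gaps, strand="+"):
    """A multi-exon transcript from explicit exon widths and intron gaps."""
    exons, pos = [], start
    for i, w in enumerate(widths):
        exons.append(GenomicInterval(chrom, pos, pos + w, strand))
        if i < len(gaps):
            pos += w + gaps[i]
    return make_t(tid, exons)


class TestDiscoveryConfig:
    def test_defaults(self):
        cfg = DiscoveryConfig()
        assert cfg.min_length_nt == 201
        assert cfg.allowed_codes == frozenset("uixy")
        assert "chrY" not in cfg.allowed_chroms
        assert "chrX" in cfg.allowed_chroms

    @pytest.mark.parametrize("kw", [
        {"min_sample_fraction": 0.0},
        {"min_sample_fraction": 1.5},
        {"min_length_nt": 0},
        {"coding_cutoff": 0.0},
        {"coding_cutoff": 1.0},
    ])
    def test_invalid(self, kw):
        with pytest.raises(ValueError):
            DiscoveryConfig(**kw)


class TestPrevalenceFilter:
    def test_all_zero_row_removed(self):
        counts = pd.DataFrame(
            [[0, 0, 0, 0], [1, 0, 2, 0]], index=["z", "k"]
        )
        assert prevalence_filter(counts) == ["k"]

    def test_exactly_half_of_ten_is_kept(self):
        row = [1] * 5 + [0] * 5
        counts = pd.DataFrame([row], index=["t"])
        assert prevalence_filter(counts, 0.5) == ["t"]

    def test_odd_n_uses_ceiling(self):
        # ceil(0.5 * 5) = 3: two detections drop, three keep
        counts = pd.DataFrame(
            [[1, 1, 0, 0, 0], [1, 1, 1, 0, 0]], index=["two", "three"]
        )
        assert prevalence_filter(counts, 0.5) == ["three"]

    def test_planted_forty_of_hundred(self):
        rng = rng_stream(70, "prevalence")
        n_samples = 12
        rows, kept_ids = [], []
        for i in range(100):
            tid = f"t{i:03d}"
            detected = int(rng.integers(6, n_samples + 1)) if i < 40 \
                else int(rng.integers(0, 6))
            if i < 40:
                kept_ids.append(tid)
            row = np.zeros(n_samples, dtype=int)
            hit = rng.choice(n_samples, size=detected, replace=False)
            row[hit] = rng.integers(1, 50, size=detected)
            rows.append(row)
        counts = pd.DataFrame(rows, index=[f"t{i:03d}" for i in range(100)])
        assert sorted(prevalence_filter(counts, 0.5)) == kept_ids

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            prevalence_filter(pd.DataFrame())
        with pytest.raises(ValueError, match="non-negative"):
            prevalence_filter(pd.DataFrame([[1, -1]], index=["t"]))


@pytest.fixture(scope="module")
def small_ref():
    """One protein-coding reference gene on chr5 to classify against."""
    ref = AnnotationCatalog()
    ref.add(TranscriptModel(
        transcript_id="REF.1", gene_id="REF.1g",
        exons=[iv(10_000, 10_600, chrom="chr5"),
               iv(11_000, 11_500, chrom="chr5")],
        biotype="protein_coding",
    ))
    return ref


class TestApplyNoveltyCriteria:
    def run_one(self, t, seq, small_ref, coding_model, cfg=None):
        model, table = coding_model
        cands = AnnotationCatalog([t])
        codes = classify_catalog(cands, small_ref)
        return apply_novelty_criteria(
            cands, codes, {t.transcript_id: seq} if seq is not None else {},
            model, table, cfg,
        )

    def test_clean_candidate_passes(self, small_ref, coding_model):
        t = make_t("cand", [iv(50_000, 50_250, chrom="chr5"),
                            iv(51_000, 51_250, chrom="chr5")])
        seq = generate_noncoding_sequence(500, rng_stream(71, "clean"))
        report = self.run_one(t, seq, small_ref, coding_model)
        assert report.surviving == ["cand"]
        assert bool(report.criteria.loc["cand", CRITERIA].all())

    def test_chry_fails_only_chromosome(self, small_ref, coding_model):
        t = make_t("cand", [iv(50_000, 50_250, chrom="chrY"),
                            iv(51_000, 51_250, chrom="chrY")])
        seq = generate_noncoding_sequence(500, rng_stream(71, "clean"))
        report = self.run_one(t, seq, small_ref, coding_model)
        assert report.surviving == []
        row = report.criteria.loc["cand"]
        assert not row["chromosome"]
        assert bool(row[["length", "multi_exonic", "class_code", "noncoding"]].all())

    def test_missing_sequence_fails_coding_criterion(
        self, small_ref, coding_model, caplog
    ):
        t = make_t("cand", [iv(50_000, 50_250, chrom="chr5"),
                            iv(51_000, 51_250, chrom="chr5")])
        with caplog.at_level("WARNING"):
            report = self.run_one(t, None, small_ref, coding_model)
        assert report.surviving == []
        assert not report.criteria.at["cand", "noncoding"]
        assert np.isnan(report.criteria.at["cand", "coding_probability"])
        assert "no sequence" in caplog.text

    def test_missing_code_is_an_error(self, small_ref, coding_model):
        model, table = coding_model
        t = make_t("cand", [iv(50_000, 50_250, chrom="chr5"),
                            iv(51_000, 51_250, chrom="chr5")])
        empty_codes = pd.DataFrame({"transcript_id": [], "code": []})
        with pytest.raises(ValueError, match="no class code"):
            apply_novelty_criteria(
                AnnotationCatalog([t]), empty_codes, {}, model, table)


@pytest.fixture(scope="module")
def audit_report(audit_fixture, coding_model):
    ref, cands, seqs, category = audit_fixture
    model, table = coding_model
    codes = classify_catalog(cands, ref)
    report = apply_novelty_criteria(cands, codes, seqs, model, table)
    return report, category


class TestAuditFixture:
    def test_per_criterion_fail_counts_match_plan(self, audit_report):
        report, category = audit_report
        crit = report.criteria
        planned = {
            "length": 10, "multi_exonic": 10, "class_code": 10,
            "noncoding": 10, "chromosome": 10,
        }
        for name, expected in planned.items():
            failing = set(crit.index[~crit[name]])
            assert len(failing) == expected, name
            # the failing ids are exactly the candidates planted to fail it
            assert failing == {t for t, c in category.items() if c == name}
        assert len(report.surviving) == 50
        assert set(report.surviving) == \
            {t for t, c in category.items() if c == "pass"}

    def test_failures_are_single_criterion(self, audit_report):
        report, category = audit_report
        crit = report.criteria
        for tid, cat in category.items():
            if cat == "pass":
                continue
            others = [c for c in CRITERIA if c != cat]
            assert bool(crit.loc[tid, others].all()), tid

    def test_order_independence(self, audit_fixture, coding_model):
        ref, cands, seqs, category = audit_fixture
        model, table = coding_model
        codes = classify_catalog(cands, ref)
        base = apply_novelty_criteria(cands, codes, seqs, model, table)
        rng = rng_stream(72, "perm")
        ids = list(cands.transcript_ids)
        for _ in range(5):
            # permute the candidate input order
            perm = list(ids)
            rng.shuffle(perm)
            shuffled = AnnotationCatalog([cands[t] for t in perm])
            rep = apply_novelty_criteria(shuffled, codes, seqs, model, table)
            assert set(rep.surviving) == set(base.surviving)
            # permute the criterion conjunction order
            cols = list(CRITERIA)
            rng.shuffle(cols)
            conj = np.ones(len(base.criteria), dtype=bool)
            for c in cols:
                conj &= base.criteria[c].to_numpy()
            assert set(base.criteria.index[conj]) == set(base.surviving)

    def test_monotonicity(self, audit_fixture, coding_model):
        ref, cands, seqs, category = audit_fixture
        model, table = coding_model
        codes = classify_catalog(cands, ref)
        base = set(apply_novelty_criteria(
            cands, codes, seqs, model, table).surviving)
        stricter_len = set(apply_novelty_criteria(
            cands, codes, seqs, model, table,
            DiscoveryConfig(min_length_nt=500)).surviving)
        stricter_cpc = set(apply_novelty_criteria(
            cands, codes, seqs, model, table,
            DiscoveryConfig(coding_cutoff=0.05)).surviving)
        assert stricter_len <= base
        assert stricter_cpc <= base


class TestCrossPlatformValidate:
    def test_identical_sets_all_validated(self):
        cat = AnnotationCatalog([
            multi_exon("a1", "chr1", 1_000, [200, 300], [150]),
            multi_exon("a2", "chr1", 5_000, [100, 100, 100], [80, 90]),
        ])
        pairs, unmatched = cross_platform_validate(cat, cat)
        assert sorted(pairs) == [("a1", "a1"), ("a2", "a2")]
        assert unmatched == []

    def test_disjoint_chromosomes_none_validated(self):
        a = AnnotationCatalog([multi_exon("a1", "chr1", 1_000, [200, 300], [150])])
        b = AnnotationCatalog([multi_exon("b1", "chr2", 1_000, [200, 300], [150])])
        pairs, unmatched = cross_platform_validate(a, b)
        assert pairs == []
        assert unmatched == ["a1"]

    def test_terminal_exon_jitter_still_matches(self):
        a = AnnotationCatalog([multi_exon("a1", "chr1", 1_000, [200, 300], [150])])
        # same intron (1200, 1350); different terminal boundaries
        b = AnnotationCatalog([make_t("b1", [iv(950, 1_200), iv(1_350, 1_700)])])
        pairs, _ = cross_platform_validate(a, b)
        assert pairs == [("a1", "b1")]

    def test_single_exon_degenerate_overlap(self):
        a = AnnotationCatalog([make_t("a1", [iv(1_000, 1_400)])])
        b = AnnotationCatalog([make_t("b1", [iv(1_300, 1_900)]),
                               make_t("b2", [iv(5_000, 5_400)])])
        pairs, _ = cross_platform_validate(a, b)
        assert pairs == [("a1", "b1")]

    @staticmethod
    def random_chain(rng, chrom, start):
        n_exons = int(rng.integers(2, 5))
        widths = [int(rng.integers(80, 400)) for _ in range(n_exons)]
        gaps = [int(rng.integers(60, 500)) for _ in range(n_exons - 1)]
        return widths, gaps, chrom, start

    def test_planted_38_shared_chains(self):
        # 150 platform-A candidates, 60 platform-B candidates, exactly 38
        # distinct intron chains planted into both; each chain occupies its
        # own genomic slot so chains cannot collide by accident.
        rng = rng_stream(73, "xplat")
        slots = iter(range(10_000, 10_000 + 4_000 * 400, 4_000))
        shared = [self.random_chain(rng, "chr1", next(slots))
                  for _ in range(38)]
        a_cat, b_cat = AnnotationCatalog(), AnnotationCatalog()
        expected = []
        for i, (widths, gaps, chrom, start) in enumerate(shared):
            a_id, b_id = f"A.SH{i}", f"B.SH{i}"
            a_cat.add(multi_exon(a_id, chrom, start, widths, gaps))
            # jitter terminal exon boundaries on the B side: intron chain
            # is untouched, so the pair must still validate
            jit = [w for w in widths]
            jit[0] += int(rng.integers(-30, 30))
            b_start = start + widths[0] - jit[0]
            jit[-1] += int(rng.integers(0, 50))
            b_cat.add(multi_exon(b_id, chrom, b_start, jit, gaps))
            expected.append((a_id, b_id))
        for i in range(150 - 38):
            widths, gaps, chrom, start = self.random_chain(
                rng, "chr1", next(slots))
            a_cat.add(multi_exon(f"A.U{i}", chrom, start, widths, gaps))
        for i in range(60 - 38):
            widths, gaps, chrom, start = self.random_chain(
                rng, "chr1", next(slots))
            b_cat.add(multi_exon(f"B.U{i}", chrom, start, widths, gaps))
        pairs, unmatched = cross_platform_validate(a_cat, b_cat)
        assert sorted(pairs) == sorted(expected)
        assert len(pairs) == 38
        assert len(unmatched) == 150 - 38


class TestAnnotateAgainstDatabases:
    def test_self_database_previously_annotated(self):
        t = multi_exon("v1", "chr1", 1_000, [200, 300], [150])
        validated = AnnotationCatalog([t])
        report = annotate_against_databases(validated, [("db", validated)])
        assert report.previously_annotated == {"v1": "db"}
        assert report.novel == []

    def test_empty_dbs_all_novel_with_warning(self, caplog):
        validated = AnnotationCatalog(
            [multi_exon("v1", "chr1", 1_000, [200, 300], [150])])
        with caplog.at_level("WARNING"):
            report = annotate_against_databases(validated, [])
        assert report.novel == ["v1"]
        assert "no databases" in caplog.text

    def test_overlap_match_and_chain_only_mode(self):
        t = multi_exon("v1", "chr1", 1_000, [200, 300], [150])
        # db entry with a different intron chain but >=50% same-strand
        # exonic overlap of the shorter transcript
        db_t = make_t("db1", [iv(1_000, 1_650)])
        db = AnnotationCatalog([db_t])
        validated = AnnotationCatalog([t])
        lax = annotate_against_databases(validated, [("db", db)])
        assert lax.previously_annotated == {"v1": "db"}
        strict = annotate_against_databases(
            validated, [("db", db)], mode="chain_only")
        assert strict.novel == ["v1"]

    def test_first_matching_database_wins(self):
        t = multi_exon("v1", "chr1", 1_000, [200, 300], [150])
        validated = AnnotationCatalog([t])
        db = AnnotationCatalog([t])
        report = annotate_against_databases(
            validated, [("first", db), ("second", db)])
        assert report.previously_annotated == {"v1": "first"}

    def test_planted_28_of_38_gives_10_novel(self):
        rng = rng_stream(74, "dbs")
        slots = iter(range(20_000, 20_000 + 4_000 * 100, 4_000))
        validated = AnnotationCatalog()
        transcripts = []
        for i in range(38):
            widths, gaps, chrom, start = \
                TestCrossPlatformValidate.random_chain(rng, "chr1", next(slots))
            t = multi_exon(f"V{i:02d}", chrom, start, widths, gaps)
            validated.add(t)
            transcripts.append(t)
        # plant 28 into two mock databases (15 + 13), leave 10 absent
        db1 = AnnotationCatalog(
            [make_t("D1." + t.transcript_id, t.exons)
             for t in transcripts[:15]])
        db2 = AnnotationCatalog(
            [make_t("D2." + t.transcript_id, t.exons)
             for t in transcripts[15:28]])
        report = annotate_against_databases(
            validated, [("gencode_mock", db1), ("noncode_mock", db2)])
        assert len(report.novel) == 10
        assert sorted(report.novel) == [f"V{i:02d}" for i in range(28, 38)]
        assert set(report.previously_annotated) | set(report.novel) == \
            set(validated.transcript_ids)
        assert not set(report.previously_annotated) & set(report.novel)
        sources = set(report.previously_annotated.values())
        assert sources == {"gencode_mock", "noncode_mock"}

    def test_stage_counts(self):
        t = multi_exon("v1", "chr1", 1_000, [200, 300], [150])
        validated = AnnotationCatalog([t])
        report = annotate_against_databases(validated, [("db", validated)])
        counts = report.stage_counts()
        assert counts["validated"] == 1
        assert counts["previously_annotated"] == 1
        assert counts["novel"] == 0
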