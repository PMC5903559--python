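"""Call-set loading, INDEL interval matching and per-sample joining."""

from __future__ import annotations

import logging

import numpy as np
import pytest

from rgenome.calls import (
    Decision,
    JoinParams,
    VariantCall,
    VariantClass,
    as_genotype,
    classify_variant,
    genotypes_match,
    indel_interval,
    join_sample,
    load_callset,
    load_joined_vcf,
    write_joined_vcf,
)

from conftest import make_vcf
from oracles import indel_pair_matches


def _call(pos, ref, alt, gt=None, contig="chr1"):
    """Shorthand VariantCall; gt defaults to het ref/alt."""
    genotype = gt if gt is not None else as_genotype(ref, alt)
    return VariantCall(
        contig=contig, pos=pos, ref=ref, alts=(alt,),
        genotype=genotype, vclass=classify_variant(ref, genotype),
    )


class TestLoadCallset:
    def test_only_pass_and_dot_filters_survive(self, tmp_path):
        vcf = make_vcf(tmp_path, "a.vcf", [
            ("chr1", 10, "A", "T", "PASS", "0/1"),
            ("chr1", 20, "A", "T", "q10", "0/1"),
            ("chr1", 30, "A", "T", ".", "0/1"),
        ])
        calls = list(load_callset(vcf, "p1"))
        assert [c.pos for c in calls] == [10, 30]
        assert calls[0].filter == "PASS" and calls[1].filter == "."

    def test_empty_vcf_yields_empty_stream(self, tmp_path):
        vcf = make_vcf(tmp_path, "empty.vcf", [])
        assert list(load_callset(vcf)) == []

    def test_gt_parsed_as_unordered_allele_pair(self, tmp_path):
        vcf = make_vcf(tmp_path, "gt.vcf", [("chr1", 10, "A", "T", "PASS", "1/0")])
        (call,) = load_callset(vcf)
        assert call.genotype == ("A", "T")
        assert call.vclass is VariantClass.SNV

    def test_multiallelic_record_is_one_call_with_all_alts(self, tmp_path):
        vcf = make_vcf(tmp_path, "ma.vcf", [("chr1", 10, "A", "T,G", "PASS", "1/2")])
        (call,) = load_callset(vcf)
        assert call.alts == ("T", "G")
        assert call.genotype == ("G", "T")

    def test_missing_gt_skipped_with_warning(self, tmp_path, caplog):
        vcf = make_vcf(tmp_path, "nogt.vcf", [
            ("chr1", 10, "A", "T", "PASS", "./."),
            ("chr1", 20, "A", "T", "PASS", "0/1"),
        ])
        with caplog.at_level(logging.WARNING):
            calls = list(load_callset(vcf, "p1"))
        assert [c.pos for c in calls] == [20]
        assert any("missing GT" in r.message for r in caplog.records)

    def test_haploid_gt_skipped_with_warning(self, tmp_path, caplog):
        vcf = make_vcf(tmp_path, "hap.vcf", [("chr1", 10, "A", "T", "PASS", "1")])
        with caplog.at_level(logging.WARNING):
            assert list(load_callset(vcf, "p1")) == []
        assert any("non-diploid" in r.message for r in caplog.records)

    def test_hom_ref_record_is_not_a_variant_call(self, tmp_path):
        vcf = make_vcf(tmp_path, "homref.vcf", [("chr1", 10, "A", "T", "PASS", "0/0")])
        assert list(load_callset(vcf)) == []

    def test_unsorted_input_raises_naming_record(self, tmp_path):
        vcf = make_vcf(tmp_path, "uns.vcf", [
            ("chr1", 30, "A", "T", "PASS", "0/1"),
            ("chr1", 10, "A", "T", "PASS", "0/1"),
        ])
        with pytest.raises(ValueError, match="chr1:10"):
            list(load_callset(vcf))


class TestIndelInterval:
    @pytest.mark.parametrize(
        "pos,ref,l,expected",
        [
            (100, "ACGT", 5, (95, 108)),  # deletion footprint + slack
            (100, "A", 0, (100, 100)),    # insertion, no extension
            (100, "A", 5, (95, 105)),
        ],
    )
    def test_extended_footprint(self, pos, ref, l, expected):
        call = _call(pos, ref, "A" if len(ref) > 1 else "ACG")
        assert call.vclass is VariantClass.INDEL
        assert indel_interval(call, JoinParams(l=l)) == expected

    def test_snv_input_is_a_contract_violation(self):
        with pytest.raises(ValueError):
            indel_interval(_call(100, "A", "T"), JoinParams())

    def test_negative_extension_rejected(self):
        with pytest.raises(ValueError):
            JoinParams(l=-1)


class TestGenotypesMatch:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (("A", "T"), ("T", "A"), True),   # phase ignored
            (("A", "T"), ("T", "T"), False),
            (("A", "ACGT"), ("ACGT", "A"), True),  # het deletion both ways
        ],
    )
    def test_unordered_pair_equality(self, a, b, expected):
        assert genotypes_match(a, b) is expected

    def test_no_call_is_a_contract_violation(self):
        with pytest.raises(ValueError):
            genotypes_match(None, ("A", "T"))


class TestJoinSample:
    def test_identical_snv_across_three_pipelines_is_concordant(self):
        callsets = {p: [_call(12, "A", "T")] for p in ("P1", "P2", "P3")}
        (d,) = join_sample(callsets)
        assert d.decision is Decision.CONCORDANT
        assert d.pos == 12 and d.vclass is VariantClass.SNV
        assert all(g == ("A", "T") for g in d.per_pipeline.values())

    def test_call_absent_from_one_pipeline_is_discordant(self):
        callsets = {
            "P1": [_call(12, "A", "T")],
            "P2": [_call(12, "A", "T")],
            "P3": [],
        }
        (d,) = join_sample(callsets)
        assert d.decision is Decision.DISCORDANT
        assert d.per_pipeline["P3"] is None

    def test_genotype_mismatch_is_discordant(self):
        callsets = {
            "P1": [_call(12, "A", "T")],
            "P2": [_call(12, "A", "T", gt=("T", "T"))],
        }
        (d,) = join_sample(callsets)
        assert d.decision is Decision.DISCORDANT

    def test_shifted_het_deletion_matches_within_slack(self):
        # 2-bp deletion at 100 vs 104: extended intervals [95,106]/[99,110]
        a = _call(100, "AC", "A")
        b = _call(104, "AC", "A")
        (d,) = join_sample({"P1": [a], "P2": [b]}, JoinParams(l=5))
        assert d.decision is Decision.CONCORDANT
        assert d.pos == 100  # leftmost member anchors the site

    def test_snv_never_satisfies_an_indel_match(self):
        callsets = {
            "P1": [_call(100, "AC", "A")],
            "P2": [_call(100, "A", "T")],
        }
        decisions = join_sample(callsets)
        assert len(decisions) == 2
        assert {d.vclass for d in decisions} == {VariantClass.SNV, VariantClass.INDEL}
        assert all(d.decision is Decision.DISCORDANT for d in decisions)

    def test_fewer_than_two_pipelines_rejected(self):
        with pytest.raises(ValueError):
            join_sample({"P1": []})

    def test_self_agreement_on_a_simulated_callset(self, small_cohort):
        calls = small_cohort.calls[small_cohort.sample_ids[0]]["P1"]
        decisions = join_sample({"A": calls, "B": calls, "C": calls})
        assert decisions
        assert all(d.decision is Decision.CONCORDANT for d in decisions)
        assert len(decisions) == len(calls)

    def test_decisions_invariant_under_pipeline_permutation(self, small_cohort):
        callsets = small_cohort.calls[small_cohort.sample_ids[1]]
        base = join_sample(callsets, sample_id="s")
        pids = list(callsets)
        permuted = {p: callsets[p] for p in reversed(pids)}
        assert join_sample(permuted, sample_id="s") == base

    def test_indel_matching_monotone_in_l_and_symmetric(self):
        rng = np.random.default_rng(7)
        pairs = []
        for _ in range(120):
            pos = int(rng.integers(1000, 900_000))
            reflen = int(rng.integers(1, 5))
            ref = ("ACGTA")[:reflen] if reflen > 1 else "A"
            delta = int(rng.integers(0, 25))
            pairs.append((pos, ref, pos + delta, ref))
        prev_matched: set[int] | None = None
        for l in (0, 2, 5, 10):
            matched = set()
            for i, (pa, ra, pb, rb) in enumerate(pairs):
                alt_a = ra[0] if len(ra) > 1 else ra + "CG"  # del or ins
                alt_b = rb[0] if len(rb) > 1 else rb + "CG"
                a = _call(pa, ra, alt_a)
                b = _call(pb, rb, alt_b)
                assert a.vclass is VariantClass.INDEL

                def is_matched(callsets):
                    ds = join_sample(callsets, JoinParams(l=l))
                    return len(ds) == 1 and ds[0].decision is Decision.CONCORDANT

                fwd = is_matched({"P1": [a], "P2": [b]})
                assert is_matched({"P1": [b], "P2": [a]}) == fwd  # symmetry
                assert fwd == indel_pair_matches(pa, ra, pb, rb, l)
                if fwd:
                    matched.add(i)
            if prev_matched is not None:
                assert prev_matched <= matched  # monotone in l
            prev_matched = matched

    def test_overlapping_indels_collapse_to_one_anchored_group(self):
        # two P1 deletions both overlap one P2 deletion -> one site anchored
        # at the leftmost member; concordant only if every member pair of
        # genotypes agrees
        agreeing = {
            "P1": [_call(100, "ACG", "A"), _call(108, "ACG", "A")],
            "P2": [_call(104, "ACG", "A")],
        }
        (d,) = join_sample(agreeing, JoinParams(l=5))
        assert d.pos == 100
        assert d.decision is Decision.CONCORDANT
        disagreeing = {
            "P1": [_call(100, "ACG", "A"), _call(108, "ACG", "A", gt=("A", "A"))],
            "P2": [_call(104, "ACG", "A")],
        }
        (d,) = join_sample(disagreeing, JoinParams(l=5))
        assert d.pos == 100
        assert d.decision is Decision.DISCORDANT


class TestJoinedVcfRoundTrip:
    def test_roundtrip_preserves_all_decisions(self, tmp_path, small_cohort):
        sample = small_cohort.sample_ids[2]
        decisions = join_sample(small_cohort.calls[sample], sample_id=sample)
        assert len(decisions) > 50
        path = tmp_path / "joined.vcf"
        write_joined_vcf(decisions, path, params=JoinParams())
        loaded = load_joined_vcf(path)
        assert loaded == decisions

    def test_filter_column_encodes_the_decision(self, tmp_path):
        decisions = join_sample({
            "P1": [_call(10, "A", "T"), _call(50, "A", "G")],
            "P2": [_call(10, "A", "T")],
        }, sample_id="s1")
        path = tmp_path / "j.vcf"
        write_joined_vcf(decisions, path)
        text = path.read_text()
        assert "RG_DISC" in text
        lines = [l for l in text.splitlines() if not l.startswith("#")]
        assert lines[0].split("\t")[6] == "PASS"
        assert lines[1].split("\t")[6] == "RG_DISC"

    def test_empty_stream_writes_header_only(self, tmp_path):
        path = tmp_path / "e.vcf"
        write_joined_vcf([], path)
        assert load_joined_vcf(path) == []
        assert all(l.startswith("#") for l in path.read_text().splitlines())
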