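"""HGVS consequence classification and the purity-zygosity VAF model."""

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

from gistmax import (
    VariantRecord,
    classify_consequence,
    concordance_across_specimens,
    expected_vaf,
    gen_variant_set,
    infer_zygosity,
    somatic_status,
    toy_transcript,
)
from gistmax.variants import HgvsParseError, parse_hgvs_c


class TestHgvsParsing:
    def test_substitution_forms(self):
        p = parse_hgvs_c("c.123A>G")
        assert (p.kind, p.start.coding_pos, p.ref, p.alt) == ("sub", 123, "A", "G")
        p = parse_hgvs_c("c.-23G>A")
        assert p.start.coding_pos == -23
        p = parse_hgvs_c("c.310+1G>T")
        assert (p.start.coding_pos, p.start.offset) == (310, 1)
        p = parse_hgvs_c("c.311-2A>G")
        assert (p.start.coding_pos, p.start.offset) == (311, -2)

    def test_indel_forms(self):
        assert parse_hgvs_c("c.100_102del").kind == "del"
        assert parse_hgvs_c("c.100dup").kind == "dup"
        assert parse_hgvs_c("c.100_101insAT").alt == "AT"

    @pytest.mark.parametrize("bad", ["c.12", "p.R60X", "c.*5A>G", "c.0A>G", "g.100A>G"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(HgvsParseError):
            parse_hgvs_c(bad)

    def test_reference_base_mismatch_names_position(self, transcript):
        actual = transcript.base_at(50)
        wrong = "A" if actual != "A" else "C"
        with pytest.raises(HgvsParseError, match="c.50"):
            classify_consequence(VariantRecord(f"c.50{wrong}>G"), transcript)

    def test_position_out_of_range(self, transcript):
        with pytest.raises((HgvsParseError, ValueError), match="outside|beyond"):
            classify_consequence(VariantRecord("c.9999A>G"), transcript)


class TestConsequenceClassification:
    def test_splice_donor_after_exon3_lists_exon3_skip(self, transcript):
        donor = transcript.exons[2].tx_end - transcript.cds_start + 1
        cons = classify_consequence(VariantRecord(f"c.{donor}+1G>T"), transcript)
        assert cons.kind == "splice_site"
        assert "exon3_skipping" in cons.splice_candidates
        assert "intron3_retention" in cons.splice_candidates

    def test_splice_site_flanking_intron4_lists_intron4_retention(self, transcript):
        donor = transcript.exons[3].tx_end - transcript.cds_start + 1
        cons = classify_consequence(VariantRecord(f"c.{donor}+2T>C"), transcript)
        assert cons.kind == "splice_site"
        assert "intron4_retention" in cons.splice_candidates
        acceptor = transcript.exons[4].tx_start - transcript.cds_start + 1
        cons = classify_consequence(VariantRecord(f"c.{acceptor}-1G>A"), transcript)
        assert cons.kind == "splice_site"
        assert "intron4_retention" in cons.splice_candidates

    def test_deep_intronic_is_intronic_not_splice(self, transcript):
        donor = transcript.exons[2].tx_end - transcript.cds_start + 1
        cons = classify_consequence(VariantRecord(f"c.{donor}+14A>G"), transcript)
        assert cons.kind == "intronic"

    def test_start_codon_substitution_is_start_loss(self, transcript):
        cons = classify_consequence(VariantRecord("c.1A>G"), transcript)
        assert cons.kind == "start_loss"

    def test_utr5_class(self, transcript):
        base = transcript.base_at(-23)
        alt = "A" if base != "A" else "G"
        cons = classify_consequence(VariantRecord(f"c.-23{base}>{alt}"), transcript)
        assert cons.kind == "utr5"

    def test_frameshift_and_inframe_deletion(self, transcript):
        cons = classify_consequence(
            VariantRecord(f"c.30del{transcript.base_at(30)}"), transcript
        )
        assert cons.kind == "frameshift"
        cons = classify_consequence(VariantRecord("c.31_36del"), transcript)
        assert cons.kind == "intragenic_deletion"

    def test_whole_exon_deletion_is_intragenic_deletion(self, transcript):
        ex2 = transcript.exons[1]
        start = ex2.tx_start - transcript.cds_start + 1
        end = ex2.tx_end - transcript.cds_start + 1
        cons = classify_consequence(VariantRecord(f"c.{start}_{end}del"), transcript)
        assert cons.kind == "intragenic_deletion"

    def test_all_substitutions_match_retranslation_oracle(self):
        """Exhaustive mutate-and-retranslate check on a 201-nt toy CDS."""
        rng = np.random.default_rng(11)
        sense = [
            "".join(c) for c in itertools.product("ACGT", repeat=3)
            if "".join(c) not in ("TAA", "TAG", "TGA")
        ]
        cds = "ATG" + "".join(rng.choice(sense) for _ in range(65)) + "TAA"
        assert len(cds) == 201
        tx = toy_transcript(cds)
        checked = 0
        for pos in range(1, len(cds) + 1):
            ref = cds[pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                got = classify_consequence(VariantRecord(f"c.{pos}{ref}>{alt}"), tx).kind
                # oracle: rebuild the CDS and translate from scratch
                mut = cds[: pos - 1] + alt + cds[pos:]
                if mut[:3] != "ATG":
                    want = "start_loss"
                else:
                    old = str(Seq(cds).translate())
                    new = str(Seq(mut).translate())
                    idx = (pos - 1) // 3
                    if new[idx] == "*" and old[idx] != "*":
                        want = "nonsense"
                    elif new[idx] == old[idx]:
                        want = "synonymous"
                    else:
                        want = "missense"
                assert got == want, f"c.{pos}{ref}>{alt}: {got} != {want}"
                checked += 1
        assert checked == 3 * len(cds)

    def test_fixture_variant_set_has_published_class_mix(self, transcript):
        kinds = [classify_consequence(v, transcript).kind for v in gen_variant_set(transcript)]
        assert sorted(kinds) == sorted(
            ["nonsense"] * 3 + ["start_loss", "frameshift", "utr5"] + ["splice_site"] * 2
        )


class TestPurityVafModel:
    @pytest.mark.parametrize(
        "zygosity,purity,expected",
        [
            ("hemizygous_LOH", 0.80, 2 / 3),
            ("heterozygous", 1.0, 0.5),
            ("hemizygous_LOH", 1.0, 1.0),
            ("homozygous", 0.75, 0.75),
        ],
    )
    def test_expected_vaf_formulae(self, zygosity, purity, expected):
        assert expected_vaf(zygosity, purity) == pytest.approx(expected)

    def test_hemizygous_at_80pct_purity_rounds_to_0_67(self):
        assert round(expected_vaf("hemizygous_LOH", 0.80), 2) == 0.67

    def test_monotone_in_purity_and_class_ordering(self):
        grid = np.linspace(0.1, 1.0, 15)
        for z in ("heterozygous", "hemizygous_LOH", "homozygous"):
            vals = [expected_vaf(z, t) for t in grid]
            assert all(a < b for a, b in zip(vals, vals[1:]))
        for t in grid:
            assert expected_vaf("hemizygous_LOH", t) >= expected_vaf("heterozygous", t)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="zygosity"):
            expected_vaf("triploid", 0.8)


class TestInferZygosity:
    def test_known_purity_examples(self):
        assert infer_zygosity(0.67, 0.80).classes == ("hemizygous_LOH",)
        assert infer_zygosity(0.5, 1.0).classes == ("heterozygous",)

    def test_round_trip_identity_where_separable(self):
        for purity in np.arange(0.5, 1.01, 0.1):
            exp = {z: expected_vaf(z, purity) for z in
                   ("heterozygous", "hemizygous_LOH", "homozygous")}
            for z, v in exp.items():
                others = [abs(v - o) for k, o in exp.items() if k != z]
                if min(others) > 2 * 0.05:
                    assert infer_zygosity(v, purity).best == z

    def test_ambiguity_reported_not_resolved(self):
        # at purity 1.0 hemizygous and homozygous expectations coincide at 1.0
        inf = infer_zygosity(1.0, 1.0)
        assert set(inf.classes) >= {"hemizygous_LOH", "homozygous"}
        assert inf.ambiguous

    def test_unknown_purity_returns_compatible_ranges(self):
        inf = infer_zygosity(0.7)
        assert set(inf.purity_ranges) == {"hemizygous_LOH", "homozygous"}
        lo, hi = inf.purity_ranges["homozygous"]
        assert (lo, hi) == (pytest.approx(0.65), pytest.approx(0.75))


class TestSomaticStatus:
    def test_matched_normal_decides(self):
        assert somatic_status(VariantRecord("c.1A>G", normal_genotype="wild_type")) == "somatic"
        assert somatic_status(VariantRecord("c.1A>G", normal_genotype="variant")) == "germline"

    def test_case19_like_vaf_without_normal(self):
        v = VariantRecord("c.-23G>A", vaf=0.7, normal_genotype="unavailable")
        assert somatic_status(v) == "consistent_with_somatic"

    def test_heterozygous_compatible_vaf_stays_indeterminate(self):
        v = VariantRecord("c.1A>G", vaf=0.45, normal_genotype="unavailable")
        assert somatic_status(v) == "indeterminate"

    def test_no_vaf_no_normal_is_indeterminate(self):
        assert somatic_status(VariantRecord("c.1A>G")) == "indeterminate"


class TestConcordance:
    def test_identical_sets_concordant(self):
        rep = concordance_across_specimens(
            {"primary": ["c.1A>G"], "met1": ["c.1A>G"], "met2": ["c.1A>G"]}
        )
        assert rep.concordant and rep.shared == ("c.1A>G",)

    def test_private_variant_listed(self):
        rep = concordance_across_specimens({"a": {"c.1A>G"}, "b": {"c.1A>G", "c.20C>A"}})
        assert not rep.concordant
        assert rep.discordant == {"b": ("c.20C>A",)}

    def test_single_specimen_rejected(self):
        with pytest.raises(ValueError, match="two specimens"):
            concordance_across_specimens({"a": ["c.1A>G"]})
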