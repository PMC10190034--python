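"""Rule-based splice features: AG/GT flags, AGEZ, U12, minimal intron,
feature-vector assembly."""

import numpy as np
import pytest

from splicetree.features import (
    BranchpointConfig,
    build_feature_vector,
    detect_ag_gt_change,
    in_ag_exclusion_zone,
    min_intron_violation,
    u12_flag,
)
from splicetree.genome import GeneModel, RegionClass, Transcript
from splicetree.pwm import default_pwms
from splicetree.variants import Variant

BASES = "ACGT"


def _dinuc_oracle(ref_w: str, alt_w: str):
    """Enumerate dinucleotides of both windows (independent oracle)."""
    count = lambda s, d: sum(s[i : i + 2] == d for i in range(len(s) - 1))
    return tuple(
        flag
        for d in ("AG", "GT")
        for flag in (count(alt_w, d) > count(ref_w, d), count(ref_w, d) > count(alt_w, d))
    )


def test_ag_gt_creation_snv():
    # AATT, T->G at 3rd base -> AAGT: creates both AG and GT
    assert detect_ag_gt_change(Variant("c", 3, "T", "G"), "AATT", 1) == (
        True, False, True, False,
    )


def test_ag_gt_removal_deletion():
    # CAGT, delete the G (anchored AG->A at pos 2) -> CAT
    flags = detect_ag_gt_change(Variant("c", 2, "AG", "A"), "CAGT", 1)
    assert flags[1] is True  # ag_removed
    assert flags[3] is True  # the GT also disappears


def test_ag_gt_no_change_in_homopolymer():
    assert detect_ag_gt_change(Variant("c", 3, "C", "T"), "CCCC", 1) == (
        False, False, False, False,
    )


def test_ag_gt_flags_match_enumeration_oracle(rng):
    seq = "".join(rng.choice(list(BASES), 40))
    for _ in range(100):
        pos = int(rng.integers(3, 38))
        alt = str(rng.choice([b for b in BASES if b != seq[pos - 1]]))
        v = Variant("c", pos, seq[pos - 1], alt)
        ref_w = seq[pos - 2 : pos + 1]
        alt_w = ref_w[0] + alt + ref_w[2]
        assert detect_ag_gt_change(v, seq, 1) == _dinuc_oracle(ref_w, alt_w)


def test_ag_gt_reversion_mirrors_flags(rng):
    seq = "".join(rng.choice(list(BASES), 40))
    for _ in range(50):
        pos = int(rng.integers(3, 38))
        alt = str(rng.choice([b for b in BASES if b != seq[pos - 1]]))
        v = Variant("c", pos, seq[pos - 1], alt)
        alt_seq = seq[: pos - 1] + alt + seq[pos:]
        rev = Variant("c", pos, alt, seq[pos - 1])
        ag_c, ag_r, gt_c, gt_r = detect_ag_gt_change(v, seq, 1)
        assert detect_ag_gt_change(rev, alt_seq, 1) == (ag_r, ag_c, gt_r, gt_c)


# --- AGEZ ------------------------------------------------------------------

# plus-strand transcript: intron 0-based (100, 200); 3'SS at 1-based 200
TX = Transcript("t", [(50, 100), (200, 260)], strand="+")


def _pos_at_d3(d3):  # 1-based genomic position d3 nt from the 3'SS
    return 200 - d3 + 1


def test_agez_membership_and_subcases():
    cfg = BranchpointConfig()
    bp = _pos_at_d3(30)  # branchpoint 30 nt from the 3'SS
    # AG created 20 nt upstream of the 3'SS, 10 nt from the bp: skip-prone
    res = in_ag_exclusion_zone(
        Variant("c", _pos_at_d3(20), "T", "G"), TX, "+", bp, cfg, ag_created=True
    )
    assert res.in_agez and res.bp_distance == 10
    assert res.subcase == "exon_skipping"
    # 5 nt downstream of the bp: also skip-prone
    res = in_ag_exclusion_zone(
        Variant("c", _pos_at_d3(25), "T", "G"), TX, "+", bp, cfg, ag_created=True
    )
    assert res.in_agez and res.bp_distance == 5 and res.subcase == "exon_skipping"
    # 25 nt from the bp (5 nt from the 3'SS): distal -> new splice site use
    res = in_ag_exclusion_zone(
        Variant("c", _pos_at_d3(5), "T", "G"), TX, "+", bp, cfg, ag_created=True
    )
    assert res.in_agez and res.bp_distance == 25 and res.subcase == "new_splice_site"


def test_agez_excludes_positions_at_or_upstream_of_branchpoint():
    bp = _pos_at_d3(30)
    for d3 in (30, 35, 60):
        res = in_ag_exclusion_zone(
            Variant("c", _pos_at_d3(d3), "T", "G"), TX, "+", bp, ag_created=True
        )
        assert not res.in_agez and res.subcase is None


def test_agez_excludes_the_acceptor_ag_itself():
    bp = _pos_at_d3(30)
    for d3 in (1, 2):
        assert not in_ag_exclusion_zone(
            Variant("c", _pos_at_d3(d3), "T", "G"), TX, "+", bp
        ).in_agez


def test_agez_default_window_when_branchpoint_missing():
    cfg = BranchpointConfig()
    res = in_ag_exclusion_zone(Variant("c", _pos_at_d3(20), "T", "G"), TX, "+", None, cfg)
    assert res.in_agez and res.bp_distance == cfg.window_max - 20
    assert not in_ag_exclusion_zone(
        Variant("c", _pos_at_d3(44), "T", "G"), TX, "+", None, cfg
    ).in_agez


def test_agez_exonic_variant_is_outside():
    res = in_ag_exclusion_zone(Variant("c", 75, "A", "G"), TX, "+", None)
    assert not res.in_agez and res.bp_distance is None


# --- U12 and minimal intron ------------------------------------------------


def test_u12_flag_contract():
    v = Variant("c", 150, "A", "G")  # in the intron (100, 200)
    assert u12_flag(v, TX, "+", [("c", 100, 200)]) is True
    assert u12_flag(v, TX, "+", [("c", 300, 400)]) is False
    assert u12_flag(v, TX, "+", None) is None  # no file: missing, not False
    exonic = Variant("c", 75, "A", "G")
    assert u12_flag(exonic, TX, "+", [("c", 100, 200)]) is False


def test_min_intron_violation_rule():
    cfg = BranchpointConfig()
    # 100-nt intron (100, 200): 60-nt deletion leaves 40 < 45
    big = Variant("c", 110, "A" * 61, "A")
    assert big.vclass == "deletion"
    assert min_intron_violation(big, TX, cfg) is True
    small = Variant("c", 110, "A" * 11, "A")
    assert min_intron_violation(small, TX, cfg) is False
    snv = Variant("c", 150, "A", "G")
    assert min_intron_violation(snv, TX, cfg) is False


# --- assembly ---------------------------------------------------------------


def _toy_genome_and_gene():
    rng = np.random.default_rng(7)
    seq = list("".join(rng.choice(list(BASES), 400)))
    # exon1 0-based (50,100), intron (100,200) with GT..AG, exon2 (200,260)
    seq[100:102] = "GT"
    seq[198:200] = "AG"
    genome = {"c": "".join(seq)}
    gene = GeneModel("g", "c", "+", [TX])
    return genome, gene


def test_build_feature_vector_composes_per_feature_calls():
    genome, gene = _toy_genome_and_gene()
    pwms = default_pwms()
    v = Variant("c", 101, "G", "C")  # kills the donor GT
    fv = build_feature_vector(v, [gene], genome, pwms)
    assert fv.region is RegionClass.DONOR
    assert fv.gt_removed == detect_ag_gt_change(v, genome["c"], 1)[3]
    assert fv.min_intron_violation is False
    assert fv.u12 is None
    # external scores absent -> all missing
    assert fv.external == {}
    # compose-vs-direct: identical variant, two calls -> identical vectors
    fv2 = build_feature_vector(v, [gene], genome, pwms)
    assert fv.to_row() == fv2.to_row()


def test_feature_vector_exonic_pwm_and_intronic_missingness():
    genome, gene = _toy_genome_and_gene()
    pwms = default_pwms()
    exonic = Variant("c", 75, genome["c"][74], "G" if genome["c"][74] != "G" else "A")
    fv = build_feature_vector(exonic, [gene], genome, pwms)
    assert all(d is not None for d in fv.pwm_delta.values())
    deep = Variant("c", 150, genome["c"][149], "C" if genome["c"][149] != "C" else "A")
    fv_deep = build_feature_vector(deep, [gene], genome, pwms)
    assert all(d is None for d in fv_deep.pwm_delta.values())  # far from exons
    row = fv_deep.to_row()
    assert np.isnan(row["pwm_delta_SRSF1"])


def test_variant_outside_gene_models_raises():
    genome, gene = _toy_genome_and_gene()
    with pytest.raises(ValueError):
        build_feature_vector(Variant("c", 380, "A", "G") if genome["c"][379] == "A"
                             else Variant("c", 380, genome["c"][379], "A"),
                             [gene], genome, [])


def test_minus_strand_pwm_delta_equals_revcomp_plus(rng):
    """Sequence features on a minus-strand gene equal the plus-strand
    computation on the reverse-complemented context (strand oracle)."""
    from splicetree.pwm import delta_pwm, score_pwm_window

    comp = str.maketrans(BASES, "TGCA")
    pwm = default_pwms()[0]
    seq = "".join(rng.choice(list(BASES), 40))
    v = Variant("c", 20, seq[19], "A" if seq[19] != "A" else "C")
    minus = delta_pwm(v, seq, 1, pwm, strand="-")
    # oracle: apply to revcomp'd coordinates explicitly
    alt = seq[:19] + v.alt + seq[20:]
    plus = score_pwm_window(alt.translate(comp)[::-1], pwm) - score_pwm_window(
        seq.translate(comp)[::-1], pwm
    )
    assert minus == pytest.approx(plus, abs=1e-12)
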