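"""Cassette model, antisense stop scanning and phenotype prediction."""

import dataclasses
import itertools

import numpy as np
import pytest

from pgrass.olivar import (
    DESTABILIZED_FUSION,
    FLUORESCENT,
    FUSION_READTHROUGH,
    LOW_FLUORESCENT,
    NON_FLUORESCENT,
    PREMATURE_ANTISENSE_STOP,
    SC_READTHROUGH,
    STRONG,
    WEAK_DESTABILIZATION,
    ModelStructureError,
    ScreenPolicy,
    VectorModel,
    antisense_stop_positions,
    build_reference_model,
    classify_insert,
    enumerate_target_codons,
    model_from_genbank,
    model_to_genbank,
    predict_gfp_outcome,
    validate_cassette,
)
from pgrass.restriction import digest, ligate_blunt
from pgrass.seqcore import (
    CIRCULAR,
    STOP_CODONS,
    NucSeq,
    reverse_complement,
    translate,
)
from pgrass.synth_fixtures import OrfSpec, random_orf

ALL_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]


def test_target_codons_derived_by_enumeration():
    targets = enumerate_target_codons()
    assert targets == {"TCA", "TTA", "CTA"}
    assert len(targets) == 3
    assert {reverse_complement(c) for c in targets} == {"TGA", "TAA", "TAG"}
    assert not targets & STOP_CODONS  # no stop is the revcomp of a stop


def test_policy_rejects_non_antisense_stop_codons():
    with pytest.raises(ValueError):
        ScreenPolicy(target_codons=frozenset({"ATG"}))


@pytest.mark.parametrize(
    "bases,expected",
    [("ATGTCAGGC", [1]), ("ATGGGCGGC", []), ("TTACTATCA", [0, 1, 2])],
)
def test_antisense_stop_positions_examples(bases, expected, policy):
    assert antisense_stop_positions(NucSeq(bases), policy) == expected


def test_antisense_scan_agrees_with_exhaustive_codon_oracle(policy):
    # every one of the 64 codons, alone in a minimal ORF context
    for codon in ALL_CODONS:
        flagged = antisense_stop_positions(NucSeq("ATG" + codon), policy)
        expect = [1] if reverse_complement(codon) in STOP_CODONS else []
        assert flagged == expect, codon
    # and on 500 random ORFs against a brute-force per-codon scan
    rng = np.random.default_rng(8)
    for _ in range(500):
        cds = "".join(rng.choice(ALL_CODONS, size=30))
        oracle = [
            i for i in range(30)
            if reverse_complement(cds[3 * i:3 * i + 3]) in STOP_CODONS
        ]
        assert antisense_stop_positions(NucSeq(cds), policy) == oracle


def test_reference_model_is_valid_and_deterministic(ref_model):
    assert validate_cassette(ref_model) == []
    again = build_reference_model(1)
    assert again.seq.bases == ref_model.seq.bases
    assert 3000 <= len(ref_model.seq) <= 6000
    # GFP sits antisense to the EC strand
    assert ref_model.sc_strand == -ref_model.ec_strand


def test_validator_detects_single_base_frame_break(ref_model):
    # insert one base between the GFP ORF and the cloning site (SC linker)
    p = ref_model.gfp_orf[1] + 1
    bases = ref_model.seq.bases
    broken = NucSeq(bases[:p] + "A" + bases[p:], CIRCULAR, "broken")
    shifted = dataclasses.replace(
        ref_model,
        seq=broken,
        sc_start=ref_model.sc_start + 1,
        ec_start=ref_model.ec_start + 1,
        smaI_cut=ref_model.smaI_cut + 1,
        his6=(ref_model.his6[0] + 1, ref_model.his6[1] + 1),
        ec_stop=ref_model.ec_stop + 1,
    )
    violations = validate_cassette(shifted)
    assert any("frame" in v for v in violations)


def test_validator_detects_planted_antisense_stop(ref_model):
    # overwrite an EC codon (top strand) with TCA -> TGA in the SC frame
    pos = ref_model.smaI_cut + 3  # first full codon downstream of the cut
    bases = ref_model.seq.bases
    mutated = NucSeq(bases[:pos] + "TCA" + bases[pos + 3:], CIRCULAR, "mut")
    model = dataclasses.replace(ref_model, seq=mutated)
    violations = validate_cassette(model)
    assert any("antisense" in v and "stop" in v for v in violations)


def test_validator_detects_his_tag_damage(ref_model):
    h0 = ref_model.his6[0]
    bases = ref_model.seq.bases
    mutated = NucSeq(bases[:h0] + "GGC" + bases[h0 + 3:], CIRCULAR, "mut")
    model = dataclasses.replace(ref_model, seq=mutated)
    assert any("His" in v for v in validate_cassette(model))


def test_structural_errors_raise(ref_model):
    with pytest.raises(ModelStructureError):  # no ATG at the claimed SC start
        validate_cassette(dataclasses.replace(ref_model, sc_start=ref_model.sc_start + 1))
    with pytest.raises(ModelStructureError):
        validate_cassette(dataclasses.replace(ref_model, ec_start=ref_model.ec_start + 1))


# ---------------------------------------------------------------------------
# Phenotype prediction
# ---------------------------------------------------------------------------

def _sc_translation_oracle(model, product_bases: str, sc_anchor: str) -> str:
    """Brute-force SC-strand peptide, by plain string operations only."""
    doubled = product_bases + product_bases
    sc = doubled.index(sc_anchor)
    out = []
    pos = sc
    n = len(product_bases)
    for _ in range(n // 3):
        codon = reverse_complement(doubled[pos:pos + 3])
        aa = translate(codon + "TAA").protein or "*"
        if codon in STOP_CODONS:
            break
        out.append(aa[0] if aa else "*")
        pos = (pos - 3) % n
    return "".join(out)


def test_phenotype_truth_table_on_reference_model(ref_model, ref_fragment, policy):
    """Self → GFP+, reverse → GFP+, correct-with-target-codon → GFP−."""
    self_p, = ligate_blunt(ref_fragment)
    assert predict_gfp_outcome(ref_model, self_p, None, policy).phenotype == FLUORESCENT

    ins = NucSeq("ATG" + "TCA" + "GGC" * 8, id="tca_insert")
    fwd, rev = ligate_blunt(ref_fragment, ins)
    fr = predict_gfp_outcome(ref_model, fwd, ins, policy)
    assert fr.phenotype == NON_FLUORESCENT
    assert fr.reason == PREMATURE_ANTISENSE_STOP
    assert fr.stop_codon_index == 1
    rr = predict_gfp_outcome(ref_model, rev, ins, policy)
    assert rr.phenotype == FLUORESCENT
    assert rr.reason == FUSION_READTHROUGH
    assert rr.fusion_layout == "tca_insert→GFP"


def test_target_free_insert_gives_low_fluorescence(ref_model, ref_fragment, policy):
    spec = OrfSpec(
        n_codons=60,
        forbid_codons=enumerate_target_codons(),
        forbid_motifs=frozenset({"CCCGGG"}),
        rng_seed=9,
    )
    ins = random_orf(spec)
    fwd, _ = ligate_blunt(ref_fragment, ins.seq)
    report = predict_gfp_outcome(ref_model, fwd, ins, policy)
    assert report.phenotype == LOW_FLUORESCENT
    assert report.reason == DESTABILIZED_FUSION
    off = ScreenPolicy(low_fluorescence_rule="off")
    assert predict_gfp_outcome(ref_model, fwd, ins, off).phenotype == FLUORESCENT


def test_prediction_matches_brute_force_translation_on_random_inserts(
    ref_model, ref_fragment, policy
):
    """Phenotypes on 500 random inserts agree with a string-level oracle."""
    rng = np.random.default_rng(21)
    sc_anchor = ref_model.seq.fragment(ref_model.sc_start, ref_model.sc_start + 30)
    gfp_probe = ref_model.seq.fragment(*ref_model.gfp_orf)
    sense = [c for c in ALL_CODONS if c not in STOP_CODONS]
    for i in range(500):
        n = int(rng.integers(5, 40))
        ins = NucSeq("ATG" + "".join(rng.choice(sense, size=n)), id=f"r{i}")
        if "CCCGGG" in ins.bases:
            continue
        stops = antisense_stop_positions(ins, policy)
        fwd, rev = ligate_blunt(ref_fragment, ins)
        f = predict_gfp_outcome(ref_model, fwd, ins, policy)
        r = predict_gfp_outcome(ref_model, rev, ins, policy)
        assert r.phenotype == FLUORESCENT
        if stops:
            assert f.phenotype == NON_FLUORESCENT
            assert f.stop_codon_index == stops[0]
        else:
            assert f.phenotype == LOW_FLUORESCENT
        # oracle: forward product reaches the GFP peptide iff no antisense stop
        peptide = _sc_translation_oracle(ref_model, fwd.seq.bases, sc_anchor)
        gfp_aa = translate(reverse_complement(gfp_probe)).protein
        assert peptide.endswith(gfp_aa) == (not stops)


def test_his_tag_contract_on_forward_construct(ref_model, ref_fragment):
    """EC translation of a correct-orientation fusion ends ...HHHHHH then stop."""
    ins = NucSeq("ATG" + "TCA" + "AAA" * 6, id="i")
    fwd, _ = ligate_blunt(ref_fragment, ins)
    # EC start in product coordinates: the vector was rotated to the cut
    ec_new = (ref_model.ec_start - ref_model.smaI_cut) % len(ref_model.seq)
    bases = fwd.seq.bases
    doubled = bases + bases
    n_max = len(bases) // 3
    peptide = []
    for j in range(n_max):
        codon = doubled[ec_new + 3 * j: ec_new + 3 * j + 3]
        if codon in STOP_CODONS:
            break
        peptide.append(translate(codon + "TAA").protein)
    tail = "".join(peptide)
    assert tail.endswith("H" * 6)
    assert not tail.endswith("H" * 7)


def test_insert_with_internal_stop_warns_and_blocks_reverse_screening(
    ref_model, ref_fragment, policy
):
    ins = NucSeq("ATG" + "GGC" + "TGA" + "GGC" * 5, id="stopins")
    fwd, rev = ligate_blunt(ref_fragment, ins)
    r = predict_gfp_outcome(ref_model, rev, ins, policy)
    assert r.phenotype == NON_FLUORESCENT  # its own stop truncates the fusion
    assert any("compromised" in w for w in r.warnings)


def test_predict_rejects_frame_incompatible_insert(ref_model, ref_fragment, policy):
    ins = NucSeq("ATGA", id="bad")
    fwd, _ = ligate_blunt(ref_fragment, NucSeq("ATGAAA"))
    with pytest.raises(Exception):
        predict_gfp_outcome(ref_model, fwd, ins, policy)


@pytest.mark.parametrize(
    "bases,eligible,count,mode",
    [
        ("ATGAAATCAGGC", True, 1, STRONG),
        ("ATGCCCGGGAAA", False, 0, WEAK_DESTABILIZATION),
        ("ATGGGCAAGGAG", True, 0, WEAK_DESTABILIZATION),
    ],
)
def test_classify_insert_examples(bases, eligible, count, mode, policy):
    rep = classify_insert(NucSeq(bases), policy)
    assert rep.one_step_eligible is eligible
    assert rep.antisense_stop_count == count
    assert rep.screening_mode == mode


def test_genbank_round_trip(ref_model, tmp_path):
    path = tmp_path / "ref.gb"
    model_to_genbank(ref_model, path)
    back = model_from_genbank(path)
    assert back.seq.bases == ref_model.seq.bases
    assert back.sc_start == ref_model.sc_start
    assert back.smaI_cut == ref_model.smaI_cut
    assert back.gfp_orf == ref_model.gfp_orf
    assert validate_cassette(back) == []
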