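"""orf: ORF discovery, motif scanning, degeneration rubric."""

import numpy as np
import pytest
from Bio.Seq import Seq

from g2lhe import orf
from g2lhe.orf import (
    FamilyContext,
    consensus_self_score,
    find_orfs,
    load_pwm,
    locate_orf_domain,
    scan_laglidadg,
    score_degeneration,
)
from g2lhe.structure import annotate_record
from g2lhe.synthetic import (
    C_ANCHOR,
    degrade_orf,
    family_context_for,
    make_intron,
    preset,
    _rand_seq,
)

from conftest import stable_seed

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def aa_to_nt(peptide, table_id=4):
    """Deterministic reverse translation for test constructions."""
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[table_id]
    back = {}
    for codon, aa in sorted(table.forward_table.items()):
        back.setdefault(aa, codon)
    return "".join(back[a] for a in peptide)


# --- find_orfs --------------------------------------------------------------

def test_find_orfs_simple():
    body = aa_to_nt("M" + "K" * 120)
    seq = "CC" + body + "TAA" + "CCCC"
    ((s, e), frame, prot), = find_orfs(seq, min_aa=100)
    assert (s, e) == (3, 3 + len(body) + 2)
    assert frame == 2
    assert prot == "M" + "K" * 120


def test_find_orfs_runs_off_end():
    seq = aa_to_nt("M" + "L" * 150) + "AC"  # no stop; trailing partial codon
    ((s, e), frame, prot), = find_orfs(seq, min_aa=100)
    assert (s, e) == (1, len(seq) - 2)
    assert prot == "M" + "L" * 150


def test_find_orfs_table4_tga_is_trp():
    # TGA terminates in the standard code but reads Trp in table 4
    body = aa_to_nt("M" + "K" * 40) + "TGA" + aa_to_nt("K" * 40)
    seq = body + "TAA"
    assert find_orfs(seq, table_id=1, min_aa=50) == []
    ((_s, _e), _f, prot), = find_orfs(seq, table_id=4, min_aa=50)
    assert prot == "M" + "K" * 40 + "W" + "K" * 40


def test_find_orfs_unknown_table():
    with pytest.raises(ValueError):
        find_orfs("ATGAAA", table_id=99)


def test_find_orfs_against_translation_oracle():
    # every reported ORF must be independently consistent with Biopython
    rng = np.random.default_rng(stable_seed("orf-oracle"))
    for rep in range(5):
        seq = _rand_seq(rng, 2000)
        for (s, e), frame, prot in find_orfs(seq, table_id=4, min_aa=30):
            assert (s - 1) % 3 == frame
            assert seq[s - 1 : s + 2] in orf.START_CODONS
            body = seq[s - 1 : e]
            trimmed = body[: 3 * (len(body) // 3)]
            trans = str(Seq(trimmed).translate(table=4))
            # a GTG start is still reported as Met
            assert prot[0] == "M"
            if trans.endswith("*"):
                assert trans[1:] == prot[1:] + "*"
                assert "*" not in trans[:-1]
            else:  # ran off the 3' end
                assert trans[1:] == prot[1:]
                assert "*" not in trans
            assert len(prot) >= 30
            # maximality: the codon stream upstream to the previous stop
            # holds no earlier start in this frame
            k = s - 1 - 3
            while k >= 0:
                codon = seq[k : k + 3]
                if str(Seq(codon).translate(table=4)) == "*":
                    break
                assert codon not in orf.START_CODONS
                k -= 3


# --- PWM and motif scan -----------------------------------------------------

def test_pwm_shape_and_consensus():
    pwm = load_pwm()
    assert set(pwm) == set(AA20)
    assert all(v.shape == (10,) for v in pwm.values())
    # the column-wise argmax spells the canonical motif
    consensus = "".join(
        max(AA20, key=lambda aa: pwm[aa][i]) for i in range(10))
    assert consensus == "LAGLIDADGL"


def test_scan_consensus_hit():
    prot = "M" * 20 + "LAGLIDADGL" + "M" * 20
    (hit,) = scan_laglidadg(prot)
    assert hit.position == 21
    assert hit.score == pytest.approx(consensus_self_score())
    assert hit.catalytic_residue == "D"


def test_scan_terminus_append_invariance():
    core = "K" * 15 + "LAGLIDADGL" + "K" * 15
    base = scan_laglidadg(core)
    extended = scan_laglidadg("W" * 7 + core + "W" * 9)
    assert [h.score for h in base] == [h.score for h in extended]
    assert [h.position + 7 for h in base] == [h.position for h in extended]


def test_scan_catalytic_substitution_still_hits():
    # D->A at the catalytic column costs score but stays above threshold
    prot = "M" * 20 + "LAGLIDAAGL" + "M" * 20
    (hit,) = scan_laglidadg(prot)
    assert hit.catalytic_residue == "A"
    assert hit.score < consensus_self_score()


def test_scan_threshold_contract():
    # window score against the matrix itself decides the call
    pwm = load_pwm()
    shuffled = "DLGAADIGLL"  # same residues, wrong order
    s = sum(pwm[aa][k] for k, aa in enumerate(shuffled))
    hits = scan_laglidadg("M" * 20 + shuffled + "M" * 20)
    if s >= 0.60 * consensus_self_score():
        assert any(h.matched == shuffled for h in hits)
    else:
        assert all(h.matched != shuffled for h in hits)


def test_scan_nonoverlap_and_order():
    prot = "K" * 12 + "LAGLIDADGL" + "K" * 12 + "LAGLIDADGL" + "K" * 12
    hits = scan_laglidadg(prot)
    assert [h.position for h in hits] == [13, 35]
    assert all(b.position - a.position >= 10 for a, b in zip(hits, hits[1:]))


def test_scan_short_protein_rejected():
    with pytest.raises(ValueError):
        scan_laglidadg("LAGLIDAD")


def test_scan_stops_and_unknowns_skipped():
    assert scan_laglidadg("LAGLI*ADGL" + "K" * 10) == []
    assert scan_laglidadg("LAGLIXADGL" + "K" * 10) == []


# --- degeneration rubric ----------------------------------------------------

def _ctx(name):
    return family_context_for(preset(name))


def test_intact_double_clean():
    rec = make_intron(preset("rns-670"), seed=stable_seed("deg-clean"))
    rep = score_degeneration(rec, family_context=_ctx("rns-670"))
    assert rep.status == "intact_double" and not rep.flags
    assert len(rep.motif_hits) == 2
    assert rep.orf_span == rec.truth.orf_span


def test_intact_single_clean():
    rec = make_intron(preset("rnl-1787"), seed=stable_seed("deg-single"))
    rep = score_degeneration(rec, family_context=_ctx("rnl-1787"))
    assert rep.status == "intact_single" and not rep.flags


@pytest.mark.parametrize("mode,flag", [
    ("premature_stop", "premature_stop"),
    ("frameshift", "frameshift"),
    ("motif_loss", "motif_loss"),
    ("truncation", "truncation"),
    ("catalytic_disruption", "catalytic_disruption"),
])
def test_rubric_detects_each_lesion(mode, flag):
    rec = make_intron(preset("rnl-2059"), seed=stable_seed("deg-mode", mode))
    deg = degrade_orf(rec, mode, seed=11)
    rep = score_degeneration(deg, family_context=_ctx("rnl-2059"))
    assert rep.status == "degenerated"
    assert flag in rep.flags


def test_rubric_single_motif_family_uses_c_anchor():
    # frameshift in a single-motif family is only callable via the
    # conserved C-terminal anchor
    rec = make_intron(preset("rnl-1787"), seed=stable_seed("deg-canchor"))
    deg = degrade_orf(rec, "frameshift", seed=3)
    rep = score_degeneration(deg, family_context=_ctx("rnl-1787"))
    assert "frameshift" in rep.flags
    # without the anchor the same lesion is invisible to the rubric
    ctx = FamilyContext(expected_motifs=1, median_intact_aa=150, c_anchor=None)
    rep2 = score_degeneration(deg, family_context=ctx)
    assert "frameshift" not in rep2.flags


def test_rubric_host_domain_with_annotation():
    rec = make_intron(preset("rns-952"), seed=stable_seed("deg-host"))
    ann = annotate_record(rec, mode="annotation_guided")
    rep = score_degeneration(rec, annotation=ann, family_context=_ctx("rns-952"))
    assert rep.host_domain == "DIII"


def test_locate_orf_domain_rules():
    spans = {"DI": (1, 400), "DII": (401, 440), "DIV": (500, 900)}
    assert locate_orf_domain((50, 350), spans) == "DIB"
    assert locate_orf_domain((520, 880), spans) == "DIV"
    assert locate_orf_domain((380, 520), spans) == "other"  # straddles


def test_report_invariants_enforced():
    rep = orf.OrfReport(status="degenerated", flags=set())
    with pytest.raises(ValueError):
        rep.check_invariants()


def test_c_anchor_present_in_synthetic_orfs():
    rec = make_intron(preset("rns-1396"), seed=stable_seed("deg-anchor2"))
    s, e = rec.truth.orf_span
    prot = str(Seq(rec.sequence[s - 1 : e - 3]).translate(table=4))
    assert C_ANCHOR in prot
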