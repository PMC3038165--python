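"""Primer-table model, motif validation, binding-site scan and in-silico PCR."""

import pytest

from hoxsurvey.primers import (
    DegeneratePrimer,
    MotifMismatchError,
    find_binding_sites,
    in_silico_pcr,
    pair_primers,
    tiered_survey,
    validate_primer_motif,
)
from hoxsurvey.simulate import SimulationConfig, make_templates, root_homeoboxes


def _mini(name, seq, direction="forward", targets=frozenset({1}), motif=None,
          tier="general"):
    return DegeneratePrimer(
        name=name, sequence=seq, direction=direction, target_pgs=targets,
        target_genes=frozenset(), aa_motif=motif, product_len=None,
        product_len_range=None, tier=tier,
    )


# -- table and motif validation ---------------------------------------------

def test_packaged_table_loads_with_unique_names(primers):
    names = [p.name for p in primers]
    assert len(names) == len(set(names))
    assert {p.direction for p in primers} == {"forward", "reverse"}
    by_name = {p.name: p for p in primers}
    assert by_name["HoxF1"].target_pgs == frozenset(range(1, 8))
    assert by_name["HoxFC5"].target_genes == frozenset({"C5"})
    assert by_name["HoxR14"].pairs_with == frozenset({"HoxF13A", "HoxF13B"})
    assert by_name["HoxB7(5'E1)F"].aa_motif is None  # 5'UTR primer


def test_every_motif_bearing_primer_validates(primers):
    for p in primers:
        if p.aa_motif is not None:
            validate_primer_motif(p)  # must not raise


@pytest.mark.parametrize(
    "name,offset",
    [("HoxF8S", 0),   # EKEFLFNP read straight off the primer
     ("HoxF1", 2),    # first two bases sit inside the Leu codon
     ("HoxR1", 0)],   # validates on the reverse complement (WFQNRRMK)
)
def test_motif_frame_offsets(primer_map, name, offset):
    assert validate_primer_motif(primer_map[name]) == offset


def test_motif_mismatch_flags_mistranscription():
    bad = _mini("bad", "ATGATG", motif="KK")
    with pytest.raises(MotifMismatchError):
        validate_primer_motif(bad)


# -- binding sites ------------------------------------------------------------

def test_exact_concrete_site():
    p = _mini("p", "ACGTACGTAC")
    template = "T" * 10 + "ACGTACGTAC" + "G" * 80
    sites = find_binding_sites(p, template, max_mismatch=0)
    assert [(s.start, s.end, s.strand, s.mismatches) for s in sites] == [
        (10, 20, "+", 0)
    ]


def test_degenerate_site_scan_is_exhaustive_and_sorted():
    p = _mini("p", "AYG")
    sites = find_binding_sites(p, "ACGATG")
    assert [(s.start, s.end) for s in sites] == [(0, 3), (3, 6)]


def test_no_sites_on_incompatible_template():
    p = _mini("p", "ACGACG")
    assert find_binding_sites(p, "T" * 50) == []
    assert find_binding_sites(p, "ACG") == []  # shorter than the primer


def test_reverse_primer_binds_as_reverse_complement():
    rev = _mini("r", "TTCAT", direction="reverse")
    # rc(TTCAT) = ATGAA embedded on the plus strand
    sites = find_binding_sites(rev, "CCCCATGAACCCC")
    assert [(s.start, s.end, s.strand) for s in sites] == [(4, 9, "-")]


def test_three_prime_mismatch_disqualifies():
    p = _mini("p", "ACGTACGTAC")
    template = "T" * 10 + "ACGTACGTAG" + "G" * 40  # mismatch at primer 3' end
    assert find_binding_sites(p, template, max_mismatch=1) == []
    relaxed = find_binding_sites(p, template, max_mismatch=1,
                                 require_3prime_match=False)
    assert len(relaxed) == 1 and relaxed[0].mismatches == 1


# -- in-silico PCR -------------------------------------------------------------

def test_amplicon_span_arithmetic():
    fwd = _mini("f", "ACGTACGTAC")
    rev = _mini("r", "GGGGGAAAAA", direction="reverse")
    insert = "CT" * 40
    template = "T" * 10 + "ACGTACGTAC" + insert + "TTTTTCCCCC" + "A" * 7
    amps = in_silico_pcr(fwd, rev, template, min_len=80, max_len=165)
    assert len(amps) == 1
    amp = amps[0]
    assert (amp.start, amp.end, len(amp)) == (10, 110, 100)
    assert amp.sequence == template[10:110]


def test_pcr_requires_forward_reverse_order():
    fwd = _mini("f", "ACGTACGTAC")
    rev = _mini("r", "GGGGGAAAAA", direction="reverse")
    with pytest.raises(ValueError):
        in_silico_pcr(rev, fwd, "ACGT" * 50)


def test_no_downstream_reverse_site_means_no_product():
    fwd = _mini("f", "ACGTACGTAC")
    rev = _mini("r", "GGGGGAAAAA", direction="reverse")
    template = "TTTTTCCCCC" + "CT" * 40 + "ACGTACGTAC"  # reverse site upstream
    assert in_silico_pcr(fwd, rev, template) == []


def test_pcr_invariant_under_template_prefix(primer_map):
    root = root_homeoboxes()["B4"]
    f, r = primer_map["HoxF1"], primer_map["HoxR1"]
    base = in_silico_pcr(f, r, root, "B4")
    shifted = in_silico_pcr(f, r, "TTGATCCA" + root, "B4")
    assert len(base) == len(shifted) == 1
    assert shifted[0].start - base[0].start == 8
    assert shifted[0].sequence == base[0].sequence


def test_roots_reproduce_exact_table_product_lengths(primer_map):
    """Primer pairs whose nominal sizes are geometrically exact on the roots."""
    roots = root_homeoboxes()
    expect = {
        ("HoxF1S", "HoxR1", "A1"): 149,
        ("HoxF2S", "HoxR1", "B2"): 152,
        ("HoxF3S", "HoxR1", "C3"): 149,
        ("HoxF3S1", "HoxR1", "D3"): 80,
        ("HoxF4S", "HoxR1", "A4"): 152,
        ("HoxF7S", "HoxR1", "A6"): 149,
        ("HoxF8S", "HoxR1", "C8"): 116,
        ("HoxF9S", "HoxR1", "D9"): 116,
        ("HoxF9", "HoxR1", "A9"): 164,
        ("HoxF10S", "HoxR1", "B10"): 155,
        ("HoxF11", "HoxR1", "C11"): 122,
        ("HoxF12", "HoxR1", "D12"): 164,
        ("HoxF12C", "HoxR1", "C12"): 149,
        ("HoxF12D", "HoxR1", "D12"): 149,
        ("HoxF13A", "HoxR13", "A13"): 164,
        ("HoxF13A1", "HoxR13", "A13"): 128,
        ("HoxF13B", "HoxR13", "B13"): 164,
        ("HoxF13B1", "HoxR13", "C13"): 128,
        ("HoxF13A", "HoxR14", "A14"): 89,
        ("HoxFC5", "HoxR1", "C5"): 161,
    }
    for (fn, rn, gene), pl in expect.items():
        amps = in_silico_pcr(primer_map[fn], primer_map[rn], roots[gene], gene)
        assert [len(a) for a in amps] == [pl], (fn, rn, gene)


# -- tiered survey -------------------------------------------------------------

@pytest.fixture(scope="module")
def pg5_pool():
    cfg = SimulationConfig()
    return make_templates("t", ["A5", "B5", "C5", "A1"], cfg, seed=3)


def test_tiered_survey_escalates_to_member_specific_for_c5(primers, pg5_pool):
    report = tiered_survey(primers, pg5_pool)
    detected = report.detected()
    assert detected["t|A1"] == "general"
    assert detected["t|A5"] == "general"
    assert detected["t|B5"] == "general"
    # C5 evades the general and PG-specific primers; only HoxFC5 finds it
    assert detected["t|C5"] == "member_specific"
    assert any(e["action"] == "escalate" and e["pg"] == 5 for e in report.events)


def test_tiered_survey_general_only_world(primers):
    cfg = SimulationConfig()
    pool = make_templates("t", ["A1", "B2", "A4"], cfg, seed=3)
    report = tiered_survey(primers, pool)
    assert set(report.detected().values()) == {"general"}


def test_tiered_survey_empty_pool_reports_nothing_detected(primers):
    report = tiered_survey(primers, [])
    assert report.detected() == {}
    assert all(row["tier"] is None for row in report.rows)


def test_tiered_survey_requires_primers():
    with pytest.raises(ValueError):
        tiered_survey([], [])


def test_pairing_uses_targets_and_explicit_notes(primers):
    pairs = {(f.name, r.name) for f, r in pair_primers(primers)}
    assert ("HoxF1", "HoxR1") in pairs
    assert ("HoxF13A", "HoxR14") in pairs        # explicit pairing note
    assert ("HoxF13A", "HoxR1") not in pairs     # PG13 is outside HoxR1's range
    assert ("HoxF1", "HoxR13") not in pairs
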