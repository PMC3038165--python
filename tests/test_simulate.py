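"""The synthetic world: determinism, evolution calibration, library anatomy."""

import numpy as np
import pytest

from hoxsurvey.clones import collapse_clones, filter_library
from hoxsurvey.distances import k2p_distance
from hoxsurvey.inventory import (
    GeneSet,
    REPORTED_DELTAS,
    PresenceMatrix,
    build_inventory,
)
from hoxsurvey.primers import in_silico_pcr
from hoxsurvey.seq import translate
from hoxsurvey.simulate import (
    GroundTruth,
    SimulationConfig,
    anchored_positions,
    evolve_panel,
    evolve_sequence,
    filter_metrics,
    make_templates,
    recovery_report,
    root_homeoboxes,
    root_proteins,
    simulate_library,
    simulate_taxon_libraries,
)


def test_roots_are_valid_and_distinct():
    roots = root_homeoboxes()
    prots = root_proteins()
    assert len(roots) == 44  # 43 genes + outgroup
    for gene, nt in roots.items():
        assert len(nt) == 180
        assert translate(nt, 0) == prots[gene]
        assert "*" not in prots[gene]
    genes = [g for g in roots if g != "OUT"]
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            diffs = sum(x != y for x, y in zip(roots[a], roots[b]))
            assert diffs >= 5, (a, b, diffs)


def test_roots_are_deterministic_constants():
    a = root_homeoboxes()["C5"]
    root_homeoboxes.cache_clear()
    assert root_homeoboxes()["C5"] == a


def test_zero_rate_panel_equals_roots():
    panel = evolve_panel(guide_tree="((sp1:0,sp2:0):0,sp3:0);", seed=9)
    roots = root_homeoboxes()
    for e in panel.entries:
        assert e.nuc == roots[e.gene]


def test_same_seed_same_panel(tmp_path):
    p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
    evolve_panel(seed=7).to_fasta(p1)
    evolve_panel(seed=7).to_fasta(p2)
    assert p1.read_bytes() == p2.read_bytes()
    evolve_panel(seed=8).to_fasta(p2)
    assert p1.read_bytes() != p2.read_bytes()


def test_k2p_process_distance_consistency():
    """Observed K2P distance tracks the simulated branch length (outgroup
    root: no frozen anchor positions to dilute the signal)."""
    root = root_homeoboxes()["OUT"]
    d_true = 0.2
    rng = np.random.default_rng(17)
    est = [
        k2p_distance(root, evolve_sequence(root, d_true, 2.0, rng), d_max=5.0)
        for _ in range(60)
    ]
    assert np.mean(est) == pytest.approx(d_true, abs=0.03)


def test_frozen_anchor_positions_never_change():
    root = root_homeoboxes()["A9"]
    frozen = anchored_positions("A9")
    rng = np.random.default_rng(3)
    out = evolve_sequence(root, 0.5, 2.0, rng, frozen)
    assert all(out[i] == root[i] for i in frozen)
    assert out != root


def test_make_templates_bijective_with_inventory():
    cfg = SimulationConfig()
    assert make_templates("t", [], cfg, seed=1) == []
    lungfish = build_inventory("lungfish", *REPORTED_DELTAS["lungfish"]).genes
    tpls = make_templates("lungfish", lungfish, cfg, seed=1)
    assert len(tpls) == 42
    assert {tid.split("|")[1] for tid, _ in tpls} == set(lungfish)
    with pytest.raises(ValueError):
        make_templates("t", ["Z9"], cfg, seed=1)


def _one_library(cfg, seed=2, genes=("A1", "B1", "C1")):
    from hoxsurvey.primers import load_primer_table

    ps = {p.name: p for p in load_primer_table()}
    templates = make_templates("t", genes, cfg, seed=seed)
    rng = np.random.default_rng(seed)
    return simulate_library(ps["HoxF1"], ps["HoxR1"], "t", templates, cfg, rng)


def test_library_all_faithful_without_noise():
    cfg = SimulationConfig(p_allele=0.0, p_error=0.0)
    clones, frame, truth = _one_library(cfg)
    assert set(truth.clone_provenance.values()) == {"faithful"}
    assert frame == 2  # HoxF1 anchors mid-codon
    assert len({c.sequence for c in clones}) == 3


def test_library_allele_probability_one_gives_linked_pairs():
    cfg = SimulationConfig(p_allele=1.0, p_error=0.0)
    clones, frame, truth = _one_library(cfg)
    frags = collapse_clones(clones, frame_offset=frame)
    assert len(frags) == 6  # two haplotypes per gene
    assert all(f.clone_count >= 2 for f in frags)
    res = filter_library(frags)
    assert res.locus_count == 3
    kinds = {k for _, k in truth.fragment_truth.values()}
    assert kinds == {"faithful", "allelic"}


def test_collapse_matches_generator_bookkeeping():
    cfg = SimulationConfig()
    clones, frame, truth = _one_library(cfg, seed=6)
    frags = collapse_clones(clones, frame_offset=frame)
    assert len(frags) == len(truth.fragment_truth)
    assert sum(f.clone_count for f in frags) == len(clones)


def test_all_clone_lengths_within_survey_window():
    from hoxsurvey.primers import load_primer_table

    cfg = SimulationConfig()
    inv = build_inventory("lungfish", *REPORTED_DELTAS["lungfish"]).genes
    libraries, _ = simulate_taxon_libraries(
        "lungfish", inv, load_primer_table(), cfg, seed=4
    )
    lengths = {len(c.sequence) for clones, _ in libraries.values() for c in clones}
    assert lengths and min(lengths) >= 80 and max(lengths) <= 165


def test_single_tier_world_misses_c5():
    from hoxsurvey.primers import load_primer_table

    primers = load_primer_table()
    inv = ("A5", "B5", "C5")
    general_only, truth_g = simulate_taxon_libraries(
        "t", inv, primers, SimulationConfig(tiers=("general",)), seed=5
    )
    full, truth_f = simulate_taxon_libraries(
        "t", inv, primers, SimulationConfig(), seed=5
    )

    def genes_with_fragments(truth):
        return {g for g, _ in truth.fragment_truth.values()}

    assert "C5" not in genes_with_fragments(truth_g)
    assert genes_with_fragments(truth_f) == {"A5", "B5", "C5"}


def test_determinism_of_taxon_libraries():
    from hoxsurvey.primers import load_primer_table

    primers = load_primer_table()
    a, _ = simulate_taxon_libraries("t", ("A1", "A4"), primers, seed=12)
    b, _ = simulate_taxon_libraries("t", ("A1", "A4"), primers, seed=12)
    assert {k: [c.sequence for c in v[0]] for k, v in a.items()} == {
        k: [c.sequence for c in v[0]] for k, v in b.items()
    }


def test_recovery_report_metrics():
    truth = GroundTruth(taxa={"t": frozenset({"A1", "B1"})})
    perfect = PresenceMatrix.from_gene_sets(
        {"t": GeneSet("t", frozenset({"A1", "B1"}))}
    )
    rep = recovery_report(perfect, truth)
    assert rep.loc["t", "accuracy"] == 1.0
    dropped = PresenceMatrix.from_gene_sets(
        {"t": GeneSet("t", frozenset({"A1"}))}
    )
    rep2 = recovery_report(dropped, truth)
    assert rep2.loc["t", "false_absences"] == 1
    assert rep2.loc["t", "accuracy"] == pytest.approx(42 / 43)


def test_filter_metrics_against_provenance():
    cfg = SimulationConfig(p_error=0.15, p_allele=0.2)
    clones, frame, truth = _one_library(cfg, seed=8)
    frags = collapse_clones(clones, frame_offset=frame)
    res = filter_library(frags)
    m = filter_metrics({clones[0].library_id: res}, truth)
    assert m["precision"] == 1.0
    assert m["recall"] >= 0.9


def test_ground_truth_tsv_written(tmp_path):
    from hoxsurvey.simulate import write_ground_truth_tsv

    cfg = SimulationConfig()
    clones, frame, truth = _one_library(cfg, seed=9)
    truth.taxa["t"] = frozenset({"A1", "B1", "C1"})
    p = tmp_path / "truth.tsv"
    write_ground_truth_tsv(p, truth)
    text = p.read_text()
    assert text.startswith("record\tkey\tvalue")
    assert "taxon_inventory\tt\tA1,B1,C1" in text
    assert "\tfaithful" in text or ":faithful" in text
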