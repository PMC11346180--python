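"""Synthetic taxonomy/proteome/PSM generator contracts."""

import io

import numpy as np
import pytest

from micropept.alphabet import STANDARD_AA
from micropept.homology import il_normalize
from micropept.synthetic_data import (
    BASE_AA_FREQ,
    SimSpec,
    TIME_POINTS,
    assign_body_sites,
    human_taxid,
    make_proteomes,
    make_taxonomy,
    planted_phylum_composition,
    simulate_psm_table,
    simulate_timecourse,
    species_taxids,
)
from micropept.taxcount import RANKS


def test_taxonomy_counts_and_ladder():
    spec = SimSpec(seed=0, n_superkingdoms=2, phyla_per_superkingdom=3)
    tree = make_taxonomy(spec)
    by_rank = {}
    for node in tree.nodes.values():
        by_rank.setdefault(node.rank, []).append(node)
    assert len(by_rank["superkingdom"]) == 2
    assert len(by_rank["phylum"]) == 6
    assert len(by_rank["species"]) == 6 * spec.organisms_per_phylum
    # every node's parent carries the next-higher rank
    ladder = ["root"] + RANKS
    for node in tree.nodes.values():
        if node.taxid == tree.root:
            continue
        parent = tree.nodes[node.parent]
        assert ladder.index(parent.rank) == ladder.index(node.rank) - 1


def test_taxonomy_deterministic_serialization(tmp_path):
    spec = SimSpec(seed=5)
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    make_taxonomy(spec).to_tsv(p1)
    make_taxonomy(spec).to_tsv(p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_invalid_spec_counts_raise():
    with pytest.raises(ValueError):
        SimSpec(phyla_per_superkingdom=0)
    with pytest.raises(ValueError):
        SimSpec(protein_length_mean=-10)
    with pytest.raises(ValueError):
        SimSpec(composition_weights={4: 0.5, 5: 0.6})


def test_proteome_counts_and_taxids():
    spec = SimSpec(
        seed=1,
        n_superkingdoms=2,
        phyla_per_superkingdom=2,
        organisms_per_phylum=1,
        proteins_per_organism=10,
        human_proteins=10,
    )
    tree = make_taxonomy(spec)
    entries = make_proteomes(tree, spec)
    assert len(entries) == 4 * 10
    species = set(species_taxids(tree))
    assert {e.taxid for e in entries} == species
    h = human_taxid(tree)
    assert all((e.origin == "human") == (e.taxid == h) for e in entries)


def test_bacterial_leucine_shift_matches_expectation():
    """At ~1e5 bacterial residues the observed Leu fraction is within
    10% relative of the shifted multinomial expectation."""
    shift = {"L": 2.0}
    spec = SimSpec(
        seed=2,
        proteins_per_organism=20,
        protein_length_mean=300,
        aa_frequency_shift=shift,
    )
    tree = make_taxonomy(spec)
    entries = [e for e in make_proteomes(tree, spec) if e.origin == "microbiota"]
    residues = "".join(e.sequence for e in entries)
    assert len(residues) > 1e5
    expected = (
        BASE_AA_FREQ["L"] * 2.0
        / sum(BASE_AA_FREQ[aa] * shift.get(aa, 1.0) for aa in STANDARD_AA)
    )
    observed = residues.count("L") / len(residues)
    assert abs(observed - expected) / expected < 0.10


def test_proteomes_deterministic():
    spec = SimSpec(seed=3, proteins_per_organism=5, human_proteins=5)
    tree = make_taxonomy(spec)
    a = make_proteomes(tree, spec)
    b = make_proteomes(tree, spec)
    assert [(e.accession, e.sequence) for e in a] == [
        (e.accession, e.sequence) for e in b
    ]


def test_two_organism_composition_recovery():
    """50/50 weights over two organisms are recovered within 3 points
    at n=5000 microbial spectra."""
    base = SimSpec(seed=4)
    tree = make_taxonomy(base)
    bact = [t for t in species_taxids(tree) if t != human_taxid(tree)]
    orgA, orgB = bact[0], bact[1]
    spec = SimSpec(
        seed=4,
        n_spectra=5000,
        fraction_human=0.0,
        composition_weights={orgA: 0.5, orgB: 0.5},
    )
    proteomes = make_proteomes(tree, spec)
    psm, _dn, truth = simulate_psm_table(proteomes, tree, spec)
    per_spectrum = psm["peptide"].map(truth.source_taxid)
    share_a = (per_spectrum == orgA).mean()
    assert abs(share_a - 0.5) < 0.03
    comp = planted_phylum_composition(tree, spec)
    assert sum(comp.values()) == pytest.approx(1.0)


def test_lookalike_bookkeeping_and_distance():
    spec = SimSpec(seed=6, n_spectra=800, fraction_human=0.4,
                   fraction_planted_lookalikes=0.1)
    tree = make_taxonomy(spec)
    proteomes = make_proteomes(tree, spec)
    psm, _dn, truth = simulate_psm_table(proteomes, tree, spec)
    look = [p for p, o in truth.origin.items() if o == "lookalike"]
    assert look, "expected some planted look-alikes"
    human_norm = [
        il_normalize(e.sequence) for e in proteomes if e.origin == "human"
    ]

    def min_hamming(pep):
        q = il_normalize(pep)
        best = len(q)
        for seq in human_norm:
            for s in range(len(seq) - len(q) + 1):
                d = sum(1 for x, y in zip(q, seq[s : s + len(q)]) if x != y)
                best = min(best, d)
        return best

    for pep in look[:25]:
        assert min_hamming(pep) == 1  # mutated copies of human substrings
    # every simulated peptide carries exactly one truth record
    assert set(truth.origin) == set(psm["peptide"])
    assert set(truth.origin) == set(truth.source_taxid)


def test_zero_spectra_yield_empty_tables():
    spec = SimSpec(seed=7, n_spectra=0)
    tree = make_taxonomy(spec)
    proteomes = make_proteomes(tree, spec)
    psm, denovo, truth = simulate_psm_table(proteomes, tree, spec)
    assert psm.empty and denovo.empty and truth.origin == {}


def test_unknown_protease_propagates():
    spec = SimSpec(seed=8, n_spectra=10, protease_name="notaprotease")
    tree = make_taxonomy(spec)
    proteomes = make_proteomes(tree, spec)
    with pytest.raises(KeyError):
        simulate_psm_table(proteomes, tree, spec)


def test_psm_table_deterministic():
    spec = SimSpec(seed=9, n_spectra=300)
    tree = make_taxonomy(spec)
    proteomes = make_proteomes(tree, spec)
    a, da, _ = simulate_psm_table(proteomes, tree, spec)
    b, db, _ = simulate_psm_table(proteomes, tree, spec)
    assert a.equals(b) and da.equals(db)


def test_alc_two_population_pass_rate():
    spec = SimSpec(seed=10, n_spectra=2000, alc_keep_fraction=0.7)
    tree = make_taxonomy(spec)
    proteomes = make_proteomes(tree, spec)
    _psm, denovo, _ = simulate_psm_table(proteomes, tree, spec)
    best = denovo.groupby("spectrum_id")["alc"].max()
    pass_rate = (best >= 80).mean()
    assert abs(pass_rate - 0.7) < 0.05


def test_timecourse_bump_peaks_at_5h():
    spec = SimSpec(seed=11, fraction_human=0.8)
    tree = make_taxonomy(spec)
    proteomes = make_proteomes(tree, spec)
    df, truths = simulate_timecourse(proteomes, tree, spec, spectra_per_timepoint=600)
    counts = {}
    for label in TIME_POINTS:
        sub = df[df["time_label"] == label]
        truth = truths[label]
        counts[label] = sum(truth.origin[p] != "human" for p in sub["peptide"])
    assert max(counts, key=counts.get) == "5h"


def test_body_site_assignment_covers_all_microbes():
    spec = SimSpec(seed=12)
    tree = make_taxonomy(spec)
    sites = assign_body_sites(tree, spec)
    microbes = set(species_taxids(tree)) - {human_taxid(tree)}
    assert set(sites) == microbes
    assert all(1 <= len(v) <= 2 for v in sites.values())
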