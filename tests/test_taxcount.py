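"""LCA resolution, fractional spectral counting and aggregation."""

import pandas as pd
import pytest

from micropept.homology import ProteomeIndex
from micropept.seqdb import ProteinEntry
from micropept.taxcount import (
    ANY_CREATURE,
    RANKS,
    UNASSIGNED,
    DeNovoCandidate,
    TaxNode,
    TaxonCountTable,
    TaxonomyTree,
    aggregate_rank,
    alc_filter,
    body_site_profile,
    lca_level,
    map_occurrences,
    spectral_count_db,
    spectral_count_denovo,
)


@pytest.fixture()
def mini_tree():
    """Two bacterial classes converging at one phylum, plus a human
    lineage in another superkingdom."""
    nodes = [
        TaxNode(1, 1, "root", "root"),
        TaxNode(2, 1, "superkingdom", "Bacteria"),
        TaxNode(3, 2, "phylum", "Proteobacteria"),
        TaxNode(4, 3, "class", "Gammaproteobacteria"),
        TaxNode(5, 4, "order", "Enterobacterales"),
        TaxNode(6, 5, "family", "Enterobacteriaceae"),
        TaxNode(7, 6, "genus", "Escherichia"),
        TaxNode(8, 7, "species", "Escherichia coli"),
        TaxNode(9, 3, "class", "Epsilonproteobacteria"),
        TaxNode(10, 9, "order", "Campylobacterales"),
        TaxNode(11, 10, "family", "Helicobacteraceae"),
        TaxNode(12, 11, "genus", "Helicobacter"),
        TaxNode(13, 12, "species", "Helicobacter pylori"),
        TaxNode(20, 1, "superkingdom", "Eukaryota"),
        TaxNode(21, 20, "phylum", "Chordata"),
        TaxNode(22, 21, "class", "Mammalia"),
        TaxNode(23, 22, "order", "Primates"),
        TaxNode(24, 23, "family", "Hominidae"),
        TaxNode(25, 24, "genus", "Homo"),
        TaxNode(26, 25, "species", "Homo sapiens"),
    ]
    return TaxonomyTree(nodes)


ECOLI, HPYLORI, HUMAN = 8, 13, 26


def test_tree_validation():
    with pytest.raises(ValueError):
        TaxonomyTree([TaxNode(1, 1, "root", "r"), TaxNode(2, 2, "root", "r2")])
    with pytest.raises(ValueError):
        TaxonomyTree([TaxNode(1, 5, "root", "r")])


def test_lca_examples(mini_tree):
    # a single organism resolves at species level
    assert lca_level({ECOLI}, mini_tree) == "species_Escherichia coli"
    # two classes of one phylum converge at the phylum
    assert lca_level({ECOLI, HPYLORI}, mini_tree) == "phylum_Proteobacteria"
    # across superkingdoms no taxonomic level applies
    assert lca_level({HPYLORI, HUMAN}, mini_tree) == ANY_CREATURE


def test_lca_errors(mini_tree):
    with pytest.raises(ValueError):
        lca_level(set(), mini_tree)
    with pytest.raises(KeyError):
        lca_level({999}, mini_tree)


def test_lca_brute_force_oracle_and_monotonicity(rng):
    """LCA agrees with ancestor-path intersection on ~100-node trees and
    never deepens when a taxid is added."""
    from micropept.synthetic_data import SimSpec, make_taxonomy, species_taxids

    spec = SimSpec(seed=7, n_superkingdoms=3, phyla_per_superkingdom=2, organisms_per_phylum=3)
    tree = make_taxonomy(spec)
    assert len(tree) <= 100
    species = species_taxids(tree)

    def brute(taxids):
        common = set(tree.ancestors(taxids[0]))
        for t in taxids[1:]:
            common &= set(tree.ancestors(t))
        return max(common, key=lambda t: len(tree.ancestors(t)))

    depth_of = {t: len(tree.ancestors(t)) for t in tree.nodes}
    for _ in range(50):
        k = int(rng.integers(1, 5))
        taxids = list(rng.choice(species, size=k, replace=False))
        assert tree.lca(taxids) == brute(taxids)
        wider = taxids + [species[int(rng.integers(len(species)))]]
        assert depth_of[tree.lca(wider)] <= depth_of[tree.lca(taxids)]


def test_alc_filter_thresholds():
    def cands(*alcs):
        return [DeNovoCandidate("s", "PEPTIDE", a) for a in alcs]

    assert [c.alc for c in alc_filter(cands(85, 60, 40))] == [85, 60]
    assert alc_filter(cands(79, 50)) == []
    assert [c.alc for c in alc_filter(cands(80))] == [80]  # inclusive
    with pytest.raises(ValueError):
        DeNovoCandidate("s", "PEPTIDE", 101)


def test_map_occurrences_per_protein_dedup():
    proteins = [
        ProteinEntry("A1", "GGPEPTIDEGGPEPTIDEGG", taxid=8),  # twice in one protein
        ProteinEntry("A2", "CCPEPTLDECC", taxid=8),  # I/L-equivalent copy
        ProteinEntry("B1", "TTPEPTIDETT", taxid=13),
    ]
    index = ProteomeIndex(proteins)
    occ = map_occurrences("PEPTIDE", index)
    assert occ == [("A1", 8), ("A2", 8), ("B1", 13)]
    assert map_occurrences("WWWWWWW", index) == []


def test_spectral_count_db_equal_division(mini_tree):
    occ = {"PEPTIDEK": [("A1", ECOLI), ("A2", ECOLI), ("B1", HPYLORI)]}
    psm = pd.DataFrame({"peptide": ["PEPTIDEK"], "spectral_count": [1]})
    table = spectral_count_db(psm, occ, mini_tree)
    assert table.counts[ECOLI] == pytest.approx(2 / 3)
    assert table.counts[HPYLORI] == pytest.approx(1 / 3)
    # linear in the spectral count
    psm3 = pd.DataFrame({"peptide": ["PEPTIDEK"], "spectral_count": [3]})
    table3 = spectral_count_db(psm3, occ, mini_tree)
    assert table3.counts[ECOLI] == pytest.approx(2.0)
    assert table3.counts[HPYLORI] == pytest.approx(1.0)


def test_spectral_count_db_conservation_and_unassigned(mini_tree, rng):
    peptides = [f"PEP{i:04d}" for i in range(40)]
    occ = {}
    for i, pep in enumerate(peptides):
        if i % 5 == 0:
            occ[pep] = []  # unmatched
        else:
            n = int(rng.integers(1, 6))
            occ[pep] = [(f"X{j}", int(rng.choice([ECOLI, HPYLORI, HUMAN]))) for j in range(n)]
    counts = rng.integers(1, 4, size=len(peptides))
    psm = pd.DataFrame({"peptide": peptides, "spectral_count": counts})
    table = spectral_count_db(psm, occ, mini_tree)
    assert table.total() == pytest.approx(float(counts.sum()), abs=1e-9)
    assert UNASSIGNED in table.counts
    with pytest.raises(ValueError):
        spectral_count_db(
            pd.DataFrame({"peptide": ["PEPTIDEK"], "spectral_count": [-1]}),
            occ,
            mini_tree,
        )


def test_spectral_count_denovo_shares(mini_tree):
    cands = {
        "s1": [
            DeNovoCandidate("s1", "CANDAAAA", 90.0),  # 1 occurrence, organism A
            DeNovoCandidate("s1", "CANDBBBB", 70.0),  # 3 occurrences, organism B
        ],
        "s2": [
            DeNovoCandidate("s2", "CANDAAAA", 85.0),
            DeNovoCandidate("s2", "NOMATCHX", 84.0),  # unmatched: not counted
        ],
        "s3": [DeNovoCandidate("s3", "NOMATCHX", 95.0)],  # all unmatched
        "s4": [DeNovoCandidate("s4", "CANDAAAA", 79.0)],  # fails the 80% filter
    }
    occ = {
        "CANDAAAA": [("A1", ECOLI)],
        "CANDBBBB": [("B1", HPYLORI), ("B2", HPYLORI), ("B3", HPYLORI)],
        "NOMATCHX": [],
    }
    table = spectral_count_denovo(cands, occ, mini_tree)
    # s1 splits 4 ways; s2 fully to organism A; s3 unassigned; s4 absent
    assert table.counts[ECOLI] == pytest.approx(0.25 + 1.0)
    assert table.counts[HPYLORI] == pytest.approx(0.75)
    assert table.counts[UNASSIGNED] == pytest.approx(1.0)
    assert table.total() == pytest.approx(3.0, abs=1e-9)


def test_aggregate_rank(mini_tree):
    table = TaxonCountTable()
    table.add(ECOLI, 2.0)
    table.add(HPYLORI, 1.0)
    table.add(ANY_CREATURE, 1.0)
    fractions = aggregate_rank(table, "phylum", mini_tree)
    assert fractions["phylum_Proteobacteria"] == pytest.approx(0.75)
    assert fractions[ANY_CREATURE] == pytest.approx(0.25)
    assert sum(fractions.values()) == pytest.approx(1.0, abs=1e-9)
    with pytest.raises(ValueError):
        aggregate_rank(table, "domain", mini_tree)
    with pytest.raises(ValueError):
        aggregate_rank(TaxonCountTable(), "phylum", mini_tree)


def test_aggregate_rank_above_rank_keeps_own_label(mini_tree):
    table = TaxonCountTable()
    table.add(2, 1.0)  # a superkingdom-level assignment
    table.add(ECOLI, 1.0)
    fractions = aggregate_rank(table, "phylum", mini_tree)
    assert fractions["superkingdom_Bacteria"] == pytest.approx(0.5)
    assert fractions["phylum_Proteobacteria"] == pytest.approx(0.5)


def test_body_site_profile():
    annotation = {1: {"gastrointestinal_tract"}, 2: {"oral", "skin"}}
    profile = body_site_profile({1: 3.0}, annotation)
    assert profile == {"gastrointestinal_tract": 100.0}
    profile = body_site_profile({2: 1.0}, annotation)
    assert profile["oral"] == pytest.approx(50.0)
    assert profile["skin"] == pytest.approx(50.0)
    profile = body_site_profile({1: 1.0, 99: 1.0}, annotation)
    assert profile["unknown"] == pytest.approx(50.0)
    assert sum(profile.values()) == pytest.approx(100.0, abs=1e-6)
    with pytest.raises(ValueError):
        body_site_profile({1: -1.0}, annotation)


def test_taxonomy_tsv_roundtrip(mini_tree, tmp_path):
    path = tmp_path / "tax.tsv"
    mini_tree.to_tsv(path)
    back = TaxonomyTree.from_tsv(path)
    assert back.nodes == mini_tree.nodes
    assert [back.nodes[t].rank for t in back.ancestors(ECOLI)] == ["root"] + RANKS
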