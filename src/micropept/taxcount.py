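"""Taxonomic attribution and fractional spectral counting.

A spectrum interpreted as a peptide occurring in proteins of several
organisms is attributed to the deepest taxonomy node ancestral to all
of them (the lowest common ancestor); a set spanning more than one
superkingdom cannot be attributed at any level and is labeled
"any creature".  For abundance estimation each spectral count is split
in equal proportions among all protein occurrences of its peptide and
the shares are summed per organism, so the total of any count table
(including "unassigned") equals the number of counted spectra.

De novo candidate interpretations pass the two-threshold confidence
filter first: a spectrum is used only when its best candidate reaches
ALC >= 80, and within such a spectrum only candidates with ALC >= 50
are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .homology import ProteomeIndex, find_matches

__all__ = [
    "RANKS",
    "TaxNode",
    "TaxonomyTree",
    "TaxonCountTable",
    "DeNovoCandidate",
    "ANY_CREATURE",
    "UNASSIGNED",
    "map_occurrences",
    "lca_level",
    "spectral_count_db",
    "spectral_count_denovo",
    "alc_filter",
    "aggregate_rank",
    "body_site_profile",
]

#: rank ladder from the most to the least inclusive
RANKS = ["superkingdom", "phylum", "class", "order", "family", "genus", "species"]
_RANK_DEPTH = {r: i for i, r in enumerate(RANKS)}

ANY_CREATURE = "any creature"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class TaxNode:
    taxid: int
    parent: int  # parent taxid; the root points at itself
    rank: str  # "root" or one of RANKS
    name: str


class TaxonomyTree:
    """Rank-laddered taxonomy supporting ancestor and LCA queries."""

    def __init__(self, nodes: Iterable[TaxNode]):
        self.nodes: dict[int, TaxNode] = {n.taxid: n for n in nodes}
        roots = [n for n in self.nodes.values() if n.parent == n.taxid]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {len(roots)}")
        self.root = roots[0].taxid
        for n in self.nodes.values():
            if n.parent not in self.nodes:
                raise ValueError(f"node {n.taxid} has unknown parent {n.parent}")

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def ancestors(self, taxid: int) -> list[int]:
        """Path of taxids from the root down to (and including) taxid."""
        if taxid not in self.nodes:
            raise KeyError(f"unknown taxid {taxid}")
        path = [taxid]
        while taxid != self.root:
            taxid = self.nodes[taxid].parent
            path.append(taxid)
        return path[::-1]

    def ancestor_at_rank(self, taxid: int, rank: str) -> int | None:
        """Ancestor (or self) of ``taxid`` at exactly ``rank``; None if
        the lineage skips that rank or sits entirely above it."""
        for anc in self.ancestors(taxid):
            if self.nodes[anc].rank == rank:
                return anc
        return None

    def lca(self, taxids: Iterable[int]) -> int:
        """Deepest node ancestral to every taxid in the set."""
        taxids = list(taxids)
        if not taxids:
            raise ValueError("empty taxid set")
        paths = [self.ancestors(t) for t in taxids]
        lca = self.root
        for level in range(min(len(p) for p in paths)):
            step = {p[level] for p in paths}
            if len(step) == 1:
                lca = step.pop()
            else:
                break
        return lca

    def label(self, taxid: int) -> str:
        n = self.nodes[taxid]
        return f"{n.rank}_{n.name}"

    # -- TSV dialect: taxid, parent_taxid, rank, name --------------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyTree":
        nodes = []
        with open(path) as fh:
            fh.readline()  # header
            for line in fh:
                taxid, parent, rank, name = line.rstrip("\n").split("\t")
                nodes.append(TaxNode(int(taxid), int(parent), rank, name))
        return cls(nodes)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("taxid\tparent_taxid\trank\tname\n")
            for taxid in sorted(self.nodes):
                n = self.nodes[taxid]
                fh.write(f"{n.taxid}\t{n.parent}\t{n.rank}\t{n.name}\n")


@dataclass
class TaxonCountTable:
    """Fractional spectral counts keyed by species taxid, with the
    sentinels "any creature" and "unassigned" as string keys."""

    counts: dict[int | str, float] = field(default_factory=dict)

    def add(self, key: int | str, value: float) -> None:
        if value < 0:
            raise ValueError("counts must be >= 0")
        self.counts[key] = self.counts.get(key, 0.0) + value

    def total(self) -> float:
        return sum(self.counts.values())

    def to_dataframe(self, tree: TaxonomyTree | None = None) -> pd.DataFrame:
        rows = []
        for key, value in sorted(self.counts.items(), key=lambda kv: str(kv[0])):
            if isinstance(key, int) and tree is not None:
                node = tree.nodes[key]
                rows.append((tree.label(key), node.rank, value))
            else:
                rows.append((str(key), "", value))
        return pd.DataFrame(rows, columns=["label", "rank", "fractional_count"])


@dataclass(frozen=True)
class DeNovoCandidate:
    """A de novo interpretation of one spectrum with its ALC confidence."""

    spectrum_id: str
    sequence: str
    alc: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alc <= 100.0:
            raise ValueError(f"ALC must be in [0, 100], got {self.alc}")


def map_occurrences(peptide: str, index: ProteomeIndex) -> list[tuple[str, int]]:
    """Distinct proteins containing the I/L-equivalent peptide as a
    substring; multiple hits inside one protein count once.

    Returns (accession, taxid) pairs; an unmatched peptide gives [].
    """
    acc_to_taxid = dict(zip(index.accessions, index.taxids))
    seen: dict[str, int] = {}
    for accession, _pos, _mm in find_matches(peptide, index, max_mismatch=0):
        seen.setdefault(accession, acc_to_taxid[accession])
    return sorted(seen.items())


def lca_level(taxids: Iterable[int], tree: TaxonomyTree) -> str:
    """Taxon label of the LCA; "any creature" when the set spans more
    than one superkingdom (LCA at or above the root)."""
    taxids = set(taxids)
    if not taxids:
        raise ValueError("empty taxid set")
    node = tree.lca(taxids)
    if node == tree.root or tree.nodes[node].rank == "root":
        return ANY_CREATURE
    return tree.label(node)


def alc_filter(
    candidates: Sequence[DeNovoCandidate],
    spectrum_threshold: float = 80.0,
    candidate_threshold: float = 50.0,
) -> list[DeNovoCandidate]:
    """Keep a spectrum's candidates only if the best reaches
    ``spectrum_threshold`` ("not lower than" — inclusive), then retain
    candidates at or above ``candidate_threshold``."""
    for c in candidates:
        if not 0.0 <= c.alc <= 100.0:
            raise ValueError(f"ALC out of range: {c.alc}")
    if not candidates or max(c.alc for c in candidates) < spectrum_threshold:
        return []
    return [c for c in candidates if c.alc >= candidate_threshold]


def spectral_count_db(
    psm_table: pd.DataFrame,
    occurrences: Mapping[str, Sequence[tuple[str, int]]],
    tree: TaxonomyTree,
) -> TaxonCountTable:
    """Equal-division fractional counting of database-search PSMs.

    ``psm_table`` needs columns ``peptide`` and ``spectral_count``;
    ``occurrences`` maps each peptide to its (accession, taxid) protein
    occurrence list.  Each spectral count is split equally across the
    peptide's occurrences and summed per organism taxid; peptides with
    no occurrences accrue to "unassigned".
    """
    table = TaxonCountTable()
    for peptide, count in zip(psm_table["peptide"], psm_table["spectral_count"]):
        if count < 0:
            raise ValueError(f"negative spectral count for {peptide!r}")
        occ = occurrences.get(peptide, [])
        if not occ:
            table.add(UNASSIGNED, float(count))
            continue
        share = float(count) / len(occ)
        for _accession, taxid in occ:
            table.add(taxid, share)
    return table


def spectral_count_denovo(
    candidates_by_spectrum: Mapping[str, Sequence[DeNovoCandidate]],
    occurrences: Mapping[str, Sequence[tuple[str, int]]],
    tree: TaxonomyTree,
) -> TaxonCountTable:
    """Equal-division counting for de novo interpretations: each spectrum
    contributes one count split equally over the pooled occurrences of
    all its (ALC-filtered) candidates; candidates with no occurrences
    are dropped, and spectra left without any matched candidate go to
    "unassigned"."""
    table = TaxonCountTable()
    for spectrum_id in sorted(candidates_by_spectrum):
        retained = alc_filter(list(candidates_by_spectrum[spectrum_id]))
        pooled: list[tuple[str, int]] = []
        for cand in retained:
            pooled.extend(occurrences.get(cand.sequence, []))
        if not retained:
            continue  # spectrum fails the 80% filter: excluded entirely
        if not pooled:
            table.add(UNASSIGNED, 1.0)
            continue
        share = 1.0 / len(pooled)
        for _accession, taxid in pooled:
            table.add(taxid, share)
    return table


def aggregate_rank(
    counts: TaxonCountTable, rank: str, tree: TaxonomyTree
) -> dict[str, float]:
    """Roll fractional counts up to ``rank`` and normalize to fractions.

    Counts assigned at or below the rank roll up to their ancestor at
    that rank; counts assigned above it (and the sentinels) are reported
    under their own labels.  A lineage that skips the rank inherits the
    nearest annotated ancestor's label with a rank-gap marker.
    """
    if rank not in _RANK_DEPTH:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    if not counts.counts:
        raise ValueError("empty count table")
    depth = _RANK_DEPTH[rank]
    out: dict[str, float] = {}
    for key, value in counts.counts.items():
        if isinstance(key, str):
            label = key
        else:
            node = tree.nodes[key]
            node_depth = _RANK_DEPTH.get(node.rank, -1)
            if node_depth < depth:
                label = tree.label(key)  # assigned above the target rank
            else:
                anc = tree.ancestor_at_rank(key, rank)
                if anc is None:
                    # incomplete lineage: nearest annotated ancestor
                    above = [
                        a
                        for a in tree.ancestors(key)
                        if _RANK_DEPTH.get(tree.nodes[a].rank, -1) <= depth
                        and tree.nodes[a].rank in _RANK_DEPTH
                    ]
                    label = (tree.label(above[-1]) if above else ANY_CREATURE) + " (rank-gap)"
                else:
                    label = tree.label(anc)
        out[label] = out.get(label, 0.0) + value
    total = sum(out.values())
    return {label: value / total for label, value in out.items()}


def body_site_profile(
    organism_counts: Mapping[int, float],
    site_annotation: Mapping[int, set[str] | Sequence[str]],
) -> dict[str, float]:
    """Percentage profile over isolation body sites.

    Each organism's count is divided equally among its annotated sites;
    organisms missing from the annotation accrue to "unknown".
    """
    shares: dict[str, float] = {}
    for taxid, count in organism_counts.items():
        if count < 0:
            raise ValueError("counts must be >= 0")
        sites = sorted(site_annotation.get(taxid, []))
        if not sites:
            shares["unknown"] = shares.get("unknown", 0.0) + count
            continue
        per_site = count / len(sites)
        for site in sites:
            shares[site] = shares.get(site, 0.0) + per_site
    total = sum(shares.values())
    if total == 0:
        return {site: 0.0 for site in shares}
    return {site: 100.0 * value / total for site, value in shares.items()}


def read_site_annotation(path: str | Path) -> dict[int, set[str]]:
    """Site annotation TSV (taxid, site), one row per pair."""
    out: dict[int, set[str]] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            taxid, site = line.rstrip("\n").split("\t")
            out.setdefault(int(taxid), set()).add(site)
    return out


def write_count_table(
    counts: TaxonCountTable, tree: TaxonomyTree, path: str | Path
) -> None:
    df = counts.to_dataframe(tree)
    total = counts.total()
    df["fraction"] = df["fractional_count"] / total if total else 0.0
    df.to_csv(path, sep="\t", index=False)
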