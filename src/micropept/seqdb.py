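"""Protein sequence databases: FASTA I/O, 90%-identity redundancy
collapse, and construction of the combined human+microbiota database.

The redundancy collapse is a desk-scale greedy incremental clustering in
the style of CD-HIT/UniRef90: entries are processed longest-first and
join the first existing representative they share >= ``threshold``
identity with, where identity is the number of matched positions of the
best global alignment divided by the length of the *shorter* sequence.
A shared-5-mer prefilter skips hopeless alignments. Ambiguity codes
(B/J/X/Z/U) are accepted on input but never count as matched positions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import EXTENDED_AA, STANDARD_AA, validate_sequence

__all__ = [
    "ProteinEntry",
    "ClusterSet",
    "pairwise_identity",
    "cluster_by_identity",
    "build_combined_db",
    "read_fasta",
    "write_fasta",
    "read_manifest",
    "write_manifest",
]


@dataclass(frozen=True)
class ProteinEntry:
    """One accessioned protein sequence with taxonomic origin."""

    accession: str
    sequence: str
    taxid: int = 0
    organism_name: str = ""
    origin: str = "microbiota"  # "human" or "microbiota"

    def __post_init__(self) -> None:
        validate_sequence(self.sequence)
        if self.origin not in ("human", "microbiota"):
            raise ValueError(f"origin must be human|microbiota, got {self.origin!r}")


@dataclass
class ClusterSet:
    """Result of greedy identity clustering: representative entries plus
    a membership map from every input accession to its representative."""

    representatives: list[ProteinEntry]
    membership: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.representatives)


def _match_count_aligner() -> PairwiseAligner:
    # global alignment maximizing the count of identical standard-residue
    # positions: match=1, mismatch=0, gaps free.  Ambiguity codes score 0
    # against everything, including themselves.
    aligner = PairwiseAligner()
    aligner.mode = "global"
    matrix = substitution_matrices.Array(EXTENDED_AA, dims=2)
    for aa in STANDARD_AA:
        matrix[aa, aa] = 1.0
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = 0.0
    aligner.extend_gap_score = 0.0
    return aligner


_ALIGNER = _match_count_aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of the shorter sequence matched in the best global
    alignment of ``a`` and ``b`` (match=1, mismatch=0, free gaps)."""
    validate_sequence(a)
    validate_sequence(b)
    matches = _ALIGNER.score(a, b)
    return float(matches) / min(len(a), len(b))


def _kmers(seq: str, k: int = 5) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def cluster_by_identity(
    entries: Sequence[ProteinEntry], threshold: float = 0.9
) -> ClusterSet:
    """Greedy incremental clustering at ``threshold`` identity.

    Entries are sorted by decreasing length (ties by accession) and each
    joins the first representative with identity >= threshold, else
    becomes a new representative.  Empty input yields an empty set.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    ordered = sorted(entries, key=lambda e: (-len(e.sequence), e.accession))
    reps: list[ProteinEntry] = []
    rep_kmers: list[set[str]] = []
    membership: dict[str, str] = {}
    for entry in ordered:
        km = _kmers(entry.sequence)
        assigned = False
        for rep, rk in zip(reps, rep_kmers):
            # shared-5-mer prefilter; sequences too short for a 5-mer
            # are always aligned
            if km and rk and not (km & rk):
                continue
            if pairwise_identity(entry.sequence, rep.sequence) >= threshold:
                membership[entry.accession] = rep.accession
                assigned = True
                break
        if not assigned:
            reps.append(entry)
            rep_kmers.append(km)
            membership[entry.accession] = entry.accession
    return ClusterSet(representatives=reps, membership=membership)


def build_combined_db(
    human: Sequence[ProteinEntry], microbiota_reps: Sequence[ProteinEntry]
) -> list[ProteinEntry]:
    """Concatenate the human database and the collapsed microbiota
    representatives into one search database, preserving origin tags.

    Raises on any accession shared between the two inputs.
    """
    seen: set[str] = set()
    for entry in itertools.chain(human, microbiota_reps):
        if entry.accession in seen:
            raise ValueError(f"duplicate accession across databases: {entry.accession!r}")
        seen.add(entry.accession)
    return list(human) + list(microbiota_reps)


# --- FASTA / manifest I/O ------------------------------------------------

def _parse_header(record: SeqRecord) -> tuple[str, int, str]:
    """Header dialect ``accession|taxid|organism`` for simulated data;
    a bare accession is accepted for real databases."""
    parts = record.description.split("|")
    if len(parts) >= 3 and parts[1].strip().isdigit():
        return parts[0].strip(), int(parts[1]), parts[2].strip()
    return record.id, 0, ""


def read_fasta(path: str | Path, origin: str = "microbiota") -> list[ProteinEntry]:
    """Read a protein FASTA (wrapped lines tolerated) into entries with
    the given origin tag."""
    entries = []
    for record in SeqIO.parse(str(path), "fasta"):
        accession, taxid, organism = _parse_header(record)
        entries.append(
            ProteinEntry(
                accession=accession,
                sequence=str(record.seq).upper(),
                taxid=taxid,
                organism_name=organism,
                origin=origin,
            )
        )
    return entries


def write_fasta(entries: Iterable[ProteinEntry], path: str | Path) -> None:
    records = [
        SeqRecord(
            Seq(e.sequence),
            id=f"{e.accession}|{e.taxid}|{e.organism_name or e.origin}",
            description="",
        )
        for e in entries
    ]
    SeqIO.write(records, str(path), "fasta")


def write_manifest(entries: Iterable[ProteinEntry], path: str | Path) -> None:
    """Database manifest TSV: accession, origin, taxid."""
    with open(path, "w") as fh:
        fh.write("accession\torigin\ttaxid\n")
        for e in entries:
            fh.write(f"{e.accession}\t{e.origin}\t{e.taxid}\n")


def read_manifest(path: str | Path) -> dict[str, tuple[str, int]]:
    out: dict[str, tuple[str, int]] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            accession, origin, taxid = line.rstrip("\n").split("\t")
            out[accession] = (origin, int(taxid))
    return out
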