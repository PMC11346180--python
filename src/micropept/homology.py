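"""Origin assignment and single-substitution homology filtering.

Leucine and isoleucine are isobaric and indistinguishable under the CID
fragmentation used for blood peptidome identification, so all matching
here runs on I/L-normalized strings (every I, and the I/L ambiguity
code J, rewritten to L).  A peptide identified against the microbiota
database that also matches the human proteome exactly is re-assigned to
the human origin; a microbiota peptide within one substitution of any
human protein window (a possible single amino acid polymorphism, SAP)
is removed from the analysis.

The one-mismatch search uses the pigeonhole split: a window at Hamming
distance <= 1 from the query must contain one of the query's two halves
exactly, so candidate windows are located by exact substring search on
the halves over a separator-delimited concatenation of the indexed
proteome and verified by direct Hamming comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .alphabet import validate_sequence
from .seqdb import ProteinEntry

__all__ = [
    "PeptideRecord",
    "ProteomeIndex",
    "il_normalize",
    "find_matches",
    "classify_origin",
    "filter_sap_homologs",
    "MIN_PEPTIDE_LENGTH",
]

MIN_PEPTIDE_LENGTH = 5

_IL_TABLE = str.maketrans({"I": "L", "J": "L"})

_SEPARATOR = "#"


@dataclass
class PeptideRecord:
    """An identified peptide with its sample, spectral count and origin."""

    sequence: str
    sample_id: str = ""
    spectral_count: int = 1
    origin: str = "unmatched"  # human | microbiota | unmatched
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        validate_sequence(self.sequence)
        if len(self.sequence) < MIN_PEPTIDE_LENGTH:
            raise ValueError(
                f"peptide {self.sequence!r} shorter than the "
                f"{MIN_PEPTIDE_LENGTH}-residue identification floor"
            )
        if self.spectral_count < 0:
            raise ValueError("spectral_count must be >= 0")


def il_normalize(seq: str) -> str:
    """Rewrite I (and the I/L code J) to L; idempotent, length-preserving."""
    validate_sequence(seq)
    return seq.translate(_IL_TABLE)


class ProteomeIndex:
    """Substring index over the I/L-normalized sequences of a proteome,
    supporting exact and one-mismatch (Hamming) peptide queries."""

    def __init__(self, entries: Sequence[ProteinEntry], origin: str | None = None):
        self.origin = origin if origin is not None else (
            entries[0].origin if entries else ""
        )
        self.accessions: list[str] = []
        self.taxids: list[int] = []
        starts: list[int] = []
        chunks: list[str] = []
        pos = 0
        for e in entries:
            norm = il_normalize(e.sequence)
            self.accessions.append(e.accession)
            self.taxids.append(e.taxid)
            starts.append(pos)
            chunks.append(norm)
            pos += len(norm) + 1  # +1 for separator
        self._starts = starts
        self._lengths = [len(c) for c in chunks]
        self._text = _SEPARATOR.join(chunks)

    def __len__(self) -> int:
        return len(self.accessions)

    def _locate(self, text_pos: int) -> int:
        """Index of the protein whose span contains ``text_pos``
        (bisect over start offsets)."""
        import bisect

        i = bisect.bisect_right(self._starts, text_pos) - 1
        return i

    def _find_all(self, pattern: str) -> Iterable[int]:
        """All (overlapping) occurrences of ``pattern`` in the text."""
        if not pattern:
            return
        start = self._text.find(pattern)
        while start != -1:
            yield start
            start = self._text.find(pattern, start + 1)

    def candidate_windows(self, query: str) -> Iterable[tuple[int, int]]:
        """(protein index, 0-based window start) pairs whose window could
        be within Hamming distance 1 of ``query`` (pigeonhole on halves)."""
        L = len(query)
        half = L // 2
        seen: set[tuple[int, int]] = set()
        for pattern, offset in ((query[:half], 0), (query[half:], half)):
            for pos in self._find_all(pattern):
                wstart = pos - offset
                if wstart < 0:
                    continue
                prot = self._locate(wstart)
                local = wstart - self._starts[prot]
                if local < 0 or local + L > self._lengths[prot]:
                    continue  # window crosses a protein boundary
                seen.add((prot, local))
        return sorted(seen)

    def window(self, prot: int, local_start: int, length: int) -> str:
        s = self._starts[prot] + local_start
        return self._text[s : s + length]


def _hamming_le(a: str, b: str, limit: int) -> int | None:
    """Hamming distance of equal-length strings if <= limit, else None."""
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return None
    return d


def find_matches(
    peptide: str, index: ProteomeIndex, max_mismatch: int = 0
) -> list[tuple[str, int, int]]:
    """All windows of the indexed proteome equal to the I/L-normalized
    peptide up to ``max_mismatch`` (0 or 1) substitutions.

    Returns (accession, 1-based start position, n_mismatch) tuples.
    """
    if max_mismatch not in (0, 1):
        raise ValueError(f"max_mismatch must be 0 or 1, got {max_mismatch}")
    query = il_normalize(peptide)
    if len(query) < MIN_PEPTIDE_LENGTH:
        raise ValueError(
            f"peptide must have >= {MIN_PEPTIDE_LENGTH} residues, got {len(query)}"
        )
    hits: list[tuple[str, int, int]] = []
    if max_mismatch == 0:
        L = len(query)
        for pos in index._find_all(query):
            prot = index._locate(pos)
            local = pos - index._starts[prot]
            if local + L <= index._lengths[prot]:
                hits.append((index.accessions[prot], local + 1, 0))
        return hits
    for prot, local in index.candidate_windows(query):
        window = index.window(prot, local, len(query))
        d = _hamming_le(query, window, 1)
        if d is not None:
            hits.append((index.accessions[prot], local + 1, d))
    return hits


def classify_origin(
    peptide: str, human_index: ProteomeIndex, microbiota_index: ProteomeIndex
) -> str:
    """Human if the peptide matches the human proteome exactly (I/L
    equivalent) — regardless of microbiota hits; else microbiota on an
    exact microbiota hit; else unmatched."""
    if find_matches(peptide, human_index, max_mismatch=0):
        return "human"
    if find_matches(peptide, microbiota_index, max_mismatch=0):
        return "microbiota"
    return "unmatched"


def filter_sap_homologs(
    microbiota_peptides: Sequence[PeptideRecord], human_index: ProteomeIndex
) -> tuple[list[PeptideRecord], list[PeptideRecord]]:
    """Partition microbiota-assigned peptides into (retained, removed):
    a record within one substitution of any human protein window (under
    I/L equivalence) is removed and flagged ``sap_homolog``."""
    retained: list[PeptideRecord] = []
    removed: list[PeptideRecord] = []
    for record in microbiota_peptides:
        if record.origin != "microbiota":
            raise ValueError(
                f"filter_sap_homologs expects microbiota records, got origin "
                f"{record.origin!r} for {record.sequence!r}"
            )
        if find_matches(record.sequence, human_index, max_mismatch=1):
            record.flags.add("sap_homolog")
            removed.append(record)
        else:
            retained.append(record)
    return retained, removed


def write_peptide_tsv(
    records: Iterable[PeptideRecord], path, removal_reason: str = ""
) -> None:
    """Peptide table TSV with a removal_reason column ('' if retained)."""
    with open(path, "w") as fh:
        fh.write("sequence\tsample_id\tspectral_count\torigin\tremoval_reason\n")
        for r in records:
            reason = removal_reason if removal_reason else (
                "sap_homolog" if "sap_homolog" in r.flags else ""
            )
            fh.write(
                f"{r.sequence}\t{r.sample_id}\t{r.spectral_count}\t{r.origin}\t{reason}\n"
            )
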