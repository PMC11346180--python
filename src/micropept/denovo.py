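"""De novo taxonomic attribution over a bounded reference database.

Each spectrum's de novo candidate list passes the ALC 80/50 filter,
candidates are matched (I/L-equivalent, exact) against the reference
proteins, and the spectrum's unit count — split in equal proportions
over the pooled occurrences of all retained candidates — accrues to the
taxon label at which the matched organisms converge (their lowest
common ancestor), or to "any creature" when they span superkingdoms.
Spectra passing the confidence filter but matching nothing are reported
as "unassigned"; spectra failing the 80% filter leave the denominator
entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .homology import ProteomeIndex
from .taxcount import (
    UNASSIGNED,
    DeNovoCandidate,
    TaxonomyTree,
    alc_filter,
    lca_level,
    map_occurrences,
)

__all__ = ["AttributionReport", "attribute_denovo", "candidates_from_table"]


@dataclass
class AttributionReport:
    """Per-label spectrum fractions for the de novo counting mode."""

    fractions: dict[str, float]
    n_effective_spectra: int
    counting_mode: str = "de_novo"

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (label, frac, self.n_effective_spectra)
            for label, frac in sorted(self.fractions.items(), key=lambda kv: -kv[1])
        ]
        return pd.DataFrame(rows, columns=["label", "fraction", "n_effective_spectra"])


def candidates_from_table(table: pd.DataFrame) -> dict[str, list[DeNovoCandidate]]:
    """Group a de novo TSV table (spectrum_id, candidate_seq, alc) by
    spectrum."""
    out: dict[str, list[DeNovoCandidate]] = {}
    for spectrum_id, seq, alc in zip(
        table["spectrum_id"], table["candidate_seq"], table["alc"]
    ):
        out.setdefault(str(spectrum_id), []).append(
            DeNovoCandidate(str(spectrum_id), str(seq), float(alc))
        )
    return out


def attribute_denovo(
    candidates_by_spectrum: Mapping[str, Sequence[DeNovoCandidate]],
    reference_index: ProteomeIndex,
    tree: TaxonomyTree,
) -> AttributionReport:
    """Attribute each ALC-passing spectrum to the LCA of the organisms
    matched by its retained candidates; normalize to label fractions."""
    if not candidates_by_spectrum:
        raise ValueError("empty candidate table")
    occurrence_cache: dict[str, list[tuple[str, int]]] = {}
    label_counts: dict[str, float] = {}
    n_effective = 0
    for spectrum_id in sorted(candidates_by_spectrum):
        retained = alc_filter(list(candidates_by_spectrum[spectrum_id]))
        if not retained:
            continue  # fails the 80% spectrum filter: out of denominator
        taxids: set[int] = set()
        n_matched = 0
        for cand in retained:
            if cand.sequence not in occurrence_cache:
                occurrence_cache[cand.sequence] = map_occurrences(
                    cand.sequence, reference_index
                )
            occ = occurrence_cache[cand.sequence]
            if occ:
                n_matched += 1
                taxids.update(taxid for _acc, taxid in occ)
        n_effective += 1
        if not taxids:
            label = UNASSIGNED
        else:
            label = lca_level(taxids, tree)
        label_counts[label] = label_counts.get(label, 0.0) + 1.0
    if n_effective == 0:
        raise ValueError("no spectrum passed the ALC filter")
    fractions = {label: c / n_effective for label, c in label_counts.items()}
    return AttributionReport(fractions=fractions, n_effective_spectra=n_effective)
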