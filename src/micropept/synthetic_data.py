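"""Synthetic taxonomies, proteomes and identification tables.

The generator emulates the statistical structure of blood peptidome
identification data against a combined human+microbiota database:

* a rank-laddered taxonomy (superkingdom ... species) holding one human
  organism and a configurable grid of microbial organisms;
* per-organism proteomes whose bacterial residue frequencies are
  shifted toward Ala/Cys/Ile/Leu and away from His/Arg/Lys/Ser/Gln,
  reproducing the hydrophobicity and composition contrast observed
  between bacterial and human blood peptides;
* a PSM table in which each spectrum draws an organism (human with
  probability ``fraction_human``, else by ``composition_weights``), a
  protein, and a protease-consistent peptide of 7-25 residues (0-1
  missed cleavages); a configurable fraction of the microbial spectra
  are planted "look-alikes" — single-substitution mutants of human
  protein fragments that the SAP homology filter must remove;
* de novo candidate lists whose ALC confidences come from a
  two-population (kept vs discarded) truncated-normal model so the
  80/50 thresholds have known expected pass rates;
* a meal time-course in which the bacterial spectrum rate peaks at the
  5-h time point.

Every output is a pure function of the SimSpec, including its seed; all
draws flow from numpy's PCG64 ``default_rng`` seeded per stage from the
run seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import STANDARD_AA
from .cleavage import digest, get_rule
from .seqdb import ProteinEntry, write_fasta
from .taxcount import RANKS, TaxNode, TaxonomyTree

__all__ = [
    "SimSpec",
    "GroundTruth",
    "make_taxonomy",
    "make_proteomes",
    "simulate_psm_table",
    "simulate_timecourse",
    "assign_body_sites",
    "species_taxids",
    "human_taxid",
    "planted_phylum_composition",
    "write_proteomes",
    "write_site_annotation",
    "TIMECOURSE_BUMP",
    "HUMAN_NAME",
    "BASE_AA_FREQ",
    "DEFAULT_AA_SHIFT",
    "TIME_POINTS",
]

HUMAN_NAME = "Homo sapiens"

#: background residue frequencies (approximate vertebrate proteome)
BASE_AA_FREQ = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}

#: default bacterial frequency multipliers: more Ala/Cys/Ile/Leu, less
#: His/Arg/Lys/Ser/Gln — the composition contrast the study reports
DEFAULT_AA_SHIFT = {
    "A": 1.5, "C": 1.3, "I": 1.4, "L": 1.4,
    "H": 0.7, "R": 0.6, "K": 0.7, "S": 0.8, "Q": 0.8,
}

TIME_POINTS = ("pre-meal", "3h", "5h", "7h", "9h")

#: bacterial-rate multiplier per time point: the abundance bump peaks 5 h
#: after the meal
TIMECOURSE_BUMP = {"pre-meal": 1.0, "3h": 1.3, "5h": 2.0, "7h": 1.5, "9h": 1.1}

_BODY_SITES = (
    "gastrointestinal_tract",
    "oral",
    "skin",
    "airways",
    "urogenital_tract",
)

_PHYLUM_NAMES = {
    "Bacteria": ["Proteobacteria", "Firmicutes", "Actinobacteria", "Bacteroidetes"],
    "Eukaryota": ["Chordata"],
}


@dataclass(frozen=True)
class SimSpec:
    """Study conditions for one simulated dataset."""

    seed: int = 0
    n_superkingdoms: int = 2
    phyla_per_superkingdom: int = 4
    organisms_per_phylum: int = 3
    proteins_per_organism: int = 30
    protein_length_mean: int = 300
    composition_weights: Mapping[int, float] | None = None  # taxid -> prob
    n_spectra: int = 5000
    protease_name: str = "trypsin"
    fraction_human: float = 0.93
    fraction_planted_lookalikes: float = 0.0
    aa_frequency_shift: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AA_SHIFT)
    )
    peptide_length_range: tuple[int, int] = (7, 25)
    alc_keep_fraction: float = 0.8
    human_proteins: int = 60
    human_protein_length_mean: int = 400
    #: human blood peptides are endogenous exopeptidase products with no
    #: single protease signature; bacterial peptides carry the termini of
    #: the named protease.  Set False to digest human proteins too.
    human_random_termini: bool = True

    def __post_init__(self) -> None:
        for name in (
            "n_superkingdoms",
            "phyla_per_superkingdom",
            "organisms_per_phylum",
            "proteins_per_organism",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.protein_length_mean <= 0 or self.human_protein_length_mean <= 0:
            raise ValueError("protein length means must be > 0")
        if self.n_spectra < 0:
            raise ValueError("n_spectra must be >= 0")
        for name in ("fraction_human", "fraction_planted_lookalikes", "alc_keep_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.composition_weights is not None:
            total = sum(self.composition_weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"composition_weights must sum to 1 (got {total})"
                )
            if any(w < 0 for w in self.composition_weights.values()):
                raise ValueError("composition weights must be >= 0")


@dataclass
class GroundTruth:
    """Truth labels for a simulated PSM table: one record per distinct
    simulated peptide, plus the planted phylum composition."""

    origin: dict[str, str] = field(default_factory=dict)  # human|microbiota|lookalike
    source_taxid: dict[str, int] = field(default_factory=dict)
    planted_composition: dict[str, float] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("peptide\ttrue_origin\tsource_taxid\n")
            for pep in sorted(self.origin):
                fh.write(f"{pep}\t{self.origin[pep]}\t{self.source_taxid[pep]}\n")


def _rng(spec: SimSpec, stage: int) -> np.random.Generator:
    return np.random.default_rng([stage, spec.seed])


def make_taxonomy(spec: SimSpec) -> TaxonomyTree:
    """Deterministic rank-laddered taxonomy.

    The first superkingdom is "Eukaryota" and its first species is Homo
    sapiens; the second is "Bacteria" with microbiota-style phylum
    names.  Every species sits under its own class/order/family/genus
    chain so that two species of one phylum converge at the phylum.
    """
    nodes = [TaxNode(1, 1, "root", "root")]
    next_id = 2
    for sk in range(spec.n_superkingdoms):
        sk_name = (
            "Eukaryota" if sk == 0 else "Bacteria" if sk == 1 else f"Superkingdom{sk + 1}"
        )
        sk_id = next_id
        next_id += 1
        nodes.append(TaxNode(sk_id, 1, "superkingdom", sk_name))
        stock = _PHYLUM_NAMES.get(sk_name, [])
        for ph in range(spec.phyla_per_superkingdom):
            ph_name = stock[ph] if ph < len(stock) else f"{sk_name}_phylum{ph + 1}"
            ph_id = next_id
            next_id += 1
            nodes.append(TaxNode(ph_id, sk_id, "phylum", ph_name))
            for org in range(spec.organisms_per_phylum):
                human = sk == 0 and ph == 0 and org == 0
                base = f"{ph_name} org{org + 1}"
                parent = ph_id
                for rank in RANKS[2:]:
                    name = (
                        HUMAN_NAME
                        if human and rank == "species"
                        else f"{base} {rank}"
                    )
                    node_id = next_id
                    next_id += 1
                    nodes.append(TaxNode(node_id, parent, rank, name))
                    parent = node_id
    return TaxonomyTree(nodes)


def species_taxids(tree: TaxonomyTree) -> list[int]:
    return sorted(t for t, n in tree.nodes.items() if n.rank == "species")


def human_taxid(tree: TaxonomyTree) -> int:
    for taxid, node in tree.nodes.items():
        if node.rank == "species" and node.name == HUMAN_NAME:
            return taxid
    raise ValueError("taxonomy has no human species")


def _frequencies(shift: Mapping[str, float] | None) -> np.ndarray:
    freq = np.array([BASE_AA_FREQ[aa] for aa in STANDARD_AA])
    if shift:
        mult = np.array([shift.get(aa, 1.0) for aa in STANDARD_AA])
        freq = freq * mult
    return freq / freq.sum()


def _random_protein(rng: np.random.Generator, mean_len: int, freq: np.ndarray) -> str:
    length = max(50, int(rng.normal(mean_len, mean_len * 0.15)))
    letters = rng.choice(list(STANDARD_AA), size=length, p=freq)
    return "".join(letters)


def make_proteomes(tree: TaxonomyTree, spec: SimSpec) -> list[ProteinEntry]:
    """Per-species random proteomes; bacterial organisms draw residues
    from the shifted frequencies, the human organism from the base."""
    if len(tree) == 0:
        raise ValueError("empty taxonomy")
    rng = _rng(spec, 1)
    base = _frequencies(None)
    shifted = _frequencies(spec.aa_frequency_shift)
    h_taxid = human_taxid(tree)
    entries: list[ProteinEntry] = []
    for taxid in species_taxids(tree):
        is_human = taxid == h_taxid
        n_prot = spec.human_proteins if is_human else spec.proteins_per_organism
        mean_len = (
            spec.human_protein_length_mean if is_human else spec.protein_length_mean
        )
        freq = base if is_human else shifted
        name = tree.nodes[taxid].name
        for k in range(n_prot):
            entries.append(
                ProteinEntry(
                    accession=f"T{taxid}_P{k + 1:03d}",
                    sequence=_random_protein(rng, mean_len, freq),
                    taxid=taxid,
                    organism_name=name,
                    origin="human" if is_human else "microbiota",
                )
            )
    return entries


def _microbial_weights(
    tree: TaxonomyTree, spec: SimSpec
) -> tuple[list[int], np.ndarray]:
    h = human_taxid(tree)
    if spec.composition_weights is not None:
        taxids = sorted(spec.composition_weights)
        weights = np.array([spec.composition_weights[t] for t in taxids])
        if h in taxids:
            raise ValueError("composition_weights must not include the human organism")
    else:
        taxids = [t for t in species_taxids(tree) if t != h]
        weights = np.ones(len(taxids))
    return taxids, weights / weights.sum()


def planted_phylum_composition(tree: TaxonomyTree, spec: SimSpec) -> dict[str, float]:
    """Expected phylum shares among microbial spectra given the
    composition weights."""
    taxids, weights = _microbial_weights(tree, spec)
    out: dict[str, float] = {}
    for taxid, w in zip(taxids, weights):
        anc = tree.ancestor_at_rank(taxid, "phylum")
        label = tree.label(anc)
        out[label] = out.get(label, 0.0) + float(w)
    return out


def _digest_peptides(protein: str, rule, length_range) -> list[str]:
    peps = digest(protein, rule, missed_cleavages=1, length_range=length_range)
    return peps


def _mutate_one(rng: np.random.Generator, peptide: str) -> str:
    """One substitution that also changes the I/L-normalized string."""
    pos = int(rng.integers(len(peptide)))
    old = peptide[pos]
    forbidden = {old} | ({"I", "L"} if old in "IL" else set())
    choices = [aa for aa in STANDARD_AA if aa not in forbidden]
    new = choices[int(rng.integers(len(choices)))]
    return peptide[:pos] + new + peptide[pos + 1 :]


def simulate_psm_table(
    proteomes: Sequence[ProteinEntry],
    tree: TaxonomyTree,
    spec: SimSpec,
    *,
    _stage: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a PSM table, a de novo candidate table and truth labels.

    Returns (psm_table, denovo_table, ground_truth); see the module
    docstring for the sampling scheme.
    """
    rule = get_rule(spec.protease_name)
    rng = _rng(spec, _stage)
    h = human_taxid(tree)
    by_taxid: dict[int, list[ProteinEntry]] = {}
    for e in proteomes:
        by_taxid.setdefault(e.taxid, []).append(e)
    taxids, weights = _microbial_weights(tree, spec)
    for t in taxids:
        if weights[list(taxids).index(t)] > 0 and t not in by_taxid:
            raise ValueError(f"no proteome for weighted organism taxid {t}")
    digests: dict[str, list[str]] = {}

    def _substring(sequence: str) -> str:
        lo, hi = spec.peptide_length_range
        n = int(rng.integers(lo, min(hi, len(sequence)) + 1))
        start = int(rng.integers(0, len(sequence) - n + 1))
        return sequence[start : start + n]

    def peptides_of(entry: ProteinEntry) -> list[str]:
        if entry.accession not in digests:
            peps = _digest_peptides(entry.sequence, rule, spec.peptide_length_range)
            if not peps:
                peps = [_substring(entry.sequence)]
            digests[entry.accession] = peps
        return digests[entry.accession]

    def human_peptide(entry: ProteinEntry) -> str:
        if spec.human_random_termini:
            return _substring(entry.sequence)
        peps = peptides_of(entry)
        return peps[int(rng.integers(len(peps)))]

    truth = GroundTruth(planted_composition=planted_phylum_composition(tree, spec))
    psm_rows = []
    denovo_rows = []
    human_pool = by_taxid.get(h, [])
    for i in range(spec.n_spectra):
        spectrum_id = f"S{i:06d}"
        is_human = bool(rng.random() < spec.fraction_human) and bool(human_pool)
        if is_human:
            entry = human_pool[int(rng.integers(len(human_pool)))]
            peptide = human_peptide(entry)
            origin, source = "human", h
        else:
            taxid = taxids[int(rng.choice(len(taxids), p=weights))]
            if rng.random() < spec.fraction_planted_lookalikes and human_pool:
                src = human_pool[int(rng.integers(len(human_pool)))]
                peptide = _mutate_one(rng, human_peptide(src))
                origin, source = "lookalike", taxid
            else:
                entry = by_taxid[taxid][int(rng.integers(len(by_taxid[taxid])))]
                peps = peptides_of(entry)
                peptide = peps[int(rng.integers(len(peps)))]
                origin, source = "microbiota", taxid
        truth.origin.setdefault(peptide, origin)
        truth.source_taxid.setdefault(peptide, source)
        psm_rows.append(("sample01", spectrum_id, peptide, 1))

        # de novo candidates: the true interpretation plus 0-2 mutated
        # alternatives; best-candidate ALC from the kept population with
        # probability alc_keep_fraction, else from the discarded one
        if rng.random() < spec.alc_keep_fraction:
            best_alc = float(np.clip(rng.normal(90.0, 5.0), 80.0, 100.0))
        else:
            best_alc = float(np.clip(rng.normal(60.0, 12.0), 0.0, 79.9))
        denovo_rows.append((spectrum_id, peptide, round(best_alc, 1)))
        for _ in range(int(rng.integers(0, 3))):
            alt = _mutate_one(rng, peptide)
            alc = float(np.clip(rng.normal(60.0, 15.0), 0.0, min(best_alc, 99.0)))
            denovo_rows.append((spectrum_id, alt, round(alc, 1)))

    psm = pd.DataFrame(
        psm_rows, columns=["sample_id", "spectrum_id", "peptide", "spectral_count"]
    )
    denovo = pd.DataFrame(denovo_rows, columns=["spectrum_id", "candidate_seq", "alc"])
    return psm, denovo, truth


def simulate_timecourse(
    proteomes: Sequence[ProteinEntry],
    tree: TaxonomyTree,
    spec: SimSpec,
    spectra_per_timepoint: int | None = None,
    bump: Mapping[str, float] = TIMECOURSE_BUMP,
) -> tuple[pd.DataFrame, dict[str, GroundTruth]]:
    """Meal time-course: one PSM table per time point with the bacterial
    spectrum rate scaled by ``bump`` (peaking at 5 h), concatenated with
    a ``time_label`` column."""
    n = spectra_per_timepoint if spectra_per_timepoint is not None else spec.n_spectra
    base_bacterial = 1.0 - spec.fraction_human
    frames = []
    truths: dict[str, GroundTruth] = {}
    for k, label in enumerate(TIME_POINTS):
        frac_bact = min(0.95, base_bacterial * bump[label])
        sub = replace(spec, n_spectra=n, fraction_human=1.0 - frac_bact)
        psm, _denovo, truth = simulate_psm_table(proteomes, tree, sub, _stage=10 + k)
        psm = psm.copy()
        psm["time_label"] = label
        psm["sample_id"] = f"donor_{label}"
        frames.append(psm)
        truths[label] = truth
    return pd.concat(frames, ignore_index=True), truths


def assign_body_sites(tree: TaxonomyTree, spec: SimSpec) -> dict[int, set[str]]:
    """Annotate each microbial species with 1-2 isolation body sites."""
    rng = _rng(spec, 3)
    h = human_taxid(tree)
    out: dict[int, set[str]] = {}
    for taxid in species_taxids(tree):
        if taxid == h:
            continue
        n_sites = 1 + int(rng.random() < 0.3)
        sites = rng.choice(len(_BODY_SITES), size=n_sites, replace=False)
        out[taxid] = {_BODY_SITES[int(s)] for s in sites}
    return out


# --- writers -------------------------------------------------------------

def write_proteomes(
    proteomes: Sequence[ProteinEntry], outdir: str | Path
) -> list[Path]:
    """One FASTA per organism, header ``accession|taxid|organism``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    by_taxid: dict[int, list[ProteinEntry]] = {}
    for e in proteomes:
        by_taxid.setdefault(e.taxid, []).append(e)
    for taxid in sorted(by_taxid):
        path = outdir / f"taxid{taxid}.fasta"
        write_fasta(by_taxid[taxid], path)
        paths.append(path)
    return paths


def write_site_annotation(annotation: Mapping[int, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("taxid\tsite\n")
        for taxid in sorted(annotation):
            for site in sorted(annotation[taxid]):
                fh.write(f"{taxid}\t{site}\n")
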