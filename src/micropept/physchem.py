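"""Peptide physicochemical descriptors and group-comparison statistics.

Descriptor panel: length, GRAVY (mean Kyte-Doolittle hydropathy),
aliphatic index (Ikai), aromaticity (F/W/Y fraction), polar-residue
fraction, net charge at a stated pH (Henderson-Hasselbalch over the
termini and the D/E/C/Y/H/K/R side chains with an EMBOSS-style pKa
table), isoelectric point (bisection on the monotone net charge),
Boman index (mean residue water->cyclohexane transfer free energy,
sign chosen so higher values mean higher protein-binding potential),
and mean side-chain bulk (Zamyatnin residue volumes, A^3).

Group comparisons between bacterial- and human-origin peptides use the
Wilcoxon rank-sum test with continuity correction (tie-corrected normal
approximation) and Benjamini-Hochberg adjustment across the panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .alphabet import STANDARD_AA, validate_sequence

__all__ = [
    "DescriptorRecord",
    "GroupComparison",
    "compute_descriptors",
    "descriptor_table",
    "net_charge",
    "isoelectric_point",
    "wilcoxon_ranksum",
    "compare_groups",
    "compare_aa_composition",
    "DESCRIPTOR_NAMES",
]

# EMBOSS-style pKa table (documented package default; the side chains
# D, E, C, Y deprotonate to -1, H, K, R protonate to +1)
PKA = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "D": 3.9,
    "E": 4.1,
    "C": 8.5,
    "Y": 10.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
}
_ACIDIC = ("D", "E", "C", "Y")
_BASIC = ("H", "K", "R")

#: polar residue set (configurable through the module constant)
POLAR_RESIDUES = frozenset("NQSTYCDEKRH")

#: Boman residue values, kcal/mol (Radzicka & Wolfenden water->cyclohexane
#: transfer free energies as used by the Boman protein-interaction index;
#: P has no published value in this scale and contributes 0)
BOMAN_SCALE = {
    "A": 1.81, "C": 1.28, "D": -8.72, "E": -6.81, "F": 2.98,
    "G": 0.94, "H": -4.66, "I": 4.92, "K": -5.55, "L": 4.92,
    "M": 2.35, "N": -6.64, "P": 0.0, "Q": -5.54, "R": -14.92,
    "S": -3.40, "T": -2.57, "V": 4.04, "W": 2.33, "Y": -0.14,
}

#: Zamyatnin (1972) residue volumes, cubic angstroms
RESIDUE_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

DESCRIPTOR_NAMES = [
    "length",
    "gravy",
    "aliphatic_index",
    "aromaticity",
    "polarity_fraction",
    "net_charge",
    "pi",
    "boman_index",
    "side_chain_bulk",
]


@dataclass(frozen=True)
class DescriptorRecord:
    length: int
    gravy: float
    aliphatic_index: float
    aromaticity: float
    polarity_fraction: float
    net_charge: float
    pi: float
    boman_index: float
    side_chain_bulk: float


def net_charge(seq: str, pH: float = 7.0) -> float:
    """Henderson-Hasselbalch net charge over the termini and ionizable
    side chains; monotone nonincreasing in pH."""
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH must be in [0, 14], got {pH}")
    validate_sequence(seq, allow_ambiguous=False)
    pos = 1.0 / (1.0 + 10.0 ** (pH - PKA["Nterm"]))
    neg = -1.0 / (1.0 + 10.0 ** (PKA["Cterm"] - pH))
    for aa in seq:
        if aa in _ACIDIC:
            neg -= 1.0 / (1.0 + 10.0 ** (PKA[aa] - pH))
        elif aa in _BASIC:
            pos += 1.0 / (1.0 + 10.0 ** (pH - PKA[aa]))
    return pos + neg


def isoelectric_point(seq: str, tol: float = 1e-4) -> float:
    """pH where the net charge vanishes, by bisection on [0, 14]."""
    lo, hi = 0.0, 14.0
    # net charge is positive at pH 0 and negative at pH 14 for any
    # peptide (the termini alone guarantee the sign change)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        charge = net_charge(seq, mid)
        if abs(charge) < tol:
            return mid
        if charge > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def compute_descriptors(seq: str, pH: float = 7.0) -> DescriptorRecord:
    """Full descriptor panel for one peptide; all values are
    order-invariant functions of the residue multiset."""
    validate_sequence(seq, allow_ambiguous=False)
    n = len(seq)
    counts = {aa: seq.count(aa) for aa in STANDARD_AA}
    gravy = sum(KYTE_DOOLITTLE[aa] * c for aa, c in counts.items()) / n
    # Ikai aliphatic index on mole percent: X_A + 2.9 X_V + 3.9 (X_I + X_L)
    aliphatic = 100.0 * (
        counts["A"] / n + 2.9 * counts["V"] / n + 3.9 * (counts["I"] + counts["L"]) / n
    )
    aromaticity = (counts["F"] + counts["W"] + counts["Y"]) / n
    polarity = sum(c for aa, c in counts.items() if aa in POLAR_RESIDUES) / n
    boman = -sum(BOMAN_SCALE[aa] * c for aa, c in counts.items()) / n
    bulk = sum(RESIDUE_VOLUME[aa] * c for aa, c in counts.items()) / n
    return DescriptorRecord(
        length=n,
        gravy=gravy,
        aliphatic_index=aliphatic,
        aromaticity=aromaticity,
        polarity_fraction=polarity,
        net_charge=net_charge(seq, pH),
        pi=isoelectric_point(seq),
        boman_index=boman,
        side_chain_bulk=bulk,
    )


def descriptor_table(sequences: Sequence[str], pH: float = 7.0) -> pd.DataFrame:
    """One descriptor row per peptide."""
    rows = []
    for seq in sequences:
        rec = compute_descriptors(seq, pH)
        rows.append({"sequence": seq, **rec.__dict__})
    return pd.DataFrame(rows)


def wilcoxon_ranksum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) test; returns (W, two-sided p)
    where W is the Mann-Whitney statistic of ``x``.

    Small tie-free samples use the exact null distribution; otherwise
    the tie-corrected normal approximation with continuity correction
    is used (the behavior of R's ``wilcox.test``, whose normal branch
    the small-sample exact p agrees with to well under 0.05).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.mannwhitneyu(
        x, y, use_continuity=True, alternative="two-sided", method="auto"
    )
    p = float(res.pvalue)
    if np.isnan(p):  # all observations tied: zero variance, no evidence
        p = 1.0
    return float(res.statistic), p


@dataclass(frozen=True)
class GroupComparison:
    descriptor: str
    median_bacterial: float
    median_human: float
    w_statistic: float
    p: float
    q: float


def _compare_panel(
    bacterial: pd.DataFrame, human: pd.DataFrame, columns: Sequence[str]
) -> list[GroupComparison]:
    stats_rows = []
    for col in columns:
        w, p = wilcoxon_ranksum(bacterial[col].to_numpy(), human[col].to_numpy())
        stats_rows.append((col, float(bacterial[col].median()), float(human[col].median()), w, p))
    qs = multipletests([r[4] for r in stats_rows], method="fdr_bh")[1]
    return [
        GroupComparison(descriptor=c, median_bacterial=mb, median_human=mh,
                        w_statistic=w, p=p, q=float(q))
        for (c, mb, mh, w, p), q in zip(stats_rows, qs)
    ]


def compare_groups(
    bacterial_records: pd.DataFrame,
    human_records: pd.DataFrame,
    descriptors: Sequence[str] | None = None,
) -> list[GroupComparison]:
    """One Wilcoxon test per descriptor between the bacterial and human
    peptide groups, BH-adjusted across the panel."""
    if len(bacterial_records) < 2 or len(human_records) < 2:
        raise ValueError("each group needs >= 2 records")
    descriptors = list(descriptors) if descriptors is not None else DESCRIPTOR_NAMES
    return _compare_panel(bacterial_records, human_records, descriptors)


def aa_composition_table(sequences: Sequence[str]) -> pd.DataFrame:
    """Per-peptide residue fractions for the 20 standard amino acids."""
    rows = []
    for seq in sequences:
        validate_sequence(seq, allow_ambiguous=False)
        n = len(seq)
        rows.append({aa: seq.count(aa) / n for aa in STANDARD_AA})
    return pd.DataFrame(rows)


def compare_aa_composition(
    bacterial_sequences: Sequence[str], human_sequences: Sequence[str]
) -> list[GroupComparison]:
    """Twenty Wilcoxon comparisons of per-peptide residue fractions,
    BH-adjusted."""
    if len(bacterial_sequences) < 2 or len(human_sequences) < 2:
        raise ValueError("each group needs >= 2 sequences")
    b = aa_composition_table(bacterial_sequences)
    h = aa_composition_table(human_sequences)
    return _compare_panel(b, h, list(STANDARD_AA))


def comparisons_to_frame(results: Sequence[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
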