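"""Protease cleavage patterns, in-silico digestion, and enrichment
statistics for proteolysis-site analysis.

The catalogue holds 36 proteolysis patterns (mostly individual
proteases) with Expasy PeptideCutter semantics, the set distributed by
the Bioconductor "cleaver" package.  Each rule is a regular expression
in the cleave-after-match-end convention: a boundary falls immediately
after the end of every match, so e.g. trypsin is ``[KR]`` with a
``(?=[^P])`` lookahead plus the published W-K-P / M-R-P exceptions.

Because peptides circulating in blood are trimmed by exopeptidases, the
enrichment analysis does not score boundaries adjacent to either
terminal residue: a peptide of length L only counts cleavage boundaries
between residues i and i+1 for 2 <= i <= L-2 (1-based).  Peptides of
bacterial vs human origin are then compared by the number with fewer
than two such internal sites, using Fisher's exact test with the
conditional maximum-likelihood odds ratio and its exact 95% CI.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio
from statsmodels.stats.multitest import multipletests

from .alphabet import validate_sequence

__all__ = [
    "CleavageRule",
    "ContingencyResult",
    "RULE_CATALOGUE",
    "get_rule",
    "list_rules",
    "cleavage_boundaries",
    "digest",
    "count_internal_sites",
    "fisher_exact",
    "cleavage_contingency",
    "run_catalogue",
]


@dataclass(frozen=True)
class CleavageRule:
    """A named proteolysis pattern.

    ``regex`` encodes the full positional rule (cleave after match
    end); ``cleave_after`` / ``blocked_by`` summarize the simple core of
    the pattern for documentation and for rules where that summary is
    exact.  ``notes`` records provenance.
    """

    name: str
    regex: str
    cleave_after: frozenset[str] = frozenset()
    blocked_by: frozenset[str] = frozenset()
    notes: str = "Expasy PeptideCutter"

    def boundaries(self, sequence: str) -> list[int]:
        """0-based cut positions p (cut between sequence[p-1] and
        sequence[p]), excluding the trivial ends."""
        L = len(sequence)
        return [
            m.end()
            for m in re.finditer(self.regex, sequence)
            if 0 < m.end() < L
        ]


def _rule(name, regex, after="", blocked="", notes="Expasy PeptideCutter"):
    return CleavageRule(
        name=name,
        regex=regex,
        cleave_after=frozenset(after),
        blocked_by=frozenset(blocked),
        notes=notes,
    )


def _caspase(n: int, regex: str) -> CleavageRule:
    return _rule(f"caspase {n}", regex, after="D", notes="Expasy PeptideCutter")


#: The 36 proteolysis patterns of the PeptideCutter/"cleaver" set.
RULE_CATALOGUE: dict[str, CleavageRule] = {
    r.name: r
    for r in [
        _rule("arg-c", r"R", after="R"),
        _rule("asp-n", r"\w(?=D)", notes="Expasy PeptideCutter; cleaves before D"),
        _rule("bnps-skatole", r"W", after="W"),
        _caspase(1, r"(?<=[FWYL]\w[HAT])D(?=[^PEDQKR])"),
        _caspase(2, r"(?<=DVA)D(?=[^PEDQKR])"),
        _caspase(3, r"(?<=DMQ)D(?=[^PEDQKR])"),
        _caspase(4, r"(?<=LEV)D(?=[^PEDQKR])"),
        _caspase(5, r"(?<=[LW]EH)D"),
        _caspase(6, r"(?<=VE[HI])D(?=[^PEDQKR])"),
        _caspase(7, r"(?<=DEV)D(?=[^PEDQKR])"),
        _caspase(8, r"(?<=[IL]ET)D(?=[^PEDQKR])"),
        _caspase(9, r"(?<=LEH)D"),
        _caspase(10, r"(?<=IEA)D"),
        _rule(
            "chymotrypsin high specificity",
            r"([FY](?=[^P]))|(W(?=[^MP]))",
            after="FYW",
            blocked="P",
        ),
        _rule(
            "chymotrypsin low specificity",
            r"([FLY](?=[^P]))|(W(?=[^MP]))|(M(?=[^PY]))|(H(?=[^DMPW]))",
            after="FLYWMH",
            blocked="P",
        ),
        _rule("clostripain", r"R", after="R"),
        _rule("cnbr", r"M", after="M"),
        _rule("enterokinase", r"(?<=[DE]{3})K", after="K"),
        _rule("factor xa", r"(?<=[AFGILTVM][DE]G)R", after="R"),
        _rule("formic acid", r"D", after="D"),
        _rule("glutamyl endopeptidase", r"E", after="E"),
        _rule("granzyme b", r"(?<=IEP)D", after="D"),
        _rule("hydroxylamine", r"N(?=G)", after="N"),
        _rule("iodosobenzoic acid", r"W", after="W"),
        _rule("lysc", r"K", after="K"),
        _rule("lysn", r"\w(?=K)", notes="Expasy PeptideCutter; cleaves before K"),
        _rule(
            "neutrophil elastase",
            r"[AV]",
            after="AV",
            notes="Expasy PeptideCutter; cleaves after small aliphatic A/V",
        ),
        _rule("ntcb", r"\w(?=C)", notes="Expasy PeptideCutter; cleaves before C"),
        _rule(
            "pepsin ph1.3",
            r"((?<=[^HKR][^P])[^R](?=[FL][^P]))|((?<=[^HKR][^P])[FL](?=\w[^P]))",
            after="FL",
        ),
        _rule(
            "pepsin ph2.0",
            r"((?<=[^HKR][^P])[^R](?=[FLWY][^P]))|((?<=[^HKR][^P])[FLWY](?=\w[^P]))",
            after="FLWY",
        ),
        _rule("proline endopeptidase", r"(?<=[HKR])P(?=[^P])", after="P"),
        _rule("proteinase k", r"[AEFILTVWY]", after="AEFILTVWY"),
        _rule("staphylococcal peptidase i", r"(?<=[^E])E", after="E"),
        _rule("thermolysin", r"[^DE](?=[AFILMV][^P])", notes="Expasy PeptideCutter; cleaves before bulky aliphatics"),
        _rule(
            "thrombin",
            r"((?<=G)R(?=G))|((?<=[AFGILTVM][AFGILTVWA]P)R(?=[^DE][^DE]))",
            after="R",
        ),
        _rule(
            "trypsin",
            r"([KR](?=[^P]))|((?<=W)K(?=P))|((?<=M)R(?=P))",
            after="KR",
            blocked="P",
        ),
    ]
}

assert len(RULE_CATALOGUE) == 36

_ALIASES = {
    "pepsin": "pepsin ph2.0",
    "pepsin ph>2": "pepsin ph2.0",
    "chymotrypsin": "chymotrypsin high specificity",
    "glu-c": "glutamyl endopeptidase",
    "lys-c": "lysc",
    "lys-n": "lysn",
    "arg-c proteinase": "arg-c",
}


def get_rule(name: str) -> CleavageRule:
    """Look up a catalogued rule by (case-insensitive) name or alias."""
    key = name.strip().lower()
    key = _ALIASES.get(key, key)
    try:
        return RULE_CATALOGUE[key]
    except KeyError:
        raise KeyError(
            f"unknown proteolysis pattern {name!r}; available: "
            f"{', '.join(sorted(RULE_CATALOGUE))}"
        ) from None


def list_rules() -> list[str]:
    return sorted(RULE_CATALOGUE)


def cleavage_boundaries(sequence: str, rule: CleavageRule | str) -> list[int]:
    if isinstance(rule, str):
        rule = get_rule(rule)
    validate_sequence(sequence, allow_ambiguous=False)
    return rule.boundaries(sequence)


def digest(
    sequence: str,
    rule: CleavageRule | str,
    missed_cleavages: int = 0,
    length_range: tuple[int, int] | None = None,
) -> list[str]:
    """In-silico digestion: cut at every allowed boundary, keep products
    with up to ``missed_cleavages`` internal boundaries, optionally
    filtered to ``length_range`` (inclusive)."""
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    bounds = [0] + cleavage_boundaries(sequence, rule) + [len(sequence)]
    peptides: list[str] = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + missed_cleavages, len(bounds))):
            pep = sequence[bounds[i] : bounds[j]]
            if length_range is not None:
                lo, hi = length_range
                if not lo <= len(pep) <= hi:
                    continue
            peptides.append(pep)
    return peptides


def count_internal_sites(peptide: str, rule: CleavageRule | str) -> int:
    """Cleavage boundaries strictly internal to the peptide, excluding
    the two boundaries adjacent to the terminal residues (positions
    2 <= i <= L-2, 1-based), since termini are exopeptidase-trimmed."""
    if len(peptide) < 3:
        raise ValueError("peptide must have >= 3 residues")
    L = len(peptide)
    return sum(1 for p in cleavage_boundaries(peptide, rule) if 2 <= p <= L - 2)


@dataclass(frozen=True)
class ContingencyResult:
    """2x2 Fisher exact result with the conditional-MLE odds ratio."""

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float  # conditional MLE; may be inf or nan (degenerate)
    ci95: tuple[float, float]
    p_two_sided: float
    degenerate: bool = False


def fisher_exact(table: Sequence[Sequence[int]]) -> ContingencyResult:
    """Fisher's exact test on a 2x2 table.

    Two-sided p sums central hypergeometric probabilities not exceeding
    that of the observed table; the odds ratio is the conditional
    maximum-likelihood estimate of the noncentral hypergeometric
    parameter with its exact-test-inversion 95% CI.  A table with an
    empty row or column margin is degenerate: p = 1, odds ratio NaN.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            raise ValueError("table entries must be integers")
        arr = arr.astype(int)
    if np.any(arr < 0):
        raise ValueError("table entries must be nonnegative")
    tup = ((int(arr[0, 0]), int(arr[0, 1])), (int(arr[1, 0]), int(arr[1, 1])))
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        return ContingencyResult(
            table=tup,
            odds_ratio=float("nan"),
            ci95=(0.0, float("inf")),
            p_two_sided=1.0,
            degenerate=True,
        )
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    res = _scipy_odds_ratio(arr, kind="conditional")
    ci = res.confidence_interval(confidence_level=0.95)
    or_hat = float(res.statistic)
    if math.isnan(or_hat):
        # conditional MLE diverges when a zero cell fixes the extreme
        # table: report the one-sided limit
        or_hat = float("inf") if arr[0, 0] * arr[1, 1] > 0 or arr[0, 1] == 0 or arr[1, 0] == 0 else 0.0
    return ContingencyResult(
        table=tup,
        odds_ratio=or_hat,
        ci95=(float(ci.low), float(ci.high)),
        p_two_sided=float(p),
    )


def cleavage_contingency(
    bacterial_peptides: Sequence[str],
    human_peptides: Sequence[str],
    rule: CleavageRule | str,
    max_sites: int = 2,
) -> ContingencyResult:
    """Fisher comparison of bacterial vs human peptides with fewer than
    ``max_sites`` internal cleavage sites for ``rule``.

    Rows are (bacterial, human); columns (< max_sites, >= max_sites), so
    an odds ratio > 1 means bacterial peptides are enriched for the
    protease-consistent (few-internal-sites) pattern.
    """
    if not bacterial_peptides or not human_peptides:
        raise ValueError("both peptide groups must be nonempty")
    if isinstance(rule, str):
        rule = get_rule(rule)
    b_low = sum(1 for p in bacterial_peptides if count_internal_sites(p, rule) < max_sites)
    h_low = sum(1 for p in human_peptides if count_internal_sites(p, rule) < max_sites)
    table = [
        [b_low, len(bacterial_peptides) - b_low],
        [h_low, len(human_peptides) - h_low],
    ]
    return fisher_exact(table)


def run_catalogue(
    bacterial_peptides: Sequence[str],
    human_peptides: Sequence[str],
    rules: Iterable[str] | None = None,
    max_sites: int = 2,
) -> pd.DataFrame:
    """Per-rule contingency results over the catalogue with
    Benjamini-Hochberg adjusted p-values."""
    names = sorted(rules) if rules is not None else list_rules()
    rows = []
    for name in names:
        res = cleavage_contingency(bacterial_peptides, human_peptides, name, max_sites)
        (a, b), (c, d) = res.table
        rows.append(
            dict(
                rule=name,
                a=a,
                b=b,
                c=c,
                d=d,
                odds_ratio=res.odds_ratio,
                ci_low=res.ci95[0],
                ci_high=res.ci95[1],
                p=res.p_two_sided,
            )
        )
    df = pd.DataFrame(rows)
    df["p_adjusted"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def write_rule_catalogue(path) -> None:
    """Export the catalogue as a documented TSV."""
    with open(path, "w") as fh:
        fh.write("name\tcleave_after\tblocked_by\tregex\tnotes\n")
        for name in list_rules():
            r = RULE_CATALOGUE[name]
            fh.write(
                f"{name}\t{''.join(sorted(r.cleave_after))}\t"
                f"{''.join(sorted(r.blocked_by))}\t{r.regex}\t{r.notes}\n"
            )
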