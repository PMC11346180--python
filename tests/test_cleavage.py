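"""Protease rule catalogue, digestion, internal-site counting, Fisher."""

import math

import pytest

from micropept.alphabet import STANDARD_AA
from micropept.cleavage import (
    RULE_CATALOGUE,
    cleavage_contingency,
    count_internal_sites,
    digest,
    fisher_exact,
    get_rule,
    list_rules,
    run_catalogue,
)
from micropept.homology import il_normalize


def test_catalogue_holds_36_patterns():
    assert len(RULE_CATALOGUE) == 36
    required = {
        "trypsin", "chymotrypsin high specificity", "pepsin ph1.3", "pepsin ph2.0",
        "asp-n", "lysc", "lysn", "arg-c", "glutamyl endopeptidase",
        "staphylococcal peptidase i", "thermolysin", "proteinase k",
        "enterokinase", "factor xa", "thrombin", "granzyme b",
        "neutrophil elastase", "proline endopeptidase",
    } | {f"caspase {i}" for i in range(1, 11)}
    assert required <= set(list_rules())


def test_get_rule_and_aliases():
    trypsin = get_rule("trypsin")
    assert trypsin.cleave_after == frozenset("KR")
    assert trypsin.blocked_by == frozenset("P")
    assert get_rule("pepsin").name == "pepsin ph2.0"
    assert get_rule("Chymotrypsin").name == "chymotrypsin high specificity"
    with pytest.raises(KeyError, match="trypsin"):  # error lists available rules
        get_rule("notaprotease")


def test_asp_n_cleaves_before_d():
    assert get_rule("asp-n").boundaries("AADAA") == [2]


@pytest.mark.parametrize(
    "seq, missed, expected",
    [
        ("AAKAAARA", 0, ["AAK", "AAAR", "A"]),
        ("AAKAAARA", 1, ["AAK", "AAKAAAR", "AAAR", "AAARA", "A"]),
        ("AKPA", 0, ["AKPA"]),  # K before P is blocked
    ],
)
def test_digest_trypsin(seq, missed, expected):
    assert sorted(digest(seq, "trypsin", missed)) == sorted(expected)


def test_digest_validation():
    with pytest.raises(ValueError):
        digest("", "trypsin", 0)
    with pytest.raises(ValueError):
        digest("AAKA", "trypsin", -1)


def test_digest_reconstructs_sequence(rng):
    for _ in range(20):
        n = int(rng.integers(20, 120))
        seq = "".join(rng.choice(list(STANDARD_AA), size=n))
        rule = list_rules()[int(rng.integers(36))]
        assert "".join(digest(seq, rule, 0)) == seq


def test_digest_matches_pyteomics(rng):
    """Independent cross-check of the digestion machinery against
    pyteomics.parser.cleave using each rule's own regex."""
    from pyteomics import parser as pparser

    for _ in range(10):
        n = int(rng.integers(30, 90))
        seq = "".join(rng.choice(list(STANDARD_AA), size=n))
        for name in ("trypsin", "lysc", "glutamyl endopeptidase", "asp-n",
                     "chymotrypsin high specificity", "pepsin ph2.0"):
            rule = get_rule(name)
            for mc in (0, 1, 2):
                mine = set(digest(seq, rule, mc))
                theirs = set(pparser.cleave(seq, rule.regex, missed_cleavages=mc, regex=True))
                assert mine == theirs, (name, mc, seq)


@pytest.mark.parametrize(
    "pep, expected",
    [
        ("AAKAA", 1),  # boundary after residue 3 is internal
        ("KAAAA", 0),  # boundary after residue 1 is terminal-adjacent
        ("AAKPA", 0),  # blocked by proline
        ("AAKAAKAA", 2),
    ],
)
def test_count_internal_sites(pep, expected):
    assert count_internal_sites(pep, "trypsin") == expected


def test_count_internal_sites_minimum_length():
    with pytest.raises(ValueError):
        count_internal_sites("AK", "trypsin")


def test_il_invariance_for_rules_without_il(rng):
    il_free = [
        "trypsin", "lysc", "lysn", "arg-c", "glutamyl endopeptidase",
        "formic acid", "cnbr", "hydroxylamine", "ntcb",
        "staphylococcal peptidase i", "bnps-skatole", "iodosobenzoic acid",
    ]
    for name in il_free:
        rule = get_rule(name)
        assert not (set("IL") & set(rule.regex))
        for _ in range(5):
            seq = "".join(rng.choice(list(STANDARD_AA), size=30))
            assert rule.boundaries(seq) == rule.boundaries(il_normalize(seq))


# --- Fisher machinery ----------------------------------------------------

def _enumerated_p(a, b, c, d):
    """Two-sided Fisher p by direct enumeration over the fixed margins,
    with hypergeometric probabilities from binomial coefficients."""
    n1, n2, m1 = a + b, c + d, a + c
    N = n1 + n2

    def pmf(x):
        return math.comb(n1, x) * math.comb(n2, m1 - x) / math.comb(N, m1)

    p_obs = pmf(a)
    total = 0.0
    for x in range(max(0, m1 - n2), min(n1, m1) + 1):
        if pmf(x) <= p_obs * (1 + 1e-9):
            total += pmf(x)
    return min(total, 1.0)


def test_fisher_exact_examples():
    res = fisher_exact([[10, 10], [10, 10]])
    assert res.odds_ratio == pytest.approx(1.0)
    assert res.p_two_sided == pytest.approx(1.0)
    res = fisher_exact([[5, 0], [0, 5]])
    assert res.p_two_sided == pytest.approx(2 / 252)  # 2 x C(5,5)C(5,0)/C(10,5)
    assert math.isinf(res.odds_ratio)
    res = fisher_exact([[0, 0], [1, 1]])
    assert res.degenerate and res.p_two_sided == 1.0 and math.isnan(res.odds_ratio)


def test_fisher_exact_validation():
    with pytest.raises(ValueError):
        fisher_exact([[1, 2, 3], [4, 5, 6]])
    with pytest.raises(ValueError):
        fisher_exact([[1, -2], [3, 4]])
    with pytest.raises(ValueError):
        fisher_exact([[1.5, 2], [3, 4]])


def test_fisher_exact_matches_enumeration(rng):
    """p agrees with brute-force hypergeometric enumeration, N <= 60."""
    for _ in range(200):
        cells = rng.integers(0, 16, size=4)
        a, b, c, d = (int(x) for x in cells)
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            continue
        res = fisher_exact([[a, b], [c, d]])
        assert res.p_two_sided == pytest.approx(_enumerated_p(a, b, c, d), rel=1e-8)


def test_conditional_mle_monotone_in_corner_cell():
    """Holding all margins fixed, a larger (1,1) cell gives a larger
    conditional-MLE odds ratio."""
    n1 = n2 = m1 = 10
    ors = []
    for a in range(1, 10):
        table = [[a, n1 - a], [m1 - a, n2 - (m1 - a)]]
        ors.append(fisher_exact(table).odds_ratio)
    assert all(x < y for x, y in zip(ors, ors[1:]))


def test_fisher_ci_brackets_estimate(rng):
    for _ in range(20):
        a, b, c, d = (int(x) + 1 for x in rng.integers(0, 12, size=4))
        res = fisher_exact([[a, b], [c, d]])
        assert res.ci95[0] <= res.odds_ratio <= res.ci95[1]


def test_cleavage_contingency_directions():
    # identical proportions: no enrichment
    bact = ["AAKAAKAA"] * 5 + ["AAAAA"] * 5
    human = ["AAKAAKAA"] * 5 + ["AAAAA"] * 5
    res = cleavage_contingency(bact, human, "trypsin")
    assert res.odds_ratio == pytest.approx(1.0)
    assert res.p_two_sided == pytest.approx(1.0)
    # complete separation: bacterial all < 2 sites, human all >= 2
    res = cleavage_contingency(["AAAAA"] * 5, ["AAKAAKAA"] * 5, "trypsin")
    assert res.p_two_sided == pytest.approx(2 / 252)
    assert math.isinf(res.odds_ratio)
    with pytest.raises(ValueError):
        cleavage_contingency([], human, "trypsin")


def test_run_catalogue_covers_all_rules(rng):
    peptides = ["".join(rng.choice(list(STANDARD_AA), size=12)) for _ in range(30)]
    df = run_catalogue(peptides[:15], peptides[15:])
    assert len(df) == 36
    assert set(df.columns) >= {"rule", "a", "b", "c", "d", "odds_ratio", "p", "p_adjusted"}
    assert (df["p_adjusted"] >= df["p"] - 1e-12).all()
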