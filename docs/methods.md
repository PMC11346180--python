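# Methods

This note documents the models, rules and numerical choices behind
`micropept`, and what its synthetic data can and cannot show.

## Problem setting

Blood peptidome identification produces, per sample, a table of
peptide-spectrum matches against a combined database of human proteins
and the proteomes of human-microbiota organisms, plus (optionally)
de novo candidate interpretations with ALC confidences. The package's
job is downstream of the search engine: decide each peptide's origin
conservatively, remove identifications explainable as human variants,
attribute the rest to taxa, and characterize how bacterial peptides
differ from the human background in proteolytic history and
physicochemistry.

## Database build

Microbial proteomes are collapsed at 90% identity before being joined
to the human database, which keeps the combined search space small
enough that low-abundance microbial peptides are not swamped by decoy
mass. The collapse is greedy incremental clustering: entries sorted by
decreasing length (ties by accession, for reproducibility); each entry
joins the first representative with identity ≥ 0.9, else founds a new
cluster. Identity is the number of matched positions of the
best-scoring global alignment (match 1, mismatch 0, gaps free — i.e. a
longest-common-subsequence count) divided by the length of the shorter
sequence, the convention of the clustering tools this emulates. A
shared-5-mer prefilter skips alignments that cannot plausibly reach the
threshold; at 90% identity over realistic protein lengths a shared
5-mer is effectively guaranteed, but the prefilter is heuristic and is
therefore exercised by the clustering oracle tests. Ambiguity codes
B/J/X/Z/U are accepted in real input and never count as matches. This
is a desk-scale reimplementation, not a performance clone: it is
quadratic in the number of entries and intended for thousands, not
millions, of sequences.

**Occurrence counting runs against the database before collapse**: the
clustered representatives exist to bound the search space, but
abundance attribution must see every organism's proteins, so the
pipeline indexes the full microbial set for counting.

## I/L equivalence, origin calls and the SAP filter

CID fragmentation cannot distinguish leucine from isoleucine, so every
comparison in the package first rewrites I (and the ambiguity code J)
to L. Origin assignment is deliberately asymmetric: an exact
(I/L-equivalent) hit in the human proteome makes a peptide *human*
regardless of microbial hits; only peptides with an exact microbial hit
and no human hit are *microbiota*; everything else is *unmatched*.
A microbiota call within Hamming distance 1 of any human protein window
could be a single amino-acid polymorphism of that human protein, so it
is removed outright (flag `sap_homolog`); the filter partitions its
input exactly, losing and duplicating nothing.

The one-mismatch search uses the pigeonhole split: any window at
distance ≤ 1 from a query must contain one of the query's two halves
exactly, so candidate windows are found by exact substring search of
both halves over a separator-delimited concatenation of the proteome
and verified by direct Hamming comparison. This is exact (no seeding
heuristics) and is tested for equality against a brute-force
sliding-window scan. Peptides shorter than 5 residues are rejected at
parse time — below the practical identification floor of blood
peptidomics. Distance-2 search and non-I/L isobaric groups (e.g. K/Q)
are out of scope.

## Taxonomic attribution and spectral counting

The taxonomy is a rank ladder (superkingdom > phylum > class > order >
family > genus > species). A peptide occurring in proteins of several
organisms is attributed to the lowest common ancestor of their taxids;
if the set spans more than one superkingdom no level applies and the
sentinel *"any creature"* is used. Abundance uses equal-division
fractional counting: each spectral count is split uniformly over the
peptide's protein occurrences and summed per organism, so the table
total equals the number of counted spectra to 1e-9 — a conservation law
asserted throughout the tests. Within-protein repeats count once per
protein (the source convention is ambiguous about repeats; one
occurrence per protein is the choice here). For de novo mode each
spectrum contributes a unit count split over the pooled occurrences of
all its retained candidates; candidates without occurrences are
dropped, spectra passing the confidence filter but matching nothing are
*"unassigned"*, and spectra whose best candidate has ALC < 80 leave the
denominator entirely. Both thresholds ("not lower than" 80 for the
spectrum, 50 per candidate) are inclusive.

Roll-up to a rank sends counts assigned at or below the rank to their
ancestor at that rank; counts assigned above it keep their own labels;
a lineage that skips the rank (possible in real taxonomies, never in
synthetic ones) inherits the nearest annotated ancestor's label with a
`(rank-gap)` marker rather than aborting. Body-site profiles divide an
organism's count equally among its annotated isolation sites (the
multi-site convention is not specified by the source data; equal
division is the documented choice), with unannotated organisms under
*"unknown"*.

## Proteolysis-site enrichment

The catalogue holds 36 proteolysis patterns — the PeptideCutter set as
distributed with the Bioconductor cleavage package: trypsin,
chymotrypsin (high/low specificity), pepsin at pH 1.3 and pH > 2,
Asp-N, Lys-C, Lys-N, Arg-C/clostripain, glutamyl endopeptidase,
staphylococcal peptidase I, thermolysin, proteinase K, enterokinase,
factor Xa, thrombin, granzyme B, neutrophil elastase, proline
endopeptidase, caspases 1–10, and the chemical cleavages (CNBr, BNPS-
skatole, formic acid, hydroxylamine, iodosobenzoic acid, NTCB). Each
rule is a regular expression in the cleave-after-match-end convention;
each carries a provenance note, and the digestion machinery is
cross-checked against an independent implementation of the same
convention. The exact pattern list is tied to the catalogue documented
here, not to any unpinned upstream version.

Because circulating peptides are trimmed by exopeptidases, terminal
residues carry no protease information: a peptide of length L counts
only cleavage boundaries between residues i and i+1 with 2 ≤ i ≤ L−2
(one residue excluded at each end — the minimal reading of
"terminal amino acids not analyzed"; the window is a parameter in the
code). A peptide with < 2 such internal sites for a protease is
consistent with having been produced by that protease; bacterial and
human groups are compared by a 2×2 Fisher exact test with rows
(bacterial, human) and columns (< 2, ≥ 2), so an odds ratio > 1 means
bacterial enrichment for the protease-consistent pattern. The odds
ratio is the **conditional maximum-likelihood** estimate of the
noncentral hypergeometric parameter with its exact-test-inversion 95%
CI (the estimator under which published per-protease odds ratios of
this analysis are reproducible), not the sample cross-product; p-values
are verified against brute-force hypergeometric enumeration. Degenerate
tables (an empty margin) return p = 1 with the odds ratio flagged
undefined. Across the catalogue, Benjamini–Hochberg adjustment is
applied.

## Physicochemical descriptors

Per-peptide panel (all permutation-invariant): length; GRAVY (mean
Kyte–Doolittle hydropathy); aliphatic index by the Ikai formula
100·(X_A + 2.9·X_V + 3.9·(X_I + X_L)) on mole fractions; aromaticity
(F/W/Y fraction); polar-residue fraction over {N,Q,S,T,Y,C,D,E,K,R,H}
(configurable); net charge at a stated pH by Henderson–Hasselbalch over
the termini and D/E/C/Y/H/K/R side chains with an EMBOSS-style pKa
table (N-term 8.6, C-term 3.6, D 3.9, E 4.1, C 8.5, Y 10.1, H 6.5,
K 10.8, R 12.5) — monotone nonincreasing in pH, which makes the
isoelectric point a unique root found by bisection to |charge| < 1e-4;
Boman index as the negated mean Radzicka–Wolfenden water→cyclohexane
transfer free energy (P contributes 0, having no published value in the
scale); and mean side-chain bulk from Zamyatnin residue volumes (Å³).
The exact hydrophobicity and volume scales of the original descriptor
tooling are not pinned anywhere; Kyte–Doolittle and Zamyatnin are the
documented stand-ins, which affects absolute values but not the rank
tests on group contrasts.

Group comparison is the Wilcoxon rank-sum test: exact null distribution
for small tie-free samples, tie-corrected normal approximation with
continuity correction otherwise — the branching of R's `wilcox.test`,
which the study's figure captions describe. The pure normal
approximation alone can miss exact small-sample p-values by slightly
more than 0.05 in the most extreme n+m = 5 configurations, which is why
the exact branch exists. Benjamini–Hochberg adjustment runs across each
panel (the multiple-testing procedure is otherwise unspecified
upstream; BH is the package's choice).

## Spectrum correlation, FDR, MRM

Peak lists are paired greedily by smallest m/z difference within a
tolerance (default 0.05 Th — the high-resolution TOF/Orbitrap regime;
the binning used by the original correlation call is unstated, so this
is the documented default), ties broken toward the lower-m/z partner
for determinism; unmatched peaks contribute zero intensity on the other
side, and the Pearson correlation of the aligned vectors is reported —
symmetric, scale-invariant, and undefined (an error) for constant
vectors. Fragment-ion annotation is display-level and out of scope.

The upstream validation software's proprietary Naïve-Bayes local-FDR is
replaced, openly, by the transparent global target-decoy estimator:
FDR(t) = #decoys ≥ t / #targets ≥ t, monotonized into q-values by a
running minimum from the top score down. On simulated score mixtures
the estimate tracks the realized false-discovery proportion within
sampling error.

MRM quantitation: LOD is the lowest calibration level with signal in
every replicate; LOQ the lowest level ≥ LOD with replicate CV ≤ 20%.
(The source analysis set per-peptide thresholds from 15 external
calibration measurements without stating its decision rule; the
all-replicates-detected / CV ≤ 20% pair is the documented, configurable
substitute.) The calibration curve is ordinary least squares of mean
area on concentration over the levels at or above the LOQ (≥ 3 levels,
linear in concentration — no transformation is stated upstream), sample
areas convert through it with `<LOD`/`<LOQ` flags, and
µg/ml = mol/L × MW(g/mol) × 1000.

## Synthetic data: what it emulates and what it does not

The generator is the package's test bed and its defaults are the study
conditions. The taxonomy is a complete rank ladder, 2 superkingdoms ×
4 phyla × 3 species by default, with Homo sapiens as the first species;
every species has its own class–genus chain so two species of one
phylum converge exactly at the phylum. Proteomes draw residues i.i.d.
from background frequencies (approximately vertebrate); bacterial
organisms use multipliers {A 1.5, C 1.3, I 1.4, L 1.4, H 0.7, R 0.6,
K 0.7, S 0.8, Q 0.8}, reproducing the reported bacterial enrichment of
Ala/Cys/Ile/Leu and depletion of His/Arg/Lys/Ser/Gln; under the
Kyte–Doolittle scale this composition contrast implies an expected
GRAVY difference of ≈ +0.55, i.e. the hydrophobicity gap arrives as a
consequence of the composition shift rather than as a separate dial.

Each of n_spectra spectra draws an organism (human with probability
`fraction_human`, default 0.93 ≈ the observed ~7% microbial share;
otherwise by `composition_weights`, default uniform over non-human
organisms), a protein uniformly, and a peptide of 7–25 residues — for
bacterial organisms a digest product of the named protease (trypsin by
default, ≤ 1 missed cleavage), for the human organism a random
substring, since human blood peptides are endogenous exopeptidase
products with no single protease signature; the protease contrast that
the enrichment analysis detects is therefore planted by construction.
A configurable fraction of microbial spectra are *look-alikes*: a human
fragment with exactly one substitution (chosen so the I/L-normalized
string changes), emulating the false microbial identifications the SAP
filter exists to remove. De novo candidate ALCs come from a
two-population truncated-normal model (kept: N(90, 5) clipped to
[80, 100]; discarded: N(60, 12) clipped below 80) so the 80/50 filters
have a known expected pass rate; the true ALC distribution of de novo
software is uncharacterized, so this is a stand-in. The meal
time-course scales the bacterial spectrum rate by {1.0, 1.3, 2.0, 1.5,
1.1} at {pre-meal, 3 h, 5 h, 7 h, 9 h}, placing the abundance bump at
5 h.

Everything is a pure function of the SimSpec: all draws flow from
numpy's PCG64 `default_rng`, seeded per stage from the run seed. Truth
keeps one record per distinct peptide; in the (rare) event the same
sequence arises from two origins the first draw wins.

Not emulated: raw fragmentation peak patterns (peak lists exist only as
tiny fixtures for the correlation tests), retention time and intensity
models, real protein homology structure (i.i.d. residues make
cross-organism peptide sharing far rarer than in real proteomes, so
LCA resolution is easier here than in nature), database-size-dependent
score calibration, and chimeric spectra. Passing recovery tests
therefore demonstrate the correctness of the bookkeeping — counting,
filtering, attribution, statistics — under known truth, not the
real-data sensitivity/specificity of the identification chain.

## Problem sizes and determinism

The recovery checks run at 5000 spectra (binomial sampling puts the
±3-percentage-point band at ≈ 4 standard errors for a 13% phylum
share), clustering oracles at ≤ 30 sequences, matching oracles at
≤ 50 proteins × ≤ 200 residues, LCA oracles at ~100-node trees, Fisher
enumeration at N ≤ 60, and Wilcoxon enumeration at n+m ≤ 10 — sizes at
which the independent oracles are exact and fast. The full suite and
the acceptance script are deterministic given their seeds; pipeline
runs with the same configuration and seed produce byte-identical
reports.

## Known limitations

Greedy clustering is order-dependent by design (length-descending,
accession tie-break) and is not a replacement for the original
clustering tools at database scale. The 36-rule catalogue follows
PeptideCutter semantics; exotic context rules beyond it raise rather
than approximate. The conditional-MLE odds ratio is reported as
infinite for tables with a structural zero (the CI lower bound remains
informative). The de novo attribution treats candidate lists as given
and does not model candidate-rank truncation. GO/orthology enrichment
of precursor proteins requires external annotation databases and is out
of scope.
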