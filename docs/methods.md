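# Methods

## The model of flagellin diversity

Flagellin variation is treated as a two-level system. At the coarse level,
variable (D2/D3) regions fall into **HVR forms**: classes so divergent that
no meaningful local alignment exists between members of different classes.
At the fine level, sequences within a form differ by SNP-scale
substitutions (**isoforms**). The conserved terminal (D0/D1) regions, by
contrast, diverge slowly and remain alignable across the whole
superkingdom. All of the package's statistics are built on this structure:
domain-based curation exploits the conserved termini, clustering and the
spanning forest measure similarity dominated by them, HVR typing
operationalises "no alignment" between forms, and the selection curves
contrast synonymous-dominated change in the termini with unconstrained
change in the middle.

## Alignment and the BSR

All pairwise comparison is exact Smith–Waterman with affine gaps via
Bio.Align.PairwiseAligner — no heuristic seeding, so scores are exactly
reproducible. Defaults: BLOSUM62, gap open −11, extend −1 (the first gap
residue costs the open penalty, each further residue the extension), and
Karlin–Altschul constants λ = 0.267, K = 0.041 for the bit-score
transform. The bit score ratio uses the *minimum* of the two self bit
scores as denominator and is clipped to [0, 1]: this makes BSR symmetric
(required for an undirected cluster graph) and guards the rare affine-gap
artifact where a cross-score exceeds the weaker self-score. Traceback ties
follow the aligner's deterministic first traceback; identity and coverage
therefore have a single well-defined value per pair, while the score
itself is path-independent.

Brute-force path enumeration on short sequences, exhaustive spanning-tree
enumeration, recursive pathway collection, and distance matrices from
known additive trees serve as independent oracles in the test suite for
the aligner, Kruskal forest, Nei–Gojobori counts and neighbor joining
respectively.

## Curation

Domain presence is judged by sliding-window PSSMs (positions × 20 amino
acids, log₂ odds against a uniform background with Dirichlet
pseudocounts). A model hits when its best window reaches `min_score` and
the window midpoint lies in the expected terminal half. When a model is
built from seed sequences, `min_score` defaults to half the lowest seed
score under the finished model — every seed-family member passes with
margin, while random 100-residue windows sit far below (the suite checks a
no-hit rate above 99% on random proteins). The detector is an interface:
models can be loaded from TSV, so an HMM-based scanner can replace it for
real corpora without touching the funnel logic.

Acceptance requires both bacterial terminal domains or the archaeal
domain. Proteins carrying both terminal domains are then screened by a
two-profile likelihood ratio — best-window score under a flagellin
discriminant profile versus an FlgL discriminant profile, ties going to
flagellin — because FlgL (the hook-filament junction protein) shares the
conserved domains and is the classic curation confounder. Homolog fishing
recruits pool sequences whose best BSR against any accepted seed reaches
`min_bsr` (default 0.4, chosen to sit well below within-cluster BSRs and
well above the random-pair noise floor of ~0.02–0.06 measured on the
synthetic panel); fished records are re-scanned by the domain filter
before acceptance. The funnel conserves records: every input id appears in
exactly one of accepted/rejected, with a stage tag.

## Clustering and the spanning forest

Unique sequences (exact full-length string equality; representative = 
lexicographically smallest member id) are clustered by single-pass greedy
set cover: longest first, a sequence joins the first earlier
representative reached at identity ≥ 0.3 over aligned columns and
coverage ≥ 0.8 of the shorter sequence, otherwise it founds a cluster.
These thresholds are configuration, not science: cluster counts depend on
them and are never asserted against any published cluster count.

Inter-cluster similarity is the maximum BSR over cross-cluster member
pairs; the forest minimises distance 1 − similarity per connected
component (Kruskal, ties broken by lexicographic cluster-id pair). Edges
at or below `link_threshold` (default 0.1) are removed first. The
threshold is deliberately non-zero: unrelated proteins always produce
small positive local-alignment scores, so genuinely unlinked clusters sit
at BSR ≈ 0.02–0.06, not 0. The default cleanly separates that noise floor
from real within-supercluster similarities (≳ 0.17 in the synthetic
panel) and yields superclusters that never mix superkingdoms.

## HVR typing

DNA mode cuts the first 570 bp and last 300 bp as conserved; protein mode
uses the same boundaries in residues (190/100). "No alignment between
forms" is operationalised as: two variable regions are *alignable* iff
local identity ≥ 0.35 **and** coverage of the shorter ≥ 0.5; forms are
connected components (single linkage) of this relation, matching a
definition phrased as non-alignability against all other forms. The
defaults sit between observed within-form identities (> 0.9) and
cross-form identities of effectively random pairs. Isoforms are the
distinct variable-region strings within a form. Form ids are assigned by
descending member count then lexicographic representative, making the
output independent of input order.

Neighbor joining is implemented directly (Saitou–Nei Q-criterion,
deterministic smallest-label-pair tie-break, negative branch lengths
clamped to 0) because the tie-break and clamping behaviour needed pinning.
Score-derived distances use d = 1 − raw(a,b)/min(raw self-scores),
clipped to [0, 1].

## Diversity regression

The per-taxon statistic is the unique/total ratio (displayed to 2
decimals). Across taxa, log₁₀ unique is regressed on log₁₀ total by OLS
(statsmodels); base 10 matches log-count axes and affects only the
displayed slope/intercept, not R², p, or classifications. The "band" is
the pointwise 95% CI of the mean response; a taxon above the band is
classified more diverse than the trend, below it less, inside it average.
Classifications are scale-equivariant: multiplying all counts by a
constant shifts only the intercept. A minimum-count filter is available
but off by default.

## Selection curves

Coding sequences are aligned through their protein translations (MAFFT;
the module equally accepts pre-aligned codon input) and gaps are threaded
back as whole codons, so every column is a codon or a gap codon.
Codon-pair differences are counted by unweighted Nei–Gojobori pathway
averaging; pathways through stop codons are excluded, and if every
pathway crosses a stop the counts fall back to including them (flagged
behaviour, documented here because the convention is not standardised).
Per reference position, the curves accumulate the *mean* over
non-reference rows (a `sum` mode is available); the indel series counts
gap openings, attributing insertions relative to the reference to the
preceding reference position. Potential synonymous/nonsynonymous site
counts per codon are computed and exposed for users who want
site-normalised rates; the headline curves are raw cumulative counts.
The reference, when not named, is drawn uniformly under the run seed.

## The synthetic panel

The generator emulates what the analysis assumes about real corpora:

* **Conserved termini** (190 + 100 aa): global consensus → phylum-level
  ancestors (substitution rate 0.40) → species ancestors (0.05) →
  per-sequence noise (ε_c = 0.02). The phylum level defines the
  cluster-family ground truth: within a lineage full-length identity is
  ≈ 0.55 (joins at the 0.3 threshold), across lineages ≈ 0.2 or the
  alignment fails coverage — either way separate.
* **Variable regions** (130–200 aa) are drawn uniformly at random per
  form, *not* evolved from a common root: the modelled claim is precisely
  that forms share no recoverable ancestry. Each new form ancestor is
  verified non-alignable against its species' previous forms and redrawn
  on collision (regenerations are counted and exposed). Isoforms apply
  Bernoulli(ε_v = 0.02) substitutions, keeping within-form identity
  > 0.9.
* **FlgL decoys** carry both terminal domains drawn from a separate FlgL
  clade (0.30 off consensus) around a random middle, so they pass the
  domain filter and must be caught by the discriminant — the realistic
  failure mode. The domain models are profiles trained on the phylum and
  FlgL ancestors (as profile databases are trained on seed families), so
  the FlgL discriminant has its clade in-profile.
* **Archaeal records** have a single unrelated conserved domain (150 aa)
  plus one variable form per species with several isoforms; because only
  the domain aligns across archaeal species, each species is its own
  cluster-family truth, and archaea connect into their own supercluster.
* **Observation multiplicity** (1–3 copies per unique sequence) creates
  the unique-vs-total distinction; CDSs pick a random synonymous codon
  per residue, giving the selection module synonymous variation wherever
  amino acids agree.

All randomness flows from one seed through numpy `SeedSequence.spawn`, so
panels are byte-reproducible. Default sizes (3 bacterial phyla × 26
forms, 2 archaeal species, ~300 records) keep a full pipeline run around
half a minute on one CPU while leaving all recovery margins wide; the
separate counts-table generator (40 phyla, slope 0.93, noise SD 0.05)
exercises the regression at a realistic corpus shape.

What passing on this panel does **not** show: robustness to fragmentary
proteins, sequencing or assembly error, biased taxon sampling,
phylogenetically correlated conserved-domain evolution, or HVR forms with
partial cross-alignability (the real data's "limited segments of poor
alignment" cases). The panel's separations are generous by construction;
on real corpora the clustering and typing thresholds are the knobs that
absorb the grey zone, and cluster/form counts should be read as
threshold-dependent.

## Numerical and degenerate-input conventions

Zero- or negative-scoring local alignments return raw score 0 with an
empty path; BSR of such pairs is 0; a sequence with non-positive self bit
score is rejected as degenerate. Codons containing N contribute (0, 0) to
pathway counts and translate to X. Empty variable regions, too-short
genes (≤ 870 bp / ≤ 290 aa), mixed-kind deduplication, fewer than 3
regression points and degenerate abscissas raise errors rather than
guessing. Ratios are displayed to 2 decimals; multi-phylum shares to the
nearest percent.
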