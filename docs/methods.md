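# Methods

This note records the models, numerical choices, and open design decisions
behind `orthoscan`, in the order the pipeline runs them.

## Local alignment engine and statistics

The search engine computes optimal local alignments under affine gaps with
the Gotoh recurrences (a gap of length k costs `gap_open + k·gap_extend`;
defaults 11/1 on BLOSUM62). Suboptimal alignments are produced
Waterman–Eggert style: the aligned cells of each reported alignment are
masked and the matrix recomputed, so no two reported HSPs share an aligned
(query, subject) cell. Tie-breaking is fully specified — among equal-scoring
end cells the smallest (q_end, s_end) wins lexicographically, and traceback
prefers diagonal moves, then gaps in the subject — so output is
platform-stable. The DP kernel operates on a generic pair-score matrix and
is shared between sequence–sequence and profile–sequence search; it is
JIT-compiled, which keeps whole-database searches at desk scale (hundreds of
records × hundreds of residues) in the seconds range.

Bit scores and E-values use the Karlin–Altschul form
`bit = (λS − ln K)/ln 2`, `E = mn·2^−bit` with the published gapped
BLOSUM62/11/1 constants λ = 0.267, K = 0.041 and n = total database
residues. We measured the engine's actual random-score tail by simulation:
for unrelated sequences with standard background composition the published
constants are slightly conservative (observed tail ≈ 0.4× predicted at the
E = 0.1 working threshold), which is the safe direction. Uniform-composition
sequences, by contrast, inflate the tail several-fold, because uniform
sampling over-represents rare residues with large self-scores (W 11, C 9);
this is why the synthetic decoys are drawn from background frequencies (see
below). Ambiguity codes (B, Z, X, U, O) score as the worst entry of the
relevant matrix column, so they can never create a hit.

## Coverage statistic

Coverage is the percent of query residues covered by non-overlapping local
alignments. HSPs are taken best-score first (ties: longer query span, then
smaller start) and accepted greedily iff their query interval overlaps no
accepted interval; the contribution of an HSP is its query-interval length,
so columns where the query has a gap contribute nothing. Overlap is defined
on query coordinates only — two HSPs hitting distinct subject repeats
through the same query region count once. The greedy-by-score rule (rather
than the maximum-coverage interval subset) is deliberate: it is
deterministic and reflects a top-hit-first reading of the procedure.
Filters are inclusive at their boundaries: coverage 30.0% passes the ≥ 30%
rule, E = 0.1 passes the ≤ 0.1 rule.

## Reciprocal confirmation

Forward hits are truncated to the top five per organism, then filtered by
coverage and E-value. A candidate is confirmed iff its reverse search
recovers the original query among the reverse top-five coverage-passing
hits of the query's organism. The reverse coverage denominator is the
reverse query (the candidate), mirroring the forward rule. Reverse searches
exclude the candidate itself — it is a member of the database being
searched, and a self-hit would make the rule vacuous.

## Progressive MSA, trimming, profiles

Pairwise distances are one minus identity over matched columns of a global
alignment; a UPGMA guide tree (average linkage) orders profile–profile
merges scored by the expected substitution score between column residue
distributions, with affine gaps. Column trimming removes columns whose gap
fraction **exceeds** the threshold (0.25 default; 0.75 as the relaxed
setting for highly conserved families that would otherwise lose too much
signal); trimming is idempotent by construction.

The "profile" is a position-specific log-odds model in half-bit units, not
a full profile HMM: per column, observed frequencies are mixed with
pseudocount mass distributed by the substitution matrix's conditional
probabilities q(j|a) ∝ p_j·2^(B(a,j)/2) (weight = 1 effective sequence by
default), then scored as 2·log2(f_j/p_j) against the BLOSUM62 background.
This choice makes a single-sequence profile converge to that sequence's
BLOSUM62 rows as the pseudocount grows, a property we verify numerically.
Henikoff sequence weighting is omitted at this scale. Profile–sequence
search uses the same local DP with the same 11/1 gap penalties (the
half-bit scale matches the matrix units); profile scores carry no E-value —
the reverse-confirmation rule, not profile statistics, carries the
specificity.

## Iterative expansion

Per family: align current members (untrimmed — trimming is only for tree
building), build the profile, search only organisms that still lack a
member, take the top five candidates per organism, and reverse-confirm each
candidate against the original database. The acceptance rule is
per-organism: the candidate's reverse hits are filtered by E-value and
coverage exactly as in the forward direction, and the candidate is accepted
iff the top surviving hit of at least one organism is a current member. A
global-rank-1 rule was considered and rejected: when two undiscovered
sibling members are each other's best hits it deadlocks, while the
per-organism rule lets the anchor organisms vouch for both. Membership only
grows, so the loop terminates; an iteration cap (10) is a safety rail.

## Distances, neighbor joining, clade confirmation

p-distances are computed over mutually ungapped column pairs and corrected
with Kimura's protein formula d = −ln(1 − p − 0.2p²); pairs beyond the
correction's domain (p ≳ 0.8541) are capped at 5.0. Neighbor joining is the
canonical Saitou–Nei algorithm with an explicit deterministic tie-break
(the joinable pair whose smallest member label is lexicographically least);
on additive matrices it recovers topology and branch lengths exactly, which
the tests verify against a least-squares brute force over all topologies at
4–5 taxa.

Tree confirmation is an explicit, automated proxy for what is usually a
manual inspection step: the tree is midpoint-rooted, and a candidate passes
iff it lies inside the smallest clade containing all reciprocal-tier
members AND its terminal branch is at most 3× the median terminal branch of
those members. Failures downgrade the call to low confidence; nothing is
ever removed at this stage. Midpoint rooting occasionally degenerates when
the midpoint falls exactly on a node of a zero-length-branch tree; the
implementation detects the dropped-leaf symptom and falls back to the
original rooting. Deeply divergent true orthologs do get flagged by the
3×-median rule — that is intended behavior, mirroring how unresolvable
placements are reported as low-confidence rather than discarded.

## Structure-based screening

Superposition is the Kabsch algorithm: SVD of the cross-covariance of
centered corresponded coordinates, with the determinant correction that
excludes reflections; fewer than three pairs or collinear sets are
rejected. Cross-model consensus demands all pairwise RMSDs over the shared
region be **strictly** below 5 Å; ortholog acceptance demands RMSD
strictly below 3 Å over a correspondence built from a global sequence
alignment of the domain sequences, with at least 50% of the shorter domain
corresponded (the floor prevents trivially small superpositions from
passing). Domain segmentation is confidence-based: the pLDDT trace is
smoothed with a centered 15-residue moving average, maximal runs ≥ 70 are
taken, boundaries are snapped outward along the raw trace, runs closer
than 10 residues are merged, and runs shorter than 40 residues dropped.
This replaces sequence-propensity segmentation because the inputs here are
predicted models that carry pLDDT; explicitly supplied intervals can
override it.

The calibrated structure-pair generator used for boundary fixtures projects
a random perturbation to remove net translation and rescales it against the
measured post-fit RMSD until the pair sits within 1e−9 **at or above** the
target, never below — so a pair built "at" a strict threshold reliably
fails that threshold.

## Gene-model rescue

ORFs are defined stop-to-stop, not ATG-initiated: reconstruction here is
homology-driven and the relevant genomes favor protein-level evidence over
start-codon annotation. Fragment selection selects the maximum-score
collinear chain of homolog-aligned ORFs, where ordering uses the genomic
span of each fragment's *aligned region* (a stop-to-stop ORF can run far
past its homologous core in the wrong frame) and each chained fragment must
contribute at least 10 new homolog residues. Junctions are chosen to
maximize the summed substitution score of the residues kept from each side,
monotonically across junctions; terminal residues outside the homolog
alignment are trimmed, since the homolog defines the gene-model boundaries.
Pileup-based indel correction applies an insertion or deletion at any
position with depth ≥ 5 where the supporting fraction exceeds 0.5, editing
right-to-left so coordinates stay valid; conflicting majorities are an
error, and every edit is recorded with its support.

## Synthetic data: what it emulates and what it does not

Families evolve over a rooted binary species tree under a
Poisson/uniform-replacement substitution model: along a branch of length b
each site substitutes with probability 1 − e^(−b) to a uniformly chosen
different residue. The closed-form expected identity at patristic distance
d, e^(−d) + (1 − e^(−d))/19, makes the generator self-verifying and is
checked by simulation. Indels are Poisson events (rate 0.01 per site per
unit branch length by default) with geometric lengths (mean 3); whole
lineages are lost with a per-branch probability; decoys are i.i.d.
background-composition sequences with lengths drawn from the family length
distribution (background, not uniform — see the statistics section). All
randomness flows through one seeded generator per run.

The benchmark conditions are 8 organisms, 3 families of root length 200,
branch lengths up to 0.5 substitutions/site, 10% per-branch loss, and 20
decoys per organism — sized so a full pipeline run takes ~15 s on one CPU
and the full test suite stays around a minute. What passing these tests
shows: the decision rules compose correctly and recover planted families
at deep but not saturated divergence, while rejecting unrelated sequences.
What it does not show: performance on real proteomes with domain shuffling,
compositional bias, paralogy, or alignment-quality pathologies — none of
which the generator emulates (it is also codon-blind and has no realistic
proteome size distribution). Frameshift fixtures use single-nucleotide
insertions only: a 1-nt deletion at a codon boundary destroys a codon
outright and makes exact round-trip recovery impossible by construction;
deletions are exercised through the pileup-correction path, where read
evidence restores the lost base.

## Benchmark scoring

The pipeline's natural output is the presence/absence grid, so the
end-to-end benchmark scores at two levels: per accepted subject (every
called record must belong to the query's family) and per (family, organism)
cell, where `found` or `low_confidence` both count as presence — the
low-confidence category is exactly the grid's "gray circle". Separately, a
simulated loss must never be reported as a *high*-confidence find;
tree-flagged low-confidence hits may land in lost lineages, which is the
same behavior the gray category exists to absorb. At the default
configuration the residual error source is a ~0.5%-per-pair rate of
reciprocal false positives between unrelated sequences at E = 0.1 — a
property of the published threshold, not of the implementation — and these
are the calls the tree stage flags.

## Known limitations

- No k-mer seeding or composition-based score adjustment: the engine is
  exact but O(nm) per pair, sized for curated families, not proteome-scale
  all-vs-all.
- Profile scores are uncalibrated (no E-values); acceptance leans entirely
  on reverse confirmation.
- The structural screen needs a usable sequence correspondence; fold
  homologs with unalignable sequences (the regime where structure search
  shines) fall back to "insufficient correspondence" rather than a
  structure-native alignment.
- clade_confirm's 3×-median branch rule is a declared proxy for manual tree
  inspection; its false-flag rate on deep true orthologs is nonzero by
  design.
- Mixed-strand rescue chains are not supported; all fragments of a gene are
  assumed on one strand of the contig.
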