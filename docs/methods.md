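# Methods

This note documents the models, defaults and design choices behind the
package; it states nothing that the test suite or `scripts/acceptance.py` do
not themselves compute.

## The fingerprint model

Family GH57 proteins are treated as five conserved sequence regions (CSRs)
embedded, in order, in otherwise unalignable sequence. The fingerprint is the
36-residue concatenation CSR-1(5) + CSR-2(6) + CSR-3(6) + CSR-4(10) +
CSR-5(9), with 1-based positions throughout (both fingerprint and
full-sequence coordinates). Two positions carry the catalytic machinery
(Glu15, Asp20); five are diagnostic of specificity (1, 12, 23, 35, 36). The
"aromatic" residue class used by the position-12 and position-36 rules is
{F, W, Y, H}; histidine is included conservatively since the source analyses
speak of "at least an aromatic residue" without enumerating the set. All of
this, the 14-group catalogue and the per-group diagnostic residues are
shipped as a versioned JSON document (`gh57/data/gh57_definition.json`), so a
different family layout can be configured without code changes.

The one historically unclassifiable GH57 sequence is modelled by the
catch-all `unclassified` label rather than a fifteenth group, and the
documented caveat that like-protein groups are not perfectly homogeneous
(some members retain full machinery) is recorded as a caveat, not a rule:
such sequences pass through with a warning flag.

## Synthetic data generator

The generator emulates the statistical structure of the curated study set;
its defaults are the study conditions used by the tests:

| parameter | default | meaning |
|---|---|---|
| `counts` | catalogue sizes (Σ = 1602) | sequences per group |
| `conservation` | 0.9 | P(non-diagnostic fingerprint position matches group consensus) |
| `linker_composition` | uniform over 20 residues | background for linkers |
| `length_jitter` | 0.05 | fractional s.d. of length around the group mean |
| `dropout_fraction` | 0.02 | decoys generated with one CSR deleted |
| `min_spacer` | 5 | minimum residues between consecutive CSRs |
| `seed` | 1602 | master seed (value itself arbitrary) |

Group consensi draw free (non-catalytic, non-diagnostic) positions uniformly
at random, redrawn until every enzyme-group pair differs at ≥ 8 of the 29
free positions; diagnostic positions follow the rule table and Glu15/Asp20
are fixed. Each like-protein group receives its base group's consensus with
10 free positions substituted: enough shared signal to stay "closely related"
to the base specificity (independent groups differ at ~27 free positions),
enough divergence that like groups form their own clades, as they do in the
real family. Per sequence, free positions flip i.i.d. with probability
1 − conservation; every member of a like group then has its nucleophile,
donor, or both substituted (45 % / 45 % / 10 %) by a random non-Glu/non-Asp
residue. Sequence length is Normal(group mean, 0.05 × mean) with the slack
apportioned over N-terminus, four spacers and C-terminus by a symmetric
Dirichlet(1) draw (internal spacers keep the 5-residue minimum); `0.05` is a
typical within-group length spread for a shared domain architecture, and the
flat Dirichlet is the maximally non-committal choice given that only total
lengths are known. Linkers are i.i.d. uniform residues.

What the generator does **not** emulate: phylogenetic correlation within
groups (members are i.i.d. around the consensus), realistic linker
composition or domain structure, indels inside CSRs, and real per-position
conservation profiles (0.9 is a stand-in; the true rates vary by position).
Passing tests therefore demonstrate correctness of the machinery under a
clean, known-truth model — not performance on real GH57 collections, where
profiles should be trained on curated fingerprints.

## Detection

Each CSR is a position-specific scoring profile: frequencies
`(count + pc) / (n + 20·pc)` with pseudocount 0.5, log₂-odds against a
uniform background. Residues outside the 20-letter alphabet (X, B, Z, U, …)
score 0 (the background expectation) and contribute no training counts. The
five windows are placed by an exact dynamic program over all ordered,
non-overlapping placements with spacer ≥ 5, maximising total log-odds; ties
break toward the leftmost (lexicographically smallest) start tuple, and the
suffix-DP formulation makes that tie-break exact. Under the generator's
assumptions (uniform linker, flat spacer apportionment) this placement is the
maximum-a-posteriori decoder: the window log-odds sum differs from the full
sequence log-likelihood by a placement-independent constant.

Detection scans with one profile set per group — all 14, like groups
included, since like-protein CSRs genuinely diverge from their base group —
and the set with the highest total log-odds wins; its floor test alone
decides acceptance. Profile scanning replaces the original
alignment-plus-manual-inspection workflow with a reproducible equivalent, and
per-group sets rather than one pooled profile keep minority specificities
(α-galactosidases are 14 of 1602) from being swamped by the majority
composition.

**Elimination rule.** A sequence is eliminated when any CSR of the winning
placement scores below `0.15 ×` that profile's own consensus score. The
fraction is chosen from the score arithmetic at the default conservation:
the least constrained CSR (CSR-2, six free positions) with three
substitutions scores ≈ 0.18 × consensus, and three-of-six substitutions
occur in ≈ 1.5 % of sequences, so a floor above ≈ 0.18 visibly eats into
recall, while random linker windows need ≥ 3 chance consensus hits (p ≈ 0.002
per window) to clear 0.15. The floor trades decoy rejection against recall:
at 0.15, recall is ≈ 99.7 % and ~90–100 % of single-CSR-deleted decoys are
eliminated (a long linker occasionally contains a three-hit spurious window).
Both the fraction and absolute per-CSR floors are configurable.

**Known limitation.** At conservation 0.9 a small number of sequences
(≈ 1–3 per 1602) contain a spurious linker window that *strictly outscores*
their heavily substituted true CSR under the best-fitting profile. Since the
detector is the exact MAP decoder of the generative model, these
misplacements are irreducible from sequence alone; the original curation
resolved such ambiguous CSRs by structure modelling, which is out of scope
here. The practical consequence is a machinery-status error rate of order
0.1 % rather than strictly zero.

## Classification

The machinery status is read directly from fingerprint positions 15 and 20.
The base specificity is the argmax of total log-odds over the nine
enzyme-group profile sets (like groups are not scored separately; the spec of
a like protein *is* its base specificity plus missing machinery). Ties break
by diagnostic-flag count, then lexicographic group name. Assignment policy:
best score below the threshold (default 0 bits, i.e. "no better than
background") → `unclassified`; incomplete machinery → the base group's
like partner (or the base label plus a warning for the four groups without a
like partner); otherwise the base label. Diagnostic-position disagreements
are recorded as warnings and never veto a score-based assignment, because the
family's growth has eroded the absolute uniqueness of several diagnostic
residues. APU and APU-CMD have no documented quantitative separator; they are
treated as distinct groups with independently trained profiles.

## Logos

Logo matrices are observed frequencies (no pseudocount) with Shannon
information content IC = log₂20 + Σ p·log₂p per column, in bits (0 for
uniform, log₂20 ≈ 4.3219 for invariant). The small-sample correction used by
display-oriented logo tools is deliberately omitted so the values have exact
closed forms; for the group sizes involved (n ≥ 14) the correction would be
≤ 19/(2·ln 2·n) ≈ 0.05–1 bit and purely subtractive.

## Tree building

Distances are p-distances (mismatch fraction) over the 36 fingerprint
columns, with non-standard residues excluded pairwise — the simplest faithful
reading of "alignment of the five CSRs + neighbor joining"; the distance
matrix is pluggable for anyone wanting corrected distances. Neighbor joining
follows the standard Saitou–Nei agglomeration with two determinism rules:
Q-matrix ties break toward the smallest (i, j) index pair, and negative
branch lengths are clamped to zero with the deficit moved to the sibling
edge. Bootstrap resamples the 36 columns with replacement (default 1000
trials, the conventional number; tests use 100 for runtime) and reports, per
internal edge, the fraction of trial trees containing the same bipartition.
The per-group `monophyly_fraction` is 1 when some edge induces exactly the
group's leaf set, else the best Jaccard overlap between the group and any
edge-induced leaf set.

Because fingerprints within a synthetic group are i.i.d., internal edges
*within* a group are arbitrary and their bootstrap supports hover near zero;
the meaningful signal is in the group-separating edges, whose supports are
reported separately by the acceptance script (≈ 0.95 on the default data).

## Problem sizes

The default validation run processes the full 1602-sequence dataset through
detection and classification; trees are built on a 200-leaf stratified
subsample (at least one leaf per group, proportional otherwise) — ample to
measure per-group monophyly while keeping the O(n³) NJ bootstrap cheap. The
brute-force placement oracle enumerates all valid five-window placements on
random sequences of 56–96 residues, and the tree oracle fits branch lengths
by least squares over every unrooted topology for n ≤ 6.
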