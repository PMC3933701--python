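# Methods

This note documents the models and conventions behind `repliscan`: what each
stage computes, the tunable parameters and their defaults, what the synthetic
data generator does and does not emulate, and the numerical choices that make
every run reproducible.

## Sequence model and degenerate-base algebra

Sequences live over the 15-letter IUPAC nucleotide alphabet plus `-` for
alignment gaps; input is uppercased and `U` mapped to `T` on ingestion, so
public records paste in directly. A degenerate primer denotes the equimolar
mixture of its concrete expansions; its degeneracy is the product of the
per-position base-set sizes.

Two distinct matching rules are used deliberately:

* **Primer–template matching (asymmetric subset rule).** A template base
  matches a primer base iff every concretization of the template base is
  covered by the primer base. An `N` in a template therefore never satisfies
  a non-`N` primer position — ambiguity in a deposited sequence cannot
  silently count as a perfect 3′ anchor. This is the conservative choice for
  a screen whose point is to guarantee extension; how ambiguous reference
  bases should be treated is genuinely underdetermined, so reports flag it as
  a convention.
* **Alignment matching (symmetric intersection rule).** During alignment two
  residues score as a match iff their expansions intersect, because alignment
  has no primer/template polarity.

The complement table extends over all ambiguity codes (W↔W, S↔S, R↔Y, K↔M,
B↔V, D↔H, N↔N), making reverse complementation an involution that preserves
degeneracy.

## Binding sites, amplicons, specificity

A primer binds a plus-strand window (reverse-role primers via their reverse
complement) when the perfect-match run from the primer's 3′ terminus reaches
`anchor_len` and the number of mismatching positions — necessarily 5′ of that
run — stays within `max_mismatch`. Defaults `anchor_len = 12`,
`max_mismatch = 4` encode how the IncP-9 oriV-rep system behaves across its
reference replicons (no mismatch over at least 12 bp at the 3′ end, 1–4
mismatches at the 5′ end per sequence type); 0 mismatches also passes, since
fewer mismatches cannot be worse.

Amplicons are all forward-site × reverse-site combinations with the reverse
site downstream, plus the mirror orientation obtained by re-scanning the
reverse complement, de-duplicated by interval. Product length is
`j + L_r − i` for forward-site start `i` and reverse-site start `j`, and
always equals the extracted subsequence length. Coordinates are 0-based
half-open internally and 1-based inclusive in TSV output.

A specificity screen counts a record as *amplified* when at least one product
of any size is predicted; size filtering is opt-in (`--size-window`), because
a gel would reveal off-size products anyway and the screen should not hide
them. Templates are treated as linear; circular plasmid topology is not
modeled, so a binding-site pair straddling the origin of a circular record
would be missed (a known limitation).

## Primer design

Design operates on a multiple alignment of the grouped targets:

1. **Conservation profile.** Per column: fractional base counts (ambiguity
   codes spread uniformly over their sets), gap fraction, and a consensus
   code — the minimal IUPAC superset of every base whose frequency among
   non-gap residues reaches `f_min`. The default `f_min = 0` makes the
   consensus cover *every* observed base, mirroring a design goal of zero
   mismatches for each sequence type; raising it down-weights singleton
   noise.
2. **Candidate enumeration.** Windows are `primer_length` (default 21)
   consecutive columns whose gap fraction is at most `max_gap_fraction`
   (default 0 — primer sites must be indel-free across references). The
   window consensus (reverse complemented for reverse-role candidates) is
   kept if its degeneracy is at most `max_degeneracy` (default 8) and its
   Wallace Tm lies in the Tm window, and if it binds every target under the
   anchor/mismatch rules. An empty candidate list is a reported outcome, not
   an error.
3. **Pairing and ranking.** A pair survives only if, on every target, the
   product length falls inside `[amplicon_min, amplicon_max]` (default
   [610, 637] bp). Ranking is deterministic: smaller pair degeneracy, then
   fewer total mismatches, then closer primer Tms, then leftmost windows.
   The rank key is an explicit package convention for choosing among feasible
   windows — nothing in the published system dictates one — and tightening
   any constraint provably never enlarges the candidate or pair set.

Tm uses the Wallace rule 2(A+T) + 4(G+C) in °C with expected base counts over
the expansion mixture; nearest-neighbor thermodynamics, dimer/hairpin
screening and multiplex optimization are out of scope. The default Tm window
is 50–62 °C: the published IncP-9 pair computes to 60 °C (forward) and 61 °C
(reverse) under the Wallace rule, and a default that rejected the system the
toolkit is built around would be self-defeating; the window is configurable
for stricter designs.

## Alignment

Pairwise global alignment is Needleman–Wunsch with linear gap costs
(defaults match +1 / mismatch −1 / gap −2 — replicon backbones are close
homologs, so affine gaps would buy little at this scale) and a fixed
traceback tie-break (diagonal > up > left). Multiple alignments are built
progressively: pairwise mismatch fractions feed a neighbor-joining guide
tree, and profiles are merged leaf-to-root with profile–profile
Needleman–Wunsch over per-column base-frequency vectors. Gap costs in
profile merges are weighted by the occupancy (non-gap fraction) of the
column being gapped, so indel blocks coalesce in the same columns across
merges instead of fragmenting — without this, near-tie plateaus in the DP
can thread a conserved block through half-gapped columns. The procedure is
deterministic given input order and involves no randomness. Reproducing any
external aligner's exact columns is a non-goal.

## Distances, trees, classification

* **p-distance** — proportion of differing sites over pairwise-deleted
  columns, compared literally after normalization (a `W` differs from an
  `A`); a pair with zero comparable columns is an error naming the pair.
* **Jukes–Cantor** correction d = −¾ ln(1 − 4p/3), the default model since
  the published analysis names only the tree method; p ≥ 0.75 raises a
  "saturated distance" error rather than clamping, because silent infinities
  corrupt neighbor joining. p-distance remains selectable.
* **Neighbor joining** — Saitou–Nei agglomeration with the Studier–Keppler
  Q-criterion. Ties in Q resolve to the lowest (row, column) index pair in
  current matrix order; negative branch lengths are clamped to 0 without
  redistribution (affects lengths, never topology). On additive matrices the
  generating topology is recovered exactly (property-tested against random
  trees of up to 8 leaves).
* **Bootstrap** — columns resampled with replacement per replicate; the
  column-index stream depends only on the seed and replicate number, so
  supports do not depend on row order (on tie-free data). Support is the
  percentage of replicate trees containing each original bipartition. The
  field-standard 1,000 replicates is the default; tests and the acceptance
  script use 20–100 replicates, which is ample for the clear-cut synthetic
  splits they assess.
* **Classification** replaces a remote BLAST lookup with local
  nearest-reference assignment, removing the network and database
  dependency: queries are co-aligned with labelled reference amplicons, each
  query takes the subgroup of its nearest reference by JC distance
  (ties to the earliest reference in input order), and a query whose nearest
  distance exceeds τ (default 0.10 substitutions/site) is reported
  *unaffiliated*, flagging putative novel subgroups. Support is the
  percentage of column-resampling replicates reproducing the label; within
  replicates, saturated or incomparable pairs count as infinitely distant.

## Synthetic panels and what they show

`simulate_panel` emulates the *structure* of a grouped replicon reference
set: a random root carries a forward primer footprint, an insert and a
reverse primer footprint at panel-wide coordinates (placed uniformly at
random where they fit); subgroup ancestors diverge from the root by
substitutions at rate μ_b, members from their ancestor at μ_w; each member
receives a fresh random concrete expansion of the planted degenerate pair
and an insert length drawn uniformly from `insert_length_range`. Length
variation is realised as a single deletion in the *middle* of the insert,
keeping every sequence homologous and both footprints embedded in long
conserved context. Decoy non-targets are site-free random sequences
(rejection-sampled against the binding rules).

Defaults are fixed study conditions, chosen once: 9 subgroups × 3 members
(27 targets — the scale of the real 28-sequence reference alignment),
sequence length 800 nt, μ_w = 0.02 and μ_b = 0.15 substitutions/site
(clearly separated families that still align), 6 decoys, insert range
[568, 595] so that products span exactly 610–637 bp with two 21-mer
footprints. With `anchor_protect` (default) no mutation touches the planted
footprints, so anchors are guaranteed intact and the planted degenerate pair
is exactly the footprint consensus; with `anchor_protect=False` a
within-rate substitution pass runs over the footprints, anchors included,
for studying degraded binding sites. `simulate_queries` emulates a cloned
amplicon library: planted amplicons of panel members mutated at a
configurable rate (default 0.02), labelled with their generating subgroup.

What passing on these panels shows: coordinate bookkeeping, the binding and
size predicates, consensus construction, recovery of a planted signal under
realistic divergence, and end-to-end determinism. What it does not show:
performance on real replicons — the generator has uniform base composition,
substitutions only (an optional single deletion per member, no scattered
indels), no recombination, no rate heterogeneity, and primer sites that are
conserved *by construction* rather than by purifying selection. Results on
real data therefore hinge on alignment quality and on how conserved true
primer-binding regions are, neither of which the synthetic tests certify.

## Reproducibility

Every stochastic step takes an explicit seed (CLI `--seed`, default 42) and
is driven by `numpy.random.default_rng`; identical command, inputs and seed
give byte-identical FASTA/TSV/Newick outputs. Each CLI run writes a
`manifest.json` with the command, parameter snapshot, SHA-256 input digests,
seed, version and timestamp — timestamps live only in the manifest, never in
primary outputs.
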