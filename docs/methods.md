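# Methods

## Contact definition and curation

Two residues are in contact when their representative atoms — Cβ, or Cα
for glycine — are strictly closer than the cutoff (default 8.0 Å). The
strict inequality is a deliberate convention: a pair at exactly 8.000 Å
is *not* a contact. The map has a unit diagonal (self-distance 0) and is
symmetric by construction; all user-facing indices are 1-based.

Chain curation for data-set building keeps X-ray structures at ≤ 1.5 Å
resolution with intact backbones (every residue has N, CA, C), standard
residues only, and lengths within [51, 450]. A chain whose resolution is
unknown fails the resolution filter. Parsing rules where conventions
vary: the first-occurring altloc wins; residues follow file order;
HETATM records are ignored; a non-glycine residue lacking Cβ falls back
to Cα with a warning (a strict flag raises instead — curated corpora
never contain such chains, but a predictor must not crash on them).

## The pair encoding (210 → 218 → 1090 → 1744 → 1747)

For columns (i, j) of the filtered MSA, every row with standard residues
at both positions increments one of the 210 unordered amino-acid pair
categories (lexicographic over sorted pairs, so (A,A) → 0); counts are
divided by the **total** retained row count, so gapped rows shrink the
vector sum — the sum equals (rows standard at both positions)/(rows).
The 218 base block appends conservation and a 3-state secondary
structure one-hot (H/E/C; DSSP states reduced as H,G,I→H; E,B→E,
else C) for each of the two positions.

The full vector stacks eight base blocks plus three globals:

| slice | content |
|---|---|
| base | the pair (i, j) itself |
| content ±1, ±2 | the shifted pairs (i+d, j+d), d ∈ {−2,−1,+1,+2} |
| segment 0–2 | (k, k), (k−1, k+1), (k−2, k+2), k = ⌊(i+j)/2⌋ |
| global | (j−i, N, j−i−1) / 450 |

Design choices where the layout was genuinely open: the two content
windows are coupled as shifted *pairs* (the only pairing consistent with
1090 = 5×218); the segment window contributes three pair blocks
symmetric about the midpoint, including the self-pair (k, k), which is
encoded as a valid diagonal-category block rather than zeroed (an
alternative scheme with three self-paired positions k−1, k, k+1 is
selectable via `segment_scheme="midpoint_self"`). Any window position
outside [1, N] zeroes its whole 218 block. Globals are normalized by
450, the longest supported chain, so every input shares the [0, 1]
scale. (i, j) is canonicalized to i < j, making the encoding of a cell
and its transpose identical by construction.

MSA preprocessing: rows with ≥ 80% identity to the target are dropped
(identity = matches over mutually non-gap columns; the target itself is
always kept), then depth is capped at 100 rows in file order.
Non-standard letters (B, Z, X, U, O) count as gaps. Conservation weights
are taken from annotation when present, else the modal non-gap residue
frequency of the column — a declared fallback, not a canonical formula.

## Networks and training

All networks are classical 3-layer perceptrons with logistic sigmoid on
hidden and output layers: six sub-networks of shape 1747-5-1 (8746
parameters) and one cascade network of shape 9-6-1 (67 parameters).
Training is full-batch gradient descent with momentum on binary
cross-entropy; gradients are derived by hand and verified against
central differences (< 1e-6) in the suite. Weights initialize uniformly
in ±1/√fan-in from a seeded generator; seeded runs are bit-reproducible.

Defaults: learning rate 0.5, momentum 0.9, up to 500 epochs, early
stopping on a 15% validation split with patience 50. The rate is high
by stochastic-gradient standards because updates are full-batch on
balanced data; at 0.05 the nets fail to leave the chance plateau within
the epoch budget on the linearly separable sanity task, while 0.5
reaches 100% on it.

**Balanced sampling.** Contacts are rare (a few percent at the required
separations), so before training exactly min(#pos, #neg) examples per
class are drawn. The balancing probability factor (default 1.0) first
keeps each positive with that probability and then draws an equal number
of negatives — thinning the set symmetrically while preserving exact
class balance. Class counts in every sample are exactly equal.

**Orchestration.** Each sub-network trains on up to 50 randomly chosen
proteins of its range (configurable), on balanced pairs at the range's
separation, optionally capped (`max_pairs_per_subnet`, default 6000) to
bound epoch cost on long chains. The cascade then trains on the
consulted sub-networks' outputs over the same proteins: outputs sit in
the input slots of their sub-network ids (zeros for unconsulted ids),
positions 7–9 carry the (left, own, right) balance weights. A packed
slotting variant (consulted outputs in the first slots) is available via
`slotting="packed"`.

**Balance weights.** Each consulted sub-network is weighted by
1/(1 + |L − midpoint of its range|), missing neighbours get 0, and the
triple is renormalized to sum to 1 — a protein near a range boundary
leans on the adjacent sub-network, one at the midpoint trusts its own.
The weights are a shipped closed-form rule (the notion of "optimized"
weights is otherwise unconstrained); a grid-search refinement hook was
considered and rejected to keep prediction strictly deterministic.

## Thresholds

Per-range decision thresholds convert probabilities into calls. The
shipped defaults (0.1, 0.6, 0.7, 0.7, 0.8, 0.9 for ranges 1–6) apply
when no tuning data is supplied. With training data, each range's
threshold is re-placed at the *coverage knee*: coverage is computed at
every grid threshold, and the chosen threshold is the largest one before
the biggest single-step coverage drop, ties broken toward the smaller
threshold. The default grid is the inner deciles of the score sample so
each step carries equal prediction mass; with a fixed absolute grid, a
weak predictor's unimodal score distribution puts the knee wherever the
distribution happens to be densest, which measures the score scale
rather than the contact structure. An explicit grid can always be
passed. Two threshold sets are stored per bundle — one for raw
sub-network calls, one for cascade calls of proteins routed to each
range — because the two output distributions differ.

## Evaluation protocol

Accuracy = 100·TP/(TP+FP), coverage = 100·TP/(TP+FN), computed per
protein over the separation-masked pair set and macro-averaged.
Undefined scores (an empty prediction set) are excluded from means, not
counted as zero, and the exclusion count is reported. Dispersion is
reported both as sample SD and SE = SD/√n, since the two are easy to
conflate in small summaries. Top-n selection takes the n
highest-probability pairs (ties: smaller i, then j). The comparison
protocol evaluates at n ∈ {⌊T/2⌋, ⌊2T/3⌋, T} with T the total observed
contacts, pooled across the test set by default (per-protein mode
available), and averages the three settings.

## Synthetic data: what it emulates, and what it does not

`synthetic_data` generates compact self-avoiding walks (consecutive
spacing 3.8 ± 0.1 Å, non-consecutive clash floor 3.0 Å) confined to a
sphere of radius 3.2·N^⅓ Å, so local packing density is
length-independent: contacts at separation ≥ 6 grow ~linearly with N
and density falls as ~1/N — the thin-density regime the architecture
targets. Sequences are assigned from burial (inner half hydrophobic,
outer half polar, 8% glycine, 15% assignment noise), so MSA pair
frequencies carry genuine signal: buried–buried pairs are enriched for
hydrophobic pair categories and for contacts. MSA rows are the target
plus copies mutated uniformly over the 19 alternative letters (default
40 rows at rate 0.25, within the ≤ 100-row, < 80%-identity regime the
encoder expects).

What passing tests on this generator demonstrate: the plumbing,
encoding arithmetic, training machinery, routing, thresholding and
scoring are correct, deterministic and internally consistent, and the
cascade genuinely improves over its sub-networks on a corpus with the
right density scaling. What they do not demonstrate: performance on
real proteins. The burial-based sequence signal is far weaker and
simpler than real evolutionary covariation (held-out AUC ≈ 0.6 here);
no secondary-structure annotation, gap structure, or phylogenetic
correlation between MSA rows is modelled.

## Benchmark problem sizes and measured behaviour

The fixed-seed benchmark (`contactcascade.benchmark`, also run by
`scripts/acceptance.py`) uses 6 training + 10 test proteins per range —
60 held-out proteins spanning all six ranges — with lengths evenly
spaced within each range, 40-row MSAs at mutation rate 0.25, balanced
training capped at 3000–6000 pairs per sub-network and a few hundred
epochs; a full run takes a few minutes on one CPU. On this corpus the
cascade's set-level accuracy exceeds the mean sub-network accuracy and
its per-pair ranking (AUC) beats the own sub-network in most ranges,
with the largest gains in the long ranges where the own sub-network is
weakest.

One qualitative pattern of the original architecture is *not*
reproduced under these conditions, and the corresponding test is left
failing rather than weakened: the accuracy-vs-length regression slope
is not flatter for the cascade. With the weak synthetic signal,
per-protein accuracy is approximately lift(L) × base-rate(L) with
base-rate ∝ 1/L for both predictors, so the slope is dominated by the
density term and a uniformly better predictor has an equal-or-steeper
raw slope; flattening requires signal strong enough that thresholded
precision saturates away from the base rate at all lengths.

## Known limitations

* HSSP files themselves are not parsed; the package reads FASTA MSAs
  and a documented HSSP-like plain-text fixture dialect carrying
  per-position DSSP states and conservation weights.
* No mmCIF input, no biological assemblies, no alignment construction.
* The 9-6-1 cascade sees at most three non-zero sub-network outputs by
  design; the six-slot input keeps per-slot semantics fixed.
* Model files are pure JSON (the largest net has 8746 parameters);
  encoding matrices can be cached as `.npy` with a JSON layout
  descriptor for training reuse.
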