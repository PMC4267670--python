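# Methods

This note documents the models and procedures implemented in bicypep, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical conventions used throughout.

## Read processing

**Demultiplexing.** Barcodes are matched exactly at a fixed offset from the
read start (default 0); amplicon designs place the sample barcode
immediately after the sequencing adaptor, which the basecaller removes.
`N` bases never match.  Optional rescue re-tests unmatched reads against
each barcode allowing one substitution, insertion or deletion (Levenshtein
distance 1, computed with edlib); a read is rescued only when exactly one
barcode matches — an equidistant tie is rejected rather than guessed,
because misassignment cross-contaminates selections.  When a trailing-base
deletion is equally explainable as a substitution of the last barcode base,
the substitution interpretation (unshifted trim point) is used; the two are
genuinely indistinguishable.  Rescue is off by default: it recovers few
reads relative to the ambiguity risk.  The trim point travels with the
rescue result because indel matches shift it by ±1.

**Quality filtering.** A whole-read criterion: pass iff at most `max_below`
bases score below `q_threshold`.  The default (Q18, 3) is deliberately
permissive.  Flow-based sequencers assign lower confidence to homopolymer
runs even when they are called correctly, so stricter filters (e.g. Q20, 1)
systematically discard peptides whose codons happen to contain poly-T or
poly-A tracts, biasing the recovered population.  Reads are never
quality-trimmed — a trimmed amplicon read would lose its flanks and become
unparseable anyway.

**Extraction and translation.** The random coding region is the substring
strictly between the first occurrence of the left constant flank and the
first subsequent occurrence of the right flank, accepted if its length is
within configured bounds (defaults 9–45 nt).  Note that flanks must be long
enough to be effectively unique: with a 6-nt flank, roughly 0.7% of 33-nt
random regions contain the flank internally by chance and are truncated at
extraction; the simulations here use 12-nt flanks, matching the length
scale of real constant regions.  Translation uses the standard genetic
code with one amendment: the amber stop TAG is read as glutamine, because
NNK-encoded libraries are propagated in supE suppressor hosts (e.g. TG1)
where TAG inserts Gln.  TAA/TGA cannot occur in NNK codons; a read
containing one (necessarily a sequencing error, or an out-of-frame read)
is discarded, as a truncated fusion cannot display a peptide.  Regions
whose length is not a multiple of three — typically indel-bearing reads —
are likewise discarded at this stage.

## Abundance-based error correction

Random peptide libraries occupy sequence space so sparsely (a library of
10⁸ clones over 10¹² possible NNK octapeptide sequences) that two genuinely
distinct clones essentially never differ by only one or two bases.  A
low-copy sequence within edit distance ≤ `max_mismatch` (default 2) of a
much more abundant clone is therefore attributed to sequencing error.

The algorithm pools nucleotide-level counts across the whole table
(so synonymous error variants of the same peptide are also corrected),
visits sequences in descending count order (ties broken lexicographically),
and merges each sequence into the most abundant already-retained parent
that satisfies both guards:

* distance(parent, seq) ≤ `max_mismatch` — Hamming for equal lengths,
  Levenshtein when lengths differ by ≤ `max_mismatch`;
* accumulated count(parent) ≥ `min_ratio` × count(seq) (default 10×).

The abundance-ratio guard is essential: without it, genuine low-copy
members of a consensus family — which can legitimately differ by 1–2 nt —
would be destroyed.  Observed error clouds around abundant clones show
parent:variant ratios in the hundreds, so 10× is conservative; it is
exposed as a parameter.

The greedy pass repeats until no merge occurs.  A single pass is not a
fixed point: parents accumulate counts while merging, so a pair left
unmerged early in one pass can become mergeable afterwards.  Iterating to
the fixed point makes the operation idempotent (a second application is
exactly the identity), which is the property a correction step should have.
In practice convergence takes one or two passes.  Total read counts are
conserved by construction, and the number of distinct sequences never
increases.  After merging, retained sequences are re-translated and the
table re-ranked.

Equal-length comparisons are vectorized (sequences byte-encoded, Hamming
distances computed against the retained-parent matrix per length class);
cross-length comparisons use edlib with an early cutoff at `max_mismatch`.
Because the ratio guard is checked before any distance computation, the
effective parent set per query is small and 10⁵-read datasets denoise in
seconds.

## Diversity estimation

The rarefaction curve plots y = number of distinct sequences among the
first x reads.  Reads are permuted uniformly at random (`repeats` times,
default 10, seeded) and the distinct counts averaged at `n_points` evenly
spaced depths — file order encodes chip geometry, not biology, so the curve
is made order-invariant by design.  Distinct-prefix counting is O(n log n)
per permutation.

Two nested models are fitted by unweighted nonlinear least squares
(scipy `curve_fit`, bounds a ∈ (0, 2·max y], k > 0, b ∈ [0, 1]):

    y = a (1 − e^(−x/k))           saturating model
    y = a (1 − e^(−x/k)) + b x     saturating + linear error term

`a` estimates the total number of distinct sequences in the sampled pool;
`k` is set by the abundance distribution (more skew → larger k relative to
a); `b` is the per-read error rate — the fraction of reads carrying an
uncorrected error that creates a novel sequence, each of which inflates the
distinct count by ~1, hence linearly in x.  Initialization: a₀ from the
curve maximum with the terminal linear slope (last 20% of points) removed,
k₀ = first depth where y exceeds a₀(1 − e⁻¹), b₀ = that terminal slope.
Failed fits return `converged=False` with NaN parameters rather than
raising; a flat-zero curve cannot satisfy a > 0 and reports
non-convergence.

`diversity_report` fits the error model to the same read stream before and
after error correction (the post-correction stream maps each read to its
merged representative).  On simulated selections the fitted b matches the
measured fraction of erroneous reads, and correction drives it well below
1%, while `a` moves toward the true clone count.  By default curves are
computed at whichever sequence level the caller streams (the pipeline uses
nucleotide level for the before/after comparison; amino-acid level
under-counts errors because synonymous errors create no new peptide).

## Format classification

A peptide's format is its cysteine census: count, loop lengths between
consecutive cysteines, and flanking residue counts.  Three-cysteine
(bicyclic) peptides are sub-labelled `m×n` by their first two loops,
matching library nomenclature.  Statistics are reported both per distinct
peptide and read-weighted; the four cysteine buckets (<3, 3, 4, >4)
partition every table and their fractions sum to 1.

## Consensus clustering and motif search

Pairwise distance between peptides p, q is derived from the global
(Needleman–Wunsch) BLOSUM62 alignment score S with gap open 10 / extend 1:

    d(p, q) = 1 − S(p, q) / min(S(p, p), S(q, q)),  clipped to [0, 1].

This is 0 for identical peptides, symmetric, and ~1 for unrelated ones; it
does not satisfy the triangle inequality, which UPGMA does not require.
Cysteines participate in the distance — they anchor the scaffold and align
families of equal topology.  Peptides of different lengths/formats are
comparable through the alignment, so sub-families with different loop
lengths can co-cluster.

The top `top_n` (default 200) most abundant peptides are clustered:
average-linkage (UPGMA) tree on the distance matrix, cut at `cut_height`
(default 0.55); clusters with ≥ `min_size` (default 3) members become
consensus groups, the rest are singletons.  `cut_height` and `min_size` are
the two tuning knobs — the defaults aim at groups of ~3–20 members.  The
quadratic cost of the distance matrix is why clustering is restricted to
the top of the table; 200 peptides ≈ 20 000 alignments, well under a
second.

Each group gets a position-frequency matrix over the 20 amino acids + gap.
Equal-length members stack positionally; unequal lengths are aligned
progressively in guide-tree leaf order, each new sequence aligned against
the running profile's majority consensus with gap columns propagated into
previously aligned members.  Column sums always equal the member count.

Motif search uses a small pattern language — a letter matches itself,
`[ST]` a residue set, `X` or `.` anything — compiled into per-position
residue sets and scanned directly against every peptide (no regex engine;
an independent regular-expression oracle is used in tests to verify exact
agreement).  Results report the matching peptides in abundance order, the
distinct-match count and the fraction of the read population carrying the
motif.

## Dataset comparison

2–3 tables are stratified by set algebra on amino-acid sequence (optionally
nucleotide level): all-way common (with per-dataset abundances), pairwise
common (3-way case), and per-dataset exclusive.  The strata partition the
union of the inputs.  Round-to-round dynamics report distinct counts, the
fraction of round-1 peptides lost, and the fraction of the round-2 read
population that was present in (or new relative to) round 1.

## Synthetic data

The generator provides ground truth for every stage:

* **Libraries.** Clones are drawn codon-wise from NNK space (any base at
  positions 1–2, G/T at position 3 — all 20 amino acids reachable, amber
  TAG the only stop, read as Gln).  Scaffold cysteines and constant flank
  residues use fixed NNK-compatible codons; a clone whose random positions
  happen to encode an extra cysteine is redrawn so every clone classifies
  as its declared format.  Clones are distinct at the nucleotide level.
* **Selections.** Reads are sampled multinomially under a uniform,
  geometric(p) or Zipf(s) abundance law over the library, emulating the
  strong skew of real selections (where the top 200 clones can hold >80% of
  reads).  Planted consensus families emulate enriched binders: one
  ancestor clone per family, a conserved core implanted at a fixed loop
  position, and each member varying `n_vary` (default 2) randomized
  positions — members are therefore highly similar across the peptide, as
  real consensus-group members are, not merely sharing a short motif.
  Member copy numbers are drawn from a configured range.  Read order is
  shuffled; the ground-truth census and per-family member lists are
  returned alongside.
* **Errors and qualities.** Substitutions occur per base at `sub_rate`
  (`sub_rate_for_read_error_rate` converts a target per-read rate, the
  scale on which sequencing error is usually quoted, 2.8–5.1% in flow
  sequencing of such amplicons).  Indels occur at `indel_rate` per base,
  multiplied by `homopolymer_multiplier` (default 5) inside runs of ≥ 3
  identical bases; an insertion duplicates its base, so indels lengthen or
  shorten runs, the signature flow-call failure mode.  Phred scores are
  drawn from discretized normal laws: correct bases around Q30, erroneous
  bases around Q12, correct-but-homopolymer bases down-shifted by 6 —
  erroneous positions are stochastically lower-quality, and even correct
  homopolymers get less confidence.  These distributions are this
  package's choices, exposed as parameters.  `ErrorModel.zero()` models an
  ideal instrument: no errors and no homopolymer confidence penalty.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: PCR amplification bias and heteroduplex
artifacts, phage propagation bias between rounds, flow-space signal
structure (errors are i.i.d. per base given the run-length profile, real
flow errors are correlated), chip-geometry effects on read order, and
barcode/flank sequencing errors (constant regions are emitted error-free;
barcode-rescue behavior is exercised by explicit constructed variants).
Synthetic validation demonstrates that the algorithms recover what they
are designed to recover under the stated error model; real datasets can
violate that model.

## Validation problem sizes

The test suite and acceptance script validate at these scales, chosen to
exercise the asymptotics while keeping runs short: denoising recovery on
50 uniform clones × 10⁵ reads at ~1% per-read error (recovered exactly);
diversity recovery over replicated selections of 1000 geometric clones ×
10⁵ reads at ~3% per-read error (median |â − a|/a ≈ 1–2%, b̂ within
±0.01 of the measured rate, post-correction b < 0.1%); planted-motif
recovery with 3 families × 20 members among 140 background peptides in a
top-200 clustering; motif search against a regex oracle on 10⁴ peptides ×
20 random patterns; and byte-exact end-to-end recovery of a 200-clone
ground truth through the full pipeline at zero error.

## Numerical conventions and edge cases

* Coordinates are 0-based, half-open; qualities are Phred+33 (Phred+64 is
  not supported).
* All rankings break count ties lexicographically, making every output
  deterministic for a given input and seed; reruns are byte-identical.
* Abundance tables reject inconsistent (peptide, nucleotide) pairs;
  empty inputs yield empty tables (total 0), and empty streams round-trip
  through FASTQ I/O.
* Degenerate fits (flat or all-zero curves) return non-converged results
  rather than raising; pipeline stage failures abort with the stage name.
* Configuration is one JSON document; unknown keys are rejected.

## Known limitations

* Error correction is purely abundance/distance-based; it does not use
  quality scores (no probabilistic error model à la amplicon denoisers).
  Reads with ≥ 3 errors are beyond `max_mismatch=2` and survive as noise —
  negligible at per-read error rates of a few percent, but a consideration
  for per-base error rates approaching 1%.
* No confidence intervals on (a, k, b); the fit is a point estimate.
* The UPGMA height cut is a global threshold; families with very different
  internal diversity may need different `cut_height` values, which is why
  both knobs are exposed.
* Three-cysteine sub-format labels use the first two loops only, following
  library nomenclature; four-cysteine disulfide formats are bucketed but
  not sub-classified.
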