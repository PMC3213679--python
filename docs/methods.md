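# Methods

## Distance model

The distance between two reads is the minimum unit-cost edit distance
over semi-global alignments: substitutions and gap characters cost 1,
matches 0. An `AlignmentPolicy` decides whether gaps at the start
(`anchor_start`) and end (`anchor_end`) of the **shorter** sequence are
charged. The default `(anchor_start=True, anchor_end=False)` anchors
reads at their 5' end and lets the shorter read stop early for free —
the natural model for amplicon reads that begin at a shared primer and
are truncated to varying degrees at the 3' end. `(True, True)` is global
alignment, `(False, False)` frees both ends. Gaps placed in the *longer*
sequence are always charged. `N` never matches any character, including
`N`: base-calling ambiguity is not allowed to create proximity.

Similarity is `s = 1 − c/L` with `c` the alignment cost and `L` the
ungapped length of the shorter sequence. `radius_for(s, L) =
⌊(1 − s)·L⌋` is the largest integer cost that still satisfies the
threshold; the floor makes "similarity ≥ s" literally true for every
admitted member. A `1e-9` epsilon absorbs binary-float error in
`(1 − s)·L` (e.g. `0.1 × 50` evaluating just below 5); the epsilon only
matters when `(1 − s)·L` is within one part in 10⁹ of an integer, far
below any meaningful precision of a user-supplied threshold.

**Asymmetry.** The semi-global measure is not symmetric: the free end
gaps belong to the subject role, which matters when both sequences have
the same length. Inside the algorithm the orientation is always fixed
(the cluster representative, the longest remaining read, is the query),
so every stated guarantee uses that orientation. For *member-to-member*
statements (the diameter bound below) the package uses
`symmetric_cost`, the minimum over both role assignments — the
orientation-free version of the measure.

## Banded threshold alignment

Costs are computed row by row with the three-way recurrence (diagonal +
match/mismatch, left + 1, up + 1). Because the cost of aligned prefixes
never decreases along a diagonal, a cell can only be within threshold
`d` if its diagonal predecessor is; each new row is therefore computed
only on `[lo, hi+1]` of the previous row's finite interval, everything
else is stored as a saturating sentinel `INF = d + 1`. The banded values
are bit-identical to the full-table values wherever the full value is
≤ d (property-tested against an unbanded oracle and edlib). A row whose
finite interval empties is dead, and dead rows are absorbing. `[lo, hi]`
is maintained as the bounding interval of finite entries rather than
assuming the finite set is contiguous, which keeps the update sound
without relying on contiguity.

Traceback re-runs the rows and walks back deterministically: diagonal
over subject-gap over query-gap at equal cost, and with a free 3' end
the leftmost minimal final column is chosen, so trailing query residues
appear as explicit free end-gap columns. Co-optimal alignments exist;
this tie-break picks one reproducibly.

## Exact radius search over the implicit trie

Candidates are kept in lexicographic order (any comparison sort;
ordering, not algorithm, is the contract). The prefix tree of the list
is never materialized: a stack of DP rows represents the path to the
current candidate, consecutive candidates share `lcp` rows (computed
once, adjacent pairs only), and when a pushed row dies at depth α every
following candidate whose common prefix is at least α is skipped without
any work. The stack never exceeds the longest candidate, and the number
of row computations is bounded by the total candidate length (prefix
sharing only saves work).

Two radii are distinguished: the **band radius** that prunes the descent
(the radius of the longest possible candidate — the center's own), and
the per-candidate **accept radius** `radius_for(s, len(candidate))`
checked at each leaf. A subtree's candidate lengths are unknown during
the descent, so the band must be the loosest radius any candidate could
need; the leaf check restores per-length tightness. Candidates longer
than the query are never eligible and are skipped defensively (the
greedy loop guarantees none is active).

## k-mer screen and filter tree

If candidate `s` is within edit distance `d` of a substring of query `q`
(what any accepted semi-global alignment means), each edit destroys at
most `k` of the candidate's k-mers, hence
`pos(spectrum_k(s) − spectrum_k(q)) ≤ k·d`. The screen rejects a pair
only when that inequality fails, so it is completely sensitive. The
candidate's spectrum must be the minuend: the longer query may own
arbitrarily many k-mers the candidate lacks. k-mers containing `N` are
not counted; on the candidate side that only lowers the left-hand sum
(safe), while dropped query windows would inflate it, so a query whose
spectrum lost windows disables the screen rather than risk a false
rejection.

The filter tree covers contiguous intervals of the lex-sorted list; a
node stores element-wise lower and upper bounds of the covered spectra
and the covered length range. In **exact** mode a node is pruned only
when the lower bound violates the inequality — then every covered
sequence does, so no true hit is lost, and clustering with the tree is
bit-identical to clustering without it. In **approximate** mode a node
is additionally pruned when the optimistic shared-k-mer count
`Σ min(query, upper)` falls short of what the shortest eligible covered
sequence would need with the edit budget tightened by one
(`(min(min_len, |q|) − k + 1) − k·max(d−1, 0)`). A true hit whose edits
all have full k-mer impact sits exactly at `k·d` and can fail the
tightened budget, so the mode is lossy; because the requirement follows
the shortest covered length it stays robust to free 3' truncations.
Lossiness can only *split* clusters (the searcher still verifies every
survivor), never corrupt them. Default `k = 3`; with a 4^k-dimensional
dense count vector, small k keeps tree nodes cheap, and the screen's
power at high similarity comes from the `k·d` budget rather than from
long words.

## Greedy clustering and the well-separated variant

Reads are processed in non-increasing length order (ties broken by
residues, then id — a total order, so the entire output is a
deterministic function of the input). Each unclustered read in turn
becomes a representative, recruits every active read within its
per-length radius, and recruited reads are never revisited. Validity
(property 1) holds by construction; exactness (property 2) follows from
search completeness: a would-be representative within threshold of an
earlier one would already have been recruited.

The well-separated variant searches to twice the radius, recruits within
the radius, and *flags* reads in the annulus (radius, 2·radius]; flagged
reads cannot seed clusters but remain recruitable. Flagged reads that
are never recruited are emitted as singleton clusters marked
`leftover` — well-separated clusterings do not always exist, and
singletons preserve the partition without weakening the separation of
the real representatives. A flagged read longer than every later
representative can never be recruited (members may not exceed their
representative's length) and always ends as a leftover.

**Diameter.** For any two members of one cluster the star alignment
induces an alignment whose policy-charged cost is at most the sum of the
two member costs, hence ≤ 2·radius. The free end region of that induced
alignment always matches one of the two query/subject orientations, so
the bound is guaranteed for `symmetric_cost` (and for the column-wise
distance in the star MSA). The raw one-orientation cost between two
equal-length members can exceed the bound by charging an overhang the
hub alignment leaves free; this is a property of the measure's
asymmetry, not of the clustering.

## Star multiple alignment

Member-versus-representative pairwise alignments are byproducts of the
search. Reconciliation allocates, before each representative position
(and after the last), an insertion block as wide as the longest
insertion any member places there; members left-justify their run and
pad with gaps ("once a gap, always a gap"). Left-justification is a
deterministic convention; any fixed justification within the block
satisfies the same guarantees. Rows degap to the original reads, and the
column-charged distance between any two rows — free end regions
following the alignment policy — is at most twice the cluster radius.
Output is aligned multi-FASTA with `-` gaps, representative first.

## Synthetic data generator

`generate_clouds` emulates the regime the tool targets: a few distinct
template molecules observed many times with sequencing errors.
Templates are uniform random sequences (default 200–260 bp, matching
~230 bp pyrosequencing amplicons), rejection-sampled until pairwise
semi-global distance exceeds twice the largest admissible radius, so
each cloud is recoverable as exactly one cluster. Reads apply
`Binomial(L, mutation_rate)` charged edits (75% substitutions, 25%
internal deletions; default rate 0.005), capped so the count never
exceeds the radius granted by the read's own final length, plus a free
3' truncation of up to 10% of the template. Any erroneous read loses at
least one base, so the template is always the longest (and among equals
lexicographically first) read of its cloud — this is what makes greedy
longest-first recovery exact, and mirrors truncated-read error profiles.
Insertions are deliberately not generated: a read longer than its
template could seed its cloud's cluster before the template and recovery
of the planted partition would no longer be guaranteed.

What the generator does **not** emulate: chimeras, `N` calls,
homopolymer-specific error structure, abundance skew between templates,
and clouds that overlap or straddle the threshold. Passing the
planted-recovery tests therefore shows the machinery is exact under
separated-cloud conditions; it does not certify biological clustering
quality on real surveys, where cloud separation is an empirical
question.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` exercise: 50 random search
instances of 200–500 sequences (lengths 30–60) against a brute-force
oracle under two policies; 10⁴ mutated pairs per (k, d) grid point,
k ∈ {3..6}, d ∈ {0..5}, for filter sensitivity (2 × 10³ per point in the
faster script variant); 20 seeded cloud configurations for recovery; and
one 10,000-read set (50 templates × 199 reads, 0.99 similarity) for the
exact-versus-approximate comparison. These sizes keep a full run in the
tens of seconds on one CPU while covering every guarantee at the scale
it is claimed. Integer saturating arithmetic (`INF = d+1`) avoids
overflow; all RNG flows through `numpy.random.default_rng` seeds;
there is no randomness anywhere in the clustering path itself.

## Known limitations

- The search assumes the query is at least as long as every active
  candidate; it is exposed as a library function but tuned for the
  clusterer's invariant.
- The filter tree's bounds are computed once over all sequences; as
  clustering deactivates reads the bounds grow stale (pruning weakens,
  correctness is unaffected).
- Pure-Python row updates: throughput is roughly 10⁴ reads of ~250 bp
  clustered in a few seconds; the design (sorted list + row stack)
  scales further but this implementation is not tuned for
  million-read inputs.
- Abundance-based center ordering, database-search mode and parallel
  execution are out of scope.
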