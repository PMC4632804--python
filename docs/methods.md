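# Methods

## The model

`dnassign` simulates a test-tube computation in the Adleman–Lipton
model. State is a *tube*: a multiset of single-stranded DNA molecules.
Twelve laboratory primitives act on tubes — merge, copy, detect,
separation by subsequence, selection by exact length, sorting into
shortest/longest classes, annealing, ligation, denaturation, discard,
read-out of one molecule, and tail appending. The simulator works at
the *word* level: a strand is an ordered sequence of named
oligonucleotide words (delimiters `s`/`e`, individual words `A_i`, job
words `B_j`, weight words `w_ij`) rather than raw bases. This is exact
for the algorithm being simulated, whose filtering logic only ever
inspects word-level motifs; the base-level identity of words matters
only for the sequence-design and thermodynamics layers, which are
separate modules.

Assumptions inherited from the model and kept deliberately:

* every primitive is error-free and complete (no mis-hybridization, no
  lost molecules) — the simulator is a *correctness* instrument, not an
  error-rate model;
* annealing/ligation/denaturation are not simulated base pair by base
  pair. The pool-construction phase is modeled as the exhaustive set of
  all k-fold edge concatenations followed by length selection — exactly
  the molecule set the chemistry is claimed to produce — and is
  accounted as its six constituent primitives in the operation counter;
* copy numbers never influence answers (the pipeline acts on supports);
  multiplicities are nevertheless tracked so conservation laws can be
  tested exactly.

Two simulator-side determinism choices replace laboratory
nondeterminism: `read` returns the lexicographically least atom
sequence, and the sort operation sends a single-length tube entirely to
the "shortest" output (the pipeline only ever consumes the shortest
class).

## The solving pipeline

For an m×n integer cost matrix (m < n, entries ≥ 0) the five steps are
pool generation, per-job motif filtering (`e B_k`), per-individual
motif filtering (`s A_i e`), per-edge weight appending (`w_ij`, length
c_ij·u), and shortest-strand selection. Exact closed forms verified by
the tests: the pool holds (mn)ⁿ strands, the job filter leaves n!·mⁿ,
the individual filter n!·S(m,n) where S is the surjection count
Σ(−1)ᵏC(m,k)(m−k)ⁿ. Solution strands number (number of optimal
assignments)·n!, one per edge ordering.

The job-presence motif is `e B_k` (two words). The three-word variant
`e B_k s` would never match a strand's final edge and would discard
every strand, so the two-word motif is the only reading consistent with
the published intermediate tube listings; the individual motif
`s A_i e` is used literally. The per-individual loop runs i = 1..m.

Operation accounting: every primitive increments a counter shared along
the tube lineage. Pool construction contributes 6, each job-filter
iteration 4 (separate, discard, copy, discard), each individual-filter
iteration 4, each matrix cell 5 (separate, detect, append, merge,
discard — the detect is always "yes" after step 3, because every edge
(i,j) occurs in some onto assignment when m < n), and the final
sort + read 2. Total: 8 + 4n + 4m + 5mn, linear in mn; the tests check
the formula exactly and by least-squares fit over a grid.

Tunable parameters: `t` (unit word length, mer; default 5 — matches the
bundled codeword table), `u` (mer per cost unit, default 1; raise it to
stretch length differences), `pool_cap` (default 10⁷ strands; the
pipeline refuses larger pools and points users to the oracle, since
(mn)ⁿ enumeration is the method). Costs must be nonnegative integers —
lengths are integral; a zero cost yields a zero-length weight word that
is kept in the symbolic strand (so decoding still sees the edge's tail
entry) but is invisible in nucleotide encodings.

## The oracle

`oracle.brute_force_min` enumerates all mⁿ job→individual mappings,
keeps the onto ones, and minimizes the summed cost. It shares no code
with the strand machinery, accepts real-valued costs, and is the
reference for every pipeline answer; the acceptance suite checks exact
agreement (minimum and full optimum set) on 200 seeded random instances
over m ∈ {2,3}, n ∈ {3,4,5} with costs 0..9 — sizes chosen so the full
(mn)ⁿ pools (up to 15⁵ = 759,375 strands) run in seconds each.

## Synthetic instances

`instances.random_instance(m, n, lo, hi, seed)` draws i.i.d. uniform
integer costs via numpy's seeded generator. Uniform integer costs in
0..9 emulate the small hand-built demo matrices (whose entries span
1..9); they do not emulate structured real workloads (correlated rows,
skill sparsity, heavy-tailed durations). Passing tests therefore
demonstrate algorithmic correctness over the full discrete cost space
at these sizes, not performance or robustness on application-scale
data — the method itself is exponential by construction.

## Sequence design

Codewords are generated greedily: propose a random t-mer over the
library alphabet {A, T, C}, then repair by successive single-base
mutations until constraints hold or a mutation threshold (default 100)
aborts. Constraints (all configurable): three-letter library alphabet,
no homopolymer run longer than four, pairwise distinctness (optionally
a minimum Hamming distance between equal-length words), and an optional
G-count window for probes — off by default because it is meaningless
for 5-mer probes.

Two weight-word modes exist because the algorithm and the wet-lab table
pull in different directions. *Algorithmic* mode gives `w_ij` length
c_ij·u, as length-encoding requires; those words are inert spacers that
never serve as probe targets, so distinctness is enforced against the
recognition words but not among the spacers themselves (with many small
costs over a three-letter alphabet spacer collisions are unavoidable —
there are only three 1-mers). *Labeled* mode makes every word a t-mer;
tail identity, not length, then carries the cost label, so labeled
weights are held to full distinctness — the bundled demo table's
w_1_3/w_2_4 collision is reported as exactly one violation. The demo
codeword FASTA reproduces a published reference table verbatim,
including that collision.

Encoded strands are stored 3′→5′ as in the reference listings; the
reverse-complement helpers make orientation explicit for probes and
linkers (`linker_and_probe_set` exports the reverse complements of the
`e·B_j·s` junctions plus the `B_j` probe words). Decoding parses the
edge section on the fixed 4-word frame and the weight tail by
backtracking over the weight words of the edges actually present, in
sorted (i,j) order — the order the appending loop uses — so pipeline
strands round-trip exactly; zero-length weight words cannot be
recovered from nucleotides.

## Thermodynamics

Duplex stability uses the nearest-neighbor model: ΔH and ΔS are sums of
stacked-dinucleotide contributions plus terminal initiation terms, and
ΔG(T) = ΔH − T·ΔS/1000 (ΔH kcal/mol, ΔS cal/mol/K, T kelvin; default
310.15 K). Values are reported as positive binding magnitudes, the
convention of probe-capture energy tables. The default parameter set is
the SantaLucia (1998) unified oligonucleotide table at 1 M NaCl; any
complete 16-stack table can be substituted. The symmetry correction for
self-complementary duplexes, salt/concentration corrections, mismatches
and dangling ends are omitted: the module scores perfect-match
probe/library duplexes only, and reported magnitudes are comparative.
Published energy tables for this design were produced with an unstated
parameter set and are treated as layout references, not numeric
targets; the module's own numbers are verified instead by identity,
additivity, reverse-complement-symmetry and independent-recomputation
tests. Summary statistics use the sample standard deviation (ddof = 1).

## Numerical and degenerate-input choices

* All arithmetic is integer except thermodynamics (float, tolerances
  1e−9 in tests) and the oracle's optional real-valued costs.
* Empty tube: `read` and sorting raise; selection/separation return
  empty partitions.
* m ≥ n is rejected everywhere as "not an unbalanced instance"; m = 1
  is legal (the single individual takes every job).
* All randomness (instance generation, codeword design) flows through
  explicit integer seeds; identical configuration implies identical
  output, including the read-out exemplar strand.

## Known limitations

* The pipeline is exponential by design; the pool cap (10⁷) limits it
  to roughly n ≤ 5 at m = 3. Larger instances belong to the oracle.
* Hybridization errors, secondary structure, and melting-curve
  prediction are out of scope; the design constraints are the only
  error-mitigation layer modeled.
* The compact strand notation (`sA1eB3…w13…`) assumes single-digit
  indices; programmatic construction has no such limit.
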