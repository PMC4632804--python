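# dnassign

An exact, deterministic in-silico simulator of a DNA molecular-computing
algorithm for the **unbalanced assignment problem** (UAP), aimed at
researchers in biomolecular computation and combinatorial optimization
who want to study, test, or extend test-tube algorithms without a wet
lab.

## The problem and the molecular algorithm

The UAP assigns *n* jobs to *m* < *n* individuals with cost matrix
A = [c_ij]: each job goes to exactly one individual, every individual
receives at least one job (so each load lies in [1, n−m+1]), and the
total cost

&nbsp;&nbsp;&nbsp;&nbsp;min Z = Σᵢ Σⱼ c_ij·x_ij

is minimized. It is solved here the way a DNA computer would, in the
Adleman–Lipton model of tube operations:

1. **Pool** — assemble all (mn)ⁿ single strands of the form
   (s·A_i·e·B_j)ⁿ, where the edge word *sA_i eB_j* spells "job j is
   assigned to individual i" and s/e are delimiter words; every word is
   *t* mer long, so each pool strand is 4nt mer.
2. **Job filter** — for each job k, keep only strands containing the
   motif *eB_k*; on n-edge strands this forces every job exactly once.
3. **Individual filter** — for each individual i, keep only strands
   containing *sA_i e*; every individual gets at least one job.
4. **Weight tails** — for each edge (i, j) present in a strand, append
   a weight word *w_ij* of length c_ij·u mer. Strand length now equals
   4nt + u·(total assignment cost).
5. **Shortest strands** — sort by length and read the shortest tube:
   those molecules spell exactly the optimal assignments.

Strand length L always obeys 4tn ≤ L ≤ (4t+y)n with y = u·max c_ij, and
the whole run costs O(mn) tube operations (the simulator's counter fits
8 + 4n + 4m + 5mn exactly). An independent brute-force oracle
(enumeration of all onto job→individual mappings) cross-checks every
answer.

The package also covers the wet-lab design layer: codeword generation
over the three-letter alphabet {A, T, C} with homopolymer-run and
distinctness constraints, nucleotide encoding of solution strands,
probe/linker export, and nearest-neighbor duplex thermodynamics
(ΔH, ΔS, ΔG = ΔH − T·ΔS/1000) for probe/library hybridization using the
SantaLucia 1998 unified parameter table.

## Worked example

The bundled 2×3 demo instance has cost matrix

|      | j1 | j2 | j3 |
|------|----|----|----|
| i1   | 2  | 4  | 1  |
| i2   | 1  | 2  | 3  |

```sh
$ dnassign demo 2x3
stage counts: pool=216 jobs_filtered=48 individuals_filtered=36 solution=6
op count: 58
min cost: 4
assignment: {j1->i2, j2->i2, j3->i1} cost=4
oracle agreement: yes (oracle min 4)
```

Reading the output: the pool held (2·3)³ = 216 strands; 48 survived the
job filter (3!·2³), 36 the individual filter (3!·(2³−2)); the six
shortest weighted strands are the 3! orderings of the optimal edge set
{(1,3), (2,1), (2,2)}, all with weight tail w13·w21·w22 of total added
length 1+1+2 = 4 — the minimum cost. The 3×5 demo (`dnassign demo 3x5`)
runs the 759,375-strand pool and prints min cost 17 with the unique
assignment {j1→i3, j2→i2, j3→i1, j4→i1, j5→i3}.

The same workflow from Python:

```python
from dnassign import EXAMPLE_3X5, solve, brute_force_min
result = solve(EXAMPLE_3X5)          # five molecular steps, exactly
result.min_cost                      # 17
best, optima = brute_force_min(EXAMPLE_3X5)   # independent cross-check
assert (best, optima) == (result.min_cost, result.optimal_assignments)
```

Other subcommands: `dnassign solve matrix.csv [--json out.json --dna
code.fasta]`, `dnassign oracle matrix.csv`, `dnassign design --costs
matrix.csv -o code.fasta`, `dnassign thermo code.fasta -o energies.tsv`,
and `dnassign random` for seeded synthetic instances.

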