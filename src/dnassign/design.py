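"""Constraint-based DNA codeword design and symbolic -> nucleotide encoding.

Library strands assembled from the codewords must hybridize cleanly with
their probes, so the words are generated under sequence constraints:
library words use only the three-letter alphabet {A, T, C} (less
secondary structure, better probe binding), no word carries a
homopolymer run longer than four bases (runs skew melting temperatures
and can fold), all words are pairwise distinct, and an optional G-count
window can be imposed on probe sequences to even out probe melting
temperatures.  Words are drawn at random and repaired by successive
single-base mutations until the constraints hold or a mutation threshold
is reached — the classic greedy generate-and-mutate design loop.

Two weight-word conventions coexist:

* ``algorithmic`` — the weight word ``w_ij`` is ``c_ij * u`` bases long,
  as the length-encoding algorithm requires (strand length = cost);
* ``labeled`` — every word, weights included, is a t-mer; useful for
  compact wet-lab export where the tail identities, not lengths, carry
  the cost labels.

Orientation note: sequences are stored and printed 3'->5' as is
conventional for these library tables; the reverse-complement helpers
make orientation explicit where it matters (probes, linkers).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

from Bio.Seq import Seq
from Bio.SeqIO import parse as fasta_parse
from Bio.SeqIO import write as fasta_write
from Bio.SeqRecord import SeqRecord

from .pipeline import CostMatrix
from .strands import (
    KIND_E,
    KIND_IND,
    KIND_JOB,
    KIND_S,
    KIND_WT,
    SymbolAtom,
    SymbolicStrand,
)

__all__ = [
    "ConstraintSet",
    "DNACode",
    "Violation",
    "DesignError",
    "gen_codeword",
    "build_code",
    "validate_code",
    "encode_strand",
    "decode_nucleotides",
    "linker_and_probe_set",
    "reverse_complement",
    "complement",
    "write_code_fasta",
    "read_code_fasta",
    "load_demo_code",
]


class DesignError(RuntimeError):
    """Sequence design failed (constraints unsatisfiable within threshold)."""


@dataclass(frozen=True)
class ConstraintSet:
    """The active sequence-design constraints.

    alphabet: bases allowed in library words (default A/T/C only).
    max_run: longest allowed homopolymer run ("no runs of more than
        four" means a run of exactly four is still legal).
    probe_g_range: optional inclusive (lo, hi) G-count window applied to
        probe sequences; off by default — 5-mer probes cannot carry
        four G's, the rule only makes sense for longer probes.
    require_distinct: enforce pairwise-distinct words.
    min_hamming: minimum Hamming distance between equal-length words
        (1 = distinctness only).
    max_mutations: single-base repair attempts before giving up.
    """

    alphabet: tuple = ("A", "T", "C")
    max_run: int = 4
    probe_g_range: tuple | None = None
    require_distinct: bool = True
    min_hamming: int = 1
    max_mutations: int = 100

    def __post_init__(self):
        if self.max_run < 1:
            raise ValueError("max_run must be >= 1")
        if not self.alphabet:
            raise ValueError("alphabet must be nonempty")
        if self.min_hamming < 1:
            raise ValueError("min_hamming must be >= 1")


def _max_run(word: str) -> int:
    best = run = 0
    prev = None
    for base in word:
        run = run + 1 if base == prev else 1
        prev = base
        best = max(best, run)
    return best


def word_satisfies(word: str, cs: ConstraintSet) -> bool:
    """Alphabet and homopolymer-run check for a single library word."""
    if any(b not in cs.alphabet for b in word):
        return False
    return _max_run(word) <= cs.max_run


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def gen_codeword(t: int, cs: ConstraintSet, rng_seed) -> str:
    """Generate one t-mer satisfying the constraint set.

    A random proposal is repaired by successive single-base mutations; if
    ``cs.max_mutations`` mutations do not produce a satisfying word the
    design fails.  ``rng_seed`` may be an integer seed or a
    ``random.Random`` instance; the same seed yields the same word.
    """
    if t < 0:
        raise ValueError("word length must be nonnegative")
    if t == 0:
        return ""
    rng = rng_seed if isinstance(rng_seed, random.Random) else random.Random(rng_seed)
    word = [rng.choice(cs.alphabet) for _ in range(t)]
    mutations = 0
    while not word_satisfies("".join(word), cs):
        if mutations >= cs.max_mutations:
            raise DesignError(
                f"design failed after threshold of {cs.max_mutations} mutations"
            )
        word[rng.randrange(t)] = rng.choice(cs.alphabet)
        mutations += 1
    return "".join(word)


@dataclass
class DNACode:
    """Concrete nucleotide words for every symbol of an instance.

    ``weights[(i, j)]`` holds the word for ``w_ij``; in ``algorithmic``
    mode its length is ``c_ij * u``, in ``labeled`` mode it is a t-mer
    like every other word.
    """

    s: str
    e: str
    individuals: tuple  # words for A_1..A_m
    jobs: tuple  # words for B_1..B_n
    weights: dict  # (i, j) -> word
    t: int
    mode: str = "algorithmic"

    def __post_init__(self):
        if self.mode not in ("algorithmic", "labeled"):
            raise ValueError("mode must be 'algorithmic' or 'labeled'")

    @property
    def m(self) -> int:
        return len(self.individuals)

    @property
    def n(self) -> int:
        return len(self.jobs)

    def word_for(self, atom: SymbolAtom) -> str:
        if atom.kind == KIND_S:
            return self.s
        if atom.kind == KIND_E:
            return self.e
        if atom.kind == KIND_IND:
            return self.individuals[atom.index_i - 1]
        if atom.kind == KIND_JOB:
            return self.jobs[atom.index_j - 1]
        if atom.kind == KIND_WT:
            return self.weights[(atom.index_i, atom.index_j)]
        raise KeyError(f"no word for atom {atom!r}")

    def items(self):
        """(record id, word) pairs in canonical order (FASTA layout)."""
        yield "s", self.s
        yield "e", self.e
        for i, word in enumerate(self.individuals, start=1):
            yield f"A{i}", word
        for j, word in enumerate(self.jobs, start=1):
            yield f"B{j}", word
        for (i, j) in sorted(self.weights):
            yield f"w_{i}_{j}", self.weights[(i, j)]

    def edge_word(self, i: int, j: int) -> str:
        """The 4t-mer spelling the edge strand ``s A_i e B_j``."""
        return self.s + self.individuals[i - 1] + self.e + self.jobs[j - 1]


class Violation(NamedTuple):
    """One violated design constraint."""

    kind: str  # alphabet | run | length | distinct | hamming | probe_g
    ids: tuple  # offending record id(s)
    detail: str


def build_code(
    costs: CostMatrix | None = None,
    m: int | None = None,
    n: int | None = None,
    t: int = 5,
    u: int = 1,
    mode: str = "algorithmic",
    cs: ConstraintSet = ConstraintSet(),
    seed: int = 0,
) -> DNACode:
    """Design a full codeword set for an instance.

    ``algorithmic`` mode needs the cost matrix (weight lengths are
    c_ij * u); ``labeled`` mode needs only the dimensions.  Words are
    generated in a fixed order from a single seeded stream, each checked
    against the constraints and against all previously accepted words
    (distinctness / minimum Hamming distance), so the same seed always
    yields the same code.
    """
    if costs is not None:
        m, n = costs.m, costs.n
    if mode == "algorithmic" and costs is None:
        raise ValueError("algorithmic mode needs the cost matrix")
    if m is None or n is None:
        raise ValueError("need a cost matrix or explicit dimensions")
    rng = random.Random(seed)
    chosen: list = []  # (id, word, is_spacer)

    # Algorithmic-mode weight words are inert length-coding spacers that
    # are never probe targets, so they may repeat among themselves (with
    # small costs over a three-letter alphabet they must); they still
    # must differ from every recognition word.  Labeled-mode weights
    # carry the cost *identity* in their spelling and stay strict.
    def next_word(record_id: str, length: int, is_spacer: bool = False) -> str:
        if length == 0:
            return ""  # zero-cost weight: empty word, exempt from distinctness
        for _ in range(1000):
            word = gen_codeword(length, cs, rng)
            if cs.require_distinct and any(
                w == word for _, w, spacer in chosen
                if w and not (is_spacer and spacer)
            ):
                continue
            if cs.min_hamming > 1 and any(
                len(w) == len(word) and _hamming(w, word) < cs.min_hamming
                for _, w, spacer in chosen
                if w and not (is_spacer and spacer)
            ):
                continue
            chosen.append((record_id, word, is_spacer))
            return word
        raise DesignError(f"could not find a distinct word for {record_id}")

    s = next_word("s", t)
    e = next_word("e", t)
    individuals = tuple(next_word(f"A{i}", t) for i in range(1, m + 1))
    jobs = tuple(next_word(f"B{j}", t) for j in range(1, n + 1))
    weights = {}
    spacer = mode == "algorithmic"
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            length = costs.c(i, j) * u if mode == "algorithmic" else t
            weights[(i, j)] = next_word(f"w_{i}_{j}", length, is_spacer=spacer)
    return DNACode(s, e, individuals, jobs, weights, t=t, mode=mode)


def validate_code(
    code: DNACode,
    cs: ConstraintSet = ConstraintSet(),
    costs: CostMatrix | None = None,
    u: int = 1,
) -> list:
    """Check every codeword against the constraint set.

    Returns a list of :class:`Violation` records; an empty list means the
    code is valid.  Alphabet/run rules apply to library words; the
    optional G-count window applies to probe sequences (the complements
    of the job words).  Weight-word lengths are checked against the cost
    matrix when one is supplied (algorithmic mode) or against t
    (labeled mode).
    """
    violations: list = []
    entries = list(code.items())
    for rec_id, word in entries:
        if not word:
            continue
        if any(b not in cs.alphabet for b in word):
            bad = sorted({b for b in word if b not in cs.alphabet})
            violations.append(
                Violation("alphabet", (rec_id,), f"{word} uses {','.join(bad)}")
            )
        if _max_run(word) > cs.max_run:
            violations.append(
                Violation("run", (rec_id,), f"{word} has a run longer than {cs.max_run}")
            )

    for rec_id, word in entries:
        expected = None
        if not rec_id.startswith("w_"):
            expected = code.t
        elif code.mode == "labeled":
            expected = code.t
        elif costs is not None:
            _, i, j = rec_id.split("_")
            expected = costs.c(int(i), int(j)) * u
        if expected is not None and len(word) != expected:
            violations.append(
                Violation("length", (rec_id,), f"{word or '(empty)'} is {len(word)} nt, expected {expected}")
            )

    if cs.require_distinct:
        # In algorithmic mode weight words are length-coding spacers:
        # collisions among them are harmless (they are never probe
        # targets), so only collisions involving a recognition word — or
        # any collision in labeled mode — are violations.
        spacers_ok = code.mode == "algorithmic"
        by_word: dict = {}
        for rec_id, word in entries:
            if word:
                by_word.setdefault(word, []).append(rec_id)
        for word, ids in by_word.items():
            if len(ids) > 1:
                if spacers_ok and all(rid.startswith("w_") for rid in ids):
                    continue
                violations.append(
                    Violation("distinct", tuple(ids), f"share the word {word}")
                )
    if cs.min_hamming > 1:
        nonempty = [(rid, w) for rid, w in entries if w]
        for idx, (rid_a, a) in enumerate(nonempty):
            for rid_b, b in nonempty[idx + 1 :]:
                if len(a) == len(b) and 0 < _hamming(a, b) < cs.min_hamming:
                    violations.append(
                        Violation(
                            "hamming",
                            (rid_a, rid_b),
                            f"Hamming distance {_hamming(a, b)} < {cs.min_hamming}",
                        )
                    )
    if cs.probe_g_range is not None:
        lo, hi = cs.probe_g_range
        for j, word in enumerate(code.jobs, start=1):
            probe = complement(word)
            g = probe.count("G")
            if not (lo <= g <= hi):
                violations.append(
                    Violation(
                        "probe_g",
                        (f"B{j}",),
                        f"probe {probe} has {g} G, outside [{lo}, {hi}]",
                    )
                )
    return violations


def encode_strand(strand: SymbolicStrand, code: DNACode) -> str:
    """Concatenate the codewords of a strand's atoms (3'->5' as stored)."""
    try:
        return "".join(code.word_for(a) for a in strand.atoms)
    except (KeyError, IndexError) as exc:
        raise KeyError(f"strand atom without a codeword: {exc}") from exc


def decode_nucleotides(seq: str, code: DNACode) -> SymbolicStrand:
    """Parse an encoded library strand back into its symbolic atoms.

    The edge section is unambiguous (fixed 4-word frame keyed on the
    start delimiter); the weight tail is parsed by backtracking over the
    nonempty weight words, trying (i, j) in sorted order — the order the
    weight-appending loop uses — so pipeline strands round-trip exactly.
    Zero-length weight words are invisible and cannot be recovered.
    """
    t = code.t
    ind_words = {w: i for i, w in enumerate(code.individuals, start=1)}
    job_words = {w: j for j, w in enumerate(code.jobs, start=1)}
    atoms: list = []
    pos = 0
    while seq.startswith(code.s, pos):
        a_word = seq[pos + t : pos + 2 * t]
        e_word = seq[pos + 2 * t : pos + 3 * t]
        b_word = seq[pos + 3 * t : pos + 4 * t]
        if a_word not in ind_words or e_word != code.e or b_word not in job_words:
            raise ValueError(f"cannot parse edge at base {pos}")
        atoms.append(SymbolAtom.s(t))
        atoms.append(SymbolAtom.individual(ind_words[a_word], t))
        atoms.append(SymbolAtom.e(t))
        atoms.append(SymbolAtom.job(job_words[b_word], t))
        pos += 4 * t
    if not atoms:
        raise ValueError("sequence does not start with the start delimiter")

    # The weight tail holds one word per edge spelled in the edge
    # section (the appending loop visits (i, j) in sorted order), so the
    # tail is parsed against those words only — this keeps the parse
    # unambiguous even when spacer words repeat elsewhere in the code.
    edge_pairs = set()
    idx = 0
    while idx < len(atoms):
        edge_pairs.add((atoms[idx + 1].index_i, atoms[idx + 3].index_j))
        idx += 4
    tail_words = [
        (ij, code.weights[ij]) for ij in sorted(edge_pairs) if code.weights.get(ij)
    ]

    def parse_tail(p: int):
        if p == len(seq):
            return []
        for (i, j), w in tail_words:
            if seq.startswith(w, p):
                rest = parse_tail(p + len(w))
                if rest is not None:
                    return [SymbolAtom.weight(i, j, len(w))] + rest
        return None

    tail = parse_tail(pos)
    if tail is None:
        raise ValueError(f"cannot parse weight tail starting at base {pos}")
    return SymbolicStrand(atoms + tail)


# ----------------------------------------------------------------------
# Orientation helpers and the probe/linker export
# ----------------------------------------------------------------------

def complement(seq: str) -> str:
    """Base-wise Watson-Crick complement (no reversal)."""
    return str(Seq(seq).complement())


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def linker_and_probe_set(code: DNACode) -> dict:
    """The hybridization helper set Q for pool assembly and job capture.

    One linker per job — the reverse complement of the junction word
    ``e B_j s`` that anneals across two abutting edges — plus the job
    probe words ``B_j`` themselves.  Returned as an ordered dict keyed
    ``linker_B1``, ``probe_B1``, ... for FASTA export.
    """
    out: dict = {}
    for j, b_word in enumerate(code.jobs, start=1):
        out[f"linker_B{j}"] = reverse_complement(code.e + b_word + code.s)
    for j, b_word in enumerate(code.jobs, start=1):
        out[f"probe_B{j}"] = b_word
    return out


# ----------------------------------------------------------------------
# FASTA I/O
# ----------------------------------------------------------------------

def write_code_fasta(code: DNACode, path) -> None:
    """Write the codeword table as FASTA (ids s, e, A1.., B1.., w_i_j)."""
    records = [
        SeqRecord(Seq(word), id=rec_id, description=f"mode={code.mode} t={code.t}")
        for rec_id, word in code.items()
    ]
    fasta_write(records, str(path), "fasta")


def read_code_fasta(path, mode: str | None = None) -> DNACode:
    """Load a codeword table from FASTA.

    The unit length t is taken from the start-delimiter word.  The mode
    is read from the record descriptions when present, else inferred:
    labeled if every weight word is a t-mer.
    """
    words: dict = {}
    desc_mode = None
    for rec in fasta_parse(str(path), "fasta"):
        words[rec.id] = str(rec.seq)
        for tokenised in rec.description.split():
            if tokenised.startswith("mode="):
                desc_mode = tokenised.split("=", 1)[1]
    if "s" not in words or "e" not in words:
        raise ValueError("code FASTA must contain records 's' and 'e'")
    t = len(words["s"])
    individuals = []
    i = 1
    while f"A{i}" in words:
        individuals.append(words[f"A{i}"])
        i += 1
    jobs = []
    j = 1
    while f"B{j}" in words:
        jobs.append(words[f"B{j}"])
        j += 1
    if not individuals or not jobs:
        raise ValueError("code FASTA must contain A1.. and B1.. records")
    weights = {}
    for rec_id, word in words.items():
        if rec_id.startswith("w_"):
            _, wi, wj = rec_id.split("_")
            weights[(int(wi), int(wj))] = word
    if mode is None:
        mode = desc_mode
    if mode is None:
        mode = (
            "labeled"
            if weights and all(len(w) == t for w in weights.values())
            else "algorithmic"
        )
    return DNACode(
        words["s"], words["e"], tuple(individuals), tuple(jobs), weights, t=t, mode=mode
    )


def load_demo_code() -> DNACode:
    """The packaged labeled-mode demo codeword table for the 3x5 instance."""
    from importlib.resources import as_file, files

    with as_file(files("dnassign") / "data" / "demo_code.fasta") as path:
        return read_code_fasta(path, mode="labeled")
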