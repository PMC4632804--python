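"""Symbolic strand and test-tube algebra for the Adleman–Lipton model.

A DNA computation in the Adleman–Lipton model manipulates *tubes* —
multisets of single-stranded DNA molecules — with a small set of
laboratory primitives (merge, copy, detect, separation by subsequence,
selection by length, sorting by length, appending a tail, reading out one
molecule).  This module implements those primitives over *symbolic*
strands: ordered sequences of named oligonucleotide words (``s``, ``e``,
``A_i``, ``B_j``, ``w_ij``) rather than raw nucleotides.  Working at the
word level keeps every operation exact and deterministic; the mapping of
words onto concrete A/C/G/T sequences lives in :mod:`dnassign.design`.

Strand lengths are tracked in *mer* (one base = one mer).  The delimiter
words ``s``/``e`` and the individual/job words ``A_i``/``B_j`` all share a
configured unit length ``t``; a weight word ``w_ij`` carries the cost of
assigning job *j* to individual *i* as its length, so the total length of
a strand encodes the total cost of the assignment it spells out.

Every tube carries a shared operation counter, incremented once per
primitive applied, so a pipeline built from these primitives can account
for its operation count (the O(mn) scaling claim is tested against it).
"""

from __future__ import annotations

import itertools
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "SymbolAtom",
    "SymbolicStrand",
    "Tube",
    "OpCounter",
    "TubeUsageError",
    "merge",
    "copy",
    "detect",
    "discard",
    "separation",
    "selection",
    "sort_split",
    "append_tail",
    "anneal_ligate_pool",
    "read",
    "parse_strand_label",
]


class TubeUsageError(ValueError):
    """A tube primitive was applied outside its contract."""


# Atom kinds. Ranks order atoms the way they appear inside an edge
# (s A_i e B_j), giving a natural lexicographic order on strands.
KIND_S = "s"
KIND_IND = "A"
KIND_E = "e"
KIND_JOB = "B"
KIND_WT = "w"

_KIND_RANK = {KIND_S: 0, KIND_IND: 1, KIND_E: 2, KIND_JOB: 3, KIND_WT: 4}

# First code point used for interned atom characters. Any block of unused
# code points works; strand keys are internal and never shown to users.
_CHAR_BASE = 0x2100


class SymbolAtom:
    """One named single-stranded DNA word (``s``, ``e``, ``A_i``, ``B_j`` or ``w_ij``).

    Atoms are interned: constructing the same (kind, indices, length)
    twice yields the identical object, and each atom owns a unique
    single-character code so a strand can be stored as a compact string
    and motif containment becomes a C-speed substring search.
    """

    __slots__ = ("kind", "index_i", "index_j", "length_mer", "_char", "_rank")

    _registry: dict = {}
    _by_char: dict = {}

    def __new__(cls, kind, index_i=None, index_j=None, length_mer=None):
        key = (kind, index_i, index_j, length_mer)
        cached = cls._registry.get(key)
        if cached is not None:
            return cached
        if kind not in _KIND_RANK:
            raise ValueError(f"unknown atom kind {kind!r}")
        if not isinstance(length_mer, int):
            raise ValueError("length_mer must be an integer number of mer")
        if kind == KIND_WT:
            if length_mer < 0:
                raise ValueError("weight atom length must be >= 0 mer")
            if not (index_i and index_j):
                raise ValueError("weight atom needs individual and job indices")
        else:
            if length_mer < 1:
                raise ValueError("atom length must be a positive number of mer")
        if kind == KIND_IND and not index_i:
            raise ValueError("individual atom needs index_i >= 1")
        if kind == KIND_JOB and not index_j:
            raise ValueError("job atom needs index_j >= 1")
        if kind in (KIND_S, KIND_E) and (index_i or index_j):
            raise ValueError("delimiter atoms carry no indices")

        atom = object.__new__(cls)
        object.__setattr__(atom, "kind", kind)
        object.__setattr__(atom, "index_i", index_i)
        object.__setattr__(atom, "index_j", index_j)
        object.__setattr__(atom, "length_mer", length_mer)
        char = chr(_CHAR_BASE + len(cls._registry))
        object.__setattr__(atom, "_char", char)
        object.__setattr__(
            atom, "_rank", (_KIND_RANK[kind], index_i or 0, index_j or 0, length_mer)
        )
        cls._registry[key] = atom
        cls._by_char[char] = atom
        return atom

    def __setattr__(self, name, value):  # pragma: no cover - guard
        raise AttributeError("SymbolAtom is immutable")

    # -- constructors -------------------------------------------------
    @classmethod
    def s(cls, t: int = 5) -> "SymbolAtom":
        """Start delimiter word, length ``t`` mer."""
        return cls(KIND_S, length_mer=t)

    @classmethod
    def e(cls, t: int = 5) -> "SymbolAtom":
        """Edge-internal delimiter word, length ``t`` mer."""
        return cls(KIND_E, length_mer=t)

    @classmethod
    def individual(cls, i: int, t: int = 5) -> "SymbolAtom":
        """Word ``A_i`` naming individual ``i``."""
        return cls(KIND_IND, index_i=i, length_mer=t)

    @classmethod
    def job(cls, j: int, t: int = 5) -> "SymbolAtom":
        """Word ``B_j`` naming job ``j``."""
        return cls(KIND_JOB, index_j=j, length_mer=t)

    @classmethod
    def weight(cls, i: int, j: int, length_mer: int) -> "SymbolAtom":
        """Weight word ``w_ij``; its length encodes the assignment cost."""
        return cls(KIND_WT, index_i=i, index_j=j, length_mer=length_mer)

    # -- presentation -------------------------------------------------
    @property
    def label(self) -> str:
        if self.kind == KIND_S:
            return "s"
        if self.kind == KIND_E:
            return "e"
        if self.kind == KIND_IND:
            return f"A{self.index_i}"
        if self.kind == KIND_JOB:
            return f"B{self.index_j}"
        return f"w{self.index_i}{self.index_j}"

    def __repr__(self) -> str:
        return f"<atom {self.label} {self.length_mer}mer>"


class SymbolicStrand:
    """An ordered sequence of :class:`SymbolAtom` words.

    Internally a strand is the string of its atoms' interned characters,
    so equality, hashing and motif containment are string operations.
    Total length in mer is cached lazily.
    """

    __slots__ = ("_key", "_length")

    def __init__(self, atoms: Iterable[SymbolAtom]):
        atoms = tuple(atoms)
        if not atoms:
            raise ValueError("a strand needs at least one atom")
        self._key = "".join(a._char for a in atoms)
        self._length = sum(a.length_mer for a in atoms)

    @classmethod
    def _from_key(cls, key: str, length: int | None = None) -> "SymbolicStrand":
        obj = object.__new__(cls)
        obj._key = key
        obj._length = length
        return obj

    @property
    def atoms(self) -> tuple:
        by_char = SymbolAtom._by_char
        return tuple(by_char[c] for c in self._key)

    @property
    def length_mer(self) -> int:
        if self._length is None:
            by_char = SymbolAtom._by_char
            self._length = sum(by_char[c].length_mer for c in self._key)
        return self._length

    def sort_key(self):
        """Deterministic ordering key: the tuple of atom ranks."""
        by_char = SymbolAtom._by_char
        return tuple(by_char[c]._rank for c in self._key)

    def contains_motif(self, motif: Sequence[SymbolAtom]) -> bool:
        """True iff ``motif`` occurs as a contiguous atom subsequence."""
        return _motif_key(motif) in self._key

    def append(self, atom: SymbolAtom) -> "SymbolicStrand":
        return SymbolicStrand._from_key(
            self._key + atom._char, self.length_mer + atom.length_mer
        )

    def edges(self) -> list:
        """The (i, j) pairs spelled by the strand's ``s A_i e B_j`` edges.

        Raises :class:`ValueError` if the strand does not match the pool
        grammar ``(s A_i e B_j)+ (w_ij)*``.
        """
        atoms = self.atoms
        pairs = []
        pos = 0
        while pos < len(atoms) and atoms[pos].kind == KIND_S:
            if pos + 3 >= len(atoms):
                raise ValueError("truncated edge in strand")
            a_s, a_i, a_e, a_j = atoms[pos : pos + 4]
            if a_i.kind != KIND_IND or a_e.kind != KIND_E or a_j.kind != KIND_JOB:
                raise ValueError("strand does not match the edge grammar")
            pairs.append((a_i.index_i, a_j.index_j))
            pos += 4
        if not pairs:
            raise ValueError("strand has no edges")
        for atom in atoms[pos:]:
            if atom.kind != KIND_WT:
                raise ValueError("trailing atoms must be weight words")
        return pairs

    def weight_atoms(self) -> tuple:
        return tuple(a for a in self.atoms if a.kind == KIND_WT)

    def is_pool_strand(self) -> bool:
        """Whether the strand matches the grammar ``(s A e B)+ (w)*``."""
        try:
            self.edges()
        except ValueError:
            return False
        return True

    def __eq__(self, other):
        return isinstance(other, SymbolicStrand) and self._key == other._key

    def __hash__(self):
        return hash(self._key)

    def __str__(self) -> str:
        return "".join(a.label for a in self.atoms)

    def __repr__(self) -> str:
        return f"<strand {self} ({self.length_mer} mer)>"


def _motif_key(motif: Sequence[SymbolAtom]) -> str:
    if isinstance(motif, SymbolicStrand):
        return motif._key
    motif = tuple(motif)
    if not motif:
        raise TubeUsageError("empty motif")
    return "".join(a._char for a in motif)


class OpCounter:
    """Shared mutable count of primitive operations applied to a tube line."""

    __slots__ = ("count",)

    def __init__(self, count: int = 0):
        self.count = count

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"OpCounter({self.count})"


class Tube:
    """A multiset of :class:`SymbolicStrand` with an operation counter.

    Tubes produced by a primitive share the input tube's counter, so a
    pipeline's final tube reports the total number of primitives applied
    along the way (``op_count``).
    """

    __slots__ = ("_contents", "counter", "_discarded")

    def __init__(
        self,
        strands: Iterable[SymbolicStrand] | Mapping[SymbolicStrand, int] | None = None,
        counter: OpCounter | None = None,
    ):
        self._contents: dict = {}
        self.counter = counter if counter is not None else OpCounter()
        self._discarded = False
        if strands is not None:
            if isinstance(strands, Mapping):
                for s, c in strands.items():
                    self.add(s, c)
            else:
                for s in strands:
                    self.add(s)

    def add(self, strand: SymbolicStrand, count: int = 1) -> None:
        if count < 1:
            raise ValueError("count must be positive")
        self._contents[strand] = self._contents.get(strand, 0) + count

    @property
    def contents(self) -> Mapping[SymbolicStrand, int]:
        return self._contents

    @property
    def op_count(self) -> int:
        return self.counter.count

    def __len__(self) -> int:
        """Total number of molecules (with multiplicity)."""
        return sum(self._contents.values())

    def distinct_count(self) -> int:
        return len(self._contents)

    def __iter__(self) -> Iterator[SymbolicStrand]:
        return iter(self._contents)

    def __contains__(self, strand) -> bool:
        return strand in self._contents

    def _check_active(self) -> None:
        if self._discarded:
            raise TubeUsageError("operation on a discarded tube")

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Tube {len(self)} molecules, {self.distinct_count()} distinct>"


# ----------------------------------------------------------------------
# Primitive operations.  Each call increments the operated tube's shared
# counter exactly once; output tubes share that counter.
# ----------------------------------------------------------------------

def merge(t1: Tube, t2: Tube) -> Tube:
    """Pour ``t2`` into ``t1``; ``t1`` holds the multiset union, ``t2`` is empty."""
    t1._check_active()
    t2._check_active()
    for s, c in t2._contents.items():
        t1._contents[s] = t1._contents.get(s, 0) + c
    t2._contents.clear()
    t1.counter.count += 1
    return t1


def copy(t1: Tube) -> Tube:
    """Produce a new tube with the same multiset contents as ``t1``."""
    t1._check_active()
    t1.counter.count += 1
    return Tube(dict(t1._contents), counter=t1.counter)


def detect(t: Tube) -> bool:
    """True ("yes") iff the tube contains at least one strand."""
    t._check_active()
    t.counter.count += 1
    return len(t._contents) > 0


def discard(t: Tube) -> None:
    """Throw the tube away; further operations on it are usage errors."""
    t._check_active()
    t._contents.clear()
    t._discarded = True
    t.counter.count += 1


def separation(
    t1: Tube, motifs: Iterable[Sequence[SymbolAtom]]
) -> tuple[Tube, Tube]:
    """Split ``t1`` by motif containment.

    Strands containing at least one of ``motifs`` as a contiguous atom
    subsequence move to the returned matched tube; ``t1`` keeps the rest.
    Both readings of the laboratory operation (keep-if-contains and
    remove-if-contains) are available since both output tubes are
    returned.  Conservation: the two outputs partition the input exactly.
    """
    t1._check_active()
    motif_keys = [_motif_key(m) for m in motifs]
    if not motif_keys:
        raise TubeUsageError("separation requires at least one motif")
    matched: dict = {}
    remaining: dict = {}
    if len(motif_keys) == 1:
        mk = motif_keys[0]
        for s, c in t1._contents.items():
            if mk in s._key:
                matched[s] = c
            else:
                remaining[s] = c
    else:
        for s, c in t1._contents.items():
            key = s._key
            if any(mk in key for mk in motif_keys):
                matched[s] = c
            else:
                remaining[s] = c
    t1._contents = remaining
    t1.counter.count += 1
    return t1, Tube(matched, counter=t1.counter)


def selection(t1: Tube, length_mer: int) -> tuple[Tube, Tube]:
    """Split ``t1`` by exact strand length (in mer)."""
    t1._check_active()
    if length_mer <= 0:
        raise TubeUsageError("selection length must be positive")
    selected: dict = {}
    remaining: dict = {}
    for s, c in t1._contents.items():
        if s.length_mer == length_mer:
            selected[s] = c
        else:
            remaining[s] = c
    t1._contents = remaining
    t1.counter.count += 1
    return t1, Tube(selected, counter=t1.counter)


def sort_split(t1: Tube) -> tuple[Tube, Tube, Tube]:
    """Split off the shortest and longest strands of ``t1``.

    Returns ``(rest, shortest, longest)``.  When all strands share one
    length they all go to the shortest tube and the longest tube is
    empty: the algorithm's consumers only ever need the shortest class.
    """
    t1._check_active()
    if not t1._contents:
        raise TubeUsageError("nothing to sort")
    lengths = [s.length_mer for s in t1._contents]
    lo, hi = min(lengths), max(lengths)
    shortest: dict = {}
    longest: dict = {}
    rest: dict = {}
    for s, c in t1._contents.items():
        ln = s.length_mer
        if ln == lo:
            shortest[s] = c
        elif ln == hi:
            longest[s] = c
        else:
            rest[s] = c
    t1._contents = rest
    t1.counter.count += 1
    return t1, Tube(shortest, counter=t1.counter), Tube(longest, counter=t1.counter)


def append_tail(t: Tube, z: SymbolAtom) -> Tube:
    """Append the word ``z`` to the end of every strand in the tube."""
    t._check_active()
    if not isinstance(z, SymbolAtom):
        raise TubeUsageError("append_tail needs a SymbolAtom")
    t._contents = {s.append(z): c for s, c in t._contents.items()}
    t.counter.count += 1
    return t


def anneal_ligate_pool(edge_units: Iterable[SymbolicStrand], k: int) -> Tube:
    """Assemble the combinatorial pool of all k-edge concatenations.

    Models the pool-construction phase — merging the edge and linker
    libraries, annealing, ligation, denaturation, separation on the start
    delimiter and selection at the full edge length — as the exhaustive
    set of ``|edges|**k`` concatenations that chemistry is claimed to
    yield.  Counts as the six primitives it stands for.
    """
    edge_units = list(edge_units)
    if not edge_units:
        raise TubeUsageError("edge set must be nonempty")
    if k < 1:
        raise TubeUsageError("edge count k must be >= 1")
    edge_keys = [e._key for e in edge_units]
    if len(set(edge_keys)) != len(edge_keys):
        raise TubeUsageError("edge units must be distinct")
    lengths = {e._key: e.length_mer for e in edge_units}
    uniform = len(set(lengths.values())) == 1
    unit_len = edge_units[0].length_mer if uniform else None
    contents: dict = {}
    from_key = SymbolicStrand._from_key
    if uniform:
        total = unit_len * k
        for combo in itertools.product(edge_keys, repeat=k):
            contents[from_key("".join(combo), total)] = 1
    else:  # pragma: no cover - pool edges are uniform in the pipeline
        for combo in itertools.product(edge_keys, repeat=k):
            contents[from_key("".join(combo), sum(lengths[c] for c in combo))] = 1
    return Tube(contents, counter=OpCounter(6))


def read(t: Tube) -> SymbolicStrand:
    """Describe exactly one molecule from the tube.

    The laboratory operation is nondeterministic over molecules; for
    reproducibility this simulator returns the lexicographically least
    atom sequence.
    """
    t._check_active()
    if not t._contents:
        raise TubeUsageError("no strand to read")
    t.counter.count += 1
    return min(t._contents, key=SymbolicStrand.sort_key)


# ----------------------------------------------------------------------
# Text notation, e.g. "sA1eB3sA2eB1sA2eB2w13w21w22" (single-digit indices).
# ----------------------------------------------------------------------

def parse_strand_label(
    label: str,
    t: int = 5,
    weight_length=None,
) -> SymbolicStrand:
    """Parse the compact text notation for a strand.

    ``weight_length`` maps an ``(i, j)`` pair to the mer length of the
    weight word ``w_ij`` (a callable or a mapping); it defaults to ``t``
    for every weight, matching the labeled encoding.  Indices in the
    notation are single digits.
    """
    if weight_length is None:
        wlen = lambda i, j: t  # noqa: E731
    elif callable(weight_length):
        wlen = weight_length
    else:
        wlen = lambda i, j: weight_length[(i, j)]  # noqa: E731

    atoms = []
    pos = 0
    while pos < len(label):
        ch = label[pos]
        if ch == "s":
            atoms.append(SymbolAtom.s(t))
            pos += 1
        elif ch == "e":
            atoms.append(SymbolAtom.e(t))
            pos += 1
        elif ch == "A":
            atoms.append(SymbolAtom.individual(int(label[pos + 1]), t))
            pos += 2
        elif ch == "B":
            atoms.append(SymbolAtom.job(int(label[pos + 1]), t))
            pos += 2
        elif ch == "w":
            i, j = int(label[pos + 1]), int(label[pos + 2])
            atoms.append(SymbolAtom.weight(i, j, wlen(i, j)))
            pos += 3
        else:
            raise ValueError(f"cannot parse strand label at {label[pos:]!r}")
    return SymbolicStrand(atoms)
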