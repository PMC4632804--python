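"""Nearest-neighbor duplex thermodynamics for probe/library hybridization.

The stability of a perfectly matched DNA duplex is modelled as a sum of
stacked-dinucleotide contributions plus initiation terms at the two
duplex ends (the nearest-neighbor, NN, model):

    dH = sum of stack enthalpies + terminal initiations
    dS = sum of stack entropies + terminal initiations
    dG(T) = dH - T * dS / 1000        (dH in kcal/mol, dS in cal/mol/K)

Energies are reported as *positive binding magnitudes* (the negatives of
the formation quantities), the sign convention used for probe-capture
energy tables.  The default parameter set is the unified oligonucleotide
NN table of SantaLucia (1998), at 1 M NaCl; any complete table can be
plugged in instead.  Salt/concentration corrections, mismatches and
dangling ends are out of scope — duplexes here are perfect matches
between a probe and its library region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DuplexEnergy",
    "NNParameterTable",
    "SANTALUCIA_1998",
    "DEFAULT_TEMPERATURE_K",
    "duplex_energy",
    "energy_table",
    "write_energy_tsv",
]

DEFAULT_TEMPERATURE_K = 310.15  # 37 degrees C

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class NNParameterTable:
    """Complete (dH, dS) contributions for the 16 stacks plus initiation.

    ``stacks`` maps a 5'->3' dinucleotide of one strand to the formation
    (dH kcal/mol, dS cal/mol/K) of that stack with its complement;
    ``initiation`` maps a terminal base to its duplex-initiation term.
    """

    name: str
    stacks: Mapping[str, tuple]
    initiation: Mapping[str, tuple]

    def __post_init__(self):
        expected = {a + b for a in "ACGT" for b in "ACGT"}
        missing = expected - set(self.stacks)
        if missing:
            raise ValueError(f"incomplete stack table, missing {sorted(missing)}")
        if set(self.initiation) != _BASES:
            raise ValueError("initiation table must cover A, C, G, T")


def _unified_stacks() -> dict:
    # Ten unique stack parameters; the other six follow from the
    # equivalence of a stack and its reverse complement.
    unique = {
        "AA": (-7.9, -22.2),
        "AT": (-7.2, -20.4),
        "TA": (-7.2, -21.3),
        "CA": (-8.5, -22.7),
        "GT": (-8.4, -22.4),
        "CT": (-7.8, -21.0),
        "GA": (-8.2, -22.2),
        "CG": (-10.6, -27.2),
        "GC": (-9.8, -24.4),
        "GG": (-8.0, -19.9),
    }
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    full = dict(unique)
    for stack, value in unique.items():
        rc = comp[stack[1]] + comp[stack[0]]
        full.setdefault(rc, value)
    return full


#: Unified oligonucleotide NN parameters (SantaLucia 1998), 1 M NaCl.
SANTALUCIA_1998 = NNParameterTable(
    name="santalucia-1998-unified",
    stacks=_unified_stacks(),
    initiation={
        "G": (0.1, -2.8),
        "C": (0.1, -2.8),
        "A": (2.3, 4.1),
        "T": (2.3, 4.1),
    },
)


@dataclass(frozen=True)
class DuplexEnergy:
    """Binding magnitudes for one duplex at temperature T.

    dH in kcal/mol, dS in cal/(mol K), dG in kcal/mol; all positive for
    a stable duplex, with dG = dH - T * dS / 1000 holding exactly.
    """

    dH: float
    dS: float
    dG: float
    T: float


def duplex_energy(
    seq: str,
    temperature: float = DEFAULT_TEMPERATURE_K,
    params: NNParameterTable = SANTALUCIA_1998,
) -> DuplexEnergy:
    """NN enthalpy, entropy and free energy of the perfect-match duplex of ``seq``.

    ``seq`` is one strand of the duplex; the result is identical for the
    reverse-complement strand (NN stack symmetry).
    """
    seq = seq.upper()
    if any(b not in _BASES for b in seq):
        bad = sorted({b for b in seq if b not in _BASES})
        raise ValueError(f"invalid base(s) {bad} in sequence")
    if len(seq) < 2:
        raise ValueError("no stacks: need at least two bases")
    h = s = 0.0
    for idx in range(len(seq) - 1):
        dh, ds = params.stacks[seq[idx : idx + 2]]
        h += dh
        s += ds
    for terminal in (seq[0], seq[-1]):
        dh, ds = params.initiation[terminal]
        h += dh
        s += ds
    dH = -h
    dS = -s
    return DuplexEnergy(dH=dH, dS=dS, dG=dH - temperature * dS / 1000.0, T=temperature)


def energy_table(
    code,
    edges: Iterable[tuple] | None = None,
    temperature: float = DEFAULT_TEMPERATURE_K,
    params: NNParameterTable = SANTALUCIA_1998,
) -> tuple:
    """Per-edge duplex energies plus their summary statistics.

    One row per edge strand ``s A_i e B_j`` with its (dH, dS, dG)
    binding magnitudes, and a summary frame holding the column means and
    standard deviations (sample, ddof=1) over all probe/library
    interactions.  Returns ``(table, summary)`` as pandas DataFrames.
    """
    if edges is None:
        edges = [(i, j) for i in range(1, code.m + 1) for j in range(1, code.n + 1)]
    rows = []
    index = []
    for i, j in edges:
        energy = duplex_energy(code.edge_word(i, j), temperature, params)
        rows.append((energy.dH, energy.dS, energy.dG))
        index.append(f"sA{i}eB{j}")
    table = pd.DataFrame(rows, index=index, columns=["dH", "dS", "dG"])
    summary = pd.DataFrame(
        [table.mean(), table.std(ddof=1)],
        index=["Average", "Standard Deviation"],
    )
    return table, summary


def write_energy_tsv(table: pd.DataFrame, summary: pd.DataFrame, path) -> None:
    """Write the energy table and its summary rows as one TSV."""
    combined = pd.concat([table, summary])
    combined.to_csv(path, sep="\t", index_label="edge", float_format="%.4f")
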