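"""Genetic-code bookkeeping shared by the codon-model modules.

The universal (standard) genetic code is used throughout; the state space of
every codon model here is the 61 sense codons, indexed alphabetically.  Stop
codons appearing in data are treated as errors, never silently dropped.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
GAP_CODON = "---"

_standard = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS: frozenset[str] = frozenset(_standard.stop_codons)

#: the 61 sense codons, alphabetical; defines the model state space
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in ("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3))
           if c not in STOP_CODONS)
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
N_CODONS = len(SENSE_CODONS)  # 61

AMINO_ACID: dict[str, str] = {c: _standard.forward_table[c] for c in SENSE_CODONS}

_PURINES = {"A", "G"}


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a<->b is a transition."""
    return (a in _PURINES) == (b in _PURINES)


def _neighbour_table():
    """All ordered sense-codon pairs differing at exactly one position.

    Returns index arrays (i, j) plus boolean transition / synonymous flags;
    this is the sparsity structure of every GY94-style rate matrix.
    """
    ii, jj, ts, syn = [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for pos in range(3):
            for nt in NUCLEOTIDES:
                if nt == ci[pos]:
                    continue
                cj = ci[:pos] + nt + ci[pos + 1:]
                if cj in STOP_CODONS:
                    continue
                j = CODON_INDEX[cj]
                ii.append(i)
                jj.append(j)
                ts.append(is_transition(ci[pos], nt))
                syn.append(AMINO_ACID[ci] == AMINO_ACID[cj])
    return (np.array(ii), np.array(jj),
            np.array(ts, dtype=bool), np.array(syn, dtype=bool))


NEIGHBOUR_I, NEIGHBOUR_J, NEIGHBOUR_TS, NEIGHBOUR_SYN = _neighbour_table()


def codons_of(seq: str) -> list[str]:
    """Split an in-frame nucleotide string into codons."""
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    return [seq[k:k + 3] for k in range(0, len(seq), 3)]


def encode_codons(seq: str, *, allow_gaps: bool = True) -> np.ndarray:
    """Encode an in-frame sequence as codon-state indices; gaps/ambiguity -> -1.

    Raises on in-frame stop codons: they indicate a frame error upstream.
    """
    out = np.empty(len(seq) // 3, dtype=np.int64)
    for k, codon in enumerate(codons_of(seq.upper())):
        if codon in CODON_INDEX:
            out[k] = CODON_INDEX[codon]
        elif codon in STOP_CODONS:
            raise ValueError(f"in-frame stop codon {codon!r} at codon {k}")
        elif allow_gaps:
            out[k] = -1  # gap or ambiguous: pairwise-deleted downstream
        else:
            raise ValueError(f"unexpected codon {codon!r} at codon {k}")
    return out


def f3x4_frequencies(seqs: list[str], floor: float = 1e-6) -> np.ndarray:
    """F3x4 codon frequencies from position-specific nucleotide counts.

    Counts A/C/G/T separately at the three codon positions over all supplied
    in-frame sequences (gap codons skipped), forms the product frequency of
    every sense codon and renormalises over the 61-codon state space.  A small
    floor keeps unobserved codons at positive frequency so the rate matrix
    stays irreducible.
    """
    counts = np.zeros((3, 4))
    lookup = {n: i for i, n in enumerate(NUCLEOTIDES)}
    for seq in seqs:
        for codon in codons_of(seq.upper()):
            if any(ch not in lookup for ch in codon):
                continue
            for pos, ch in enumerate(codon):
                counts[pos, lookup[ch]] += 1
    if counts.sum() == 0:
        raise ValueError("no countable codons for F3x4 estimation")
    pos_freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array([
        pos_freqs[0, lookup[c[0]]] * pos_freqs[1, lookup[c[1]]] * pos_freqs[2, lookup[c[2]]]
        for c in SENSE_CODONS
    ])
    pi = np.maximum(pi, floor)
    return pi / pi.sum()


def f3x4_from_position_freqs(pos_freqs: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """F3x4 codon frequencies from a given 3x4 nucleotide frequency table."""
    pos_freqs = np.asarray(pos_freqs, dtype=float)
    if pos_freqs.shape != (3, 4):
        raise ValueError("expected a 3x4 table of position-specific frequencies")
    lookup = {n: i for i, n in enumerate(NUCLEOTIDES)}
    pi = np.array([
        pos_freqs[0, lookup[c[0]]] * pos_freqs[1, lookup[c[1]]] * pos_freqs[2, lookup[c[2]]]
        for c in SENSE_CODONS
    ])
    pi = np.maximum(pi, floor)
    return pi / pi.sum()


def gc3_percent(seq: str) -> float:
    """Percentage of G or C at third codon positions over ungapped codons."""
    third = [c[2] for c in codons_of(seq.upper()) if all(ch in NUCLEOTIDES for ch in c)]
    if not third:
        raise ValueError("no ungapped codons for GC3")
    return 100.0 * sum(ch in "GC" for ch in third) / len(third)
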