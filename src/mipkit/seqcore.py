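"""Nucleotide string utilities and nearest-neighbor duplex thermodynamics.

This module carries the low-level primitives the probe designer scores arm
candidates with: reverse complementation, GC content, homopolymer runs,
double-stranded motif search (for type IIS restriction sites) and a
nearest-neighbor melting-temperature model.

The thermodynamic model is the unified nearest-neighbor parameter set
(SantaLucia-style dinucleotide enthalpies/entropies with duplex initiation
terms), with an entropic monovalent-salt correction and a fixed total strand
concentration. All constants live on :class:`ThermoModel` so an alternative
parameter set can be swapped in without touching the calculator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

__all__ = [
    "revcomp",
    "gc_percent",
    "max_homopolymer_run",
    "find_motif_both_strands",
    "ThermoModel",
    "DEFAULT_THERMO",
    "melting_temp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")
_ACGT = frozenset("ACGT")

# Unified nearest-neighbor stack parameters for DNA/DNA duplexes:
# ΔH° in kcal/mol, ΔS° in cal/(mol·K), 1 M NaCl reference.
# Only the 10 unique stacks are stored; the other 6 dinucleotides resolve
# through reverse-complement symmetry (e.g. "TG" -> "CA").
_NN_DH: Mapping[str, float] = MappingProxyType({
    "AA": -7.9, "AT": -7.2, "TA": -7.2,
    "CA": -8.5, "GT": -8.4, "CT": -7.8, "GA": -8.2,
    "CG": -10.6, "GC": -9.8, "GG": -8.0,
})
_NN_DS: Mapping[str, float] = MappingProxyType({
    "AA": -22.2, "AT": -20.4, "TA": -21.3,
    "CA": -22.7, "GT": -22.4, "CT": -21.0, "GA": -22.2,
    "CG": -27.2, "GC": -24.4, "GG": -19.9,
})


def _validate(seq: str, alphabet: frozenset[str], what: str = "sequence") -> None:
    for i, base in enumerate(seq):
        if base not in alphabet:
            raise ValueError(
                f"invalid character {base!r} at position {i} in {what}"
            )


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string (involution)."""
    _validate(seq, _VALID)
    return seq.translate(_COMPLEMENT)[::-1]


def gc_percent(seq: str) -> float:
    """GC content as a percentage in [0, 100]; rejects empty input."""
    if not seq:
        raise ValueError("gc_percent of empty sequence is undefined")
    _validate(seq, _ACGT)
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest run of identical consecutive bases."""
    if not seq:
        raise ValueError("max_homopolymer_run of empty sequence is undefined")
    best = run = 1
    prev = seq[0]
    for base in seq[1:]:
        run = run + 1 if base == prev else 1
        prev = base
        if run > best:
            best = run
    return best


def find_motif_both_strands(seq: str, motif: str) -> list[tuple[int, str]]:
    """All start positions of ``motif`` on either strand of ``seq``.

    Returns 0-based start positions on the given (Watson) coordinate system,
    tagged ``"+"`` for a forward occurrence and ``"-"`` where the reverse
    complement of the motif occurs (i.e. the motif sits on the Crick strand).
    Overlapping hits are reported. For a palindromic motif both orientations
    coincide and each position is reported once, as ``"+"``.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    _validate(seq, _VALID)
    _validate(motif, _VALID, "motif")
    hits: list[tuple[int, str]] = []
    rc = revcomp(motif)
    for pattern, strand in ((motif, "+"), (rc, "-")):
        if strand == "-" and rc == motif:
            break  # palindrome: minus-strand hits duplicate the plus ones
        start = seq.find(pattern)
        while start != -1:
            hits.append((start, strand))
            start = seq.find(pattern, start + 1)
    hits.sort()
    return hits


@dataclass(frozen=True)
class ThermoModel:
    """Nearest-neighbor duplex model constants.

    Parameters
    ----------
    nn_dh, nn_ds:
        Stacking enthalpies (kcal/mol) and entropies (cal/mol·K) for the 10
        unique dinucleotide stacks; the remaining 6 resolve by
        reverse-complement symmetry.
    init_dh_at, init_ds_at, init_dh_gc, init_ds_gc:
        Duplex initiation terms applied once per terminal base pair.
    sym_ds:
        Entropy penalty for self-complementary duplexes.
    c_t:
        Total strand concentration in mol/L (non-self-complementary duplexes
        use C_T/4 in the Tm denominator).
    na:
        Monovalent cation concentration in mol/L; the salt correction
        0.368·(N−1)·ln[Na+] is added to ΔS°.
    r:
        Gas constant in cal/(mol·K).
    """

    nn_dh: Mapping[str, float] = field(default_factory=lambda: _NN_DH)
    nn_ds: Mapping[str, float] = field(default_factory=lambda: _NN_DS)
    init_dh_at: float = 2.3
    init_ds_at: float = 4.1
    init_dh_gc: float = 0.1
    init_ds_gc: float = -2.8
    sym_ds: float = -1.4
    c_t: float = 0.25e-6
    na: float = 0.05
    r: float = 1.987

    def __post_init__(self) -> None:
        if self.c_t <= 0:
            raise ValueError("total strand concentration must be positive")
        if self.na <= 0:
            raise ValueError("salt concentration must be positive")
        for dinuc in ("AA AC AG AT CA CC CG CT GA GC GG GT TA TC TG TT".split()):
            self.stack(dinuc)  # all 16 lookups must resolve

    def stack(self, dinuc: str) -> tuple[float, float]:
        """(ΔH°, ΔS°) for one stack, resolving symmetry-equivalent keys."""
        if dinuc in self.nn_dh:
            return self.nn_dh[dinuc], self.nn_ds[dinuc]
        rc = revcomp(dinuc)
        if rc in self.nn_dh:
            return self.nn_dh[rc], self.nn_ds[rc]
        raise KeyError(f"no nearest-neighbor parameters for stack {dinuc!r}")

    def _initiation(self, base: str) -> tuple[float, float]:
        if base in "AT":
            return self.init_dh_at, self.init_ds_at
        return self.init_dh_gc, self.init_ds_gc


DEFAULT_THERMO = ThermoModel()

MIN_TM_LENGTH = 8


def melting_temp(seq: str, model: ThermoModel = DEFAULT_THERMO) -> float:
    """Duplex melting temperature in °C by the nearest-neighbor method.

    Tm = ΔH°·1000 / (ΔS°_salt + R·ln(C_T/x)) − 273.15, with ΔH°, ΔS° summed
    over dinucleotide stacks plus the two terminal initiation terms, the salt
    correction applied to ΔS°, and x = 4 for non-self-complementary duplexes
    (1 for self-complementary, which also incur the symmetry entropy).

    Sequences shorter than 8 bases or containing characters outside A/C/G/T
    (including N) are rejected: arm candidates with ambiguous bases are
    discarded upstream rather than scored.
    """
    if len(seq) < MIN_TM_LENGTH:
        raise ValueError(
            f"melting_temp requires length >= {MIN_TM_LENGTH}, got {len(seq)}"
        )
    _validate(seq, _ACGT)
    dh = ds = 0.0
    for i in range(len(seq) - 1):
        h, s = model.stack(seq[i : i + 2])
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        h, s = model._initiation(terminal)
        dh += h
        ds += s
    selfcomp = seq == revcomp(seq)
    ct_divisor = 1.0 if selfcomp else 4.0
    if selfcomp:
        ds += model.sym_ds
    ds += 0.368 * (len(seq) - 1) * math.log(model.na)
    return dh * 1000.0 / (ds + model.r * math.log(model.c_t / ct_divisor)) - 273.15
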