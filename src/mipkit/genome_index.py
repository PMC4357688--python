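"""Exact-occurrence counting over a reference genome.

The probe designer must reject any annealing arm whose sequence occurs at
more than one genomic site (on either strand): such an arm could anneal
ambiguously and capture off-target loci. Rather than running an external
aligner, this module counts perfect full-length matches directly with a
k-mer-anchored substring index, which implements the "perfectly aligned to
more than one position" criterion exactly and deterministically.

Counting convention: a placement is a (contig, offset, strand) triple; a
plus placement exists where the genome substring equals the query, a minus
placement where it equals the query's reverse complement. A palindromic
query would name the same genomic duplex site twice, once per strand, so
its minus placements are collapsed and each site counts once. Under this
convention count(q) == count(revcomp(q)) for every q.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .seqcore import revcomp

__all__ = ["ReferenceGenome", "OccurrenceIndex", "load_reference", "build_index"]

_VALID = frozenset("ACGTN")

MIN_ANCHOR_K = 8
MAX_ANCHOR_K = 21  # never longer than the shortest arm query


@dataclass
class ReferenceGenome:
    """Ordered set of uppercase contigs."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError("reference genome has no contigs")
        for name, seq in self.contigs.items():
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(
                    f"contig {name!r} contains illegal characters {sorted(bad)}"
                )

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def fetch(self, contig: str, start: int, end: int) -> str | None:
        """Subsequence in 0-based half-open coordinates; None if out of bounds."""
        seq = self.contigs.get(contig)
        if seq is None or start < 0 or end > len(seq) or start > end:
            return None
        return seq[start:end]


def load_reference(fasta_path: str | Path) -> ReferenceGenome:
    """Load a (possibly multi-contig, line-wrapped) FASTA, case-folded to uppercase."""
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id in contigs:
            raise ValueError(f"duplicate contig name {record.id!r} in {fasta_path}")
        contigs[record.id] = str(record.seq).upper()
    if not contigs:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    return ReferenceGenome(contigs)


@dataclass
class OccurrenceIndex:
    """K-mer-anchored exact-match index over all contigs.

    Forward-strand k-mer start positions are stored; arbitrary-length queries
    are verified by direct comparison after anchor lookup, on both strands.
    """

    genome: ReferenceGenome
    anchor_k: int
    _anchors: dict[str, list[tuple[str, int]]] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not (MIN_ANCHOR_K <= self.anchor_k <= MAX_ANCHOR_K):
            raise ValueError(
                f"anchor_k must be in [{MIN_ANCHOR_K}, {MAX_ANCHOR_K}], got {self.anchor_k}"
            )
        if not self._anchors:
            k = self.anchor_k
            for name, seq in self.genome.contigs.items():
                for off in range(len(seq) - k + 1):
                    kmer = seq[off : off + k]
                    if "N" in kmer:
                        continue  # genomic N never matches any base
                    self._anchors.setdefault(kmer, []).append((name, off))

    def _forward_hits(self, query: str) -> list[tuple[str, int]]:
        k = self.anchor_k
        hits = []
        for name, off in self._anchors.get(query[:k], ()):  # verify full length
            seq = self.genome.contigs[name]
            if seq.startswith(query, off):
                hits.append((name, off))
        return hits

    def find_occurrences(self, query: str) -> list[tuple[str, int, str]]:
        """All perfect full-length placements of ``query`` as (contig, offset, strand)."""
        if len(query) < self.anchor_k:
            raise ValueError(
                f"query length {len(query)} shorter than anchor_k={self.anchor_k}"
            )
        placements = [(c, o, "+") for c, o in self._forward_hits(query)]
        rc = revcomp(query)
        if rc != query:  # palindromes: one duplex site counts once
            placements += [(c, o, "-") for c, o in self._forward_hits(rc)]
        placements.sort()
        return placements

    def count_occurrences(self, query: str) -> int:
        """Number of perfect full-length matches over both strands of all contigs."""
        return len(self.find_occurrences(query))


def build_index(genome: ReferenceGenome, anchor_k: int = 12) -> OccurrenceIndex:
    """Build the exact-occurrence index; anchor_k must fit the shortest query."""
    return OccurrenceIndex(genome, anchor_k)
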