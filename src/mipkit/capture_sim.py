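"""Synthetic capture-experiment generator.

Emulates the statistical structure of a barcoded MIP capture run so the read
processor can be exercised end to end without any external data:

* a uniform random reference genome with planted het/hom SNVs;
* per-probe circularization events whose counts follow a Poisson draw around
  a lognormally dispersed per-probe abundance factor (capture efficiency
  varies strongly between probes in real panels);
* a fresh random 10-nt barcode per event — PCR duplicates of an event share
  its barcode, so distinct (probe, barcode) keys recover true events;
* a geometric PCR duplicate-count model: each event is sequenced as
  1 + Geometric(mean r) read pairs, giving an expected duplicate fraction of
  r/(1+r);
* paired-end reads over the amplicon layout
  [AmpF][barcode][extension arm][gap-fill][ligation arm][rc AmpR], with
  i.i.d. per-base substitution errors and Gaussian-jittered Phred qualities.

Every stage is deterministic under the seed in :class:`SimParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .designer import ProbeDesign
from .genome_index import ReferenceGenome
from .seqcore import revcomp

__all__ = [
    "SimParams",
    "TruthRecord",
    "Molecule",
    "ReadPair",
    "plant_variants",
    "simulate_reference_with_variants",
    "simulate_capture_products",
    "emit_read_pairs",
    "write_fastq_pairs",
    "write_truth_table",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the simulated capture experiment.

    Defaults emulate a deeply sequenced barcoded MIP run: strong per-probe
    abundance dispersion (lognormal sigma 1.3, which puts roughly 60% of
    probes within a 10-fold abundance window), a duplicate-count mean of
    2.45 extra copies per event (expected duplicate fraction
    r/(1+r) ~ 0.71), and Illumina-like error/quality figures.
    """

    genome_length: int = 50_000
    n_variants: int = 30
    het_fraction: float = 0.67
    abundance_sigma: float = 1.3
    mean_events: float = 250.0
    duplicate_mean: float = 2.45
    error_rate: float = 1e-3
    mean_q: float = 33.0
    q_jitter: float = 5.0
    read_length: int = 150
    barcode_length: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("abundance_sigma", "mean_events", "duplicate_mean",
                     "error_rate", "q_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.het_fraction <= 1.0:
            raise ValueError("het_fraction must lie in [0, 1]")


@dataclass
class TruthRecord:
    event_id: int
    probe_id: str
    barcode: str
    alleles: str  # "pos:base" per applied variant allele, comma-joined
    copies: int


@dataclass
class Molecule:
    event_id: int
    copy: int
    probe_id: str
    barcode: str
    insert: str  # barcode + extension arm + gap-fill + ligation arm


@dataclass
class ReadPair:
    pair_id: str
    r1_seq: str
    r1_qual: np.ndarray
    r2_seq: str
    r2_qual: np.ndarray


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def plant_variants(genome: ReferenceGenome, params: SimParams) -> pd.DataFrame:
    """Draw SNVs at distinct positions of an existing genome.

    Genotypes are het with probability ``het_fraction``, otherwise hom-alt.
    Returns a VCF-like table (contig, pos [0-based], ref, alt, genotype).
    """
    if params.n_variants > genome.total_length:
        raise ValueError("more variants requested than genome positions")
    rng = np.random.default_rng(params.seed)
    contig = next(iter(genome.contigs))
    seq = genome.contigs[contig]
    positions = np.sort(
        rng.choice(len(seq), size=params.n_variants, replace=False)
    )
    rows = []
    for pos in positions:
        ref = seq[pos]
        if ref == "N":
            continue
        alt = rng.choice([b for b in "ACGT" if b != ref])
        genotype = "het" if rng.random() < params.het_fraction else "hom"
        rows.append({"contig": contig, "pos": int(pos), "ref": ref,
                     "alt": str(alt), "genotype": genotype})
    return pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt", "genotype"])


def simulate_reference_with_variants(
    params: SimParams, contig: str = "sim1"
) -> tuple[ReferenceGenome, pd.DataFrame]:
    """Uniform random genome plus a table of planted SNVs (seed-deterministic)."""
    if params.genome_length < 10_000:
        raise ValueError("genome_length must be >= 10 kb")
    rng = np.random.default_rng(params.seed)
    genome = ReferenceGenome({contig: _random_seq(rng, params.genome_length)})
    return genome, plant_variants(genome, params)


def simulate_capture_products(
    probes: Sequence[ProbeDesign],
    genome: ReferenceGenome,
    variants: pd.DataFrame,
    params: SimParams,
) -> tuple[list[TruthRecord], list[Molecule]]:
    """Per-probe capture events, barcodes, allele draws and PCR copies.

    Event counts per probe are Poisson(mean_events x lognormal factor), the
    lognormal factor having unit mean. Each event draws a fresh i.i.d.
    barcode; het sites inside the gap-fill contribute either allele with
    probability 0.5 (hom-alt sites always the alt); each event is emitted as
    1 + Geometric(duplicate_mean) molecule copies sharing barcode and allele.
    """
    rng = np.random.default_rng(params.seed + 1)
    designed = [p for p in probes if p.status == "designed"]
    p_geom = 1.0 / (1.0 + params.duplicate_mean)
    truth: list[TruthRecord] = []
    molecules: list[Molecule] = []
    event_id = 0
    for probe in designed:
        if params.abundance_sigma > 0:
            factor = rng.lognormal(
                -0.5 * params.abundance_sigma ** 2, params.abundance_sigma
            )
        else:
            factor = 1.0
        n_events = rng.poisson(params.mean_events * factor)
        gap_ref = genome.fetch(probe.tile.contig, probe.gapfill_start, probe.gapfill_end)
        local = variants[
            (variants["contig"] == probe.tile.contig)
            & (variants["pos"] >= probe.gapfill_start)
            & (variants["pos"] < probe.gapfill_end)
        ]
        for _ in range(n_events):
            barcode = _random_seq(rng, params.barcode_length)
            gap = list(gap_ref)
            applied = []
            for v in local.itertuples(index=False):
                use_alt = v.genotype == "hom" or rng.random() < 0.5
                if use_alt:
                    gap[v.pos - probe.gapfill_start] = v.alt
                    applied.append(f"{v.pos}:{v.alt}")
            insert = barcode + probe.ext.seq + "".join(gap) + probe.lig.seq
            copies = int(rng.geometric(p_geom))
            truth.append(
                TruthRecord(event_id, probe.probe_id, barcode, ",".join(applied), copies)
            )
            molecules.extend(
                Molecule(event_id, c, probe.probe_id, barcode, insert)
                for c in range(copies)
            )
            event_id += 1
    return truth, molecules


def emit_read_pairs(
    molecules: Sequence[Molecule], params: SimParams
) -> list[ReadPair]:
    """Sequence each molecule copy into a read pair.

    R1 is the first ``read_length`` bases of the insert (the amplicon after
    the AmpF region); R2 is the reverse complement of the last ``read_length``
    bases before the AmpR region. Substitution errors are applied i.i.d. per
    base and per copy; qualities are Gaussian around ``mean_q``, clipped to
    [2, 41]. Read ids encode the truth event id (testing convenience only).
    """
    rng = np.random.default_rng(params.seed + 2)
    pairs: list[ReadPair] = []
    n = params.read_length
    for mol in molecules:
        if n > len(mol.insert):
            raise ValueError(
                f"read length {n} exceeds insert length {len(mol.insert)} "
                f"for event {mol.event_id}"
            )
        r1 = _mutate(mol.insert[:n], params, rng)
        r2 = _mutate(revcomp(mol.insert[-n:]), params, rng)
        q1 = _qualities(n, params, rng)
        q2 = _qualities(n, params, rng)
        pairs.append(ReadPair(f"ev{mol.event_id}.{mol.copy}", r1, q1, r2, q2))
    return pairs


def _mutate(seq: str, params: SimParams, rng: np.random.Generator) -> str:
    if params.error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < params.error_rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _qualities(n: int, params: SimParams, rng: np.random.Generator) -> np.ndarray:
    q = np.rint(rng.normal(params.mean_q, params.q_jitter, size=n))
    return np.clip(q, 2, 41).astype(np.int32)


def write_fastq_pairs(
    pairs: Sequence[ReadPair], r1_path: str | Path, r2_path: str | Path
) -> None:
    """Write the pairs as Phred+33 FASTQ files."""
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.pair_id}\n{p.r1_seq}\n+\n{_phred(p.r1_qual)}\n")
            f2.write(f"@{p.pair_id}\n{p.r2_seq}\n+\n{_phred(p.r2_qual)}\n")


def _phred(quals: np.ndarray) -> str:
    return (quals.astype(np.uint8) + 33).tobytes().decode()


def write_truth_table(truth: Sequence[TruthRecord], path: str | Path) -> None:
    pd.DataFrame(
        [{"event_id": t.event_id, "probe_id": t.probe_id, "barcode": t.barcode,
          "alleles": t.alleles, "copies": t.copies} for t in truth]
    ).to_csv(path, sep="\t", index=False)
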