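"""Duplex MIP panel design.

A molecular inversion probe (MIP) captures a genomic target by annealing two
terminal arms to the sequence flanking the target; gap-filling polymerization
and ligation then circularize the probe around the captured span. This module
implements the full panel-design procedure:

1.  Target regions are tiled into 100-bp target tiles stepped by 50 bp
    (2x tiling), so most target bases are covered by two probes and a failed
    probe rarely leaves a hole.
2.  For each tile and each side, 25 arm candidates are enumerated (arm lengths
    21–25 x shifts 0–4). A candidate of length l and shift s has its inner
    edge displaced d = (25 − l) + s bases outward from the tile boundary, so
    the captured gap-fill span is the tile expanded by d on each side —
    attainable gap-fill lengths are exactly 100–116 bases, a deliberately
    narrow window that keeps post-capture PCR length bias small.
3.  Candidates are excluded if they contain an EarI recognition site on either
    strand (EarI releases probes from the synthesized precursor and must not
    cut arms), occur more than once in the genome, contain a homopolymer of
    more than eight bases, or have extreme GC content (<10% or >90%).
4.  Among survivors the arm with melting temperature closest to 60 °C is
    chosen (ties: GC closest to 50%, then longer arm, then smaller shift).
5.  Each designed probe is assembled into a microarray-synthesizable duplex
    precursor: amplification primer regions and EarI cassettes flank the MIP
    so that digestion releases the probe exactly; a 10-nt random barcode
    (unique molecular identifier) sits in the backbone next to the extension
    arm, keying independent circularization events for duplicate removal.

All coordinates are 0-based half-open on the Watson strand.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome_index import OccurrenceIndex, ReferenceGenome, build_index
from .seqcore import (
    find_motif_both_strands,
    gc_percent,
    max_homopolymer_run,
    melting_temp,
    revcomp,
)

__all__ = [
    "DesignParams",
    "Region",
    "TargetTile",
    "ArmCandidate",
    "ProbeDesign",
    "PrecursorOligo",
    "DesignReport",
    "read_bed",
    "tile_targets",
    "enumerate_arm_candidates",
    "filter_candidates",
    "select_best_candidate",
    "design_probe",
    "assemble_precursor",
    "digest_precursor",
    "design_panel",
    "export_design",
]

EXCLUSION_ORDER = ("earI", "redundancy", "homopolymer", "gc_extreme")

# EarI cut geometry: CTCTTC(1/4) — the recognition strand is cut 1 nt
# downstream of the site, the complement 4 nt downstream.
_EARI_TOP_OFFSET = 1
_EARI_BOTTOM_OFFSET = 4


def _no_eari(seq: str, motif: str) -> bool:
    return not find_motif_both_strands(seq, motif)


@dataclass(frozen=True)
class DesignParams:
    """Panel-design parameters (defaults are the standard design conditions)."""

    tile_length: int = 100
    tile_overlap: int = 50
    arm_lengths: tuple[int, ...] = (21, 22, 23, 24, 25)
    shifts: tuple[int, ...] = (0, 1, 2, 3, 4)
    tm_optimum: float = 60.0
    gc_optimum: float = 50.0
    gc_min: float = 10.0
    gc_max: float = 90.0
    max_homopolymer: int = 8
    gapfill_min: int = 100
    gapfill_max: int = 116
    barcode_length: int = 10
    eari_motif: str = "CTCTTC"
    amp_f: str = "GCAGTCAGGCACTAGTCAAG"
    amp_r: str = "CTGGATCACGCTGAGTGTCA"
    backbone_core: str = "ATCGGTGTCGAGCTGGTACA"
    spacer_left: str = "ACTA"
    spacer_right: str = "TGCA"
    pad_left_choices: tuple[str, ...] = ("A", "T", "C", "G")
    pad_right_choices: tuple[str, ...] = ("ATCA", "TGAT", "CAGT", "GTCA")

    def __post_init__(self) -> None:
        if not self.tile_overlap < self.tile_length:
            raise ValueError("tile_overlap must be smaller than tile_length")
        max_d = max(25 - l + s for l in self.arm_lengths for s in self.shifts)
        if self.gapfill_max < self.tile_length + 2 * max_d:
            raise ValueError("gapfill bounds inconsistent with arm geometry")
        for name in ("amp_f", "amp_r", "backbone_core", "spacer_left", "spacer_right"):
            if not _no_eari(getattr(self, name), self.eari_motif):
                raise ValueError(f"{name} contains the restriction motif")

    @property
    def max_displacement(self) -> int:
        return max(25 - l + s for l in self.arm_lengths for s in self.shifts)

    @property
    def flank_needed(self) -> int:
        """Genomic flank required per side: max displacement + longest arm."""
        return self.max_displacement + max(self.arm_lengths)

    @property
    def barcode_space(self) -> int:
        """Number of distinct barcodes, 4^barcode_length."""
        return 4 ** self.barcode_length


class Region(NamedTuple):
    contig: str
    start: int
    end: int
    name: str


@dataclass(frozen=True)
class TargetTile:
    contig: str
    start: int
    end: int
    ordinal: int
    region: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ArmCandidate:
    """One enumerated arm placement, scored on the Watson strand."""

    side: str  # "extension" | "ligation"
    seq: str
    length: int
    shift: int
    contig: str
    start: int
    end: int
    d: int  # outward displacement of the inner edge from the tile boundary
    tm: float
    gc: float
    flags: dict[str, bool] = field(default_factory=dict)

    @property
    def excluded(self) -> bool:
        return any(self.flags.values())

    def first_failing(self) -> str | None:
        for reason in EXCLUSION_ORDER:
            if self.flags.get(reason):
                return reason
        return None


@dataclass
class PrecursorOligo:
    barcode: str
    mip: str
    precursor: str


@dataclass
class ProbeDesign:
    probe_id: str
    tile: TargetTile
    status: str = "failed"  # "designed" | "failed"
    fail_category: str | None = None
    ext: ArmCandidate | None = None
    lig: ArmCandidate | None = None
    gapfill_start: int = -1
    gapfill_end: int = -1
    barcode: str = ""
    mip: str = ""
    precursor: str = ""
    flank_truncated: bool = False

    @property
    def gapfill_length(self) -> int:
        return self.gapfill_end - self.gapfill_start


@dataclass
class DesignReport:
    attempted: int
    designed: int
    failures: dict[str, int]
    coverage: float
    regions_failed: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if self.attempted != self.designed + sum(self.failures.values()):
            raise AssertionError("design accounting does not conserve tiles")
        if not 0.0 <= self.coverage <= 1.0:
            raise AssertionError("coverage outside [0, 1]")


def read_bed(path: str | Path) -> list[Region]:
    """Read target regions from a BED file (first 3–4 columns used)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["contig", "start", "end"],
        dtype={"contig": str, "start": int, "end": int},
    )
    try:
        names = pd.read_csv(path, sep="\t", header=None, comment="#")[3].astype(str)
    except (KeyError, IndexError):
        names = pd.Series([f"region{i}" for i in range(len(df))])
    return [
        Region(row.contig, row.start, row.end, names.iloc[i])
        for i, row in enumerate(df.itertuples(index=False))
    ]


def tile_targets(
    regions: Sequence[Region],
    params: DesignParams,
    genome: ReferenceGenome | None = None,
) -> tuple[list[TargetTile], list[str]]:
    """Tile each region into tile_length windows stepped by tile_length − tile_overlap.

    The last tile is anchored to the region end (its overlap with the previous
    tile may exceed the nominal overlap). Regions shorter than one tile yield
    a single tile centered on the region, expanded symmetrically into flanking
    genomic sequence. Regions that would extend beyond their contig (including
    the arm flank the designer needs) are reported failed, not fatal.
    """
    step = params.tile_length - params.tile_overlap
    tiles: list[TargetTile] = []
    failed: list[str] = []
    for region in regions:
        contig, start, end, name = region
        length = end - start
        if length <= 0:
            failed.append(name)
            continue
        if length < params.tile_length:
            center = (start + end) // 2
            t0 = center - params.tile_length // 2
            starts = [t0]
        else:
            starts = list(range(start, end - params.tile_length + 1, step))
            if starts[-1] != end - params.tile_length:
                starts.append(end - params.tile_length)
        if genome is not None:
            contig_seq = genome.contigs.get(contig)
            flank = params.flank_needed
            if contig_seq is None or starts[0] - flank < 0 or (
                starts[-1] + params.tile_length + flank > len(contig_seq)
            ):
                failed.append(name)
                continue
        tiles.extend(
            TargetTile(contig, s, s + params.tile_length, i, name)
            for i, s in enumerate(starts)
        )
    return tiles, failed


def enumerate_arm_candidates(
    tile: TargetTile,
    side: str,
    genome: ReferenceGenome,
    params: DesignParams,
) -> list[ArmCandidate]:
    """All (length, shift) arm placements for one side of a tile.

    The extension arm anneals on the left (upstream) flank and the ligation
    arm on the right flank, in Watson coordinates. A candidate's inner edge
    sits d = (25 − l) + s bases outward from the tile boundary and the arm
    extends a further l bases outward. Candidates falling off the contig or
    containing ambiguous bases (N, which the thermodynamic model refuses)
    are skipped, so fewer than 25 may be returned near contig edges.
    """
    if side not in ("extension", "ligation"):
        raise ValueError(f"side must be 'extension' or 'ligation', got {side!r}")
    candidates: list[ArmCandidate] = []
    for length in params.arm_lengths:
        for shift in params.shifts:
            d = (25 - length) + shift
            if side == "extension":
                end = tile.start - d
                start = end - length
            else:
                start = tile.end + d
                end = start + length
            seq = genome.fetch(tile.contig, start, end)
            if seq is None or "N" in seq:
                continue
            candidates.append(
                ArmCandidate(
                    side=side, seq=seq, length=length, shift=shift,
                    contig=tile.contig, start=start, end=end, d=d,
                    tm=melting_temp(seq), gc=gc_percent(seq),
                )
            )
    return candidates


def filter_candidates(
    candidates: Iterable[ArmCandidate],
    index: OccurrenceIndex,
    params: DesignParams,
) -> tuple[list[ArmCandidate], dict[str, int]]:
    """Apply the four exclusion criteria; return survivors and exclusion counts.

    Every candidate carries all applicable flags; the per-reason counts
    attribute each excluded candidate to its first failing criterion in the
    order EarI site → genomic redundancy → homopolymer → extreme GC.
    """
    survivors: list[ArmCandidate] = []
    counts = {reason: 0 for reason in EXCLUSION_ORDER}
    for cand in candidates:
        cand.flags = {
            "earI": bool(find_motif_both_strands(cand.seq, params.eari_motif)),
            "redundancy": index.count_occurrences(cand.seq) > 1,
            "homopolymer": max_homopolymer_run(cand.seq) > params.max_homopolymer,
            "gc_extreme": cand.gc < params.gc_min or cand.gc > params.gc_max,
        }
        reason = cand.first_failing()
        if reason is None:
            survivors.append(cand)
        else:
            counts[reason] += 1
    return survivors, counts


def select_best_candidate(
    survivors: Sequence[ArmCandidate], params: DesignParams
) -> ArmCandidate:
    """Arm closest to the Tm optimum; ties by GC, then longer arm, then smaller shift."""
    if not survivors:
        raise ValueError("no surviving arm candidates to select from")
    return min(
        survivors,
        key=lambda c: (
            abs(c.tm - params.tm_optimum),
            abs(c.gc - params.gc_optimum),
            -c.length,
            c.shift,
        ),
    )


def _failure_category(excluded: Sequence[ArmCandidate]) -> str:
    """Majority first-failing flag; ties resolved in criterion order."""
    tally = Counter(c.first_failing() for c in excluded if c.first_failing())
    if not tally:
        return "flank"
    best = max(tally.values())
    for reason in EXCLUSION_ORDER:
        if tally.get(reason) == best:
            return reason
    return "flank"


def design_probe(
    tile: TargetTile,
    genome: ReferenceGenome,
    index: OccurrenceIndex,
    params: DesignParams,
) -> ProbeDesign:
    """Enumerate, filter and select arms for both sides of one tile."""
    probe = ProbeDesign(probe_id=f"{tile.region}.t{tile.ordinal}", tile=tile)
    chosen: dict[str, ArmCandidate] = {}
    for side in ("extension", "ligation"):
        cands = enumerate_arm_candidates(tile, side, genome, params)
        if len(cands) < len(params.arm_lengths) * len(params.shifts):
            probe.flank_truncated = True
        survivors, _counts = filter_candidates(cands, index, params)
        if not survivors:
            probe.status = "failed"
            probe.fail_category = _failure_category(
                [c for c in cands if c.excluded]
            )
            return probe
        chosen[side] = select_best_candidate(survivors, params)
    probe.ext = chosen["extension"]
    probe.lig = chosen["ligation"]
    probe.gapfill_start = tile.start - probe.ext.d
    probe.gapfill_end = tile.end + probe.lig.d
    assert params.gapfill_min <= probe.gapfill_length <= params.gapfill_max
    probe.status = "designed"
    return probe


def _random_barcode(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def digest_precursor(precursor: str, motif: str = "CTCTTC") -> list[str]:
    """Top-strand fragments after complete digestion by the type IIS enzyme.

    For a forward recognition site at q the top strand is cut 1 nt downstream
    (position q+7); for a reverse site (revcomp motif starting at p) the top
    strand is cut 4 nt upstream of the site (position p−4), mirroring the
    enzyme's (1/4) cut offsets.
    """
    cuts = sorted(
        (pos + len(motif) + _EARI_TOP_OFFSET) if strand == "+" else (pos - _EARI_BOTTOM_OFFSET)
        for pos, strand in find_motif_both_strands(precursor, motif)
    )
    cuts = [c for c in cuts if 0 <= c <= len(precursor)]
    bounds = [0, *cuts, len(precursor)]
    return [precursor[a:b] for a, b in zip(bounds, bounds[1:])]


class AssemblyError(RuntimeError):
    pass


def assemble_precursor(
    probe: ProbeDesign, params: DesignParams, rng: np.random.Generator
) -> PrecursorOligo:
    """Assemble the synthesizable duplex precursor for a designed probe.

    Precursor (Watson, 5'→3'):

        AmpF + spacer + CTCTTC + pad(1 nt) + MIP + pad(4 nt) + GAAGAG + spacer + AmpR

    where MIP = ligation arm + backbone core + barcode + extension arm (the
    barcode sits adjacent to the extension arm). The 1-nt / 4-nt pads absorb
    the enzyme's asymmetric cut offsets so the top-strand cuts land exactly at
    the MIP termini; the spacers keep the recognition sites away from the
    primers. If a junction accidentally creates an extra recognition site the
    pads are re-picked from the configured alternatives (and the barcode
    redrawn if it is at fault); exhaustion raises AssemblyError.
    """
    if probe.status != "designed" or probe.ext is None or probe.lig is None:
        raise ValueError(f"probe {probe.probe_id} is not designed")
    motif = params.eari_motif
    for _ in range(64):  # barcode redraw budget; each failure has prob ~1e-2
        barcode = _random_barcode(rng, params.barcode_length)
        mip = probe.lig.seq + params.backbone_core + barcode + probe.ext.seq
        if not _no_eari(mip, motif):
            continue  # junction through the barcode created a site
        for pad1 in params.pad_left_choices:
            for pad4 in params.pad_right_choices:
                precursor = (
                    params.amp_f + params.spacer_left + motif + pad1
                    + mip
                    + pad4 + revcomp(motif) + params.spacer_right + params.amp_r
                )
                if len(find_motif_both_strands(precursor, motif)) != 2:
                    continue
                fragments = digest_precursor(precursor, motif)
                if len(fragments) == 3 and fragments[1] == mip:
                    probe.barcode = barcode
                    probe.mip = mip
                    probe.precursor = precursor
                    return PrecursorOligo(barcode, mip, precursor)
    raise AssemblyError(f"could not assemble an enzyme-clean precursor for {probe.probe_id}")


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _coverage(regions: Sequence[Region], probes: Sequence[ProbeDesign]) -> float:
    """Fraction of original region bases inside ≥1 designed gap-fill span."""
    spans: dict[str, list[tuple[int, int]]] = {}
    for p in probes:
        if p.status == "designed":
            spans.setdefault(p.tile.contig, []).append(
                (p.gapfill_start, p.gapfill_end)
            )
    merged = {c: _merge_intervals(v) for c, v in spans.items()}
    total = covered = 0
    for region in regions:
        total += region.end - region.start
        for start, end in merged.get(region.contig, ()):  # merged, so no double count
            covered += max(0, min(end, region.end) - max(start, region.start))
    return covered / total if total else 0.0


def design_panel(
    regions: Sequence[Region],
    genome: ReferenceGenome,
    params: DesignParams | None = None,
    seed: int = 0,
    anchor_k: int = 12,
) -> tuple[list[ProbeDesign], DesignReport]:
    """Design the whole panel: tile, design, assemble; deterministic under seed."""
    params = params or DesignParams()
    rng = np.random.default_rng(seed)
    index = build_index(genome, anchor_k=anchor_k)
    tiles, regions_failed = tile_targets(regions, params, genome)
    probes: list[ProbeDesign] = []
    failures = {reason: 0 for reason in EXCLUSION_ORDER}
    for tile in tiles:
        probe = design_probe(tile, genome, index, params)
        if probe.status == "designed":
            try:
                assemble_precursor(probe, params, rng)
            except AssemblyError:
                probe.status = "failed"
                probe.fail_category = "earI"  # junction site could not be avoided
        if probe.status == "failed":
            failures[probe.fail_category] = failures.get(probe.fail_category, 0) + 1
        probes.append(probe)
    designed = sum(p.status == "designed" for p in probes)
    report = DesignReport(
        attempted=len(tiles),
        designed=designed,
        failures=failures,
        coverage=_coverage(regions, probes),
        regions_failed=regions_failed,
    )
    report.validate()
    return probes, report


_TSV_COLUMNS = [
    "probe_id", "contig", "tile_start", "tile_end", "tile_ordinal", "region",
    "status", "fail_category",
    "ext_seq", "ext_len", "ext_shift", "ext_d", "ext_start", "ext_end", "ext_tm", "ext_gc",
    "lig_seq", "lig_len", "lig_shift", "lig_d", "lig_start", "lig_end", "lig_tm", "lig_gc",
    "gapfill_start", "gapfill_end", "gapfill_len", "barcode", "precursor",
]


def _probe_row(p: ProbeDesign) -> dict:
    row = {
        "probe_id": p.probe_id, "contig": p.tile.contig,
        "tile_start": p.tile.start, "tile_end": p.tile.end,
        "tile_ordinal": p.tile.ordinal, "region": p.tile.region,
        "status": p.status, "fail_category": p.fail_category or "",
        "gapfill_start": p.gapfill_start, "gapfill_end": p.gapfill_end,
        "gapfill_len": p.gapfill_length if p.status == "designed" else 0,
        "barcode": p.barcode, "precursor": p.precursor,
    }
    for tag, arm in (("ext", p.ext), ("lig", p.lig)):
        row.update({
            f"{tag}_seq": arm.seq if arm else "",
            f"{tag}_len": arm.length if arm else 0,
            f"{tag}_shift": arm.shift if arm else 0,
            f"{tag}_d": arm.d if arm else 0,
            f"{tag}_start": arm.start if arm else -1,
            f"{tag}_end": arm.end if arm else -1,
            f"{tag}_tm": round(arm.tm, 4) if arm else float("nan"),
            f"{tag}_gc": round(arm.gc, 4) if arm else float("nan"),
        })
    return row


def export_design(
    probes: Sequence[ProbeDesign], report: DesignReport, out_dir: str | Path
) -> dict[str, Path]:
    """Write the probe table TSV, precursor FASTA, gap-fill BED and report JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "probes": out / "probes.tsv",
        "precursors": out / "precursors.fasta",
        "gapfills": out / "gapfills.bed",
        "report": out / "report.json",
    }
    df = pd.DataFrame([_probe_row(p) for p in probes], columns=_TSV_COLUMNS)
    df.to_csv(paths["probes"], sep="\t", index=False)
    designed = [p for p in probes if p.status == "designed"]
    SeqIO.write(
        (SeqRecord(Seq(p.precursor), id=p.probe_id, description="") for p in designed),
        str(paths["precursors"]), "fasta",
    )
    with open(paths["gapfills"], "w") as bed:
        for p in designed:
            bed.write(f"{p.tile.contig}\t{p.gapfill_start}\t{p.gapfill_end}\t{p.probe_id}\n")
    with open(paths["report"], "w") as fh:
        json.dump(dataclasses.asdict(report), fh, indent=2)
    return paths
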