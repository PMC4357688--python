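"""Capture-read processing: probe identification, UMI dedup, capture statistics.

Each read pair from a barcoded MIP capture carries, in fixed positions, the
10-nt barcode and the extension arm (R1) and the ligation arm (R2, reverse
complemented). Processing proceeds in three stages:

1.  **Identification** — arms are matched against the probe table (up to a
    configurable number of mismatches per arm); the barcode and the gap-fill
    (the captured target, merged from both mates with higher-quality bases
    winning in the overlap) are extracted. Only gap-fills of 100–116 bases —
    the lengths the designer can produce — are accepted as valid.
2.  **Deduplication** — read pairs sharing a (probe, barcode) key are PCR
    duplicates of one circularization event; the pair with the highest
    representative quality score (sum of base qualities >= Q, Q = 15 by
    default, as Picard MarkDuplicates scores pairs) is kept.
3.  **Statistics** — read accounting (raw -> arm-identified -> gap-valid ->
    unique), per-probe unique counts (the circularized-product quantities),
    fold-range capture uniformity, and the depth-normalized percent-unique
    used to compare capture conditions at equal sequencing depth.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd
import pysam

from .seqcore import revcomp

__all__ = [
    "DedupParams",
    "ProbeRecord",
    "CaptureRecord",
    "CaptureStats",
    "load_probe_table",
    "probe_records",
    "read_fastq_pairs",
    "identify_and_extract",
    "process_pairs",
    "deduplicate",
    "capture_stats",
    "percent_unique_at_depth",
    "uniformity",
    "flag_arm_variants",
]


@dataclass(frozen=True)
class DedupParams:
    """Read-processing parameters.

    ``quality_mode`` selects how the representative score reads the rule
    "highest sum of base quality scores >= 15": ``"floor"`` (default) sums
    the base qualities that are >= Q; ``"threshold"`` sums all base
    qualities and zeroes pairs whose sum is below Q.
    """

    max_mismatch: int = 1
    q_floor: int = 15
    gapfill_min: int = 100
    gapfill_max: int = 116
    subsample_size: int = 2_000_000
    fold_windows: tuple[int, ...] = (10, 100)
    seed: int = 0
    quality_mode: str = "floor"

    def __post_init__(self) -> None:
        if self.q_floor < 0:
            raise ValueError("q_floor must be >= 0")
        if self.quality_mode not in ("floor", "threshold"):
            raise ValueError("quality_mode must be 'floor' or 'threshold'")


class ProbeRecord(NamedTuple):
    probe_id: str
    contig: str
    ext_seq: str
    lig_seq: str
    ext_start: int
    ext_end: int
    lig_start: int
    lig_end: int
    gapfill_len: int
    barcode_length: int


@dataclass
class CaptureRecord:
    pair_id: str
    probe_id: str | None
    barcode: str
    gapfill_seq: str
    gapfill_qual: np.ndarray
    score: int
    arms_found: bool
    length_valid: bool
    gapfill_len: int = 0
    ambiguous: bool = False

    @property
    def key(self) -> tuple[str, str]:
        return (self.probe_id or "", self.barcode)


@dataclass
class CaptureStats:
    total_pairs: int
    arm_identified: int
    gap_valid: int
    unique: int
    duplicate_fraction: float
    per_probe_unique: dict[str, int]
    probes_detected: int

    def validate(self) -> None:
        if not (self.total_pairs >= self.arm_identified >= self.gap_valid >= self.unique):
            raise AssertionError("read accounting is not monotone")

    def to_dict(self) -> dict:
        return {
            "total_pairs": self.total_pairs,
            "arm_identified": self.arm_identified,
            "gap_valid": self.gap_valid,
            "unique": self.unique,
            "duplicate_fraction": self.duplicate_fraction,
            "probes_detected": self.probes_detected,
        }


def load_probe_table(path: str | Path) -> pd.DataFrame:
    """Load a probe table TSV written by the designer (lossless round trip)."""
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str, "precursor": str})
    for col in ("fail_category", "barcode", "precursor", "ext_seq", "lig_seq"):
        if col in df:
            df[col] = df[col].fillna("")
    return df


def probe_records(table: pd.DataFrame, barcode_length: int = 10) -> list[ProbeRecord]:
    """Designed probes from a probe table, as lightweight matching records."""
    designed = table[table["status"] == "designed"]
    return [
        ProbeRecord(
            r.probe_id, r.contig, r.ext_seq, r.lig_seq,
            int(r.ext_start), int(r.ext_end), int(r.lig_start), int(r.lig_end),
            int(r.gapfill_len), barcode_length,
        )
        for r in designed.itertuples(index=False)
    ]


def read_fastq_pairs(
    r1_path: str | Path, r2_path: str | Path
) -> Iterator[tuple[str, str, np.ndarray, str, np.ndarray]]:
    """Stream (id, r1_seq, r1_qual, r2_seq, r2_qual) from Phred+33 FASTQ mates."""
    with pysam.FastxFile(str(r1_path)) as f1, pysam.FastxFile(str(r2_path)) as f2:
        for e1, e2 in zip(f1, f2):
            if e1.name != e2.name:
                raise ValueError(f"mate name mismatch: {e1.name} vs {e2.name}")
            yield (
                e1.name,
                e1.sequence, np.array(e1.get_quality_array(), dtype=np.int32),
                e2.sequence, np.array(e2.get_quality_array(), dtype=np.int32),
            )


class _ProbeMatcher:
    """Arm matching with a mismatch budget.

    Exact extension-arm lookup serves as a fast path (a unique 0-mismatch
    probe cannot be beaten); otherwise all probes are scanned and the best
    total mismatch count must be unique, else the pair is ambiguous.
    """

    def __init__(self, probes: Sequence[ProbeRecord], params: DedupParams):
        self.probes = list(probes)
        self.params = params
        self.bl = probes[0].barcode_length if probes else 10
        self._by_ext: dict[str, list[int]] = {}
        self._ext_arr: list[np.ndarray] = []
        self._ligrc_arr: list[np.ndarray] = []
        for i, p in enumerate(self.probes):
            self._by_ext.setdefault(p.ext_seq, []).append(i)
            self._ext_arr.append(np.frombuffer(p.ext_seq.encode(), dtype=np.uint8))
            self._ligrc_arr.append(
                np.frombuffer(revcomp(p.lig_seq).encode(), dtype=np.uint8)
            )
        self._ext_lengths = sorted({len(p.ext_seq) for p in self.probes})

    def match(self, r1: str, r2: str) -> tuple[int | None, int, bool]:
        """Return (probe index | None, total mismatches, ambiguous)."""
        mm = self.params.max_mismatch
        bl = self.bl
        # fast path: exact extension arm and exact ligation arm
        for length in self._ext_lengths:
            for i in self._by_ext.get(r1[bl : bl + length], ()):  # exact ext hit
                p = self.probes[i]
                if r2.startswith(revcomp(p.lig_seq)):
                    return i, 0, False  # 0 mismatches cannot be tied or beaten*
        # *unless two probes share both arms, which the designer's redundancy
        # screen precludes; the slow path below handles foreign probe tables.
        r1a = np.frombuffer(r1.encode(), dtype=np.uint8)
        r2a = np.frombuffer(r2.encode(), dtype=np.uint8)
        best_i: int | None = None
        best_mm = 2 * mm + 1
        tied = False
        for i, p in enumerate(self.probes):
            ea = self._ext_arr[i]
            if bl + ea.size > r1a.size:
                continue
            e_mm = int((r1a[bl : bl + ea.size] != ea).sum())
            if e_mm > mm:
                continue
            la = self._ligrc_arr[i]
            if la.size > r2a.size:
                continue
            l_mm = int((r2a[: la.size] != la).sum())
            if l_mm > mm:
                continue
            total = e_mm + l_mm
            if total < best_mm:
                best_i, best_mm, tied = i, total, False
            elif total == best_mm:
                tied = True
        if best_i is None or tied:
            return None, best_mm, tied
        return best_i, best_mm, False


_GAP_SCAN = 60  # half-width of the gap-length scan around the design length
_OVERLAP_MISMATCH_MAX = 0.1


def _estimate_gap_length(
    r1a: np.ndarray, rc2a: np.ndarray, probe: ProbeRecord, bl: int
) -> int:
    """Infer the actual gap-fill length from the mate overlap.

    The design length is tried first; if the implied R1/R2 overlap disagrees
    (mismatch fraction above threshold), nearby lengths are scanned and the
    one with the cleanest overlap wins (ties go to the length closest to the
    design length). When the mates do not overlap the design length is
    assumed — it cannot be contradicted.
    """
    le = probe.ext_end - probe.ext_start
    ll = probe.lig_end - probe.lig_start
    head = bl + le

    def overlap_mismatch(gap_len: int) -> float | None:
        insert_len = head + gap_len + ll
        o = insert_len - rc2a.size
        a0, a1 = max(0, o), min(r1a.size, o + rc2a.size)
        if a1 - a0 < 8:
            return None  # too little overlap to judge
        return float((r1a[a0:a1] != rc2a[a0 - o : a1 - o]).mean())

    expected = probe.gapfill_len
    frac = overlap_mismatch(expected)
    if frac is None or frac <= _OVERLAP_MISMATCH_MAX:
        return expected
    best = (2.0, 0, expected)
    for gap_len in range(max(1, expected - _GAP_SCAN), expected + _GAP_SCAN + 1):
        f = overlap_mismatch(gap_len)
        if f is not None and (f, abs(gap_len - expected)) < (best[0], best[1]):
            best = (f, abs(gap_len - expected), gap_len)
    return best[2]


def identify_and_extract(
    pair_id: str,
    r1_seq: str,
    r1_qual: np.ndarray,
    r2_seq: str,
    r2_qual: np.ndarray,
    matcher: _ProbeMatcher,
    params: DedupParams,
) -> CaptureRecord:
    """Identify the probe in one read pair and extract barcode and gap-fill.

    R1 is scanned for barcode + extension arm at the expected offset and R2
    for the reverse-complemented ligation arm, each tolerating up to
    ``max_mismatch`` mismatches; a unique best probe is required. The
    gap-fill is merged from both mates, resolving overlap by the
    higher-quality base (tie: R1). Pairs failing arm matching, matching two
    probes equally well, or with a gap-fill outside the accepted length
    window are flagged and excluded from deduplication.
    """
    idx, _mm, ambiguous = matcher.match(r1_seq, r2_seq)
    if idx is None:
        return CaptureRecord(
            pair_id, None, "", "", np.empty(0, dtype=np.int32), 0,
            arms_found=False, length_valid=False, ambiguous=ambiguous,
        )
    probe = matcher.probes[idx]
    bl = matcher.bl
    score = _representative_score(r1_qual, r2_qual, params)
    r1a = np.frombuffer(r1_seq.encode(), dtype=np.uint8)
    rc2a = np.frombuffer(revcomp(r2_seq).encode(), dtype=np.uint8)
    q2r = r2_qual[::-1]
    le = probe.ext_end - probe.ext_start
    ll = probe.lig_end - probe.lig_start
    gap_len = _estimate_gap_length(r1a, rc2a, probe, bl)
    g0 = bl + le
    insert_len = g0 + gap_len + ll
    o = insert_len - rc2a.size  # offset of the R2 window within the insert
    seq = np.full(gap_len, ord("N"), dtype=np.uint8)
    qual = np.zeros(gap_len, dtype=np.int32)
    pos = np.arange(g0, g0 + gap_len)
    in1 = pos < r1a.size
    in2 = pos >= o
    q1 = np.where(in1, r1_qual[np.minimum(pos, r1a.size - 1)], -1)
    q2 = np.where(in2, q2r[np.clip(pos - o, 0, rc2a.size - 1)], -1)
    use1 = in1 & (~in2 | (q1 >= q2))
    use2 = in2 & ~use1
    seq[use1] = r1a[pos[use1]]
    qual[use1] = q1[use1]
    seq[use2] = rc2a[pos[use2] - o]
    qual[use2] = q2[use2]
    return CaptureRecord(
        pair_id=pair_id,
        probe_id=probe.probe_id,
        barcode=r1_seq[:bl],
        gapfill_seq=seq.tobytes().decode(),
        gapfill_qual=qual,
        score=score,
        arms_found=True,
        length_valid=params.gapfill_min <= gap_len <= params.gapfill_max,
        gapfill_len=gap_len,
    )


def _representative_score(
    r1_qual: np.ndarray, r2_qual: np.ndarray, params: DedupParams
) -> int:
    if params.quality_mode == "floor":
        return int(r1_qual[r1_qual >= params.q_floor].sum()
                   + r2_qual[r2_qual >= params.q_floor].sum())
    total = int(r1_qual.sum() + r2_qual.sum())
    return total if total >= params.q_floor else 0


def process_pairs(
    pairs: Iterable[tuple[str, str, np.ndarray, str, np.ndarray]],
    probes: Sequence[ProbeRecord],
    params: DedupParams | None = None,
) -> list[CaptureRecord]:
    """Identify and extract every pair; returns all records, valid or not."""
    params = params or DedupParams()
    matcher = _ProbeMatcher(probes, params)
    return [
        identify_and_extract(pid, s1, q1, s2, q2, matcher, params)
        for pid, s1, q1, s2, q2 in pairs
    ]


def deduplicate(records: Sequence[CaptureRecord]) -> tuple[list[CaptureRecord], int]:
    """Collapse PCR duplicates by (probe, barcode) key.

    Per key the record with the highest representative score is kept (tie:
    lexicographically smallest pair id); output is ordered by probe id then
    barcode. The duplicate count is input minus output.
    """
    best: dict[tuple[str, str], CaptureRecord] = {}
    for rec in records:
        cur = best.get(rec.key)
        if cur is None or (-rec.score, rec.pair_id) < (-cur.score, cur.pair_id):
            best[rec.key] = rec
    unique = [best[k] for k in sorted(best)]
    return unique, len(records) - len(unique)


def capture_stats(
    records: Sequence[CaptureRecord],
    unique: Sequence[CaptureRecord],
    probes: Sequence[ProbeRecord],
) -> CaptureStats:
    """Read accounting and per-probe circularized-product quantities."""
    arm_identified = sum(r.arms_found for r in records)
    gap_valid = sum(r.arms_found and r.length_valid for r in records)
    per_probe = Counter(r.probe_id for r in unique)
    stats = CaptureStats(
        total_pairs=len(records),
        arm_identified=arm_identified,
        gap_valid=gap_valid,
        unique=len(unique),
        duplicate_fraction=(1.0 - len(unique) / gap_valid) if gap_valid else 0.0,
        per_probe_unique={p.probe_id: per_probe.get(p.probe_id, 0) for p in probes},
        probes_detected=sum(1 for p in probes if per_probe.get(p.probe_id, 0) > 0),
    )
    stats.validate()
    return stats


def percent_unique_at_depth(
    records: Sequence[CaptureRecord],
    n: int | None = None,
    fraction: float | None = None,
    seed: int = 0,
) -> float:
    """Percent of distinct (probe, barcode) keys in a seeded random subsample.

    Normalizes capture-product yield across conditions sequenced at different
    depths by comparing them at a fixed number of reads. If ``n`` exceeds the
    record count all records are used.
    """
    if fraction is not None:
        n = max(1, round(fraction * len(records)))
    if n is None or n <= 0:
        raise ValueError("subsample size must be positive")
    n = min(n, len(records))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(records), size=n, replace=False)
    keys = {records[i].key for i in idx}
    return 100.0 * len(keys) / n


def uniformity(counts: Sequence[int], fold: float, method: str = "best") -> float:
    """Fraction of detected probes whose counts lie within a ``fold``-range.

    ``method="best"`` slides a log10 window of width log10(fold) over the
    positive counts and returns the maximal contained fraction;
    ``method="median"`` centers the window on the median count
    ([m/sqrt(fold), m*sqrt(fold)]). Probes with zero counts are excluded
    (they are undetected, not non-uniform).
    """
    arr = np.asarray([c for c in counts if c > 0], dtype=float)
    if arr.size == 0:
        raise ValueError("uniformity undefined for all-zero counts")
    if fold < 1:
        raise ValueError("fold must be >= 1")
    arr.sort()
    if method == "median":
        m = float(np.median(arr))
        lo, hi = m / np.sqrt(fold), m * np.sqrt(fold)
        return float(((arr >= lo) & (arr <= hi)).mean())
    if method != "best":
        raise ValueError("method must be 'best' or 'median'")
    best = 0
    for i in range(arr.size):
        j = np.searchsorted(arr, arr[i] * fold, side="right")
        best = max(best, j - i)
    return best / arr.size


def flag_arm_variants(
    probe_table: pd.DataFrame, variants: pd.DataFrame
) -> tuple[dict[str, bool], int, pd.DataFrame]:
    """Flag probes with a variant on either annealing arm.

    Variants falling only in the gap-fill do not flag a probe. Returns the
    per-probe flags, the flagged count, and a per-probe covariate table (arm
    Tm, GC, lengths, flag) suitable for external regression of capture yield.
    """
    designed = probe_table[probe_table["status"] == "designed"]
    known_contigs = set(designed["contig"])
    flags = {pid: False for pid in designed["probe_id"]}
    for v in variants.itertuples(index=False):
        if v.contig not in known_contigs:
            warnings.warn(f"variant on unknown contig {v.contig!r} skipped")
            continue
        hits = designed[
            (designed["contig"] == v.contig)
            & (
                ((designed["ext_start"] <= v.pos) & (v.pos < designed["ext_end"]))
                | ((designed["lig_start"] <= v.pos) & (v.pos < designed["lig_end"]))
            )
        ]
        for pid in hits["probe_id"]:
            flags[pid] = True
    covariates = designed[
        ["probe_id", "ext_tm", "ext_gc", "ext_len", "lig_tm", "lig_gc", "lig_len"]
    ].copy()
    covariates["arm_variant"] = covariates["probe_id"].map(flags)
    return flags, sum(flags.values()), covariates
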