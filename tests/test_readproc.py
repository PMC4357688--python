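from collections import Counter, defaultdict

import numpy as np
import pandas as pd
import pytest

from mipkit import capture_sim, readproc
from mipkit.readproc import (
    CaptureRecord,
    DedupParams,
    capture_stats,
    deduplicate,
    flag_arm_variants,
    percent_unique_at_depth,
    process_pairs,
    uniformity,
)
from mipkit.seqcore import revcomp

from conftest import as_pair_tuples


def _pairs_for_molecules(molecules, params):
    return as_pair_tuples(capture_sim.emit_read_pairs(molecules, params))


@pytest.fixture(scope="module")
def one_molecule(genome, panel):
    params = capture_sim.SimParams(mean_events=2, duplicate_mean=0.0,
                                   abundance_sigma=0.0, error_rate=0.0, seed=1,
                                   n_variants=0)
    variants = capture_sim.plant_variants(genome, params)
    _, molecules = capture_sim.simulate_capture_products(
        panel.designed, genome, variants, params
    )
    return params, molecules[0]


class TestIdentification:
    def test_clean_read_identified(self, probe_table, one_molecule):
        params, mol = one_molecule
        (rec,) = process_pairs(_pairs_for_molecules([mol], params),
                               probe_table.records)
        assert rec.arms_found and rec.length_valid
        assert rec.probe_id == mol.probe_id
        assert rec.barcode == mol.barcode

    def test_one_arm_mismatch_tolerated_only_at_max_mm_1(self, probe_table,
                                                         one_molecule):
        params, mol = one_molecule
        (pid, s1, q1, s2, q2), = list(_pairs_for_molecules([mol], params))
        i = 15  # inside the extension arm (barcode is the first 10 bases)
        s1_mut = s1[:i] + ("A" if s1[i] != "A" else "C") + s1[i + 1:]
        (tolerant,) = process_pairs([(pid, s1_mut, q1, s2, q2)],
                                    probe_table.records, DedupParams(max_mismatch=1))
        assert tolerant.arms_found and tolerant.probe_id == mol.probe_id
        (strict,) = process_pairs([(pid, s1_mut, q1, s2, q2)],
                                  probe_table.records, DedupParams(max_mismatch=0))
        assert not strict.arms_found

    def test_truncated_gapfill_flagged_length_invalid(self, genome, panel,
                                                      probe_table):
        p = panel.designed[0]
        gap = genome.fetch("chr1", p.gapfill_start, p.gapfill_start + 99)
        insert = "G" * 10 + p.ext.seq + gap + p.lig.seq
        mol = capture_sim.Molecule(0, 0, p.probe_id, "G" * 10, insert)
        params = capture_sim.SimParams(error_rate=0.0, seed=0)
        (rec,) = process_pairs(_pairs_for_molecules([mol], params),
                               probe_table.records)
        assert rec.arms_found
        assert rec.gapfill_len == 99
        assert not rec.length_valid

    def test_unrelated_read_unidentified(self, probe_table):
        rng = np.random.default_rng(0)
        s = "".join("ACGT"[i] for i in rng.integers(0, 4, size=150))
        q = np.full(150, 30, dtype=np.int32)
        (rec,) = process_pairs([("x", s, q, revcomp(s), q)], probe_table.records)
        assert not rec.arms_found and rec.probe_id is None

    def test_gapfill_merge_prefers_higher_quality_base(self, genome, panel,
                                                       probe_table):
        """Plant a discrepancy in the mate overlap; the consensus must follow
        whichever mate has the higher base quality."""
        p = panel.designed[0]
        gap = genome.fetch("chr1", p.gapfill_start, p.gapfill_end)
        insert = "G" * 10 + p.ext.seq + gap + p.lig.seq
        n = 150
        r1 = insert[:n]
        r2 = revcomp(insert[-n:])
        # overlap position in insert coordinates: middle of the gap-fill
        pos = 10 + p.ext.length + p.gapfill_length // 2
        wrong = "A" if insert[pos] != "A" else "C"
        r1_mut = r1[:pos] + wrong + r1[pos + 1:]
        q_low = np.full(n, 20, dtype=np.int32)
        q_high = np.full(n, 38, dtype=np.int32)
        (rec,) = process_pairs([("m", r1_mut, q_low, r2, q_high)],
                               probe_table.records)
        gi = pos - 10 - p.ext.length
        assert rec.gapfill_seq[gi] == insert[pos]  # R2's high-quality base won
        (rec2,) = process_pairs([("m", r1_mut, q_high, r2, q_low)],
                                probe_table.records)
        assert rec2.gapfill_seq[gi] == wrong  # now R1 outranks R2


def _rec(pair_id, probe, barcode, score):
    return CaptureRecord(pair_id, probe, barcode, "A" * 100,
                         np.full(100, 30, dtype=np.int32), score,
                         arms_found=True, length_valid=True, gapfill_len=100)


class TestDedup:
    def test_highest_score_kept(self):
        unique, dups = deduplicate([_rec("a", "p1", "ACGT", 300),
                                    _rec("b", "p1", "ACGT", 280)])
        assert dups == 1 and unique[0].pair_id == "a"

    def test_tie_broken_by_smallest_pair_id(self):
        unique, _ = deduplicate([_rec("z", "p1", "ACGT", 300),
                                 _rec("a", "p1", "ACGT", 300)])
        assert unique[0].pair_id == "a"

    def test_distinct_keys_untouched(self):
        records = [_rec("a", "p1", "AAAA", 1), _rec("b", "p1", "CCCC", 1),
                   _rec("c", "p2", "AAAA", 1)]
        unique, dups = deduplicate(records)
        assert len(unique) == 3 and dups == 0

    def test_output_order_deterministic(self):
        records = [_rec("a", "p2", "TTTT", 1), _rec("b", "p1", "GGGG", 1),
                   _rec("c", "p1", "AAAA", 1)]
        unique, _ = deduplicate(records)
        assert [(r.probe_id, r.barcode) for r in unique] == [
            ("p1", "AAAA"), ("p1", "GGGG"), ("p2", "TTTT")]

    def test_idempotence(self, sim_large):
        again, dups = deduplicate(sim_large.unique)
        assert dups == 0
        assert [r.pair_id for r in again] == [r.pair_id for r in sim_large.unique]

    def test_matches_brute_force_grouping(self, sim_large):
        groups = defaultdict(list)
        for r in sim_large.valid:
            groups[(r.probe_id, r.barcode)].append(r)
        expected = {k: min(g, key=lambda r: (-r.score, r.pair_id)).pair_id
                    for k, g in groups.items()}
        assert {r.key: r.pair_id for r in sim_large.unique} == expected


class TestStats:
    def test_conservation_identities(self, sim_large, probe_table):
        stats = capture_stats(sim_large.records, sim_large.unique,
                              probe_table.records)
        assert stats.total_pairs == len(sim_large.pairs)
        assert stats.total_pairs >= stats.arm_identified >= stats.gap_valid
        assert stats.gap_valid == stats.unique + sim_large.dups
        assert stats.duplicate_fraction == pytest.approx(
            1 - stats.unique / stats.gap_valid)
        assert sum(stats.per_probe_unique.values()) == stats.unique

    def test_zero_duplication_duplicate_fraction_is_barcode_collision_rate(
            self, genome, panel, probe_table):
        """Without PCR duplication every molecule is an independent event, so
        the only records dedup may collapse are true barcode collisions —
        independent events of one probe drawing the same 10-nt barcode, a
        ~1e-6 per-pair chance the assay itself cannot distinguish."""
        params = capture_sim.SimParams(mean_events=30, duplicate_mean=0.0,
                                       abundance_sigma=0.0, error_rate=0.0,
                                       seed=3, n_variants=0)
        truth, mols = capture_sim.simulate_capture_products(
            panel.designed, genome, capture_sim.plant_variants(genome, params),
            params)
        records = process_pairs(_pairs_for_molecules(mols, params),
                                probe_table.records)
        valid = [r for r in records if r.arms_found and r.length_valid]
        unique, _ = deduplicate(valid)
        stats = capture_stats(records, unique, probe_table.records)
        truth_keys = {(t.probe_id, t.barcode) for t in truth}
        assert stats.unique == len(truth_keys)
        assert stats.duplicate_fraction == 1 - len(truth_keys) / len(truth)
        assert stats.duplicate_fraction < 0.01

    def test_undetected_probes_not_counted(self, probe_table):
        records = [_rec("a", probe_table.records[0].probe_id, "AAAA", 1)]
        unique, _ = deduplicate(records)
        stats = capture_stats(records, unique, probe_table.records)
        assert stats.probes_detected == 1
        assert stats.per_probe_unique[probe_table.records[1].probe_id] == 0


class TestPercentUnique:
    def test_subsample_of_one(self, sim_large):
        assert percent_unique_at_depth(sim_large.valid, n=1) == 100.0

    def test_all_unique_input(self):
        records = [_rec(str(i), "p1", f"{i:010d}", 1) for i in range(50)]
        assert percent_unique_at_depth(records, n=20) == 100.0
        assert percent_unique_at_depth(records, n=50) == 100.0

    def test_oversized_subsample_uses_all(self, sim_large):
        full = percent_unique_at_depth(sim_large.valid, n=10 ** 9)
        expected = 100.0 * len({r.key for r in sim_large.valid}) / len(sim_large.valid)
        assert full == pytest.approx(expected)

    def test_nonpositive_rejected(self, sim_large):
        with pytest.raises(ValueError):
            percent_unique_at_depth(sim_large.valid, n=0)

    def test_seed_determinism(self, sim_large):
        a = percent_unique_at_depth(sim_large.valid, fraction=0.25, seed=3)
        b = percent_unique_at_depth(sim_large.valid, fraction=0.25, seed=3)
        assert a == b


class TestUniformity:
    def test_equal_counts(self):
        assert uniformity([7] * 40, 10) == 1.0

    def test_documented_example(self):
        assert uniformity([1, 1, 1, 100], 10) == 0.75

    def test_monotone_in_fold(self, sim_large, probe_table):
        stats = capture_stats(sim_large.records, sim_large.unique,
                              probe_table.records)
        counts = list(stats.per_probe_unique.values())
        assert uniformity(counts, 100) >= uniformity(counts, 10)

    def test_zeros_excluded_and_all_zero_rejected(self):
        assert uniformity([0, 0, 5, 5], 10) == 1.0
        with pytest.raises(ValueError):
            uniformity([0, 0], 10)

    def test_median_method(self):
        assert uniformity([1, 1, 1, 100], 10, method="median") == 0.75
        assert uniformity([10, 10, 10], 10, method="median") == 1.0


class TestArmVariants:
    def test_planted_arm_variants_flagged(self, panel, probe_table):
        rows = []
        for p in panel.designed[:10]:
            rows.append({"contig": "chr1", "pos": p.ext.start + 3,
                         "ref": "A", "alt": "G", "genotype": "het"})
        flags, count, cov = flag_arm_variants(probe_table.table,
                                              pd.DataFrame(rows))
        assert count == 10
        flagged = {pid for pid, f in flags.items() if f}
        assert flagged == {p.probe_id for p in panel.designed[:10]}

    def test_gapfill_only_variant_not_flagged(self, panel, probe_table):
        p = panel.designed[0]
        v = pd.DataFrame([{"contig": "chr1", "pos": p.tile.start + 50,
                           "ref": "A", "alt": "G", "genotype": "het"}])
        flags, count, _ = flag_arm_variants(probe_table.table, v)
        assert count == 0

    def test_unknown_contig_warned_and_skipped(self, probe_table):
        v = pd.DataFrame([{"contig": "chrUn", "pos": 1, "ref": "A",
                           "alt": "G", "genotype": "het"}])
        with pytest.warns(UserWarning, match="chrUn"):
            _, count, _ = flag_arm_variants(probe_table.table, v)
        assert count == 0

    def test_covariate_table_columns(self, panel, probe_table):
        _, _, cov = flag_arm_variants(probe_table.table, pd.DataFrame(
            columns=["contig", "pos", "ref", "alt", "genotype"]))
        assert list(cov.columns) == ["probe_id", "ext_tm", "ext_gc", "ext_len",
                                     "lig_tm", "lig_gc", "lig_len", "arm_variant"]
        assert len(cov) == len(panel.designed)


def test_quality_mode_switch():
    q1 = np.array([10, 20, 30], dtype=np.int32)
    q2 = np.array([5, 40, 14], dtype=np.int32)
    floor = readproc._representative_score(q1, q2, DedupParams())
    assert floor == 20 + 30 + 40  # only bases >= 15 count
    threshold = readproc._representative_score(
        q1, q2, DedupParams(quality_mode="threshold"))
    assert threshold == int(q1.sum() + q2.sum())


def test_dedup_params_validation():
    with pytest.raises(ValueError):
        DedupParams(quality_mode="mean")
    with pytest.raises(ValueError):
        DedupParams(q_floor=-1)
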