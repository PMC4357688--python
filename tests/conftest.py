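"""Shared fixtures: a random reference, a designed panel, and a large
error-free simulated capture run reused by the dedup/quantification tests."""

from types import SimpleNamespace

import numpy as np
import pytest

from mipkit import capture_sim, designer, genome_index, readproc


def random_genome(seed: int, length: int, contig: str = "chr1"):
    rng = np.random.default_rng(seed)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
    return genome_index.ReferenceGenome({contig: seq})


def as_pair_tuples(pairs):
    return ((p.pair_id, p.r1_seq, p.r1_qual, p.r2_seq, p.r2_qual) for p in pairs)


@pytest.fixture(scope="session")
def genome():
    return random_genome(42, 50_000)


@pytest.fixture(scope="session")
def panel(genome):
    regions = [designer.Region("chr1", 2000, 3000, "r1")]
    probes, report = designer.design_panel(regions, genome, seed=7)
    return SimpleNamespace(regions=regions, probes=probes, report=report,
                           designed=[p for p in probes if p.status == "designed"])


@pytest.fixture(scope="session")
def probe_table(panel, tmp_path_factory):
    out = tmp_path_factory.mktemp("panel")
    paths = designer.export_design(panel.probes, panel.report, out)
    table = readproc.load_probe_table(paths["probes"])
    return SimpleNamespace(paths=paths, table=table,
                           records=readproc.probe_records(table))


@pytest.fixture(scope="session")
def sim_large(genome, panel, probe_table):
    """~25k capture events, ~50k molecules; no sequencing errors; one extra
    PCR copy per event on average (geometric mean 1 -> expected duplicate
    fraction 1/2)."""
    params = capture_sim.SimParams(
        mean_events=1300, duplicate_mean=1.0, abundance_sigma=0.0,
        error_rate=0.0, seed=11,
    )
    variants = capture_sim.plant_variants(genome, params)
    truth, molecules = capture_sim.simulate_capture_products(
        panel.designed, genome, variants, params
    )
    pairs = capture_sim.emit_read_pairs(molecules, params)
    records = readproc.process_pairs(as_pair_tuples(pairs), probe_table.records)
    valid = [r for r in records if r.arms_found and r.length_valid]
    unique, dups = readproc.deduplicate(valid)
    return SimpleNamespace(params=params, variants=variants, truth=truth,
                           molecules=molecules, pairs=pairs, records=records,
                           valid=valid, unique=unique, dups=dups)
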