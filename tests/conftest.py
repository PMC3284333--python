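import numpy as np
import pytest

import sporepool.mapping as mp
import sporepool.pileup as pl
import sporepool.simulate as sim
from sporepool.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def small_genome() -> sim.ReferenceGenome:
    return sim.generate_genome(1, [50_000], 0.5, seed=101)


@pytest.fixture(scope="session")
def two_contig_genome() -> sim.ReferenceGenome:
    return sim.generate_genome(2, [30_000, 20_000], 0.5, seed=102)


@pytest.fixture(scope="session")
def mapped_pool(small_genome):
    """One pooled sample simulated, cleaned, mapped and piled up (shared)."""
    rng = np.random.default_rng(7)
    specs = sim.random_snp_specs(small_genome, 12, rng, lineage="L")
    fixed = sim.MutationSpec("snp", specs[0].contig, specs[0].pos,
                             specs[0].ref_allele, specs[0].alt_allele,
                             lineage="L", causative=True)
    specs = [fixed] + specs[1:]
    _, truth = sim.plant_mutations(small_genome, specs)
    design = sim.PoolDesign(["mut", "wt"], ["L"],
                            {"mut": {"L": "fixed"}, "wt": {"L": "counterselected"}},
                            n_isolates=40)
    pool = sim.simulate_pool(truth, design, "mut", seed=8)
    r1, r2 = sim.simulate_reads(small_genome, pool, coverage=35, read_len=76,
                                insert_mean=2000, insert_sd=200,
                                error_rate=0.0, n_rate=0.0, seed=9)
    index = mp.ReferenceIndex(small_genome, 20)
    al1 = mp.map_reads(r1, index)
    al2 = mp.map_reads(r2, index)
    mp.pair_inserts(al1, al2)
    pile = pl.build_pileup("mut", [al1, al2], small_genome)
    return {"genome": small_genome, "truth": truth, "design": design, "pool": pool,
            "reads": (r1, r2), "alignments": (al1, al2), "pileup": pile}


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """A full four-pool pipeline run at desk scale (shared across tests)."""
    out = tmp_path_factory.mktemp("run")
    cfg = PipelineConfig(seed=42, outdir=str(out), genome_length=200_000,
                         n_background=60, coverage=40)
    report = run_pipeline(cfg)
    return {"cfg": cfg, "report": report, "outdir": str(out)}
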