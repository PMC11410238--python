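import numpy as np
import pytest

from intertaxon.genome import Genome
from intertaxon.simulate import (
    SimConfig,
    SVSpec,
    apply_svs,
    evolve_lineage,
    generate_ancestor,
)


def random_genome(length: int, seed: int, n_chromosomes: int = 1, gc: float = 0.4) -> Genome:
    cfg = SimConfig(
        ancestor_length=length, n_chromosomes=n_chromosomes, gc_content=gc, seed=seed
    )
    return generate_ancestor(cfg)


@pytest.fixture
def small_ancestor() -> Genome:
    return random_genome(20_000, seed=11)


def five_event_scenario(seed: int):
    """Reference + rearranged query carrying the five-event architecture.

    One reciprocal translocation, two non-reciprocal translocations across
    three chromosomes, one large inversion and one deletion, at reduced
    chromosome scale, plus a planted 500-bp deletion below the size filter.
    Returns (reference, rearranged query, applied event records).
    """
    cfg = SimConfig(ancestor_length=80_000, n_chromosomes=6, seed=seed)
    reference = generate_ancestor(cfg)
    query, _ = evolve_lineage(reference, 0.02, seed + 1000, "query")
    events = [
        SVSpec("reciprocal_translocation", donor="chr2", breakpoint=74_600,
               acceptor="chr4", acceptor_breakpoint=48_200),
        SVSpec("nonreciprocal_translocation", donor="chr6", breakpoint=20_000,
               acceptor="chr1", acceptor_breakpoint=50_000, size=43_300),
        SVSpec("nonreciprocal_translocation", donor="chr1", breakpoint=10_000,
               acceptor="chr3", acceptor_breakpoint=30_000, size=14_300),
        SVSpec("inversion", donor="chr5", breakpoint=15_000, size=48_700),
        SVSpec("deletion", donor="chr3", breakpoint=60_000, size=5_000),
        SVSpec("deletion", donor="chr5", breakpoint=70_000, size=500),
    ]
    rearranged, truth = apply_svs(query, events)
    return reference, rearranged, truth.sv_events


def genotype_table(genotypes, populations, L, positions=None, ploidy=1, depth=None,
                   qual=None):
    """VariantTable from a plain genotype matrix, for estimator tests."""
    from intertaxon.popgen import VariantTable

    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape
    samples = [f"s{i}" for i in range(n_samples)]
    pops = {s: populations[i] for i, s in enumerate(samples)} if isinstance(
        populations, (list, tuple)
    ) else populations
    sites = {
        "chrom": ["chr1"] * n_sites,
        "pos": positions if positions is not None else list(range(1, n_sites + 1)),
        "ref": ["A"] * n_sites,
        "alt": ["T"] * n_sites,
    }
    if qual is not None:
        sites["qual"] = qual
    import pandas as pd

    return VariantTable(
        pd.DataFrame(sites), g, samples, pops, L, ploidy=ploidy,
        depth=np.asarray(depth, dtype=float) if depth is not None else None,
    )
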