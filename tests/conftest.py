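import warnings

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from plastpop import (
    AlignedSet,
    collapse_haplotypes,
    simulate_population_alignment,
    simulate_reference_plastome,
    trim_alignment,
)
from plastpop.simulate import DemographySpec, Hotspot, PlastomeSpec, default_demo_spec


@pytest.fixture(scope="session")
def demo_plastome():
    """Compact quadripartite plastome with AT-rich, SSR-seeded hotspots."""
    spec, _ = default_demo_spec()
    ref, ann = simulate_reference_plastome(spec, seed=1)
    return spec, ref, ann


@pytest.fixture(scope="session")
def snp_hotspot_plastome():
    """SNP + indel hotspot plastome without seeded SSRs (clean coordinates)."""
    hotspots = [
        Hotspot(1200, 1799, 0.20, 0.02, 0.008),
        Hotspot(3600, 4199, 0.22, 0.02, 0.008),
        Hotspot(6200, 6799, 0.20, 0.02, 0.008),
        Hotspot(8300, 8899, 0.24, 0.02, 0.008),
    ]
    spec = PlastomeSpec(6000, 1200, 2400, 0.37, hotspots)
    ref, ann = simulate_reference_plastome(spec, seed=1)
    return spec, ref, ann


def two_deme_demography(seed, n=6, divergence=8.0, admixture=0.0):
    return DemographySpec(
        populations=[("A", n, "g1"), ("B", n, "g2")],
        haplotype_pool_size=6,
        divergence_steps=divergence,
        admixture=admixture,
        seed=seed,
    )


@pytest.fixture(scope="session")
def simulated_study(demo_plastome):
    """One full five-population simulated study: alignment, truth, haplotypes."""
    spec, ref, ann = demo_plastome
    _, demo = default_demo_spec()
    demo.seed = 3
    aln, truth, popmap = simulate_population_alignment(ref, demo, spec, ann)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        trimmed, kept = trim_alignment(aln)
        table, dists = collapse_haplotypes(trimmed)
    return {
        "aln": aln,
        "trimmed": trimmed,
        "kept": kept,
        "truth": truth,
        "popmap": popmap,
        "table": table,
        "dists": dists,
    }


@pytest.fixture
def tiny_alignment():
    return AlignedSet(
        [("s1", "AAT"), ("s2", "AAT"), ("s3", "ACT")],
        {"s1": "p1", "s2": "p1", "s3": "p2"},
    )
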