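import math

import pytest

from metachip.annotation import derive_intergenic_regions
from metachip.normalize import normalize_probe_table
from metachip.simulate import SimulationParams, simulate_bundle


def flat_params(**overrides) -> SimulationParams:
    """Noise-free configuration with one constant planted ORF level.

    All stochastic signal features are off (noise, boundary bump, length
    slope, rate spread, occupancy ramp/noise) so every ORF probe carries
    the same planted enrichment and recovery can be asserted exactly.
    """
    base = dict(
        noise_sd=0.0,
        occupancy_noise_sd=0.0,
        occupancy_transition_bp=0,
        boundary_bump_height=0.0,
        enrichment_slope_length=0.0,
        rate_sdlog=0.0,
        n_genes=30,
        n_chroms=1,
        seed=5,
    )
    base.update(overrides)
    return SimulationParams(**base)


def flat_orf_level(params: SimulationParams) -> float:
    """Planted constant exon-level enrichment of a flat_params simulation,
    computed from first principles (rate = exp(meanlog), rounded as the
    generator rounds)."""
    rate = round(math.exp(params.rate_meanlog), 4)
    return (params.intergenic_baseline
            + params.enrichment_slope_rate * math.log2(1 + rate)
            + params.enrichment_slope_length * 0.0)


@pytest.fixture(scope="session")
def noisy_bundle():
    """One moderately sized noisy simulation shared across tests."""
    params = SimulationParams(n_genes=80, n_chroms=2, fraction_intron_containing=0.3, seed=11)
    layout, genes, rates, probes, occupancy = simulate_bundle(params)
    track = normalize_probe_table(probes)
    intergenic = derive_intergenic_regions(genes, layout)
    return {
        "params": params, "layout": layout, "genes": genes, "rates": rates,
        "probes": probes, "occupancy": occupancy, "track": track, "intergenic": intergenic,
    }
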