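"""Shared fixtures: the packaged site table, its PSSM, and simulated datasets.

Simulation fixtures are session-scoped because generating a full-size
synthetic dataset takes a few seconds and many tests share it.
"""

import numpy as np
import pytest

from sigma54 import io as gio
from sigma54 import motif as mot
from sigma54 import peaks as pk
from sigma54 import simulate as sim


@pytest.fixture(scope="session")
def fixture_sites():
    return gio.load_site_fixture()


@pytest.fixture(scope="session")
def fixture_frame():
    return gio.load_site_fixture_frame()


@pytest.fixture(scope="session")
def pssm(fixture_sites):
    return mot.build_pssm([s.motif for s in fixture_sites])


@pytest.fixture(scope="session")
def paper_sim(pssm):
    """Full-size synthetic dataset mirroring the study conditions:
    135 sites, E. coli-like coding density, default depths; seed 1."""
    cfg = sim.SimConfig(seed=1)
    genome, annotation = sim.generate_genome(cfg)
    genome, truth = sim.plant_sites(genome, annotation, pssm, cfg)
    sigma, plus, minus, ctrl, strengths = sim.simulate_chip_coverage(genome, truth, cfg)
    norm = pk.normalize_coverage(sigma)
    threshold = pk.compute_threshold(norm)
    called = pk.call_peaks(norm, threshold)
    return {
        "config": cfg,
        "genome": genome,
        "annotation": annotation,
        "truth": truth,
        "sigma": sigma,
        "rnap_plus": plus,
        "rnap_minus": minus,
        "input": ctrl,
        "strengths": strengths,
        "norm": norm,
        "threshold": threshold,
        "peaks": called,
    }


@pytest.fixture(scope="session")
def small_sim(pssm):
    """Compact planted dataset (300 kb, 50 sites) for ortholog replicates."""
    cfg = sim.SimConfig(seed=3, genome_length=300_000, n_sites=50)
    genome, annotation = sim.generate_genome(cfg)
    genome, truth = sim.plant_sites(genome, annotation, pssm, cfg)
    return {"config": cfg, "genome": genome, "annotation": annotation, "truth": truth}


def truth_site_records(truth):
    """Adapt planted-site truth rows to SiteRecord objects."""
    return [
        gio.SiteRecord(
            site_id=t.site_id,
            peak_center=t.position,
            fat=1,
            motif=t.sequence,
            motif_center=t.position,
            motif_strand=t.strand,
            overlapping_gene=t.host_gene or "",
            downstream_gene=t.downstream_gene,
            distance=max(t.distance, 0),
            pssm_score=0.0,
        )
        for t in truth
    ]


@pytest.fixture(scope="session")
def small_sim_records(small_sim):
    return truth_site_records(small_sim["truth"])
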