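"""Shared fixtures: a small synthetic world reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from tnscape import hmm, motif, simulate
from tnscape.genome import annotation_class_track


@pytest.fixture(scope="session")
def small_world():
    """A 50-kb single-chromosome world with genes, tracks and truth states."""
    cfg = simulate.SimulationConfig(chrom_lengths={"chrI": 50_000})
    genome, annotations, truth = simulate.generate_genome_and_annotations(cfg, 101)
    nuc, cons, expr = simulate.generate_covariate_tracks(
        genome, annotations, cfg, 102, truth
    )
    return {
        "config": cfg,
        "genome": genome,
        "annotations": annotations,
        "truth": truth,
        "nucleosome": nuc,
        "conservation": cons,
        "expression": expr,
        "classes": annotation_class_track(genome, annotations),
    }


@pytest.fixture(scope="session")
def small_series(small_world):
    """Generative-twin observed series over the small world."""
    cfg = small_world["config"]
    genome = small_world["genome"]
    nuc_norm = hmm.normalize_nucleosome(small_world["nucleosome"])
    imss = motif.imss_scan(genome, simulate.planted_motif(), stranded="plus")
    series = simulate.simulate_observed_series(
        genome, small_world["truth"], nuc_norm, imss, cfg, 103,
        class_codes=small_world["classes"],
    )["chrI"]
    return series


@pytest.fixture(scope="session")
def ident_series():
    """Twin series from the identifiable recovery conditions (60 kb)."""
    cfg = simulate.recovery_config(60_000)
    genome, annotations, truth = simulate.generate_genome_and_annotations(cfg, 201)
    nuc, _, _ = simulate.generate_covariate_tracks(genome, annotations, cfg, 202, truth)
    nuc_norm = hmm.normalize_nucleosome(nuc)
    imss = motif.imss_scan(genome, simulate.planted_motif(), stranded="plus")
    classes = annotation_class_track(genome, annotations)
    return simulate.simulate_observed_series(
        genome, truth, nuc_norm, imss, cfg, 203, class_codes=classes
    )["chrI"]


@pytest.fixture(scope="session")
def site_world(small_world):
    """Count-level site table + read records over the small world."""
    cfg = small_world["config"]
    genome = small_world["genome"]
    nuc_norm = hmm.normalize_nucleosome(small_world["nucleosome"])
    imss = motif.imss_scan(genome, simulate.planted_motif(), stranded="plus")
    sites = simulate.simulate_insertion_counts(
        genome, small_world["truth"], nuc_norm, imss, cfg, 104
    )
    records = simulate.simulate_read_records(sites, cfg, 105)
    return {"sites": sites, "records": records, "imss": imss, "nuc_norm": nuc_norm}


def random_emissions(rng: np.random.Generator, n: int) -> list[hmm.ZIPEmission]:
    """Random but sane ZIP emissions for oracle tests."""
    return [
        hmm.ZIPEmission(
            beta0=float(rng.uniform(-1.5, 1.5)),
            beta1=float(rng.uniform(-0.5, 0.5)),
            beta2=float(rng.uniform(-0.5, 0.5)),
            omega=float(rng.uniform(0.0, 0.7)),
        )
        for _ in range(n)
    ]


def random_model(rng: np.random.Generator, n: int) -> hmm.CovariateHMM:
    pi = rng.dirichlet(np.ones(n))
    A = rng.dirichlet(np.ones(n), size=n)
    return hmm.CovariateHMM(n, pi, A, random_emissions(rng, n))


def random_series(rng: np.random.Generator, T: int) -> hmm.ObservedSeries:
    return hmm.ObservedSeries(
        "chrT",
        np.arange(T),
        rng.poisson(1.0, size=T),
        rng.normal(size=T),
        rng.normal(scale=0.5, size=T),
    )
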