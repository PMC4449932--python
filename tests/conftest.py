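"""Shared fixtures: one small end-to-end run reused across test modules."""

from __future__ import annotations

import pytest

from maizefp import fingerprint_eval, locusqc, panelselect, signalmodel, simdata


@pytest.fixture(scope="session")
def small_run():
    """A 400-locus default-defect universe pushed through the full
    pipeline on a 96-sample study panel (computed once per session)."""
    seed = 20_240_101
    universe = simdata.generate_locus_universe(400, seed=seed)
    samples, truth = simdata.study_panel(universe, seed=seed)
    intensities = simdata.generate_intensities(universe, samples, truth, seed=seed)
    meta = simdata.samples_frame(samples)
    cluster_file = signalmodel.build_cluster_file(intensities, meta)
    result = signalmodel.call_genotypes(intensities, cluster_file)
    qc = locusqc.score_panel(intensities, result.calls, cluster_file, meta)
    inbreds = list(meta.index[meta["role"] == "inbred"])
    maf = fingerprint_eval.compute_maf(result.calls, inbreds)
    report = panelselect.run_pipeline(qc, simdata.universe_frame(universe), maf)
    return {
        "seed": seed,
        "universe": universe,
        "samples": samples,
        "truth": truth,
        "intensities": intensities,
        "meta": meta,
        "cluster_file": cluster_file,
        "calls": result.calls,
        "confidence": result.confidence,
        "qc": qc,
        "maf": maf,
        "report": report,
        "inbreds": inbreds,
    }


@pytest.fixture()
def clean_universe():
    """200 defect-free loci for tests that need clean geometry."""
    return simdata.generate_locus_universe(200, defect_fractions={}, seed=7)
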