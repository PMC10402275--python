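import numpy as np
import pytest

from rrnpipe import synthetic
from rrnpipe.pipeline import mock_composition, run_synthetic_pipeline


@pytest.fixture(scope="session")
def clean_run():
    """A small zero-error, concatemer-free simulated run (ground truth trivially
    recoverable at every stage)."""
    cfg = synthetic.SimConfig(
        n_taxa=8, n_samples=2, reads_per_sample=150,
        error_rate=0.0, concatemer_fraction=0.0, seed=11,
    )
    db = synthetic.build_reference(cfg)
    scheme = synthetic.make_scheme(cfg.n_samples, seed=cfg.seed)
    mock = mock_composition(db)
    comp = {s: dict(mock) for s in sorted(scheme.sample_map.values())}
    reads, manifest = synthetic.simulate_reads(db, scheme, comp, cfg)
    return {"config": cfg, "db": db, "scheme": scheme,
            "composition": comp, "reads": reads, "manifest": manifest}


@pytest.fixture(scope="session")
def noisy_run():
    """An error-bearing run (1% substitutions) with concatemers, for
    robustness and retention checks."""
    cfg = synthetic.SimConfig(
        n_taxa=8, n_samples=2, reads_per_sample=400,
        error_rate=0.01, concatemer_fraction=0.05, seed=13,
    )
    db = synthetic.build_reference(cfg)
    scheme = synthetic.make_scheme(cfg.n_samples, seed=cfg.seed)
    mock = mock_composition(db)
    comp = {s: dict(mock) for s in sorted(scheme.sample_map.values())}
    reads, manifest = synthetic.simulate_reads(db, scheme, comp, cfg)
    cat_reads, cat_manifest = synthetic.inject_concatemers(
        reads, manifest, cfg.concatemer_fraction, cfg.seed, adapter=cfg.adapter)
    return {"config": cfg, "db": db, "scheme": scheme, "composition": comp,
            "reads": reads, "manifest": manifest,
            "cat_reads": cat_reads, "cat_manifest": cat_manifest}


@pytest.fixture(scope="session")
def mock_pipeline_result():
    """The full study-condition benchmark: 8-taxon mock at known proportions,
    1% error, 2,000 reads/sample, 3 samples, seeded."""
    cfg = synthetic.SimConfig(
        n_taxa=12, n_samples=3, reads_per_sample=2000,
        error_rate=0.01, concatemer_fraction=0.02, seed=20260926,
    )
    return run_synthetic_pipeline(cfg)
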