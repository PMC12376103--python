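"""Shared fixtures: default parameters and the session-scoped sampler runs.

The long runs are generated once per session at the statistics used
throughout the analysis tests (classical: 6e5 sweeps; quantum: P = 6,
2.3e5 sweeps recorded every other sweep; Wannier runs: ~1e4 recorded
frames)."""

import numpy as np
import pytest

import shblab as sl


@pytest.fixture(scope="session")
def params():
    return sl.SHBModelParams()


@pytest.fixture(scope="session")
def pyro_fixture(params):
    return sl.build_pyro_fixture(params)


@pytest.fixture(scope="session")
def tracked_sites(pyro_fixture):
    return list(sl.tracked_oxygen_sites(pyro_fixture))


@pytest.fixture(scope="session")
def classical_run(params):
    cfg = sl.SamplerConfig(n_sweeps=600_000, seed=1)
    return sl.sample_classical(params, cfg)


@pytest.fixture(scope="session")
def quantum_run(params):
    cfg = sl.SamplerConfig(n_sweeps=230_000, seed=1, P=6, record_every=2)
    return sl.sample_pimc(params, cfg)


@pytest.fixture(scope="session")
def classical_wannier_run(params):
    cfg = sl.SamplerConfig(n_sweeps=112_000, seed=31, record_every=10, emit_wannier=True)
    return sl.sample_classical(params, cfg)


@pytest.fixture(scope="session")
def quantum_wannier_run(params):
    cfg = sl.SamplerConfig(n_sweeps=30_000, seed=32, record_every=10, P=6, emit_wannier=True)
    return sl.sample_pimc(params, cfg)


@pytest.fixture(scope="session")
def classical_shb(classical_run):
    triples = sl.detect_shb_tracked(classical_run)
    assert len(triples) == 1
    return triples[0]


@pytest.fixture(scope="session")
def quantum_shb(quantum_run):
    triples = sl.detect_shb_tracked(quantum_run)
    assert len(triples) == 1
    return triples[0]
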