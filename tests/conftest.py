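"""Shared fixtures: small synthetic references and depth tracks."""

import numpy as np
import pytest

import goatcnv as g

SEED = 1234


@pytest.fixture(scope="session")
def small_config():
    return g.SimulationConfig(seed=SEED, n_sequences=2, sequence_length=100_000)


@pytest.fixture(scope="session")
def small_reference(small_config):
    return g.simulate_reference(small_config, n_genes=10, gene_length=1_500)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)


def make_track(counts_by_seq, sample_id="S", window=200, step=100):
    """Build a WindowDepthTrack directly from window-count arrays."""
    counts = {s: np.asarray(a, dtype=float) for s, a in counts_by_seq.items()}
    lengths = {s: (len(a) - 1) * step + window for s, a in counts.items()}
    return g.WindowDepthTrack(
        sample_id=sample_id,
        window_size=window,
        step=step,
        counts=counts,
        sequence_lengths=lengths,
    )
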