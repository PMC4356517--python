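import pytest

import alurecomb as ar

# Standard study conditions: 300-bp synthetic consensus, 5% evenly spaced
# divergence (one diagnostic site every 20 bp), default cassette geometry.
CONSENSUS_SEED = 101
DIVERGENCE_SEED = 202
CASSETTE_SEED = 303


@pytest.fixture(scope="session")
def consensus():
    return ar.synthetic_consensus(300, seed=CONSENSUS_SEED)


@pytest.fixture(scope="session")
def pair5(consensus):
    diverged = ar.generate_diverged_alu(consensus, 5, "evenly_spaced", seed=DIVERGENCE_SEED)
    return ar.AluPair.from_ungapped(diverged, consensus)


@pytest.fixture(scope="session")
def cassette5(pair5):
    return ar.build_cassette(pair5, seed=CASSETTE_SEED)


@pytest.fixture(scope="session")
def imap5(pair5):
    return ar.build_interval_map(pair5)


def make_pair(consensus, divergence, mode="evenly_spaced", seed=DIVERGENCE_SEED):
    diverged = ar.generate_diverged_alu(consensus, divergence, mode, seed=seed)
    return ar.AluPair.from_ungapped(diverged, consensus)
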