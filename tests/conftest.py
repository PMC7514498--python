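import numpy as np
import pytest

from speechlaws import SynthSpec, generate_corpus, read_alignment

TINY_TSV = """speaker\tlevel\tlabel\tstart\tend
s1\tword\tpau\t0.000\t0.300
s1\tphoneme\tp\t0.000\t0.100
s1\tphoneme\ta\t0.100\t0.180
s1\tphoneme\tu\t0.180\t0.300
"""


@pytest.fixture
def tiny_tsv(tmp_path):
    """Three phoneme rows spanning one word row."""
    path = tmp_path / "tiny.tsv"
    path.write_text(TINY_TSV, encoding="utf-8")
    return path


@pytest.fixture
def tiny_corpus(tiny_tsv):
    return read_alignment(tiny_tsv)


@pytest.fixture(scope="session")
def coupled_corpus():
    """50k-token corpus with the Zipf/brevity/size-rank coupling.

    The 100-type vocabulary keeps every type's token count high enough
    that per-type mean durations are well estimated (least-squares
    recovery of the brevity rate is then consistent; see docs/methods.md).
    """
    spec = SynthSpec(seed=5, zipf_alpha=1.42, brevity_lambda=23.8, vocab_size=100)
    return spec, generate_corpus(spec, 50_000)


@pytest.fixture(scope="session")
def default_corpus():
    """Mid-sized corpus under the default (realistic) generator conditions."""
    spec = SynthSpec(seed=3)
    return spec, generate_corpus(spec, 20_000)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
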