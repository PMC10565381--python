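import numpy as np
import pytest
from hypothesis import settings

from lncscreen.annotation_io import GenomicInterval, TranscriptModel
from lncscreen.synthetic import GeneratorConfig

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20369)


@pytest.fixture
def small_cfg():
    """A scaled-down generator configuration for fast unit tests."""
    return GeneratorConfig(
        n_genes=300, n_de=30, n_background=400, n_planted_regulated=12, n_lowcount=20
    )


def make_transcript(exon_spans, strand="+", chrom="chr1", tid="t1", gid="g1",
                    annotated=False):
    return TranscriptModel(
        tid,
        gid,
        tuple(GenomicInterval(chrom, s, e, strand) for s, e in exon_spans),
        annotated=annotated,
    )


@pytest.fixture
def make_t():
    return make_transcript
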