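import numpy as np
import pytest

from tagseq3.annotation import TranscriptModel
from tagseq3.peaks import Peak
from tagseq3.synthetic import FragmentOffsetModel, ToyGenome, make_toy_annotation


@pytest.fixture
def genome():
    return ToyGenome({"chr1": 1_000_000, "chr2": 800_000})


@pytest.fixture
def toy_annotation(genome):
    return make_toy_annotation(genome, n_coding=8, n_lncrna=4, n_unannotated_loci=4, seed=11)


@pytest.fixture
def offsets():
    return FragmentOffsetModel(mean_offset=275, spread=25)


def make_peak(peak_id="p1", chrom="chr1", strand="+", start=100, end=200,
              n_reads=300, n_unique=30, per_sample=None):
    return Peak(peak_id, chrom, strand, start, end, n_reads, n_unique,
                per_sample or {"s1": n_reads})


def make_transcript(tid="t1", chrom="chr1", strand="+", exons=((1000, 2000),),
                    is_coding=True, source=None):
    if source is None:
        source = "refseq-like" if is_coding else "lncRNA-catalog-1"
    return TranscriptModel(tid, chrom, strand, list(exons), is_coding, source)
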