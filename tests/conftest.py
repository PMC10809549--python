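import numpy as np
import pytest

from karyoshuffle.io_formats import GenomicInterval, OrthologHit
from karyoshuffle.rearrangements import SpeciesTree


@pytest.fixture
def tree() -> SpeciesTree:
    return SpeciesTree()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def make_hit(og, species, chrom, start, end, strand="+", status="single"):
    sign = {"+": 1, "-": -1}.get(strand) if status == "single" else None
    return OrthologHit(
        ortholog_id=og,
        species=species,
        chrom=chrom,
        interval=GenomicInterval(chrom, start, end, strand=strand if strand in "+-" else ".", label=og),
        sign=sign,
        copy_status=status,
    )
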