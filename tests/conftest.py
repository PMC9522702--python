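import numpy as np
import pytest

from mirnapop.annotation import MirnaHairpin
from mirnapop.variation import HaplotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


def random_hairpin(rng, chrom="chr1", strand=None, both_matures=True,
                   start=None) -> MirnaHairpin:
    """A random hairpin with valid geometry: span 60-120 bp, 22-bp matures."""
    strand = strand or rng.choice(["+", "-"])
    start = int(start if start is not None else rng.integers(1_000, 1_000_000))
    span_len = int(rng.integers(70, 121))
    m_len = 22
    pre5 = int(rng.integers(0, 6))
    loop = int(rng.integers(8, span_len - 2 * m_len - pre5))
    m5 = (start + pre5, start + pre5 + m_len)
    m3 = (m5[1] + loop, m5[1] + loop + m_len)
    assert m3[1] <= start + span_len
    kwargs = {"mature5p": m5, "mature3p": m3}
    if not both_matures:
        drop = rng.choice(["mature5p", "mature3p"])
        kwargs.pop(drop)
    if strand == "-":  # arms swap transcript roles on the minus strand
        if "mature5p" in kwargs and "mature3p" in kwargs:
            kwargs["mature5p"], kwargs["mature3p"] = kwargs["mature3p"], kwargs["mature5p"]
        elif "mature5p" in kwargs:
            kwargs = {"mature3p": kwargs["mature5p"]}
        else:
            kwargs = {"mature5p": kwargs["mature3p"]}
    return MirnaHairpin(id=f"mir{start}", chrom=chrom, strand=strand,
                        span=(start, start + span_len), **kwargs)


def random_hapmat(rng, n_hap=20, n_sites=50, spacing=100, population="POP1"
                  ) -> HaplotypeMatrix:
    hap = rng.integers(0, 2, size=(n_hap, n_sites)).astype(np.int8)
    positions = np.cumsum(rng.integers(1, spacing, n_sites))
    return HaplotypeMatrix(population=population, haplotypes=hap,
                           positions=positions,
                           site_ids=[f"s{i}" for i in range(n_sites)])
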