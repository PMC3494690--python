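import numpy as np
import pytest

from poolld.pair_counting import HaplotypeTable, LocusCounts
from poolld.variants_io import SnpSite


def make_table(
    x11: int,
    x12: int,
    x21: int,
    x22: int,
    extra_a: dict | None = None,
    extra_b: dict | None = None,
) -> HaplotypeTable:
    """A haplotype table whose all-read counts default to its own marginals.

    ``extra_a``/``extra_b`` add non-intersecting coverage to the all-read
    counts, decoupling the all-read frequencies from the table.
    """
    site_a = SnpSite("chr2L", 100, ("A", "T"))
    site_b = SnpSite("chr2L", 150, ("C", "G"))
    counts_a = {"A": x11 + x12, "T": x21 + x22}
    counts_b = {"C": x11 + x21, "G": x12 + x22}
    for base, k in (extra_a or {}).items():
        counts_a[base] = counts_a.get(base, 0) + k
    for base, k in (extra_b or {}).items():
        counts_b[base] = counts_b.get(base, 0) + k
    return HaplotypeTable(
        site_a=site_a,
        site_b=site_b,
        allele_a_major="A",
        allele_a_minor="T",
        allele_b_major="C",
        allele_b_minor="G",
        x11=x11,
        x12=x12,
        x21=x21,
        x22=x22,
        locus_a_all=LocusCounts(site_a, counts_a),
        locus_b_all=LocusCounts(site_b, counts_b),
    )


def brute_force_r2(x11: int, x12: int, x21: int, x22: int) -> float:
    """Independent r^2: squared Pearson correlation of allele indicators.

    Expands the table into explicit per-template 0/1 indicator vectors and
    squares their empirical correlation — no use of the D-based formula.
    """
    a = np.concatenate(
        [np.ones(x11 + x12), np.zeros(x21 + x22)]
    )
    b = np.concatenate(
        [np.ones(x11), np.zeros(x12), np.ones(x21), np.zeros(x22)]
    )
    return float(np.corrcoef(a, b)[0, 1] ** 2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
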