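"""Two-locus haplotype tables from intersecting templates.

The central object of the method is the 2x2 haplotype table: for a pair of
polymorphic sites, x_ij counts the templates observed carrying allele i at
the first site and allele j at the second, over the *intersecting* templates
only — those yielding calls at both sites. Allele frequencies are also
tallied over *all* templates covering each locus individually, because those
marginal estimates are more precise than the intersecting-read marginals.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .variants_io import SnpSite, TemplateObservation

_BASE_ORDER = "ACGT"


@dataclass
class LocusCounts:
    """Allele counts at one site over all templates covering it."""

    site: SnpSite
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    def frequency(self, base: str) -> float:
        d = self.depth
        return self.counts.get(base, 0) / d if d else float("nan")


@dataclass
class HaplotypeTable:
    """2x2 intersecting-template haplotype counts plus all-read marginals.

    Rows index the alleles at ``site_a`` (major, minor), columns the alleles
    at ``site_b``. ``n`` is the intersecting read depth; templates carrying a
    non-retained (third) allele at either site are excluded from both the
    cells and ``n``, so x11+x12+x21+x22 == n.
    """

    site_a: SnpSite
    site_b: SnpSite
    allele_a_major: str
    allele_a_minor: str
    allele_b_major: str
    allele_b_minor: str
    x11: int
    x12: int
    x21: int
    x22: int
    locus_a_all: LocusCounts
    locus_b_all: LocusCounts

    def __post_init__(self) -> None:
        if self.site_a.chrom != self.site_b.chrom or not (
            self.site_a.pos < self.site_b.pos
        ):
            raise ValueError("site_a must precede site_b on the same chromosome")

    @property
    def n(self) -> int:
        return self.x11 + self.x12 + self.x21 + self.x22

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.x11, self.x12, self.x21, self.x22)

    @property
    def distance(self) -> int:
        return self.site_b.pos - self.site_a.pos

    def maf_a_all(self) -> float:
        return self.locus_a_all.frequency(self.allele_a_minor)

    def maf_b_all(self) -> float:
        return self.locus_b_all.frequency(self.allele_b_minor)


class TemplateIndex:
    """Per-site lookup of template calls, built once per run.

    Maps each site key to {template_id: base} so haplotype tables for many
    pairs can be assembled without re-scanning the template stream.
    """

    def __init__(self, observations: Iterable[TemplateObservation]):
        self.by_site: dict[tuple[str, int], dict[str, str]] = {}
        n_templates = 0
        for obs in observations:
            n_templates += 1
            for key, (base, _qual) in obs.calls.items():
                self.by_site.setdefault(key, {})[obs.template_id] = base
        self.n_templates = n_templates

    def locus_counts(self, site: SnpSite) -> LocusCounts:
        calls = self.by_site.get(site.key, {})
        return LocusCounts(site, dict(Counter(calls.values())))


def enumerate_pairs(
    sites: list[SnpSite], max_distance: int
) -> list[tuple[SnpSite, SnpSite]]:
    """All same-chromosome site pairs with 0 < posB - posA <= max_distance.

    ``sites`` must be sorted by (chrom, pos); each pair appears once with the
    upstream site first. Linkage is only estimable within the template span,
    so ``max_distance`` should be the library's maximum insert size.
    """
    if max_distance <= 0:
        raise ValueError("max_distance must be positive")
    pairs = []
    for i, a in enumerate(sites):
        for b in sites[i + 1 :]:
            if b.chrom != a.chrom:
                break
            if b.pos - a.pos > max_distance:
                break
            pairs.append((a, b))
    return pairs


def choose_biallelic(counts: LocusCounts) -> tuple[str, str]:
    """The two most frequent alleles at a locus, (major, minor).

    Ties are broken by fixed base order A < C < G < T so results are
    deterministic. A monomorphic locus (a single observed base) raises
    ``ValueError``; callers exclude such sites.
    """
    if counts.depth <= 0:
        raise ValueError(f"no coverage at {counts.site.chrom}:{counts.site.pos}")
    observed = [b for b in counts.counts if counts.counts[b] > 0]
    if len(observed) < 2:
        raise ValueError(
            f"monomorphic locus {counts.site.chrom}:{counts.site.pos}"
        )
    ranked = sorted(observed, key=lambda b: (-counts.counts[b], _BASE_ORDER.index(b)))
    return ranked[0], ranked[1]


def build_haplotype_table(
    index: TemplateIndex,
    site_a: SnpSite,
    site_b: SnpSite,
    alleles_a: tuple[str, str],
    alleles_b: tuple[str, str],
) -> HaplotypeTable:
    """Assemble the 2x2 table for one site pair from indexed template calls.

    Only templates with retained-allele calls at BOTH sites enter the cells;
    all-read marginal counts accumulate over every template covering each
    site individually. ``n`` may be zero.
    """
    calls_a = index.by_site.get(site_a.key, {})
    calls_b = index.by_site.get(site_b.key, {})
    maj_a, min_a = alleles_a
    maj_b, min_b = alleles_b
    x = [[0, 0], [0, 0]]
    if len(calls_b) < len(calls_a):
        small, other, flipped = calls_b, calls_a, True
    else:
        small, other, flipped = calls_a, calls_b, False
    for tid, base_s in small.items():
        base_o = other.get(tid)
        if base_o is None:
            continue
        base_a, base_b = (base_o, base_s) if flipped else (base_s, base_o)
        if base_a == maj_a:
            i = 0
        elif base_a == min_a:
            i = 1
        else:
            continue  # third allele: excluded from table and n
        if base_b == maj_b:
            j = 0
        elif base_b == min_b:
            j = 1
        else:
            continue
        x[i][j] += 1
    return HaplotypeTable(
        site_a=site_a,
        site_b=site_b,
        allele_a_major=maj_a,
        allele_a_minor=min_a,
        allele_b_major=maj_b,
        allele_b_minor=min_b,
        x11=x[0][0],
        x12=x[0][1],
        x21=x[1][0],
        x22=x[1][1],
        locus_a_all=index.locus_counts(site_a),
        locus_b_all=index.locus_counts(site_b),
    )


def passes_filters(
    table: HaplotypeTable,
    min_intersecting: int = 10,
    maf_cutoff: float = 0.01,
    max_depth_multiple: float | None = None,
    mean_depth: float | None = None,
) -> tuple[bool, str]:
    """Apply the estimability filters; returns (passed, reason).

    Filters, in order: intersecting depth >= ``min_intersecting`` (default
    ten); all-read minor allele frequency >= ``maf_cutoff`` (default 1%) at
    both loci; optionally, each locus depth <= ``max_depth_multiple`` x
    ``mean_depth`` — the copy-number guard used for empirical data ("less
    than twice the chromosomal average"). The reason names the first filter
    failed, or "ok".
    """
    if table.n < min_intersecting:
        return False, "min_intersecting"
    if table.maf_a_all() < maf_cutoff or table.maf_b_all() < maf_cutoff:
        return False, "maf"
    if max_depth_multiple is not None and mean_depth is not None:
        cap = max_depth_multiple * mean_depth
        if table.locus_a_all.depth > cap or table.locus_b_all.depth > cap:
            return False, "depth_cap"
    return True, "ok"
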