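"""End-to-end estimation: alignments + site list -> per-pair LD table."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from . import ld_core, pair_counting, variants_io
from .ld_core import LdEstimate
from .pair_counting import TemplateIndex
from .variants_io import SnpSite

logger = logging.getLogger(__name__)

OUTPUT_COLUMNS = [
    "chrom",
    "pos_a",
    "pos_b",
    "distance",
    "n_intersecting",
    "depth_a",
    "depth_b",
    "p_a",
    "p_b",
    "p_a_all",
    "p_b_all",
    "maf_a_all",
    "maf_b_all",
    "r2_direct",
    "r2_mle",
    "ci_low",
    "ci_high",
    "boundary_flag",
    "d_hat",
]


@dataclass
class RunSummary:
    """Log-friendly accounting of what happened to each enumerated pair."""

    n_sites: int = 0
    n_sites_monomorphic: int = 0
    n_pairs_enumerated: int = 0
    n_pairs_built: int = 0
    n_pairs_passing: int = 0
    n_boundary: int = 0
    filter_reasons: dict[str, int] = field(default_factory=dict)


def infer_max_distance(alignment: str | Path, n_records: int = 10_000) -> int:
    """Largest |TLEN| over the first records: the library's template span."""
    best = 0
    with pysam.AlignmentFile(str(alignment), check_sq=False) as af:
        for i, read in enumerate(af):
            if i >= n_records:
                break
            tlen = abs(read.template_length)
            span = tlen if tlen else (read.query_length or 0)
            best = max(best, span)
    if best <= 0:
        raise ValueError(
            "cannot infer max distance from the alignment; pass it explicitly"
        )
    return best


def estimate_ld(
    alignment: str | Path,
    sites: list[SnpSite] | str | Path,
    n_chrom: int,
    max_distance: int | None = None,
    min_baseq: int = 20,
    min_mapq: int = 0,
    min_intersecting: int = 10,
    maf_cutoff: float = 0.01,
    max_depth_multiple: float | None = None,
    drop_duplicates: bool = False,
) -> tuple[list[LdEstimate], RunSummary]:
    """Run the full estimation pipeline for every passing SNP pair.

    Results are ordered by (chrom, pos_a, pos_b) and deterministic for a
    given input. ``n_chrom`` is the number of chromosomes in the pool (for
    a pool of fully inbred lines, one per strain).
    """
    if not isinstance(sites, list):
        sites = variants_io.load_snp_sites(sites)
    if max_distance is None:
        max_distance = infer_max_distance(alignment)
    summary = RunSummary(n_sites=len(sites))

    observations = variants_io.stream_templates(
        alignment,
        sites,
        min_baseq=min_baseq,
        min_mapq=min_mapq,
        drop_duplicates=drop_duplicates,
    )
    index = TemplateIndex(observations)

    alleles: dict[tuple[str, int], tuple[str, str]] = {}
    usable_sites = []
    depths = []
    for site in sites:
        counts = index.locus_counts(site)
        if counts.depth > 0:
            depths.append(counts.depth)
        try:
            alleles[site.key] = pair_counting.choose_biallelic(counts)
        except ValueError:
            summary.n_sites_monomorphic += 1
            continue
        usable_sites.append(site)
    mean_depth = float(np.mean(depths)) if depths else 0.0

    pairs = pair_counting.enumerate_pairs(usable_sites, max_distance)
    summary.n_pairs_enumerated = len(pairs)

    estimates: list[LdEstimate] = []
    for site_a, site_b in pairs:
        table = pair_counting.build_haplotype_table(
            index, site_a, site_b, alleles[site_a.key], alleles[site_b.key]
        )
        summary.n_pairs_built += 1
        ok, reason = pair_counting.passes_filters(
            table,
            min_intersecting=min_intersecting,
            maf_cutoff=maf_cutoff,
            max_depth_multiple=max_depth_multiple,
            mean_depth=mean_depth,
        )
        if not ok:
            summary.filter_reasons[reason] = summary.filter_reasons.get(reason, 0) + 1
            continue
        direct = ld_core.direct_r2(table)
        p_a_all = table.locus_a_all.frequency(table.allele_a_major)
        p_b_all = table.locus_b_all.frequency(table.allele_b_major)
        if not (0.0 < p_a_all < 1.0 and 0.0 < p_b_all < 1.0):
            summary.filter_reasons["monomorphic_all_reads"] = (
                summary.filter_reasons.get("monomorphic_all_reads", 0) + 1
            )
            continue
        mle = ld_core.approx_mle_r2(table, p_a_all, p_b_all, n_chrom)
        if mle.boundary:
            summary.n_boundary += 1
        estimates.append(
            LdEstimate(
                chrom=site_a.chrom,
                pos_a=site_a.pos,
                pos_b=site_b.pos,
                n=table.n,
                n_eff=mle.n_eff,
                p_a=direct.p_a,
                p_b=direct.p_b,
                p_a_all=p_a_all,
                p_b_all=p_b_all,
                depth_a=table.locus_a_all.depth,
                depth_b=table.locus_b_all.depth,
                maf_a_all=table.maf_a_all(),
                maf_b_all=table.maf_b_all(),
                r2_direct=direct.r2,
                r2_mle=mle.r2,
                ci_low=mle.ci_low,
                ci_high=mle.ci_high,
                boundary=mle.boundary,
                d_hat=mle.d_hat,
            )
        )
    summary.n_pairs_passing = len(estimates)
    estimates.sort(key=lambda e: (e.chrom, e.pos_a, e.pos_b))
    logger.info(
        "estimate_ld: %d sites (%d monomorphic), %d pairs enumerated, "
        "%d passing, %d boundary-flagged; filtered: %s",
        summary.n_sites,
        summary.n_sites_monomorphic,
        summary.n_pairs_enumerated,
        summary.n_pairs_passing,
        summary.n_boundary,
        summary.filter_reasons,
    )
    return estimates, summary


def _fmt(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "NA"
    if isinstance(value, bool):
        return "TRUE" if value else "FALSE"
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def estimates_to_frame(estimates: list[LdEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": e.chrom,
                "pos_a": e.pos_a,
                "pos_b": e.pos_b,
                "distance": e.distance,
                "n_intersecting": e.n,
                "depth_a": e.depth_a,
                "depth_b": e.depth_b,
                "p_a": e.p_a,
                "p_b": e.p_b,
                "p_a_all": e.p_a_all,
                "p_b_all": e.p_b_all,
                "maf_a_all": e.maf_a_all,
                "maf_b_all": e.maf_b_all,
                "r2_direct": e.r2_direct,
                "r2_mle": e.r2_mle,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "boundary_flag": e.boundary,
                "d_hat": e.d_hat,
            }
            for e in estimates
        ],
        columns=OUTPUT_COLUMNS,
    )


def write_estimates_tsv(estimates: list[LdEstimate], path: str | Path) -> None:
    """Write the per-pair output TSV (header + 6-significant-digit floats)."""
    df = estimates_to_frame(estimates)
    with open(path, "w") as fh:
        fh.write("\t".join(OUTPUT_COLUMNS) + "\n")
        for _, row in df.iterrows():
            fh.write("\t".join(_fmt(v) for v in row.to_list()) + "\n")
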