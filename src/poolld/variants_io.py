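"""Reading polymorphic-site lists and extracting per-template base calls.

Pooled resequencing loses individual identity, but each sequencing template
(a single read or a mate pair) is still a faithful sample of one chromosome.
This module turns an alignment file plus a list of known polymorphic sites
into :class:`TemplateObservation` records: the base calls each template
contributes at those sites, after base-quality filtering and mate merging.

Coordinates are 1-based inclusive everywhere (SAM/VCF convention); the only
0-based arithmetic happens at the pysam boundary inside
:func:`stream_templates`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True, order=True)
class SnpSite:
    """A polymorphic genomic position and its candidate alleles.

    ``alleles`` holds up to four distinct upper-case bases; reduction to the
    two most frequent alleles happens downstream, from observed counts.
    """

    chrom: str
    pos: int  # 1-based
    alleles: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"duplicate alleles at {self.chrom}:{self.pos}")
        for a in self.alleles:
            if a not in _VALID_BASES:
                raise ValueError(
                    f"invalid allele {a!r} at {self.chrom}:{self.pos}"
                )

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass
class TemplateObservation:
    """Base calls one template (read or mate pair) makes at SNP sites.

    ``calls`` maps (chrom, pos) -> (base, base_quality). At most one call per
    site: overlapping mates with concordant calls count once; discordant
    mates drop the site for this template.
    """

    template_id: str
    calls: dict[tuple[str, int], tuple[str, int]] = field(default_factory=dict)


def load_snp_sites(path: str | Path, fmt: str | None = None) -> list[SnpSite]:
    """Read a polymorphic-site list from a TSV or VCF file.

    TSV columns: chrom, pos (1-based), then one or more allele columns, each
    either a single base or a slash-separated list (``A/T``). Format is
    inferred from the extension when ``fmt`` is None. Returns sites sorted by
    (chrom, pos); duplicates and malformed rows raise ``ValueError`` naming
    the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if fmt == "tsv":
        sites = _load_tsv(path)
    elif fmt == "vcf":
        sites = _load_vcf(path)
    else:
        raise ValueError(f"unknown site-list format {fmt!r}")

    seen: set[tuple[str, int]] = set()
    for s in sites:
        if s.key in seen:
            raise ValueError(f"duplicate site {s.chrom}:{s.pos} in {path}")
        seen.add(s.key)
    sites.sort(key=lambda s: (s.chrom, s.pos))
    if not sites:
        logger.warning("site list %s is empty", path)
    return sites


def _load_tsv(path: Path) -> list[SnpSite]:
    sites = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields"
                )
            chrom = fields[0]
            try:
                pos = int(fields[1])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: position {fields[1]!r} is not an integer"
                ) from exc
            alleles: list[str] = []
            for col in fields[2:]:
                for a in col.upper().split("/"):
                    if a and a not in alleles:
                        alleles.append(a)
            try:
                sites.append(SnpSite(chrom, pos, tuple(alleles)))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return sites


def _load_vcf(path: Path) -> list[SnpSite]:
    sites = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alleles = tuple(
                a.upper() for a in rec.alleles or () if a.upper() in _VALID_BASES
            )
            if len(alleles) < 2:
                logger.debug("skipping non-SNP record %s:%s", rec.chrom, rec.pos)
                continue
            sites.append(SnpSite(rec.chrom, rec.pos, alleles))
    return sites


def stream_templates(
    alignment: str | Path,
    sites: Iterable[SnpSite],
    min_baseq: int = 20,
    min_mapq: int = 0,
    drop_duplicates: bool = False,
) -> Iterator[TemplateObservation]:
    """Yield per-template base calls at SNP positions from a SAM/BAM file.

    Primary alignments are grouped by template (query) name. Reference
    positions are mapped to read bases CIGAR-aware, so positions under
    deletions, skips or clips yield no call. Calls with base quality <=
    ``min_baseq`` (a strict ``>`` threshold), reads with mapping quality
    below ``min_mapq``, and non-ACGT bases are discarded. When mates
    overlap a site: concordant calls are counted once (keeping the higher
    quality), discordant calls drop the site for that template.

    Unmapped, secondary and supplementary records are skipped silently and
    tallied in a log summary.
    """
    site_keys: set[tuple[str, int]] = {s.key for s in sites}
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in site_keys:
        by_chrom.setdefault(chrom, []).append(pos)
    for poss in by_chrom.values():
        poss.sort()

    observations: dict[str, TemplateObservation] = {}
    # sites dropped for a template due to mate disagreement
    dropped: dict[str, set[tuple[str, int]]] = {}
    n_skipped = 0
    n_used = 0

    with pysam.AlignmentFile(str(alignment), check_sq=False) as af:
        for read in af:
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or (drop_duplicates and read.is_duplicate)
            ):
                n_skipped += 1
                continue
            if (read.mapping_quality or 0) < min_mapq:
                n_skipped += 1
                continue
            chrom = read.reference_name
            if chrom not in by_chrom:
                continue
            n_used += 1
            seq = read.query_sequence
            quals = read.query_qualities
            if seq is None:
                continue
            name = read.query_name
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                key = (chrom, rpos + 1)  # pysam is 0-based
                if key not in site_keys:
                    continue
                base = seq[qpos].upper()
                qual = quals[qpos] if quals is not None else 0
                if base not in _VALID_BASES or qual <= min_baseq:
                    continue
                obs = observations.get(name)
                if obs is None:
                    obs = observations[name] = TemplateObservation(name)
                if key in dropped.get(name, ()):
                    continue
                prev = obs.calls.get(key)
                if prev is None:
                    obs.calls[key] = (base, qual)
                elif prev[0] == base:
                    if qual > prev[1]:
                        obs.calls[key] = (base, qual)
                else:  # mate disagreement: drop site for this template
                    del obs.calls[key]
                    dropped.setdefault(name, set()).add(key)

    logger.info(
        "stream_templates: %d reads used, %d skipped, %d templates with calls",
        n_used,
        n_skipped,
        sum(1 for o in observations.values() if o.calls),
    )
    for obs in observations.values():
        if obs.calls:
            yield obs


def write_site_tsv(sites: Iterable[SnpSite], path: str | Path) -> None:
    """Write a site list in the TSV layout `load_snp_sites` reads back."""
    with open(path, "w") as fh:
        for s in sorted(sites, key=lambda s: (s.chrom, s.pos)):
            fh.write(f"{s.chrom}\t{s.pos}\t" + "/".join(s.alleles) + "\n")
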