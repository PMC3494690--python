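"""Haplotype panels, pooled-read simulation and forward Wright-Fisher models.

Validation scaffold for the LD estimators. Three layers:

* :func:`generate_panel` builds a phased 0/1 haplotype panel with a chosen
  allele-frequency spectrum, optionally injecting site pairs with exact
  two-locus haplotype counts (hence exact ground-truth r^2).
* :func:`simulate_reads` emulates pooled paired-end sequencing of a panel:
  each template samples one haplotype uniformly (the pooling process), a
  start position, and a Normal insert length; per-base errors substitute a
  uniform different base. Output is coordinate-sorted SAM plus a truth table.
* :func:`wf_bottleneck_panel` runs a discrete-generation Wright-Fisher
  forward simulation (per-base mutation, single-crossover recombination)
  through an equilibrium -> bottleneck -> recovery size trajectory and
  returns a sampled panel.

Ground truth (:func:`true_r2`, :func:`pi`) is computed from the full panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .variants_io import SnpSite

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class HaplotypePanel:
    """Phased haplotypes over a reference region.

    ``matrix`` is n_hap x n_sites with entries 0 (reference allele) / 1
    (alternative allele); ``positions`` are 1-based coordinates on
    ``reference``. Every column is polymorphic after finalization.
    """

    chrom: str
    reference: str
    positions: np.ndarray  # 1-based, sorted, int
    alt_bases: np.ndarray  # dtype S1, alternative allele per site
    matrix: np.ndarray  # n_hap x n_sites, uint8

    @property
    def n_hap(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    @property
    def region_length(self) -> int:
        return len(self.reference)

    def ref_base(self, j: int) -> str:
        return self.reference[self.positions[j] - 1]

    def sites(self) -> list[SnpSite]:
        return [
            SnpSite(
                self.chrom,
                int(p),
                (self.ref_base(j), self.alt_bases[j].decode()),
            )
            for j, p in enumerate(self.positions)
        ]

    def haplotype_seq(self, i: int) -> str:
        """Full sequence of haplotype i (reference with alt substitutions)."""
        seq = np.frombuffer(self.reference.encode(), dtype="S1").copy()
        carried = self.matrix[i].astype(bool)
        seq[self.positions[carried] - 1] = self.alt_bases[carried]
        return seq.tobytes().decode()


@dataclass
class ReadSimConfig:
    """Pooled paired-end sequencing parameters."""

    read_length: int = 93
    mean_depth: float = 40.0
    insert_mean: float = 450.0
    insert_sd: float = 45.0
    error_rate: float = 0.0
    base_quality: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.insert_mean < 2 * self.read_length:
            logger.warning(
                "insert_mean %.0f < 2x read length; mates will overlap heavily",
                self.insert_mean,
            )


@dataclass
class DemographicModel:
    """Equilibrium -> bottleneck -> recovery population-size trajectory.

    Times are in units of 4·Ne generations of their own phase: the
    bottleneck lasts 4·Nb·t_bottleneck generations and the post-recovery
    period 4·N0·t_recovery generations. Defaults follow an out-of-Africa
    style history for D. melanogaster: equilibrium size N0 = 1000 contracts
    to Nb = 47 for t_bottleneck = 0.021, recovers to N0, and is sampled
    t_recovery = 0.048 later (20 diploid individuals). ``theta`` is the
    per-base-pair population mutation rate; the recombination rate is
    ``rho_over_theta`` times it (default 7).
    """

    n0: int = 1000
    nb: float = 47.0
    t_bottleneck: float = 0.021
    t_recovery: float = 0.048
    sample_size: int = 20
    theta: float = 0.004
    rho_over_theta: float = 7.0

    def __post_init__(self) -> None:
        if min(self.n0, self.nb, self.sample_size) <= 0:
            raise ValueError("population and sample sizes must be positive")
        if self.t_bottleneck < 0 or self.t_recovery < 0:
            raise ValueError("times must be non-negative")
        if self.sample_size > self.n0:
            raise ValueError("cannot sample more individuals than N0")

    def bottleneck_generations(self) -> int:
        return int(round(4 * self.nb * self.t_bottleneck))

    def recovery_generations(self) -> int:
        return int(round(4 * self.n0 * self.t_recovery))

    def severe(self) -> "DemographicModel":
        """Half the bottleneck size for twice the scaled duration.

        In the 4·Ne time units this keeps the absolute generation count
        fixed while doubling the per-generation drift, so the expected
        heterozygosity loss stays small and comparable while the LD the
        bottleneck generates roughly doubles.
        """
        return replace(self, nb=self.nb / 2, t_bottleneck=self.t_bottleneck * 2)

    def mild(self) -> "DemographicModel":
        """Twice the bottleneck size for half the scaled duration."""
        return replace(self, nb=self.nb * 2, t_bottleneck=self.t_bottleneck / 2)


def _random_reference(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _alt_alleles(
    reference: str, positions: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    ref = np.frombuffer(reference.encode(), dtype="S1")[positions - 1]
    alts = rng.choice(_BASES, size=positions.size)
    clash = alts == ref
    while clash.any():
        alts[clash] = rng.choice(_BASES, size=int(clash.sum()))
        clash = alts == ref
    return alts


def generate_panel(
    n_hap: int,
    region_length: int,
    n_sites: int,
    freq_spectrum: str = "neutral",
    seed: int | np.random.Generator = 0,
    chrom: str = "sim1",
    injected_pairs: Sequence[tuple[int, int, tuple[int, int, int, int]]] = (),
) -> HaplotypePanel:
    """Random phased panel with a chosen allele-frequency spectrum.

    ``freq_spectrum`` is "uniform" (derived-allele count uniform on
    1..n_hap−1) or "neutral" (count k with probability proportional to 1/k,
    the standard neutral site-frequency spectrum). ``injected_pairs`` places
    exact two-locus haplotype counts (n11, n10, n01, n00) — counts of
    haplotypes carrying (alt,alt), (alt,ref), (ref,alt), (ref,ref) — at the
    given site indices, fixing the pair's true r^2 by construction.
    """
    if n_sites > region_length:
        raise ValueError("n_sites cannot exceed region_length")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reference = _random_reference(region_length, rng)
    positions = np.sort(
        rng.choice(region_length, size=n_sites, replace=False) + 1
    ).astype(np.int64)
    alt = _alt_alleles(reference, positions, rng)

    ks = np.arange(1, n_hap)
    if freq_spectrum == "uniform":
        probs = np.full(ks.size, 1.0 / ks.size)
    elif freq_spectrum == "neutral":
        probs = (1.0 / ks) / np.sum(1.0 / ks)
    else:
        raise ValueError(f"unknown freq_spectrum {freq_spectrum!r}")

    matrix = np.zeros((n_hap, n_sites), dtype=np.uint8)
    counts = rng.choice(ks, size=n_sites, p=probs)
    for j, k in enumerate(counts):
        carriers = rng.choice(n_hap, size=int(k), replace=False)
        matrix[carriers, j] = 1

    for ja, jb, cell_counts in injected_pairs:
        n11, n10, n01, n00 = cell_counts
        if n11 + n10 + n01 + n00 != n_hap:
            raise ValueError("injected pair counts must sum to n_hap")
        if n11 + n10 in (0, n_hap) or n11 + n01 in (0, n_hap):
            raise ValueError("injected pair would make a site monomorphic")
        order = rng.permutation(n_hap)
        col_a = np.repeat([1, 1, 0, 0], [n11, n10, n01, n00])
        col_b = np.repeat([1, 0, 1, 0], [n11, n10, n01, n00])
        matrix[order, ja] = col_a
        matrix[order, jb] = col_b

    keep = (matrix.sum(axis=0) > 0) & (matrix.sum(axis=0) < n_hap)
    return HaplotypePanel(chrom, reference, positions[keep], alt[keep], matrix[:, keep])


def true_r2(panel: HaplotypePanel, i: int, j: int) -> float:
    """Exact r^2 between sites i and j from the full panel.

    Same arithmetic as the direct estimator, with n = n_hap haplotypes.
    """
    a = panel.matrix[:, i].astype(float)
    b = panel.matrix[:, j].astype(float)
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("monomorphic column")
    d = np.mean(a * b) - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def pi(panel: HaplotypePanel) -> float:
    """Nucleotide diversity: mean pairwise differences per base pair.

    Uses the unbiased per-site form 2p(1−p)·n/(n−1) summed over segregating
    sites, divided by the region length.
    """
    n = panel.n_hap
    if n < 2:
        raise ValueError("need at least two haplotypes")
    p = panel.matrix.mean(axis=0)
    return float(np.sum(2 * p * (1 - p)) * n / (n - 1) / panel.region_length)


def bottleneck_heterozygosity(h0: float, nb: float, t: float) -> float:
    """Expected heterozygosity after t generations at bottleneck size Nb.

    Standard drift decay: H_t = H0 · (1 − 1/(2·Nb))^t.
    """
    if not 0 <= h0 <= 1:
        raise ValueError("H0 must be in [0, 1]")
    if nb < 1 or t < 0:
        raise ValueError("Nb >= 1 and t >= 0 required")
    return h0 * (1 - 1 / (2 * nb)) ** t


# ---------------------------------------------------------------------------
# pooled paired-end read simulation


@dataclass
class SimulatedReads:
    """In-memory result of a read simulation run."""

    panel: HaplotypePanel
    config: ReadSimConfig
    # per template: haplotype index, 0-based start of read1, insert length
    haplotypes: np.ndarray
    starts: np.ndarray
    inserts: np.ndarray
    truth: "pandas.DataFrame" = None  # type: ignore[name-defined]

    @property
    def n_templates(self) -> int:
        return self.haplotypes.size


def simulate_reads(
    panel: HaplotypePanel, config: ReadSimConfig
) -> SimulatedReads:
    """Simulate pooled paired-end templates from a haplotype panel.

    The number of templates is mean_depth · L / (2 · read_length). Each
    template draws a haplotype uniformly at random (pooling), an insert
    length ~ Normal(insert_mean, insert_sd) rounded and clamped to
    [2·read_length, L], and a start uniform over valid positions. The truth
    table records, per site, the number of covering reads and how many carry
    the alternative allele on their source haplotype (before errors).
    """
    import pandas as pd

    rng = np.random.default_rng(config.seed)
    L = panel.region_length
    rl = config.read_length
    if L < 2 * rl:
        raise ValueError("region shorter than a read pair")
    n_templates = int(round(config.mean_depth * L / (2 * rl)))
    haps = rng.integers(0, panel.n_hap, size=n_templates)
    inserts = np.rint(
        rng.normal(config.insert_mean, config.insert_sd, size=n_templates)
    ).astype(np.int64)
    np.clip(inserts, 2 * rl, L, out=inserts)
    starts = rng.integers(0, L - inserts + 1)  # 0-based read1 start

    # truth: per-site covering reads and alt-carrying reads (pre-error)
    pos0 = panel.positions - 1
    depth = np.zeros(panel.n_sites, dtype=np.int64)
    alt_count = np.zeros(panel.n_sites, dtype=np.int64)
    r1_lo, r1_hi = starts, starts + rl
    r2_lo, r2_hi = starts + inserts - rl, starts + inserts
    for j, p0 in enumerate(pos0):
        cov = ((r1_lo <= p0) & (p0 < r1_hi)) | ((r2_lo <= p0) & (p0 < r2_hi))
        depth[j] = int(cov.sum())
        alt_count[j] = int(panel.matrix[haps[cov], j].sum())
    truth = pd.DataFrame(
        {
            "chrom": panel.chrom,
            "pos": panel.positions,
            "ref_allele": [panel.ref_base(j) for j in range(panel.n_sites)],
            "alt_allele": [b.decode() for b in panel.alt_bases],
            "reads_total": depth,
            "reads_alt": alt_count,
            "panel_freq_alt": panel.matrix.mean(axis=0),
        }
    )
    return SimulatedReads(panel, config, haps, starts, inserts, truth)


def write_sam(sim: SimulatedReads, path: str | Path) -> None:
    """Write the simulated templates as coordinate-sorted SAM.

    Mate fields (FLAG, PNEXT, TLEN) are set for a proper FR pair; base
    qualities are constant at ``config.base_quality``; sequencing errors are
    applied here, substituting a uniformly chosen different base.
    """
    panel, cfg = sim.panel, sim.config
    rl = cfg.read_length
    rng = np.random.default_rng((cfg.seed + 1) * 7919)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": panel.chrom, "LN": panel.region_length}],
    }
    hap_seqs = [
        np.frombuffer(panel.haplotype_seq(i).encode(), dtype="S1")
        for i in range(panel.n_hap)
    ]
    quals = pysam.qualitystring_to_array(chr(cfg.base_quality + 33) * rl)

    records: list[tuple[int, int, pysam.AlignedSegment]] = []
    for t in range(sim.n_templates):
        hap, start, ins = int(sim.haplotypes[t]), int(sim.starts[t]), int(sim.inserts[t])
        r2_start = start + ins - rl
        for mate, (mstart, flag, pnext, tlen) in enumerate(
            (
                (start, 99, r2_start, ins),
                (r2_start, 147, start, -ins),
            )
        ):
            seq = hap_seqs[hap][mstart : mstart + rl].copy()
            if cfg.error_rate > 0:
                errs = np.nonzero(rng.random(rl) < cfg.error_rate)[0]
                for e in errs:
                    choices = _BASES[_BASES != seq[e]]
                    seq[e] = rng.choice(choices)
            a = pysam.AlignedSegment()
            a.query_name = f"tpl{t:07d}"
            a.flag = flag
            a.reference_id = 0
            a.reference_start = mstart
            a.mapping_quality = 60
            a.cigarstring = f"{rl}M"
            a.next_reference_id = 0
            a.next_reference_start = pnext
            a.template_length = tlen
            a.query_sequence = seq.tobytes().decode()
            a.query_qualities = quals
            records.append((mstart, t, a))
    records.sort(key=lambda r: (r[0], r[1]))
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for _, _, a in records:
            out.write(a)


def write_panel_fasta(panel: HaplotypePanel, path: str | Path) -> None:
    """Write the panel haplotypes (and reference) as FASTA."""
    recs = [SeqRecord(Seq(panel.reference), id=f"{panel.chrom}_ref", description="")]
    recs += [
        SeqRecord(Seq(panel.haplotype_seq(i)), id=f"hap{i:04d}", description="")
        for i in range(panel.n_hap)
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# worked-example fixture: two loci, partial intersection


def worked_example_records() -> tuple[dict, list, list[SnpSite]]:
    """The two-locus worked example: 8 reads at locus A, 5 intersecting.

    Eight 93 bp reads cover locus A (pos 100), four carrying allele A; five
    of them extend across locus B (pos 150), three of those carrying allele
    A at locus A. The intersecting-read frequency of A at locus A is thus
    3/5 while the all-read frequency is 4/8. Returns (header, alignment
    records, sites).
    """
    chrom, length, rl = "ex1", 300, 93
    site_a = SnpSite(chrom, 100, ("A", "T"))
    site_b = SnpSite(chrom, 150, ("C", "G"))
    header = {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": chrom, "LN": length}]}
    ref = ["T"] * length  # background; only the two SNP columns matter

    # (start0, base at A, base at B or None)
    layout = [
        (79, "A", "C"),
        (80, "A", "C"),
        (81, "A", "C"),
        (82, "T", "G"),
        (83, "T", "G"),
        (30, "A", None),
        (31, "T", None),
        (32, "T", None),
    ]
    records = []
    for i, (start, base_a, base_b) in enumerate(layout):
        seq = list("".join(ref[start : start + rl]))
        seq[99 - start] = base_a
        if base_b is not None:
            seq[149 - start] = base_b
        a = pysam.AlignedSegment()
        a.query_name = f"ex{i}"
        a.flag = 0
        a.reference_id = 0
        a.reference_start = start
        a.mapping_quality = 60
        a.cigarstring = f"{rl}M"
        a.query_sequence = "".join(seq)
        a.query_qualities = pysam.qualitystring_to_array("I" * rl)  # Q40
        records.append(a)
    records.sort(key=lambda r: r.reference_start)
    return header, records, [site_a, site_b]


def write_worked_example(directory: str | Path) -> tuple[Path, Path]:
    """Write the worked-example SAM and site TSV; returns their paths."""
    from .variants_io import write_site_tsv

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    header, records, sites = worked_example_records()
    sam = directory / "example.sam"
    with pysam.AlignmentFile(str(sam), "wh", header=header) as out:
        for a in records:
            out.write(a)
    tsv = directory / "example_sites.tsv"
    write_site_tsv(sites, tsv)
    return sam, tsv


# ---------------------------------------------------------------------------
# forward Wright-Fisher simulation


class _WfState:
    """Mutable population state: haplotype matrix over segregating sites."""

    def __init__(self, size: int, region_length: int):
        self.matrix = np.zeros((size, 0), dtype=np.uint8)
        self.positions = np.zeros(0, dtype=np.int64)  # 1-based
        self.region_length = region_length

    def copy(self) -> "_WfState":
        s = _WfState(self.matrix.shape[0], self.region_length)
        s.matrix = self.matrix.copy()
        s.positions = self.positions.copy()
        return s


def _wf_generation(
    state: _WfState,
    new_size: int,
    mu_per_bp: float,
    rec_per_bp: float,
    rng: np.random.Generator,
) -> None:
    """Advance one generation in place: resample, recombine, mutate, prune."""
    m, L = state.matrix.shape[0], state.region_length
    a = rng.integers(0, m, size=new_size)
    child = state.matrix[a]
    p_rec = min(1.0, rec_per_bp * L)
    rec = rng.random(new_size) < p_rec
    n_rec = int(rec.sum())
    if n_rec and state.positions.size:
        b = rng.integers(0, m, size=n_rec)
        cuts = rng.integers(1, L + 1, size=n_rec)
        right = state.positions[None, :] >= cuts[:, None]
        child = child.copy()
        child[rec] = np.where(right, state.matrix[b], child[rec])
    else:
        child = child.copy()
    state.matrix = child

    n_mut = rng.poisson(new_size * mu_per_bp * L)
    if n_mut:
        existing = set(state.positions.tolist())
        new_pos, new_ind = [], []
        for _ in range(n_mut):
            p = int(rng.integers(1, L + 1))
            if p in existing:
                continue  # finite-sites collision: skip (rare)
            existing.add(p)
            new_pos.append(p)
            new_ind.append(int(rng.integers(0, new_size)))
        if new_pos:
            block = np.zeros((new_size, len(new_pos)), dtype=np.uint8)
            block[new_ind, np.arange(len(new_pos))] = 1
            state.matrix = np.hstack([state.matrix, block])
            state.positions = np.concatenate(
                [state.positions, np.array(new_pos, dtype=np.int64)]
            )

    if state.positions.size:
        tot = state.matrix.sum(axis=0)
        keep = (tot > 0) & (tot < new_size)
        state.matrix = state.matrix[:, keep]
        state.positions = state.positions[keep]
        order = np.argsort(state.positions)
        state.positions = state.positions[order]
        state.matrix = state.matrix[:, order]


def _sample_panel(
    state: _WfState, n_sample: int, rng: np.random.Generator, chrom: str = "wf1"
) -> HaplotypePanel:
    rows = rng.choice(state.matrix.shape[0], size=n_sample, replace=False)
    mat = state.matrix[rows]
    tot = mat.sum(axis=0)
    keep = (tot > 0) & (tot < n_sample)
    mat = mat[:, keep]
    positions = state.positions[keep]
    ref_rng = np.random.default_rng(12345)  # reference bases are cosmetic
    reference = _random_reference(state.region_length, ref_rng)
    alt = _alt_alleles(reference, positions, ref_rng)
    return HaplotypePanel(chrom, reference, positions, alt, mat)


def _model_rates(model: DemographicModel) -> tuple[float, float, int]:
    """Per-bp per-generation mutation and recombination rates, haploid M0."""
    m0 = 2 * model.n0
    mu = model.theta / (2 * m0)
    rec = model.rho_over_theta * mu
    return mu, rec, m0


def wf_bottleneck_panel(
    model: DemographicModel,
    region_length: int,
    seed: int | np.random.Generator = 0,
    burn_in_factor: int = 10,
) -> HaplotypePanel:
    """Forward-simulate the size trajectory and sample a haplotype panel.

    The population of M0 = 2·N0 haplotypes evolves for burn_in_factor · M0
    generations at equilibrium, contracts to 2·Nb haplotypes for
    4·Nb·t_bottleneck generations, recovers to M0, and after
    4·N0·t_recovery generations 2·sample_size haplotypes are drawn.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu, rec, m0 = _model_rates(model)
    state = _WfState(m0, region_length)
    for _ in range(burn_in_factor * m0):
        _wf_generation(state, m0, mu, rec, rng)
    _run_bottleneck(state, model, mu, rec, rng)
    return _sample_panel(state, 2 * model.sample_size, rng)


def wf_equilibrium_panel(
    n_hap: int,
    region_length: int,
    theta: float = 0.002,
    rho_over_theta: float = 7.0,
    n0: int | None = None,
    seed: int | np.random.Generator = 0,
    burn_in_factor: int = 10,
) -> HaplotypePanel:
    """Sample a panel from a neutral equilibrium Wright-Fisher population.

    Unlike :func:`generate_panel`, the sampled haplotypes share a genealogy,
    so nearby sites carry genuine linkage disequilibrium decaying with
    distance — the structure a real inbred-line reference panel has.
    ``n0`` defaults to n_hap (population of 2·n_hap haplotypes).
    """
    if n0 is None:
        n0 = n_hap
    if n_hap > 2 * n0:
        raise ValueError("cannot sample more haplotypes than the population")
    model = DemographicModel(
        n0=n0,
        nb=n0,
        t_bottleneck=0.0,
        t_recovery=0.0,
        sample_size=min(n0, max(1, n_hap // 2)),
        theta=theta,
        rho_over_theta=rho_over_theta,
    )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu, rec, m0 = _model_rates(model)
    state = _WfState(m0, region_length)
    for _ in range(burn_in_factor * m0):
        _wf_generation(state, m0, mu, rec, rng)
    return _sample_panel(state, n_hap, rng)


def _run_bottleneck(
    state: _WfState,
    model: DemographicModel,
    mu: float,
    rec: float,
    rng: np.random.Generator,
) -> None:
    m0 = 2 * model.n0
    mb = max(2, int(round(2 * model.nb)))
    t_b = model.bottleneck_generations()
    if model.t_bottleneck > 0:
        t_b = max(1, t_b)
    for _ in range(t_b):
        _wf_generation(state, mb, mu, rec, rng)
    for _ in range(model.recovery_generations()):
        _wf_generation(state, m0, mu, rec, rng)


def panel_mean_r2(
    panel: HaplotypePanel, min_minor_count: int = 2, max_distance: int | None = None
) -> float:
    """Mean pairwise r^2 over panel site pairs.

    Singleton sites (minor count below ``min_minor_count``) are excluded:
    their r^2 is dominated by sampling noise. NaN when fewer than one usable
    pair exists.
    """
    tot = panel.matrix.sum(axis=0)
    minor = np.minimum(tot, panel.n_hap - tot)
    idx = np.nonzero(minor >= min_minor_count)[0]
    if idx.size < 2:
        return float("nan")
    vals = []
    for ii in range(idx.size):
        for jj in range(ii + 1, idx.size):
            i, j = idx[ii], idx[jj]
            if max_distance is not None and (
                panel.positions[j] - panel.positions[i] > max_distance
            ):
                break
            vals.append(true_r2(panel, int(i), int(j)))
    return float(np.mean(vals)) if vals else float("nan")


def bottleneck_experiment(
    model: DemographicModel,
    n_replicates: int,
    region_length: int,
    seed: int = 0,
    spacing_factor: int = 2,
    burn_in_factor: int = 10,
):
    """Replicated comparison of π-matched bottleneck severities.

    Runs one long equilibrium simulation; every ``spacing_factor · M0``
    generations a snapshot seeds three trajectories sharing the same
    standing variation: the reference model, a severe variant (Nb/2, 2t)
    and a mild variant (2·Nb, t/2). In the 4·Ne time units severity and
    scaled duration trade off so all three bottlenecks last the same number
    of generations and lose comparably little heterozygosity, yet the LD
    generated differs with bottleneck size. Returns a DataFrame with one
    row per (replicate, model): sampled-panel π and mean pairwise r^2.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    mu, rec, m0 = _model_rates(model)
    variants = {"reference": model, "severe": model.severe(), "mild": model.mild()}

    state = _WfState(m0, region_length)
    for _ in range(burn_in_factor * m0):
        _wf_generation(state, m0, mu, rec, rng)

    rows = []
    for rep in range(n_replicates):
        for _ in range(spacing_factor * m0):
            _wf_generation(state, m0, mu, rec, rng)
        for name, variant in variants.items():
            branch = state.copy()
            branch_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
            _run_bottleneck(branch, variant, mu, rec, branch_rng)
            panel = _sample_panel(branch, 2 * variant.sample_size, branch_rng)
            rows.append(
                {
                    "replicate": rep,
                    "model": name,
                    "pi": pi(panel) if panel.n_sites else 0.0,
                    "mean_r2": panel_mean_r2(panel),
                    "n_sites": panel.n_sites,
                }
            )
    return pd.DataFrame(rows)
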