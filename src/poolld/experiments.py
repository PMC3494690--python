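"""Replicated simulation experiments tying the simulator to the estimators.

These drivers reproduce the qualitative behaviour expected of pooled LD
estimation: accuracy and estimability rising with read depth, the two
characteristic bias modes at low intersecting depth, MAF-dependent accuracy,
and LD decay with distance on recombining panels. They are the same code
paths exercised by the test suite and the results-reproduction script.
"""

from __future__ import annotations

import tempfile
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import ld_analysis, pipeline, pool_sim
from .pool_sim import DemographicModel, HaplotypePanel, ReadSimConfig


def run_panel_estimation(
    panel: HaplotypePanel,
    config: ReadSimConfig,
    n_chrom: int,
    min_intersecting: int = 10,
    maf_cutoff: float = 0.01,
    max_distance: int | None = None,
    workdir: str | Path | None = None,
) -> pd.DataFrame:
    """Simulate reads from a panel, run the pipeline, attach true r^2.

    Returns the per-pair estimate table with a ``true_r2`` column computed
    from the full panel. ``max_distance`` defaults to the simulated insert
    mean plus three SDs (the template span).
    """
    if max_distance is None:
        max_distance = int(config.insert_mean + 3 * config.insert_sd)
    sim = pool_sim.simulate_reads(panel, config)
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        sam = Path(tmp) / "reads.sam"
        pool_sim.write_sam(sim, sam)
        estimates, summary = pipeline.estimate_ld(
            sam,
            panel.sites(),
            n_chrom=panel.n_hap,
            max_distance=max_distance,
            min_intersecting=min_intersecting,
            maf_cutoff=maf_cutoff,
        )
    df = pipeline.estimates_to_frame(estimates)
    pos_to_idx = {int(p): j for j, p in enumerate(panel.positions)}
    df["true_r2"] = [
        pool_sim.true_r2(panel, pos_to_idx[a], pos_to_idx[b])
        for a, b in zip(df["pos_a"], df["pos_b"])
    ]
    df.attrs["summary"] = summary
    df.attrs["n_chrom"] = n_chrom
    return df


def depth_sweep(
    seed: int = 0,
    depths: tuple[float, ...] = (10.0, 40.0, 100.0, 200.0),
    n_hap: int = 100,
    region_length: int = 50_000,
    theta: float = 0.002,
    read_length: int = 93,
    insert_mean: float = 450.0,
    insert_sd: float = 45.0,
    error_rate: float = 0.001,
) -> dict[float, pd.DataFrame]:
    """Estimate LD from the same panel sequenced at increasing depths.

    A single panel sampled from an equilibrium Wright-Fisher population
    (so site pairs carry genuine, distance-decaying LD) is sequenced at each
    depth with 93 bp paired-end reads; the minimum intersecting depth is
    relaxed to 5 at 10x (at that coverage almost no pair reaches ten
    intersecting templates). Returns {depth: per-pair estimate table with
    true_r2}, each table also carrying its run summary in ``attrs``.
    """
    panel = pool_sim.wf_equilibrium_panel(
        n_hap=n_hap,
        region_length=region_length,
        theta=theta,
        seed=seed,
    )
    out: dict[float, pd.DataFrame] = {}
    for k, depth in enumerate(depths):
        config = ReadSimConfig(
            read_length=read_length,
            mean_depth=depth,
            insert_mean=insert_mean,
            insert_sd=insert_sd,
            error_rate=error_rate,
            seed=seed * 1000 + k + 1,
        )
        min_intersecting = 5 if depth <= 10 else 10
        out[depth] = run_panel_estimation(
            panel, config, n_chrom=n_hap, min_intersecting=min_intersecting
        )
    return out


def sweep_metrics(sweep: dict[float, pd.DataFrame]) -> pd.DataFrame:
    """Estimable fraction and truth correlations per depth of a sweep.

    Correlations are reported twice: over each depth's own estimable pairs
    (``corr_*``) and over the pairs estimable at every depth
    (``corr_*_common``). The common-pair columns isolate how depth changes
    accuracy; the per-depth columns confound accuracy with the changing
    composition of estimable pairs, since deeper libraries rescue rarer and
    harder pairs.
    """
    keysets = [
        set(zip(df["pos_a"], df["pos_b"])) for df in sweep.values()
    ]
    common = set.intersection(*keysets) if keysets else set()
    rows = []
    for depth, df in sorted(sweep.items()):
        summary = df.attrs["summary"]
        report = ld_analysis.validation_correlation(df, df["true_r2"])
        sel = df[[k in common for k in zip(df["pos_a"], df["pos_b"])]]
        if len(sel) >= 3:
            common_report = ld_analysis.validation_correlation(sel, sel["true_r2"])
            corr_d_c, corr_m_c = common_report.corr_direct, common_report.corr_mle
        else:
            corr_d_c = corr_m_c = float("nan")
        rows.append(
            {
                "depth": depth,
                "n_pairs_enumerated": summary.n_pairs_enumerated,
                "n_pairs_estimable": summary.n_pairs_passing,
                "estimable_fraction": summary.n_pairs_passing
                / max(summary.n_pairs_enumerated, 1),
                "corr_direct": report.corr_direct,
                "corr_mle": report.corr_mle,
                "corr_direct_common": corr_d_c,
                "corr_mle_common": corr_m_c,
                "n_common": len(sel),
                "frac_direct_at_one": report.frac_direct_at_one,
                "frac_boundary": report.frac_boundary,
            }
        )
    return pd.DataFrame(rows)


def decay_panels(
    seed: int = 0,
    n0: int = 50,
    region_length: int = 5000,
    theta: float = 0.01,
    rho_over_theta_levels: tuple[float, ...] = (1.0, 10.0),
    rec_rate_labels: tuple[float, ...] = (0.5, 5.0),
    burn_in_factor: int = 10,
    max_distance: int = 2000,
) -> pd.DataFrame:
    """True-r^2 decay data from equilibrium panels at two recombination rates.

    Each panel is an equilibrium Wright-Fisher population (no bottleneck)
    simulated at a different crossover rate and labelled with a nominal
    recombination rate in cM/Mb, giving the variation the decay regression's
    recombination terms need. Returns rows of (r2, distance, rec_rate).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for rho_ratio, label in zip(rho_over_theta_levels, rec_rate_labels):
        model = DemographicModel(
            n0=n0,
            nb=n0,
            t_bottleneck=0.0,
            t_recovery=0.0,
            sample_size=min(20, n0),
            theta=theta,
            rho_over_theta=rho_ratio,
        )
        panel = pool_sim.wf_bottleneck_panel(
            model,
            region_length,
            seed=rng,
            burn_in_factor=burn_in_factor,
        )
        tot = panel.matrix.sum(axis=0)
        minor = np.minimum(tot, panel.n_hap - tot)
        idx = np.nonzero(minor >= 2)[0]
        for ii in range(idx.size):
            for jj in range(ii + 1, idx.size):
                i, j = int(idx[ii]), int(idx[jj])
                dist = int(panel.positions[j] - panel.positions[i])
                if dist > max_distance:
                    break
                if dist < 1:
                    continue
                rows.append(
                    {
                        "r2": pool_sim.true_r2(panel, i, j),
                        "distance": dist,
                        "rec_rate": label,
                    }
                )
    return pd.DataFrame(rows)
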