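"""Downstream summaries: LD decay regression, truth validation, r^2 tables.

The decay of r^2 with physical distance, and its modulation by local
recombination rate, is the classic sanity check that pooled LD estimates
are biologically meaningful. The model is an ordinary least-squares fit

    r^2 ~ log(distance) + rec_rate + log(distance) x rec_rate

with natural logarithm, distance in bp and recombination rate in cM/Mb.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .ld_core import LdEstimate

TERM_NAMES = ("intercept", "log_distance", "rec_rate", "log_distance_x_rec_rate")


@dataclass
class DecayModelFit:
    params: dict[str, float]
    bse: dict[str, float]
    tvalues: dict[str, float]
    n_pairs: int

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.params,
                "std_error": self.bse,
                "t_value": self.tvalues,
            }
        )


def decay_regression(
    r2: Sequence[float],
    distance: Sequence[float],
    rec_rate: Sequence[float],
) -> DecayModelFit:
    """OLS fit of r^2 on log(distance), recombination rate and interaction.

    Requires >= 5 pairs, distances >= 1 and a full-rank design (degenerate
    inputs — e.g. constant distance AND constant rec rate — raise
    ``ValueError``).
    """
    r2 = np.asarray(r2, dtype=float)
    dist = np.asarray(distance, dtype=float)
    rec = np.asarray(rec_rate, dtype=float)
    if r2.size < 5:
        raise ValueError("need at least 5 pairs")
    if np.any(dist < 1):
        raise ValueError("distances must be >= 1 bp")
    logd = np.log(dist)
    X = np.column_stack([np.ones_like(logd), logd, rec, logd * rec])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("degenerate (collinear) design matrix")
    fit = sm.OLS(r2, X).fit()
    return DecayModelFit(
        params=dict(zip(TERM_NAMES, fit.params)),
        bse=dict(zip(TERM_NAMES, fit.bse)),
        tvalues=dict(zip(TERM_NAMES, fit.tvalues)),
        n_pairs=int(r2.size),
    )


@dataclass
class ValidationReport:
    corr_direct: float
    corr_mle: float
    bias_direct: float  # mean signed error, direct − truth
    bias_mle: float
    frac_direct_at_one: float  # excess over truth of estimates pinned at 1
    frac_mle_at_zero: float
    frac_boundary: float
    frac_truth_at_one: float
    frac_truth_at_zero: float
    n: int


def validation_correlation(
    estimates: Sequence[LdEstimate] | pd.DataFrame,
    truth: Sequence[float],
) -> ValidationReport:
    """Correlation and bias of both estimators against ground-truth r^2.

    The two characteristic bias modes of pooled estimation are quantified:
    sparse haplotype-table sampling pins direct estimates at exactly 1;
    incongruence between all-read frequencies and the intersecting table
    pins ML estimates at 0 (boundary cases). ``ValueError`` on fewer than 3
    matched pairs; zero variance yields NaN correlations.
    """
    if isinstance(estimates, pd.DataFrame):
        direct = estimates["r2_direct"].to_numpy(dtype=float)
        mle = estimates["r2_mle"].to_numpy(dtype=float)
        boundary = estimates["boundary_flag"].to_numpy(dtype=bool)
    else:
        direct = np.array([e.r2_direct for e in estimates], dtype=float)
        mle = np.array([e.r2_mle for e in estimates], dtype=float)
        boundary = np.array([e.boundary for e in estimates], dtype=bool)
    truth = np.asarray(truth, dtype=float)
    if truth.size != direct.size:
        raise ValueError("estimates and truth must be matched")
    ok = ~np.isnan(truth)
    direct, mle, boundary, truth = direct[ok], mle[ok], boundary[ok], truth[ok]
    if truth.size < 3:
        raise ValueError("need at least 3 matched pairs")
    # each method is scored on the pairs where it is defined
    ok_d = ~np.isnan(direct)
    ok_m = ~np.isnan(mle)

    def _corr(a, b):
        if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
            return float("nan")
        return float(stats.pearsonr(a, b)[0])

    return ValidationReport(
        corr_direct=_corr(direct[ok_d], truth[ok_d]),
        corr_mle=_corr(mle[ok_m], truth[ok_m]),
        bias_direct=float(np.mean(direct[ok_d] - truth[ok_d])) if ok_d.any() else float("nan"),
        bias_mle=float(np.mean(mle[ok_m] - truth[ok_m])) if ok_m.any() else float("nan"),
        frac_direct_at_one=float(np.mean(direct[ok_d] >= 1.0 - 1e-9)) if ok_d.any() else float("nan"),
        frac_mle_at_zero=float(np.mean(mle[ok_m] <= 1e-9)) if ok_m.any() else float("nan"),
        frac_boundary=float(np.mean(boundary)),
        frac_truth_at_one=float(np.mean(truth >= 1.0 - 1e-9)),
        frac_truth_at_zero=float(np.mean(truth <= 1e-9)),
        n=int(truth.size),
    )


def summarize_r2(
    r2: Sequence[float],
    distance: Sequence[float] | None = None,
    mode: str = "mean",
    bins: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Summaries of a set of r^2 values.

    mode "mean": overall mean and sample SD. mode "mean_per_bp": mean and SD
    of r^2/distance. mode "binned": mean r^2 within distance classes (edges
    in ``bins``, default 10 equal-width bins).
    """
    r2 = np.asarray(r2, dtype=float)
    if r2.size < 1:
        raise ValueError("need at least one estimate")
    if mode == "mean":
        return pd.DataFrame(
            {"mean": [r2.mean()], "sd": [r2.std(ddof=1) if r2.size > 1 else 0.0], "n": [r2.size]}
        )
    if distance is None:
        raise ValueError(f"mode {mode!r} requires distances")
    dist = np.asarray(distance, dtype=float)
    if mode == "mean_per_bp":
        per = r2 / dist
        return pd.DataFrame(
            {"mean": [per.mean()], "sd": [per.std(ddof=1) if per.size > 1 else 0.0], "n": [per.size]}
        )
    if mode == "binned":
        if bins is None:
            bins = np.linspace(dist.min(), dist.max() + 1e-9, 11)
        cut = pd.cut(dist, bins=bins, include_lowest=True)
        grouped = pd.DataFrame({"r2": r2, "bin": cut}).groupby("bin", observed=True)["r2"]
        out = grouped.agg(["mean", "std", "count"]).reset_index()
        out.columns = ["distance_bin", "mean", "sd", "n"]
        return out
    raise ValueError(f"unknown mode {mode!r}")


def welch_r2_test(group_a: Sequence[float], group_b: Sequence[float]):
    """Welch two-sample t-test on two groups of (per-replicate mean) r^2."""
    res = stats.ttest_ind(np.asarray(group_a), np.asarray(group_b), equal_var=False)
    return float(res.statistic), float(res.pvalue)


def maf_stratified_correlation(
    df: pd.DataFrame,
    truth_col: str = "true_r2",
    est_col: str = "r2_mle",
    maf_edges: Sequence[float] = (0.01, 0.05, 0.1, 0.5),
) -> pd.DataFrame:
    """Pearson correlation with truth within minimum-MAF bins.

    The binning MAF for a pair is the smaller of its two all-read minor
    allele frequencies; accuracy is expected to rise with MAF because high
    frequency pairs expose all four haplotypes to sampling.
    """
    maf = np.minimum(df["maf_a_all"], df["maf_b_all"])
    rows = []
    for lo, hi in zip(maf_edges[:-1], maf_edges[1:]):
        sel = (maf >= lo) & (maf < hi if hi < 0.5 else maf <= hi)
        sub = df[sel][[est_col, truth_col]].dropna()
        if len(sub) >= 3 and sub[truth_col].std() > 0 and sub[est_col].std() > 0:
            r = float(stats.pearsonr(sub[est_col], sub[truth_col])[0])
        else:
            r = float("nan")
        rows.append({"maf_low": lo, "maf_high": hi, "corr": r, "n": len(sub)})
    return pd.DataFrame(rows)
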