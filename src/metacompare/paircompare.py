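"""Per-sample-pair agreement between 16S and shotgun profiles.

For each biological sample sequenced by both strategies this module
partitions the detected genera into common / 16S-exclusive /
shotgun-exclusive sets, correlates the common genera's log2 abundances, and
fits the *detection-limit regression*: ordinary least squares of
log2(shotgun count) on log2(16S count) over common genera.  The intercept
is the expected number of shotgun reads for a genus mapped by a single 16S
read, so ``2**intercept`` acts as the 16S detection limit expressed in
shotgun reads; across pairs the intercept tracks the (log) shotgun
sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import SamplePair


@dataclass
class PairPartition:
    """Common/exclusive genus accounting for one pair at one rank."""

    pair_id: str
    common: set[str]
    amplicon_exclusive: set[str]
    shotgun_exclusive: set[str]
    frac_reads_common_16s: float
    frac_reads_common_shotgun: float


def partition_pair(pair: SamplePair, rank: str = "genus") -> PairPartition:
    """Split detected taxa (count >= 1) into common and exclusive sets.

    Also reports, per strategy, the fraction of that sample's reads mapping
    to the common taxa — high fractions mean the strategy-exclusive taxa
    are rare.
    """
    if rank == "genus":
        ca, cs = pair.amplicon.nonzero_counts(), pair.shotgun.nonzero_counts()
    elif rank == "phylum":
        ca, cs = pair.amplicon.phylum_counts(), pair.shotgun.phylum_counts()
    else:
        raise ValueError(f"unknown rank {rank!r}")
    sa, ss = set(ca.index), set(cs.index)
    common = sa & ss
    frac_a = float(ca[ca.index.isin(common)].sum() / ca.sum()) if ca.sum() else 0.0
    frac_s = float(cs[cs.index.isin(common)].sum() / cs.sum()) if cs.sum() else 0.0
    return PairPartition(
        pair_id=pair.pair_id,
        common=common,
        amplicon_exclusive=sa - common,
        shotgun_exclusive=ss - common,
        frac_reads_common_16s=frac_a,
        frac_reads_common_shotgun=frac_s,
    )


def _common_log_counts(pair: SamplePair) -> tuple[np.ndarray, np.ndarray]:
    ca = pair.amplicon.nonzero_counts()
    cs = pair.shotgun.nonzero_counts()
    common = sorted(set(ca.index) & set(cs.index))
    x = np.log2(ca[common].to_numpy(dtype=float))
    y = np.log2(cs[common].to_numpy(dtype=float))
    return x, y


def pair_correlation(pair: SamplePair, log_scale: bool = True):
    """Pearson correlation of the two strategies' common-genus abundances.

    Computed on log2 counts by default (a ``log_scale=False`` flag gives
    raw counts).  Returns ``(r, p, n_common)``; with fewer than 3 common
    genera the correlation is undefined and ``(nan, nan, n)`` is returned.
    """
    x, y = _common_log_counts(pair)
    if not log_scale:
        x, y = 2.0**x, 2.0**y
    n = len(x)
    if n < 3:
        return np.nan, np.nan, n
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan, n
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n


@dataclass
class DetectionFit:
    """OLS fit of log2 shotgun vs log2 16S abundance for one pair."""

    pair_id: str
    slope: float
    intercept: float
    intercept_ci: tuple[float, float]
    n_common: int
    total_shotgun_reads: int
    ci_level: float

    @property
    def threshold_reads(self) -> float:
        """16S detection limit in shotgun reads: ``2**intercept``."""
        return float(2.0**self.intercept)

    def summary(self) -> str:
        lo, hi = self.intercept_ci
        return (
            f"Detection-limit fit for pair {self.pair_id!r}\n"
            f"  common genera: {self.n_common}\n"
            f"  slope: {self.slope:.3f}\n"
            f"  intercept: {self.intercept:.3f} "
            f"[{lo:.3f}, {hi:.3f}] ({100 * self.ci_level:.0f}% CI)\n"
            f"  detection threshold: {self.threshold_reads:.1f} shotgun reads\n"
            f"  total shotgun reads: {self.total_shotgun_reads}"
        )


def detection_limit_fit(pair: SamplePair, ci_level: float = 0.95) -> DetectionFit:
    """Regress log2 shotgun counts on log2 16S counts over common genera.

    16S abundance is the independent variable, shotgun the dependent one;
    the intercept (log2 shotgun reads at one 16S read) defines the
    detection threshold.  The intercept CI uses the t quantile times the
    OLS standard error.
    """
    x, y = _common_log_counts(pair)
    if len(x) < 3:
        raise ValueError(
            f"pair {pair.pair_id!r}: need >= 3 common genera for the fit, got {len(x)}"
        )
    if np.ptp(x) == 0:
        raise ValueError(f"pair {pair.pair_id!r}: 16S log-abundances are constant")
    fit = stats.linregress(x, y)
    tq = stats.t.ppf(0.5 + ci_level / 2.0, df=len(x) - 2)
    half = tq * fit.intercept_stderr
    return DetectionFit(
        pair_id=pair.pair_id,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        intercept_ci=(float(fit.intercept - half), float(fit.intercept + half)),
        n_common=len(x),
        total_shotgun_reads=pair.shotgun.total_reads,
        ci_level=ci_level,
    )


def intercept_depth_correlation(fits: list[DetectionFit]):
    """Pearson correlation of intercepts with total shotgun reads.

    Low-depth pairs are deliberately *not* excluded here: the relationship
    between detection limit and sequencing depth is the point.  Returns
    ``(r, p)``; with zero variance on either axis returns ``(nan, nan)``.
    """
    if len(fits) < 3:
        raise ValueError(f"need >= 3 fits, got {len(fits)}")
    x = np.array([f.intercept for f in fits], dtype=float)
    y = np.array([f.total_shotgun_reads for f in fits], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def undetected_fraction(fit: DetectionFit, pair: SamplePair) -> float:
    """Fraction of shotgun-detected genera below the detection threshold.

    Genera with ``0 < shotgun count < 2**intercept`` would likely be missed
    by 16S sequencing.
    """
    counts = pair.shotgun.nonzero_counts().to_numpy(dtype=float)
    if len(counts) == 0:
        return 0.0
    return float((counts < fit.threshold_reads).sum() / len(counts))


def pair_comparison_table(pairs: list[SamplePair], ci_level: float = 0.95) -> pd.DataFrame:
    """Per-pair summary: partition sizes, correlation and detection fit."""
    rows = []
    for pair in pairs:
        part = partition_pair(pair)
        r, rp, n = pair_correlation(pair)
        row = dict(
            pair_id=pair.pair_id,
            n_common=len(part.common),
            n_16s_only=len(part.amplicon_exclusive),
            n_shotgun_only=len(part.shotgun_exclusive),
            frac_reads_common_16s=part.frac_reads_common_16s,
            frac_reads_common_shotgun=part.frac_reads_common_shotgun,
            r=r,
            r_pvalue=rp,
            total_shotgun_reads=pair.shotgun.total_reads,
            total_16s_reads=pair.amplicon.total_reads,
        )
        try:
            fit = detection_limit_fit(pair, ci_level)
            row.update(
                slope=fit.slope,
                intercept=fit.intercept,
                intercept_ci_lo=fit.intercept_ci[0],
                intercept_ci_hi=fit.intercept_ci[1],
                threshold_reads=fit.threshold_reads,
                frac_genera_below_threshold=undetected_fraction(fit, pair),
            )
        except ValueError:
            row.update(
                slope=np.nan, intercept=np.nan, intercept_ci_lo=np.nan,
                intercept_ci_hi=np.nan, threshold_reads=np.nan,
                frac_genera_below_threshold=np.nan,
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("pair_id")
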