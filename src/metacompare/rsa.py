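"""Relative-abundance distribution diagnostics and the read-depth filter.

A sample's relative species abundance distribution (RSA) — how many taxa
occur at each abundance — is summarized here as a Preston histogram (taxa
binned by log2 read-count octave) and by the skewness of the log2-count
distribution.  Under-sampling truncates the rare left tail of the RSA and
inflates its skewness, so skewness acts as a depth-adequacy diagnostic:
deeply sequenced shotgun samples are near-symmetric on the log scale while
shallow samples (and typical 16S samples) are positively skewed.

The module also provides analytic rarefaction (expected richness under
hypergeometric subsampling) and the paired read-depth quality filter:
shotgun samples below a read threshold are excluded together with the 16S
profile of the same biological sample, keeping the comparison balanced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .profiles import ProfileSet, SamplePair, TaxonomicProfile, pair_profiles


@dataclass
class SkewnessRecord:
    """Skewness of the log2-transformed nonzero counts of one profile."""

    sample_id: str
    strategy: str
    skewness: float  # NaN when undefined
    total_reads: int
    defined: bool


def _rank_counts(profile: TaxonomicProfile, rank: str) -> pd.Series:
    if rank == "genus":
        return profile.nonzero_counts()
    if rank == "phylum":
        return profile.phylum_counts()
    raise ValueError(f"unknown rank {rank!r}; expected 'genus' or 'phylum'")


def preston_histogram(profile: TaxonomicProfile, rank: str = "genus") -> pd.Series:
    """Bin detected taxa into log2 abundance octaves.

    A taxon with count ``c`` lands in octave ``floor(log2 c)`` (octave k
    holds counts in ``[2**k, 2**(k+1))``).  The returned Series covers
    octaves 0..max contiguously; its values sum to the number of detected
    taxa at the chosen rank.
    """
    counts = _rank_counts(profile, rank)
    if counts.empty:
        raise ValueError(f"profile {profile.sample_id!r} has no detected taxa at rank {rank}")
    octaves = np.floor(np.log2(counts.to_numpy())).astype(int)
    top = octaves.max()
    hist = pd.Series(0, index=pd.RangeIndex(0, top + 1, name="octave"), dtype=int)
    vals, n = np.unique(octaves, return_counts=True)
    hist.loc[vals] = n
    return hist


def rsa_skewness(profile: TaxonomicProfile, rank: str = "genus") -> SkewnessRecord:
    """Fisher-Pearson g1 skewness of log2 counts over detected taxa.

    Undefined (NaN, ``defined=False``) with fewer than 3 detected taxa or
    zero variance — flagged, never silently zero.
    """
    counts = _rank_counts(profile, rank)
    log2c = np.log2(counts.to_numpy(dtype=float)) if len(counts) else np.array([])
    if len(log2c) < 3 or np.ptp(log2c) == 0:
        return SkewnessRecord(profile.sample_id, profile.strategy, np.nan,
                              profile.total_reads, False)
    g1 = float(stats.skew(log2c, bias=True))
    return SkewnessRecord(profile.sample_id, profile.strategy, g1,
                          profile.total_reads, True)


def skewness_table(pset: ProfileSet, rank: str = "genus") -> pd.DataFrame:
    recs = [rsa_skewness(p, rank) for p in pset.profiles]
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in recs],
            "strategy": [r.strategy for r in recs],
            "skewness": [r.skewness for r in recs],
            "total_reads": [r.total_reads for r in recs],
            "defined": [r.defined for r in recs],
        }
    ).set_index("sample_id")


def paired_skewness_test(
    pairs: list[SamplePair], rank: str = "genus"
) -> tuple[float, float, int]:
    """Paired Student's t-test on per-pair (16S - shotgun) RSA skewness.

    Returns ``(t, two-sided p, n)`` over pairs where both skewnesses are
    defined.  With zero variance of the differences the test degenerates:
    reported as ``t = +/-inf, p = 0`` (or ``t = 0, p = 1`` when all
    differences are zero).
    """
    diffs = []
    for pair in pairs:
        a = rsa_skewness(pair.amplicon, rank)
        s = rsa_skewness(pair.shotgun, rank)
        if a.defined and s.defined:
            diffs.append(a.skewness - s.skewness)
    n = len(diffs)
    if n < 2:
        raise ValueError(f"paired skewness test needs >= 2 defined pairs, got {n}")
    d = np.asarray(diffs)
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0, n
        return float(np.sign(d[0]) * np.inf), 0.0, n
    t, p = stats.ttest_rel(d, np.zeros_like(d))
    return float(t), float(p), n


def rarefaction_curve(profile: TaxonomicProfile, depths, rank: str = "genus") -> pd.Series:
    """Expected taxon richness under subsampling without replacement.

    For total reads N, per-taxon counts N_g and subsample size n,

        E[S_n] = S_obs - sum_g C(N - N_g, n) / C(N, n),

    evaluated via log-gamma for numerical safety.  Exact endpoints:
    E[S_1] = 1 and E[S_N] = S_obs.
    """
    counts = _rank_counts(profile, rank).to_numpy(dtype=float)
    N = counts.sum()
    depths = np.asarray(list(depths), dtype=int)
    if (depths < 1).any():
        raise ValueError("depths must be positive")
    if (depths > N).any():
        raise ValueError(f"depth exceeds total reads ({int(N)}) of {profile.sample_id!r}")
    s_obs = len(counts)

    def lchoose(a, b):
        return special.gammaln(a + 1) - special.gammaln(b + 1) - special.gammaln(a - b + 1)

    out = np.empty(len(depths))
    for i, n in enumerate(depths):
        keep = (N - counts) >= n  # taxa that can be entirely missed
        miss = np.exp(lchoose(N - counts[keep], n) - lchoose(N, n)).sum()
        out[i] = s_obs - miss
    return pd.Series(out, index=pd.Index(depths, name="depth"), name="expected_richness")


@dataclass
class FilterResult:
    """Outcome of the paired read-depth quality filter."""

    included: ProfileSet
    excluded: pd.DataFrame  # sample_id, strategy, total_reads, reason
    min_reads: int

    @property
    def excluded_ids(self) -> list[str]:
        return list(self.excluded["sample_id"])


def quality_filter(pset: ProfileSet, min_reads: int = 500_000) -> FilterResult:
    """Exclude shallow shotgun samples and propagate to their 16S mates.

    A shotgun profile with ``total_reads < min_reads`` (strictly below) is
    excluded; the paired 16S profile of the same biological sample is then
    excluded too, so both strategies see the same biological samples.  The
    operation is idempotent.
    """
    meta = {m.sample_id: m for m in pset.metadata}
    rows = []
    bad_pairs = set()
    for p in pset.by_strategy("shotgun"):
        if p.total_reads < min_reads:
            rows.append(
                dict(sample_id=p.sample_id, strategy="shotgun",
                     total_reads=p.total_reads,
                     reason=f"total_reads < {min_reads}")
            )
            bad_pairs.add(meta[p.sample_id].pair_id)
    for p in pset.by_strategy("16S"):
        if meta[p.sample_id].pair_id in bad_pairs:
            rows.append(
                dict(sample_id=p.sample_id, strategy="16S",
                     total_reads=p.total_reads,
                     reason="paired shotgun sample excluded")
            )
    excluded = pd.DataFrame(rows, columns=["sample_id", "strategy", "total_reads", "reason"])
    keep = [p.sample_id for p in pset.profiles if p.sample_id not in set(excluded["sample_id"])]
    return FilterResult(included=pset.subset(keep), excluded=excluded, min_reads=min_reads)


def filtered_pairs(pset: ProfileSet, min_reads: int = 500_000):
    """Convenience: quality-filter then pair the retained profiles."""
    res = quality_filter(pset, min_reads)
    pairs, unpaired = pair_profiles(res.included)
    return pairs, res
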