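"""Negative-binomial differential abundance and cross-strategy concordance.

A self-contained count-based differential engine in the DESeq2 family:

1. **Median-of-ratios normalization** — per-sample size factors from the
   median ratio of counts to a geometric-mean pseudo-reference built on
   genera with all-positive counts.
2. **Dispersion estimation** — per-genus method-of-moments NB dispersion on
   normalized counts (within condition groups), shrunk toward a fitted
   mean-dispersion trend ``a0 + a1/mu`` by equal-weight geometric
   averaging.
3. **Wald test** — per-genus NB model with log link, size factors as
   offsets and a two-level condition design; the two group means are
   profiled-out MLEs, the log2 fold change standard error comes from the
   observed Fisher information, and the two-sided p-value from the normal
   reference of the Wald statistic.
4. **BH adjustment** — Benjamini-Hochberg step-up over testable genera
   (all-zero genera are excluded from the multiple-testing family).
5. **Fold-change shrinkage** — empirical-Bayes normal prior ``N(0, tau^2)``
   with ``tau^2`` moment-matched from the MLE LFC spread; the posterior
   mean shrinks noisy fold changes toward zero and never flips a sign.

This is a documented simplification of the full DESeq2 procedure: no
Cook's-distance outlier handling, no independent filtering, and a two-term
dispersion trend.

The concordance analysis compares two strategies' results on their common
genera, classifying each genus by which strategy calls it significant and
asking whether the fold-change *signs* agree (Pearson r and a least-squares
line are reported for genera significant under both strategies).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

LOG2 = np.log(2.0)
MIN_DISPERSION = 1e-8


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (genus x sample count matrix).

    The reference is the per-genus geometric mean across samples, computed
    on genera with strictly positive counts in every sample; each sample's
    factor is the median over those genera of count/reference.  Factors are
    rescaled to unit geometric mean (a constant that cancels in fold
    changes), so normalized counts stay on the counts scale.
    """
    x = counts.to_numpy(dtype=float)
    all_pos = (x > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no genus has positive counts in every sample; cannot build the "
            "geometric-mean reference (consider a pseudo-reference fallback)"
        )
    logx = np.log(x[all_pos])
    ref = logx.mean(axis=1)  # log geometric mean per genus
    logsf = np.median(logx - ref[:, None], axis=0)
    sf = np.exp(logsf - logsf.mean())
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, sf: pd.Series | None = None) -> pd.DataFrame:
    """Counts divided by per-sample size factors."""
    if sf is None:
        sf = size_factors(counts)
    return counts / sf


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def estimate_dispersion(
    counts: pd.DataFrame,
    sf: pd.Series,
    groups: pd.Series | None = None,
) -> pd.Series:
    """Per-genus NB dispersion: method of moments shrunk to a trend.

    With normalized counts ``q = y/s`` the NB model gives
    ``Var(q) ~= mu * mean(1/s) + alpha * mu^2`` within a condition group,
    so the raw estimate is ``alpha_hat = (s2 - mu*xi)/mu^2`` (floored at
    1e-8), pooled across groups by degrees of freedom.  Raw estimates are
    then shrunk toward the least-squares trend ``a0 + a1/mu`` by an
    equal-weight geometric average, taming the noisy per-genus values at
    these sample sizes.
    """
    x = counts.to_numpy(dtype=float)
    s = sf.reindex(counts.columns).to_numpy(dtype=float)
    q = x / s
    if groups is None:
        grp = np.zeros(x.shape[1], dtype=int)
    else:
        grp = pd.Categorical(pd.Series(groups).reindex(counts.columns)).codes
    levels = np.unique(grp)
    for lv in levels:
        if (grp == lv).sum() < 2:
            raise ValueError("each condition group needs >= 2 samples for dispersion")

    num = np.zeros(x.shape[0])
    den = 0.0
    mu_all = q.mean(axis=1)
    for lv in levels:
        cols = grp == lv
        n_k = int(cols.sum())
        qk = q[:, cols]
        m = qk.mean(axis=1)
        v = qk.var(axis=1, ddof=1)
        xi = float(np.mean(1.0 / s[cols]))
        with np.errstate(divide="ignore", invalid="ignore"):
            a_k = np.where(m > 0, (v - m * xi) / np.maximum(m, 1e-300) ** 2, 0.0)
        num += (n_k - 1) * a_k
        den += n_k - 1
    alpha_raw = np.maximum(num / den, MIN_DISPERSION)

    # mean-dispersion trend a0 + a1/mu on informative genera
    ok = (mu_all > 0) & (alpha_raw > MIN_DISPERSION)
    if ok.sum() >= 10:
        A = np.column_stack([np.ones(ok.sum()), 1.0 / mu_all[ok]])
        coef, *_ = np.linalg.lstsq(A, alpha_raw[ok], rcond=None)
        a0, a1 = max(coef[0], MIN_DISPERSION), max(coef[1], 0.0)
    else:
        a0, a1 = max(float(np.median(alpha_raw[ok])) if ok.any() else 0.1, MIN_DISPERSION), 0.0
    with np.errstate(divide="ignore"):
        trend = np.where(mu_all > 0, a0 + a1 / np.maximum(mu_all, 1e-300), a0)
    trend = np.maximum(trend, MIN_DISPERSION)
    alpha = np.exp(0.5 * np.log(alpha_raw) + 0.5 * np.log(trend))
    alpha = np.where(mu_all > 0, alpha, MIN_DISPERSION)
    return pd.Series(np.maximum(alpha, MIN_DISPERSION), index=counts.index, name="dispersion")


# ---------------------------------------------------------------------------
# NB Wald test
# ---------------------------------------------------------------------------

def _fit_group_mean(y: np.ndarray, s: np.ndarray, alpha: np.ndarray, n_iter: int = 50):
    """Vectorized Newton solve of the NB score equation for one group.

    Solves, per genus, sum_j (y_j - s_j e^t) / (1 + alpha s_j e^t) = 0 for
    the log group mean t.  The score is monotone decreasing in t, so Newton
    from the quasi-Poisson start is stable.  Genera with all-zero counts in
    the group sit on the boundary (t -> -inf): their mean is clamped to
    half a count over the group's total size factor and flagged.

    Returns (t, fisher_information, boundary_flag, converged_flag).
    """
    G = y.shape[0]
    tot_y = y.sum(axis=1)
    tot_s = s.sum()
    boundary = tot_y == 0
    t = np.log(np.maximum(tot_y, 0.5) / tot_s)  # quasi-Poisson start / boundary clamp
    active = ~boundary
    converged = np.zeros(G, dtype=bool)
    for _ in range(n_iter):
        mu = np.exp(t)[:, None] * s[None, :]
        denom = 1.0 + alpha[:, None] * mu
        f = ((y - mu) / denom).sum(axis=1)
        fp = -(mu * (1.0 + alpha[:, None] * y) / denom**2).sum(axis=1)
        step = np.where(active, f / fp, 0.0)
        step = np.clip(step, -5.0, 5.0)
        t = t - step
        newly = active & (np.abs(f) < 1e-8 * np.maximum(tot_y, 1.0))
        converged |= newly
        active &= ~newly
        if not active.any():
            break
    mu = np.exp(t)[:, None] * s[None, :]
    info = (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)
    converged |= boundary  # boundary genera are resolved, just flagged
    return t, info, boundary, converged


def nb_wald_test(
    counts: pd.DataFrame,
    sf: pd.Series,
    dispersions: pd.Series,
    groups: pd.Series,
) -> pd.DataFrame:
    """Per-genus NB Wald test of a two-level condition.

    Returns a frame indexed by genus with columns ``baseMean`` (mean
    normalized count), ``lfc`` (MLE log2 fold change, second level vs
    first), ``se``, ``stat``, ``pvalue`` plus ``boundary`` and
    ``converged`` flags.  Genera with zero counts in every sample get
    ``pvalue = NaN`` and are excluded from the multiple-testing family.
    """
    g = pd.Series(groups).reindex(counts.columns)
    cat = pd.Categorical(g)
    if len(cat.categories) != 2:
        raise ValueError(f"need exactly two group levels, got {list(cat.categories)}")
    for lv in cat.categories:
        if (cat == lv).sum() < 2:
            raise ValueError(f"group {lv!r} has fewer than 2 samples")
    y = counts.to_numpy(dtype=float)
    s = sf.reindex(counts.columns).to_numpy(dtype=float)
    alpha = dispersions.reindex(counts.index).to_numpy(dtype=float)
    mask_b = np.asarray(cat.codes == 1)

    t_a, i_a, bnd_a, conv_a = _fit_group_mean(y[:, ~mask_b], s[~mask_b], alpha)
    t_b, i_b, bnd_b, conv_b = _fit_group_mean(y[:, mask_b], s[mask_b], alpha)

    lfc = (t_b - t_a) / LOG2
    se = np.sqrt(1.0 / i_a + 1.0 / i_b) / LOG2
    stat = lfc / se
    pvalue = 2.0 * stats.norm.sf(np.abs(stat))

    all_zero = y.sum(axis=1) == 0
    not_conv = ~(conv_a & conv_b)
    pvalue = np.where(all_zero | not_conv, np.nan, pvalue)
    lfc = np.where(all_zero, 0.0, lfc)

    return pd.DataFrame(
        {
            "baseMean": (y / s).mean(axis=1),
            "lfc": lfc,
            "se": se,
            "stat": stat,
            "pvalue": pvalue,
            "boundary": bnd_a | bnd_b,
            "converged": conv_a & conv_b,
        },
        index=counts.index,
    )


def bh_adjust(pvalues: pd.Series) -> pd.Series:
    """Benjamini-Hochberg step-up; NaN entries are excluded from the family."""
    p = pd.Series(pvalues, dtype=float)
    ok = p.notna()
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = pd.Series(np.nan, index=p.index)
    if ok.any():
        out[ok] = multipletests(p[ok].to_numpy(), method="fdr_bh")[1]
    return out


def shrink_lfc(lfc: pd.Series, se: pd.Series) -> pd.Series:
    """Empirical-Bayes normal shrinkage of log2 fold changes.

    Prior N(0, tau^2) with ``tau^2 = max(var(lfc) - mean(se^2), 1e-6)``
    moment-matched on the observed MLE spread; the posterior mean is
    ``lfc * tau^2 / (tau^2 + se^2)``.  Magnitudes never increase and signs
    never flip.
    """
    l = pd.Series(lfc, dtype=float)
    s2 = pd.Series(se, dtype=float) ** 2
    ok = l.notna() & s2.notna()
    tau2 = max(float(l[ok].var(ddof=0) - s2[ok].mean()), 1e-6) if ok.any() else 1e-6
    return l * tau2 / (tau2 + s2)


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class DifferentialAbundance:
    """Two-group NB differential-abundance model for one strategy's counts.

    Parameters
    ----------
    counts : DataFrame
        Genus x sample integer counts.
    groups : Series or mapping
        Two-level condition label per sample (the log2 fold change is the
        second categorical level versus the first).
    """

    def __init__(self, counts: pd.DataFrame, groups) -> None:
        self.counts = counts
        self.groups = pd.Series(groups).reindex(counts.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValueError(f"samples without group label: {missing}")

    @classmethod
    def from_profile_set(cls, pset, strategy: str, contrast: str, subset=None):
        """Build from a ProfileSet using a metadata column as the condition.

        ``contrast`` is ``"compartment"`` or ``"day"`` (day restricted to 14
        vs 35); ``subset`` optionally restricts to one compartment for the
        day contrast.
        """
        meta = pset.metadata_frame().set_index("sample_id")
        meta = meta[meta["strategy"] == strategy]
        if contrast == "compartment":
            labels = meta["compartment"]
        elif contrast == "day":
            meta = meta[meta["day"].isin([14, 35])]
            if subset is not None:
                meta = meta[meta["compartment"] == subset]
            labels = meta["day"].astype(str)
        else:
            raise ValueError(f"unknown contrast {contrast!r}")
        counts = pset.counts_matrix(strategy)[meta.index]
        return cls(counts, labels)

    def fit(self, alpha_level: float = 0.05) -> "DifferentialAbundanceResults":
        sf = size_factors(self.counts)
        disp = estimate_dispersion(self.counts, sf, self.groups)
        res = nb_wald_test(self.counts, sf, disp, self.groups)
        res["padj"] = bh_adjust(res["pvalue"])
        res["lfcShrunk"] = shrink_lfc(res["lfc"], res["se"])
        res["dispersion"] = disp
        return DifferentialAbundanceResults(self, res, sf, alpha_level)


class DifferentialAbundanceResults:
    """Estimates, uncertainties and significance calls per genus."""

    def __init__(self, model, frame: pd.DataFrame, sf: pd.Series, alpha_level: float):
        self.model = model
        self._frame = frame
        self.size_factors = sf
        self.alpha_level = alpha_level

    @property
    def frame(self) -> pd.DataFrame:
        cols = ["baseMean", "lfc", "lfcShrunk", "se", "pvalue", "padj",
                "dispersion", "boundary", "converged"]
        return self._frame[cols]

    @property
    def significant(self) -> pd.Index:
        f = self._frame
        return f.index[f["padj"] < self.alpha_level]

    def summary(self) -> str:
        f = self._frame
        levels = list(pd.Categorical(self.model.groups).categories)
        n_test = int(f["pvalue"].notna().sum())
        lines = [
            "Differential abundance (NB Wald test)",
            "=====================================",
            f"contrast: {levels[1]} vs {levels[0]}",
            f"genera: {len(f)} total, {n_test} testable",
            f"significant (BH-adjusted p < {self.alpha_level:g}): {len(self.significant)}",
            f"  up:   {int((f.loc[self.significant, 'lfc'] > 0).sum())}",
            f"  down: {int((f.loc[self.significant, 'lfc'] < 0).sum())}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

CATEGORIES = ("both", "16S-only", "shotgun-only", "neither")


@dataclass
class ConcordanceTable:
    """Sign concordance of fold changes between strategies, by category.

    ``table`` has one row per significance category (both / 16S-only /
    shotgun-only / neither) with concordant count, total and percentage;
    ``r``/``slope``/``intercept`` describe shotgun-vs-16S fold changes over
    the genera significant under both strategies.
    """

    table: pd.DataFrame
    r: float
    r_pvalue: float
    slope: float
    intercept: float
    n_common: int
    alpha: float

    def summary(self) -> str:
        lines = [
            "Fold-change concordance between strategies",
            "==========================================",
            f"common genera tested: {self.n_common}  (alpha = {self.alpha:g})",
            self.table.to_string(),
            f"'both' category: Pearson r = {self.r:.3f} (p = {self.r_pvalue:.3g}), "
            f"slope = {self.slope:.3f}, intercept = {self.intercept:.3f}",
        ]
        return "\n".join(lines)


def concordance_analysis(
    res_16s: pd.DataFrame,
    res_shotgun: pd.DataFrame,
    alpha: float = 0.05,
    use_shrunken: bool = True,
) -> ConcordanceTable:
    """Classify common genera by significance pattern and sign agreement.

    Both inputs are result frames (as produced by
    :class:`DifferentialAbundanceResults`) indexed by genus; only genera
    present in both indexes (the common genera) enter the analysis.  A
    genus is concordant when its fold-change sign (shrunken by default)
    agrees between strategies; a zero fold change on either side counts as
    discordant.
    """
    common = res_16s.index.intersection(res_shotgun.index)
    if len(common) == 0:
        raise ValueError("no common genera between the two result sets")
    a = res_16s.loc[common]
    b = res_shotgun.loc[common]
    col = "lfcShrunk" if use_shrunken else "lfc"
    sig_a = a["padj"].fillna(1.0) < alpha
    sig_b = b["padj"].fillna(1.0) < alpha
    cat = np.select(
        [sig_a & sig_b, sig_a & ~sig_b, ~sig_a & sig_b],
        ["both", "16S-only", "shotgun-only"],
        default="neither",
    )
    sign_a = np.sign(a[col].to_numpy())
    sign_b = np.sign(b[col].to_numpy())
    concordant = (sign_a == sign_b) & (sign_a != 0)

    rows = []
    for c in CATEGORIES:
        m = cat == c
        tot = int(m.sum())
        conc = int(concordant[m].sum())
        rows.append(
            dict(category=c, concordant=conc, total=tot,
                 percentage=100.0 * conc / tot if tot else np.nan)
        )
    table = pd.DataFrame(rows).set_index("category")

    both = cat == "both"
    if both.sum() >= 3:
        x = a[col].to_numpy()[both]
        y = b[col].to_numpy()[both]
        r, rp = stats.pearsonr(x, y)
        fit = stats.linregress(x, y)
        slope, intercept = float(fit.slope), float(fit.intercept)
    else:
        r, rp, slope, intercept = np.nan, np.nan, np.nan, np.nan
    return ConcordanceTable(
        table=table, r=float(r), r_pvalue=float(rp), slope=slope,
        intercept=intercept, n_common=int(len(common)), alpha=alpha,
    )


def synthetic_results_from_categories(
    spec: dict[str, tuple[int, int]], seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build a synthetic pair of result frames realizing category counts.

    ``spec`` maps each significance category to ``(concordant, total)``;
    the returned frames, fed to :func:`concordance_analysis`, reproduce
    exactly those counts.  Used for worked examples and fixtures.
    """
    rng = np.random.default_rng(seed)
    rows_a, rows_b, names = [], [], []
    i = 0
    for catname, (conc, tot) in spec.items():
        sig_a = catname in ("both", "16S-only")
        sig_b = catname in ("both", "shotgun-only")
        for j in range(tot):
            mag_a = float(rng.uniform(0.5, 3.0))
            mag_b = float(rng.uniform(0.5, 3.0))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            if j < conc:
                la, lb = sign * mag_a, sign * mag_b
            else:
                la, lb = sign * mag_a, -sign * mag_b
            rows_a.append(dict(lfc=la, lfcShrunk=la, padj=0.01 if sig_a else 0.5))
            rows_b.append(dict(lfc=lb, lfcShrunk=lb, padj=0.01 if sig_b else 0.5))
            names.append(f"genus{i:04d}")
            i += 1
    idx = pd.Index(names, name="genus")
    return pd.DataFrame(rows_a, index=idx), pd.DataFrame(rows_b, index=idx)
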