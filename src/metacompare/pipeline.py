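"""End-to-end strategy comparison: one model object, one results bundle.

:class:`StrategyComparison` runs the full study workflow on a paired
dataset — read-depth quality filtering with paired propagation, RSA
skewness diagnostics and the paired skewness test, per-contrast
differential abundance under each strategy with cross-strategy
concordance, per-pair detection-limit regression with the intercept-depth
correlation, and silhouette-scored ordination over the four genus
subsets — and returns a :class:`StrategyComparisonResults` with a
machine-readable report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffabund, ordination, paircompare, rsa
from .profiles import ProfileSet, load_profile_set, pair_profiles

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one comparison run (YAML-loadable)."""

    counts_16s: str | None = None
    counts_shotgun: str | None = None
    metadata: str | None = None
    design: dict | None = None          # SimulationDesign fields for synthetic runs
    min_reads: int = 500_000
    alpha: float = 0.05
    contrasts: list = field(default_factory=lambda: ["compartment", "day"])
    day_subset: str | None = None       # restrict the day contrast to one compartment
    seed: int = 0
    outdir: str = "metacompare_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate_paths(self) -> None:
        if self.design is not None:
            return
        for name in ("counts_16s", "counts_shotgun", "metadata"):
            p = getattr(self, name)
            if p is None:
                raise ValueError(f"config needs either 'design' or '{name}'")
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: no such file {p!r}")


class StrategyComparison:
    """Paired 16S/shotgun comparison model over a :class:`ProfileSet`."""

    def __init__(self, pset: ProfileSet) -> None:
        self.pset = pset

    @classmethod
    def from_tables(cls, counts_16s, counts_shotgun, metadata) -> "StrategyComparison":
        return cls(load_profile_set(counts_16s, counts_shotgun, metadata))

    @classmethod
    def from_config(cls, config: RunConfig) -> "StrategyComparison":
        config.validate_paths()
        if config.design is not None:
            from .simulate import SimulationDesign, generate_paired_dataset

            design = SimulationDesign(**{**config.design, "seed": config.seed})
            pset, _ = generate_paired_dataset(design)
            return cls(pset)
        return cls.from_tables(config.counts_16s, config.counts_shotgun, config.metadata)

    def fit(
        self,
        min_reads: int = 500_000,
        alpha: float = 0.05,
        contrasts: tuple[str, ...] = ("compartment", "day"),
        day_subset: str | None = None,
    ) -> "StrategyComparisonResults":
        n_in = len(self.pset.profiles)
        logger.info("quality filter: %d input profiles", n_in)
        filt = rsa.quality_filter(self.pset, min_reads)
        retained = filt.included
        pairs, unpaired = pair_profiles(retained)
        logger.info(
            "quality filter: excluded %d profiles, retained %d pairs",
            len(filt.excluded), len(pairs),
        )

        skew = rsa.skewness_table(retained)
        try:
            t_stat, t_p, t_n = rsa.paired_skewness_test(pairs)
        except ValueError as err:
            logger.warning("paired skewness test skipped: %s", err)
            t_stat, t_p, t_n = np.nan, np.nan, 0

        differential: dict[str, dict[str, pd.DataFrame]] = {}
        concordance: dict[str, diffabund.ConcordanceTable] = {}
        for contrast in contrasts:
            per_strategy: dict[str, pd.DataFrame] = {}
            for strategy in ("16S", "shotgun"):
                model = diffabund.DifferentialAbundance.from_profile_set(
                    retained, strategy, contrast,
                    subset=day_subset if contrast == "day" else None,
                )
                per_strategy[strategy] = model.fit(alpha).frame
                logger.info(
                    "differential %s/%s: %d genera, %d significant",
                    contrast, strategy, len(per_strategy[strategy]),
                    int((per_strategy[strategy]["padj"] < alpha).sum()),
                )
            differential[contrast] = per_strategy
            concordance[contrast] = diffabund.concordance_analysis(
                per_strategy["16S"], per_strategy["shotgun"], alpha
            )

        pair_table = paircompare.pair_comparison_table(pairs)
        fits = [
            paircompare.detection_limit_fit(p)
            for p in pairs
            if len(p.common_genera) >= 3
        ]
        if len(fits) >= 3:
            int_r, int_p = paircompare.intercept_depth_correlation(fits)
        else:
            int_r, int_p = np.nan, np.nan

        strat = ordination.stratification_analysis(retained)

        return StrategyComparisonResults(
            model=self,
            filter_result=filt,
            n_pairs=len(pairs),
            unpaired=unpaired,
            skewness=skew,
            skewness_test=(t_stat, t_p, t_n),
            differential=differential,
            concordance=concordance,
            pair_table=pair_table,
            intercept_depth=(int_r, int_p),
            stratification=strat,
            alpha=alpha,
            min_reads=min_reads,
        )


@dataclass
class StrategyComparisonResults:
    """All comparison outputs plus serialization helpers."""

    model: StrategyComparison
    filter_result: rsa.FilterResult
    n_pairs: int
    unpaired: list
    skewness: pd.DataFrame
    skewness_test: tuple
    differential: dict
    concordance: dict
    pair_table: pd.DataFrame
    intercept_depth: tuple
    stratification: ordination.StratificationReport
    alpha: float
    min_reads: int

    def report(self) -> dict:
        """Machine-readable report of every stage."""
        t_stat, t_p, t_n = self.skewness_test
        rep = {
            "quality_filter": {
                "min_reads": self.min_reads,
                "n_excluded": int(len(self.filter_result.excluded)),
                "excluded": self.filter_result.excluded.to_dict(orient="records"),
                "n_retained_pairs": self.n_pairs,
                "unpaired": list(self.unpaired),
            },
            "skewness": {
                "per_sample": self.skewness.reset_index().to_dict(orient="records"),
                "paired_t": {"t": _f(t_stat), "p": _f(t_p), "n": t_n},
            },
            "differential": {},
            "concordance": {},
            "detection": {
                "per_pair": self.pair_table.reset_index().to_dict(orient="records"),
                "intercept_depth_r": _f(self.intercept_depth[0]),
                "intercept_depth_p": _f(self.intercept_depth[1]),
            },
            "stratification": self.stratification.scores.to_dict(orient="records"),
        }
        for contrast, per_strategy in self.differential.items():
            rep["differential"][contrast] = {
                strategy: {
                    "n_genera": int(len(frame)),
                    "n_significant": int((frame["padj"] < self.alpha).sum()),
                }
                for strategy, frame in per_strategy.items()
            }
        for contrast, conc in self.concordance.items():
            rep["concordance"][contrast] = {
                "n_common": conc.n_common,
                "r": _f(conc.r),
                "slope": _f(conc.slope),
                "intercept": _f(conc.intercept),
                "categories": conc.table.reset_index().to_dict(orient="records"),
            }
        return rep

    def summary(self) -> str:
        t_stat, t_p, t_n = self.skewness_test
        lines = [
            "Paired 16S vs shotgun strategy comparison",
            "=========================================",
            f"retained pairs: {self.n_pairs} "
            f"(excluded {len(self.filter_result.excluded)} profiles below "
            f"{self.min_reads} shotgun reads, with paired propagation)",
            f"paired RSA skewness t-test (16S - shotgun): "
            f"t = {t_stat:.3f}, p = {t_p:.3g} (n = {t_n})",
            "",
        ]
        for contrast, per_strategy in self.differential.items():
            sig = {
                s: int((f["padj"] < self.alpha).sum()) for s, f in per_strategy.items()
            }
            lines.append(
                f"contrast {contrast!r}: significant genera 16S = {sig['16S']}, "
                f"shotgun = {sig['shotgun']}"
            )
            lines.append(self.concordance[contrast].summary())
            lines.append("")
        r, p = self.intercept_depth
        lines.append(
            f"detection-limit intercept vs shotgun depth: r = {r:.3f} (p = {p:.3g})"
        )
        lines.append("")
        lines.append(self.stratification.summary())
        return "\n".join(lines)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(self.report(), fh, indent=2, sort_keys=True)
        self.skewness.to_csv(outdir / "skewness.tsv", sep="\t")
        self.filter_result.excluded.to_csv(outdir / "exclusions.tsv", sep="\t", index=False)
        self.pair_table.to_csv(outdir / "pairs.tsv", sep="\t")
        self.stratification.scores.to_csv(outdir / "silhouette.tsv", sep="\t", index=False)
        for contrast, per_strategy in self.differential.items():
            for strategy, frame in per_strategy.items():
                frame.to_csv(outdir / f"diff_{contrast}_{strategy}.tsv", sep="\t")
            self.concordance[contrast].table.to_csv(
                outdir / f"concordance_{contrast}.tsv", sep="\t"
            )


def _f(x) -> float | None:
    """JSON-safe float (NaN/inf -> None)."""
    x = float(x)
    return None if not np.isfinite(x) else x


def run_all(config: RunConfig) -> StrategyComparisonResults:
    """Execute the whole workflow from one config and write the report."""
    config.validate_paths()
    model = StrategyComparison.from_config(config)
    results = model.fit(
        min_reads=config.min_reads,
        alpha=config.alpha,
        contrasts=tuple(config.contrasts),
        day_subset=config.day_subset,
    )
    results.save(config.outdir)
    rep_path = Path(config.outdir) / "report.json"
    logger.info("report written to %s", rep_path)
    return results
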