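"""Paired 16S/shotgun community simulator with known ground truth.

The generator emulates the structure of a paired chicken-gut sequencing
study: the same biological samples profiled both by 16S amplicon sequencing
(V3-V4, nominal depth ~187,500 reads/sample) and by shotgun metagenomics
(depths from below 500,000 up to several million reads), across two gut
compartments (caeca, crop) and three sampling days (1, 14, 35).

Model
-----
* A *true community* of several hundred genera with lognormal relative
  abundances (near-symmetric relative-abundance distribution on the log
  scale, so that under-sampling truncation of the rare tail is observable).
* Shotgun reads are a plain multinomial draw over the true proportions.
* 16S reads are a multinomial draw over proportions re-weighted by a
  per-genus amplification bias factor ``b_g`` (lognormal around 1);
  ``b_g = 0`` encodes primer dropout, making the genus shotgun-exclusive
  in expectation.
* A small set of *phantom* genera is observable only in 16S, standing in
  for reference-database disagreement between the two strategies' taxonomic
  assignments; phantoms carry no condition effect.
* Condition effects multiply the proportions of a designated fraction of
  genera by ``2**LFC`` in one level of a contrast (crop vs caeca;
  day 35 vs day 14), after which proportions are renormalized.  The
  per-genus true LFC is recorded as ground truth.

All strategy distortions are folded into ``b_g``: there is no genome-size
weighting, no separate 16S copy-number term, and no read-level error model.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .profiles import ProfileSet, SampleMetadata, TaxonomicProfile

# Replicates per (compartment, day) cell in the default study layout:
# 40 caeca + 38 crop paired samples.
DEFAULT_LAYOUT: dict[tuple[str, int], int] = {
    ("caeca", 1): 4,
    ("caeca", 14): 16,
    ("caeca", 35): 20,
    ("crop", 1): 5,
    ("crop", 14): 15,
    ("crop", 35): 18,
}


@dataclass
class SimulationDesign:
    """Parameters of one synthetic paired dataset.

    Defaults reproduce the depth regimes and genus-count order of magnitude
    of the emulated study: 400 genera across 14 phyla, 16S depth uniform in
    [150,000; 200,000], shotgun depth log-uniform in [200,000; 5,000,000]
    with 28/78 of samples forced below the 500,000-read quality threshold.
    """

    n_genera: int = 400
    n_phyla: int = 14
    log_mean: float = 0.0
    log_sd: float = 2.5
    layout: dict = field(default_factory=lambda: dict(DEFAULT_LAYOUT))
    depth_16s: tuple[int, int] = (150_000, 200_000)
    depth_shotgun: tuple[int, int] = (200_000, 5_000_000)
    low_depth_fraction: float = 28 / 78
    low_depth_threshold: int = 500_000
    dropout_fraction: float = 0.10
    phantom_fraction: float = 0.05
    phantom_mass: float = 0.02
    bias_log_sd: float = 0.5
    affected_fraction: dict = field(
        default_factory=lambda: {"compartment": 0.5, "day": 0.25}
    )
    lfc_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genera < 2:
            raise ValueError("need at least 2 genera")
        for name in ("dropout_fraction", "phantom_fraction", "low_depth_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for f in self.affected_fraction.values():
            if not 0 <= f <= 1:
                raise ValueError("affected fractions must be in [0, 1]")
        for lo, hi in (self.depth_16s, self.depth_shotgun):
            if lo < 1 or hi < lo:
                raise ValueError("depth ranges must be positive and ordered")


@dataclass
class TrueCommunity:
    """Ground-truth community underlying one condition level.

    ``proportions`` covers the real (shotgun-observable) genera and sums to
    one; phantom genera live only in ``phantom_proportions`` (their 16S
    sampling weight relative to the real community mass).
    """

    proportions: pd.Series            # genus -> true proportion (sums to 1)
    lineage: dict[str, str]
    bias: pd.Series                   # genus -> b_g >= 0 (0 = primer dropout)
    phantom_proportions: pd.Series    # 16S-only genera -> small mass-space weight
    mass_scale: float = 1.0           # total community mass relative to base

    def __post_init__(self) -> None:
        total = float(self.proportions.sum())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"proportions sum to {total}, not 1")
        if (self.bias < 0).any():
            raise ValueError("bias factors must be non-negative")
        overlap = set(self.proportions.index) & set(self.phantom_proportions.index)
        if overlap:
            raise ValueError(f"phantom genera overlap real genera: {sorted(overlap)[:5]}")

    @property
    def dropout_genera(self) -> set[str]:
        return set(self.bias.index[self.bias == 0])

    @property
    def phantom_genera(self) -> set[str]:
        return set(self.phantom_proportions.index)


def _rng_for(seed: int, key: str) -> np.random.Generator:
    """Deterministic per-sample substream derived from (seed, key)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(key.encode())])
    )


def generate_true_community(design: SimulationDesign) -> TrueCommunity:
    """Draw the base community (proportions, lineage, bias, phantoms)."""
    design.validate()
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 0]))
    n = design.n_genera
    names = [f"g{i:04d}" for i in range(n)]
    phyla = [f"p{i:02d}" for i in rng.integers(0, design.n_phyla, size=n)]
    lineage = dict(zip(names, phyla))

    # lognormal relative species abundance (natural-log scale)
    props = np.exp(rng.normal(design.log_mean, design.log_sd, size=n))
    props /= props.sum()

    # disjoint dropout / phantom assignment
    n_drop = int(round(design.dropout_fraction * n))
    n_phantom = int(round(design.phantom_fraction * n))
    special = rng.choice(n, size=n_drop + n_phantom, replace=False)
    drop_idx = special[:n_drop]
    phantom_idx = special[n_drop:]

    bias = np.exp(rng.normal(0.0, design.bias_log_sd, size=n))
    bias[drop_idx] = 0.0

    phantom_names = [names[i] for i in phantom_idx]
    real_mask = np.ones(n, dtype=bool)
    real_mask[phantom_idx] = False
    real_names = [names[i] for i in range(n) if real_mask[i]]

    real_props = props[real_mask]
    real_props = real_props / real_props.sum()

    # phantoms get small 16S weights totalling `phantom_mass` of community mass
    if len(phantom_names) > 0:
        w = np.exp(rng.normal(design.log_mean, design.log_sd, size=len(phantom_names)))
        w = w / w.sum() * design.phantom_mass
    else:
        w = np.array([])
    return TrueCommunity(
        proportions=pd.Series(real_props, index=pd.Index(real_names, name="genus")),
        lineage=lineage,
        bias=pd.Series(bias[real_mask], index=real_names),
        phantom_proportions=pd.Series(w, index=pd.Index(phantom_names, name="genus")),
    )


def apply_condition_effects(
    base: TrueCommunity, contrast: str, design: SimulationDesign
) -> tuple[TrueCommunity, pd.Series]:
    """Perturb a fraction of genera in the alternative condition level.

    Returns the perturbed community plus the recorded true log2 fold change
    per affected genus (unaffected genera are absent from the record; note
    that renormalization makes realized compositional fold changes differ
    slightly from the recorded per-genus multipliers).
    """
    frac = design.affected_fraction.get(contrast, 0.0)
    rng = np.random.default_rng(
        np.random.SeedSequence([design.seed, 1, zlib.crc32(contrast.encode())])
    )
    genera = list(base.proportions.index)
    n_aff = int(round(frac * len(genera)))
    affected = rng.choice(len(genera), size=n_aff, replace=False)
    lfc = pd.Series(0.0, index=base.proportions.index)
    lfc.iloc[affected] = rng.normal(0.0, design.lfc_sd, size=n_aff)
    return perturb_community(base, lfc), lfc[lfc != 0.0]


def perturb_community(base: TrueCommunity, lfc: pd.Series) -> TrueCommunity:
    """Multiply proportions by ``2**lfc`` per genus, then renormalize.

    The pre-normalization total mass is tracked in ``mass_scale`` so that
    phantom genera, whose weights live in the unperturbed mass space, keep
    a condition-independent absolute abundance.
    """
    mass = base.proportions * np.exp2(lfc.reindex(base.proportions.index).fillna(0.0))
    total = float(mass.sum())
    return TrueCommunity(
        proportions=mass / total,
        lineage=base.lineage,
        bias=base.bias,
        phantom_proportions=base.phantom_proportions,
        mass_scale=base.mass_scale * total,
    )


def simulate_shotgun_profile(
    community: TrueCommunity, depth: int, seed, sample_id: str = "sample"
) -> TaxonomicProfile:
    """Multinomial read sampling over the true proportions (no bias)."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = rng.multinomial(depth, community.proportions.to_numpy())
    return TaxonomicProfile(
        sample_id=sample_id,
        strategy="shotgun",
        counts=dict(zip(community.proportions.index, (int(c) for c in counts))),
        lineage=community.lineage,
    )


def simulate_16s_profile(
    community: TrueCommunity, depth: int, seed, sample_id: str = "sample"
) -> TaxonomicProfile:
    """Multinomial sampling under amplification bias plus phantom genera.

    Sampling weights are ``p_g * b_g`` for real genera and the assigned
    small weights for phantom genera; genera with ``b_g = 0`` are never
    observed.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w_real = community.proportions.to_numpy() * community.bias.to_numpy()
    # phantom weights live in the base mass space: dividing by mass_scale
    # keeps their absolute abundance condition-independent, like an
    # unaffected real genus
    w_ph = community.phantom_proportions.to_numpy() / community.mass_scale
    weights = np.concatenate([w_real, w_ph])
    total = weights.sum()
    if total <= 0:
        raise ValueError("all bias factors are zero and no phantom genera: nothing to sample")
    names = list(community.proportions.index) + list(community.phantom_proportions.index)
    counts = rng.multinomial(depth, weights / total)
    return TaxonomicProfile(
        sample_id=sample_id,
        strategy="16S",
        counts=dict(zip(names, (int(c) for c in counts))),
        lineage=community.lineage,
    )


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    communities: dict[tuple[str, int], TrueCommunity]  # (compartment, day) -> community
    lfc_compartment: pd.Series  # true LFC crop vs caeca (affected genera)
    lfc_day: pd.Series          # true LFC day 35 vs day 14 (affected genera)
    bias: pd.Series
    phantom_genera: set[str]
    dropout_genera: set[str]
    depths: pd.Series           # sample_id -> depth
    seed: int

    def table(self) -> pd.DataFrame:
        base = self.communities[("caeca", 14)]
        genera = list(base.proportions.index) + sorted(self.phantom_genera)
        df = pd.DataFrame(index=pd.Index(genera, name="genus"))
        df["phylum"] = [base.lineage.get(g, "NA") for g in genera]
        df["true_proportion"] = base.proportions.reindex(genera).fillna(0.0)
        df["bias_16s"] = self.bias.reindex(genera)
        df.loc[sorted(self.phantom_genera), "bias_16s"] = np.nan
        df["phantom"] = [g in self.phantom_genera for g in genera]
        df["dropout"] = [g in self.dropout_genera for g in genera]
        df["true_lfc_compartment"] = self.lfc_compartment.reindex(genera).fillna(0.0)
        df["true_lfc_day"] = self.lfc_day.reindex(genera).fillna(0.0)
        return df


def generate_paired_dataset(design: SimulationDesign) -> tuple[ProfileSet, GroundTruth]:
    """Generate the full factorial paired dataset plus its ground truth.

    A fixed fraction of shotgun samples is forced below the low-depth
    threshold to exercise the read-count quality filter; at the default
    layout these are assigned preferentially to the day-1 and early crop
    cells, mirroring the low-biomass samples of the emulated study.
    """
    design.validate()
    base = generate_true_community(design)
    crop_shift, lfc_comp = apply_condition_effects(base, "compartment", design)
    day_shift, lfc_day = apply_condition_effects(base, "day", design)

    def cell_community(compartment: str, day: int) -> TrueCommunity:
        lfc = pd.Series(0.0, index=base.proportions.index)
        if compartment == "crop":
            lfc = lfc + lfc_comp.reindex(lfc.index).fillna(0.0)
        if day == 35:
            lfc = lfc + lfc_day.reindex(lfc.index).fillna(0.0)
        return perturb_community(base, lfc)

    communities = {
        (comp, day): cell_community(comp, day) for (comp, day) in design.layout
    }

    # enumerate samples; order low-depth preference: day 1 first, then crop
    # day 14, then remaining cells
    cells = sorted(design.layout, key=lambda cd: (cd[1] != 1, cd[0] != "crop", cd))
    sample_plan = [
        (comp, day, rep)
        for comp, day in cells
        for rep in range(1, design.layout[(comp, day)] + 1)
    ]
    n_samples = len(sample_plan)
    n_low = int(round(design.low_depth_fraction * n_samples))

    depth_rng = np.random.default_rng(np.random.SeedSequence([design.seed, 2]))
    lo, hi = design.depth_shotgun
    thr = design.low_depth_threshold
    profiles: list[TaxonomicProfile] = []
    metadata: list[SampleMetadata] = []
    depths: dict[str, int] = {}
    for i, (comp, day, rep) in enumerate(sample_plan):
        pair_id = f"{comp}_d{day:02d}_r{rep:02d}"
        if i < n_low:
            depth_sg = int(np.exp(depth_rng.uniform(np.log(lo), np.log(min(thr, hi)))))
            depth_sg = min(depth_sg, thr - 1)
        else:
            depth_sg = int(np.exp(depth_rng.uniform(np.log(max(lo, thr)), np.log(hi))))
        depth_a = int(depth_rng.integers(design.depth_16s[0], design.depth_16s[1] + 1))
        comm = communities[(comp, day)]
        sg_id, a_id = f"{pair_id}_sg", f"{pair_id}_16s"
        profiles.append(
            simulate_shotgun_profile(comm, depth_sg, _rng_for(design.seed, sg_id), sg_id)
        )
        profiles.append(
            simulate_16s_profile(comm, depth_a, _rng_for(design.seed, a_id), a_id)
        )
        metadata.append(SampleMetadata(sg_id, "shotgun", comp, day, pair_id))
        metadata.append(SampleMetadata(a_id, "16S", comp, day, pair_id))
        depths[sg_id] = depth_sg
        depths[a_id] = depth_a

    truth = GroundTruth(
        communities=communities,
        lfc_compartment=lfc_comp,
        lfc_day=lfc_day,
        bias=base.bias,
        phantom_genera=base.phantom_genera,
        dropout_genera=base.dropout_genera,
        depths=pd.Series(depths, name="depth"),
        seed=design.seed,
    )
    return ProfileSet(profiles=profiles, metadata=metadata), truth


def write_dataset(design: SimulationDesign, outdir) -> tuple[ProfileSet, GroundTruth]:
    """Generate and write counts/metadata/ground-truth/design files."""
    from pathlib import Path

    from .profiles import write_count_table, write_metadata

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pset, truth = generate_paired_dataset(design)
    lineage = pset.lineage()
    write_count_table(pset.by_strategy("16S"), lineage, outdir / "counts_16s.tsv")
    write_count_table(pset.by_strategy("shotgun"), lineage, outdir / "counts_shotgun.tsv")
    write_metadata(pset.metadata, outdir / "metadata.tsv")
    truth.table().to_csv(outdir / "ground_truth.tsv", sep="\t")
    cfg = asdict(design)
    cfg["layout"] = {f"{c}:{d}": r for (c, d), r in design.layout.items()}
    cfg["affected_fraction"] = dict(design.affected_fraction)
    with open(outdir / "design.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return pset, truth
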