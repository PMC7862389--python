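"""Shared fixtures: tiny hand-built profiles and small simulated datasets."""

import numpy as np
import pandas as pd
import pytest

from metacompare.profiles import (
    ProfileSet,
    SampleMetadata,
    SamplePair,
    TaxonomicProfile,
)
from metacompare.simulate import SimulationDesign, generate_paired_dataset


def make_profile(sample_id, strategy, counts, phylum="pA"):
    """Profile with a single-phylum lineage unless a dict is given."""
    lineage = phylum if isinstance(phylum, dict) else {g: phylum for g in counts}
    return TaxonomicProfile(sample_id=sample_id, strategy=strategy,
                            counts=dict(counts), lineage=lineage)


@pytest.fixture
def tiny_pair():
    """One pair: shotgun counts are exactly 16x the 16S counts."""
    a = make_profile("s1_16s", "16S", {"g1": 1, "g2": 2, "g3": 4, "g4": 8})
    s = make_profile("s1_sg", "shotgun", {"g1": 16, "g2": 32, "g3": 64, "g4": 128})
    return SamplePair(pair_id="s1", amplicon=a, shotgun=s)


@pytest.fixture
def tiny_pset():
    """Two pairs, one shotgun sample below any realistic depth threshold."""
    profiles = [
        make_profile("p1_16s", "16S", {"g1": 5, "g2": 3}),
        make_profile("p1_sg", "shotgun", {"g1": 700_000, "g2": 300_000}),
        make_profile("p2_16s", "16S", {"g1": 4, "g2": 4}),
        make_profile("p2_sg", "shotgun", {"g1": 200_000, "g2": 200_000}),
    ]
    metadata = [
        SampleMetadata("p1_16s", "16S", "caeca", 14, "p1"),
        SampleMetadata("p1_sg", "shotgun", "caeca", 14, "p1"),
        SampleMetadata("p2_16s", "16S", "crop", 35, "p2"),
        SampleMetadata("p2_sg", "shotgun", "crop", 35, "p2"),
    ]
    return ProfileSet(profiles=profiles, metadata=metadata)


SMALL_LAYOUT = {("caeca", 14): 6, ("caeca", 35): 6, ("crop", 14): 6, ("crop", 35): 6}


def small_design(seed=0, **kwargs):
    """A scaled-down simulation design for fast end-to-end tests."""
    params = dict(
        n_genera=150,
        layout=dict(SMALL_LAYOUT),
        depth_16s=(30_000, 40_000),
        depth_shotgun=(600_000, 2_000_000),
        low_depth_fraction=0.0,
        seed=seed,
    )
    params.update(kwargs)
    return SimulationDesign(**params)


@pytest.fixture(scope="session")
def small_dataset():
    """One small paired dataset plus its ground truth (session-cached)."""
    return generate_paired_dataset(small_design(seed=42))


def nb_counts(rng, mu, alpha, n, prefix="s"):
    """Gamma-Poisson NB counts: genus x sample DataFrame at means ``mu``."""
    mu = np.asarray(mu, dtype=float)
    if alpha > 0:
        lam = rng.gamma(shape=1.0 / alpha, scale=mu[:, None] * alpha,
                        size=(len(mu), n))
    else:
        lam = np.tile(mu[:, None], (1, n))
    y = rng.poisson(lam)
    return pd.DataFrame(y, index=[f"g{i}" for i in range(len(mu))],
                        columns=[f"{prefix}{j}" for j in range(n)])
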