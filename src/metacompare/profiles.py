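"""Genus-level taxonomic profiles, sample metadata and 16S/shotgun pairing.

The whole package works from genus x sample integer count tables, one per
sequencing strategy, plus a metadata table linking the 16S and the shotgun
profile of each biological sample.  This module defines the in-memory data
model (:class:`TaxonomicProfile`, :class:`SampleMetadata`,
:class:`ProfileSet`, :class:`SamplePair`) and the TSV readers/writers every
other module consumes.

File formats
------------
``counts.tsv``
    Tab-separated, UTF-8, no quoting.  First column ``genus``, second column
    ``phylum`` (the lineage of each genus), remaining columns sample ids;
    cells are non-negative integer read counts.
``metadata.tsv``
    Tab-separated with columns ``sample_id``, ``strategy`` (``16S`` or
    ``shotgun``), ``compartment`` (``caeca`` or ``crop``), ``day`` (1, 14 or
    35) and ``pair_id`` linking the two strategies' profiles of one
    biological sample.

Genus identity is by exact name string: the input tables are assumed
pre-harmonized between the two strategies' reference databases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

STRATEGIES = ("16S", "shotgun")
COMPARTMENTS = ("caeca", "crop")
DAYS = (1, 14, 35)


class ProfileError(ValueError):
    """Raised when a profile, metadata table or pairing is invalid."""


@dataclass
class TaxonomicProfile:
    """Genus-level read counts for one sample under one sequencing strategy.

    Parameters
    ----------
    sample_id : str
        Sample identifier; must match a metadata row.
    strategy : {"16S", "shotgun"}
    counts : mapping of genus name to non-negative integer read count.
        Genera with zero counts may be present (they belong to the dataset
        genus universe but not to this profile's support).
    lineage : mapping of genus name to phylum name.
        Must cover every genus with a positive count.
    """

    sample_id: str
    strategy: str
    counts: dict[str, int]
    lineage: dict[str, str]

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ProfileError(
                f"unknown strategy {self.strategy!r}; expected one of {STRATEGIES}"
            )
        for genus, c in self.counts.items():
            if int(c) != c or c < 0:
                raise ProfileError(
                    f"count for genus {genus!r} in sample {self.sample_id!r} "
                    f"is not a non-negative integer: {c!r}"
                )
            if c > 0 and genus not in self.lineage:
                raise ProfileError(
                    f"genus {genus!r} detected in sample {self.sample_id!r} "
                    "has no lineage (phylum) entry"
                )

    @property
    def total_reads(self) -> int:
        """Total reads in the sample (sum of genus counts)."""
        return int(sum(self.counts.values()))

    @property
    def support(self) -> set[str]:
        """Genera detected in this profile (count >= 1)."""
        return {g for g, c in self.counts.items() if c > 0}

    def nonzero_counts(self) -> pd.Series:
        """Counts of detected genera as a pandas Series (genus-indexed)."""
        s = pd.Series({g: c for g, c in self.counts.items() if c > 0}, dtype=int)
        s.index.name = "genus"
        return s

    def phylum_counts(self) -> pd.Series:
        """Aggregate detected-genus counts to phylum level."""
        nz = self.nonzero_counts()
        if nz.empty:
            return pd.Series(dtype=int)
        phyla = nz.index.map(self.lineage.get)
        return nz.groupby(phyla).sum()


@dataclass(frozen=True)
class SampleMetadata:
    """Experimental factors and pairing key for one sequenced sample."""

    sample_id: str
    strategy: str
    compartment: str
    day: int
    pair_id: str

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ProfileError(f"sample {self.sample_id!r}: bad strategy {self.strategy!r}")
        if self.compartment not in COMPARTMENTS:
            raise ProfileError(
                f"sample {self.sample_id!r}: unknown compartment {self.compartment!r}"
            )
        if self.day not in DAYS:
            raise ProfileError(f"sample {self.sample_id!r}: unknown day {self.day!r}")


@dataclass
class SamplePair:
    """The 16S and shotgun profile of the same biological sample."""

    pair_id: str
    amplicon: TaxonomicProfile
    shotgun: TaxonomicProfile

    @property
    def common_genera(self) -> set[str]:
        return self.amplicon.support & self.shotgun.support

    @property
    def amplicon_exclusive(self) -> set[str]:
        return self.amplicon.support - self.shotgun.support

    @property
    def shotgun_exclusive(self) -> set[str]:
        return self.shotgun.support - self.amplicon.support


@dataclass
class ProfileSet:
    """A collection of profiles plus validated metadata.

    The per-strategy *genus universe* is the union of genera observed in any
    profile of that strategy; keeping zero-count genera on a shared axis
    gives all samples one coordinate system for beta-diversity vectors.
    """

    profiles: list[TaxonomicProfile] = field(default_factory=list)
    metadata: list[SampleMetadata] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [m.sample_id for m in self.metadata]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ProfileError(f"duplicate sample ids in metadata: {dup}")
        meta_ids = set(ids)
        missing = sorted(p.sample_id for p in self.profiles if p.sample_id not in meta_ids)
        if missing:
            raise ProfileError(f"profiles without metadata: {missing}")
        # each pair_id has at most one profile per strategy
        seen: dict[tuple[str, str], str] = {}
        for m in self.metadata:
            key = (m.pair_id, m.strategy)
            if key in seen:
                raise ProfileError(
                    f"pair {m.pair_id!r} has two {m.strategy} samples: "
                    f"{seen[key]!r} and {m.sample_id!r}"
                )
            seen[key] = m.sample_id

    # -- lookups -----------------------------------------------------------
    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": m.sample_id,
                    "strategy": m.strategy,
                    "compartment": m.compartment,
                    "day": m.day,
                    "pair_id": m.pair_id,
                }
                for m in self.metadata
            ]
        )

    def profile(self, sample_id: str) -> TaxonomicProfile:
        for p in self.profiles:
            if p.sample_id == sample_id:
                return p
        raise KeyError(sample_id)

    def by_strategy(self, strategy: str) -> list[TaxonomicProfile]:
        return [p for p in self.profiles if p.strategy == strategy]

    def genus_universe(self, strategy: str | None = None) -> set[str]:
        """Union of detected genera across profiles (optionally one strategy)."""
        out: set[str] = set()
        for p in self.profiles:
            if strategy is None or p.strategy == strategy:
                out |= p.support
        return out

    def lineage(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for p in self.profiles:
            out.update(p.lineage)
        return out

    def counts_matrix(self, strategy: str) -> pd.DataFrame:
        """Genus x sample integer matrix over the strategy's genus universe."""
        profs = self.by_strategy(strategy)
        genera = sorted(self.genus_universe(strategy))
        data = {
            p.sample_id: [int(p.counts.get(g, 0)) for g in genera] for p in profs
        }
        return pd.DataFrame(data, index=pd.Index(genera, name="genus"), dtype=int)

    def subset(self, sample_ids: Iterable[str]) -> "ProfileSet":
        keep = set(sample_ids)
        return ProfileSet(
            profiles=[p for p in self.profiles if p.sample_id in keep],
            metadata=[m for m in self.metadata if m.sample_id in keep],
        )

    def merge(self, other: "ProfileSet") -> "ProfileSet":
        return ProfileSet(
            profiles=self.profiles + other.profiles,
            metadata=self.metadata + other.metadata,
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_count_table(path, strategy: str) -> list[TaxonomicProfile]:
    """Read a genus x sample TSV count table into profiles.

    The table must have columns ``genus``, ``phylum`` then one column per
    sample.  Zero-count genera stay in each profile's ``counts`` map (they
    are part of the genus universe) but not in its support.

    Raises
    ------
    ProfileError
        On duplicate genus rows or non-integer / negative cells; the error
        names the offending row and column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["genus", "phylum"]:
        raise ProfileError(
            f"{path}: first two columns must be 'genus' and 'phylum', "
            f"got {list(df.columns[:2])}"
        )
    genera = df["genus"].tolist()
    if len(genera) != len(set(genera)):
        dup = sorted({g for g in genera if genera.count(g) > 1})
        raise ProfileError(f"{path}: duplicate genus rows: {dup}")
    lineage = dict(zip(df["genus"], df["phylum"]))
    sample_cols = list(df.columns[2:])
    counts: dict[str, dict[str, int]] = {s: {} for s in sample_cols}
    for _, row in df.iterrows():
        g = row["genus"]
        for s in sample_cols:
            cell = row[s]
            try:
                val = int(cell)
                if val < 0:
                    raise ValueError
            except (TypeError, ValueError):
                raise ProfileError(
                    f"{path}: cell for genus {g!r}, sample {s!r} is not a "
                    f"non-negative integer: {cell!r}"
                ) from None
            counts[s][g] = val
    return [
        TaxonomicProfile(sample_id=s, strategy=strategy, counts=counts[s], lineage=lineage)
        for s in sample_cols
    ]


def write_count_table(profiles: list[TaxonomicProfile], lineage: Mapping[str, str], path) -> None:
    """Write profiles as a genus x sample TSV (round-trips with the reader)."""
    genera = sorted({g for p in profiles for g in p.counts})
    df = pd.DataFrame(
        {
            "genus": genera,
            "phylum": [lineage.get(g, "NA") for g in genera],
            **{
                p.sample_id: [int(p.counts.get(g, 0)) for g in genera]
                for p in profiles
            },
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> list[SampleMetadata]:
    """Read and validate a metadata TSV.

    An empty file yields an empty collection (with a warning logged);
    unknown compartment/day/strategy values raise :class:`ProfileError`.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("metadata file %s is empty", path)
        return []
    if df.empty:
        logger.warning("metadata file %s has no rows", path)
        return []
    required = {"sample_id", "strategy", "compartment", "day", "pair_id"}
    missing = required - set(df.columns)
    if missing:
        raise ProfileError(f"{path}: missing metadata columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        try:
            day = int(row["day"])
        except (TypeError, ValueError):
            raise ProfileError(
                f"{path}: sample {row['sample_id']!r}: day {row['day']!r} is not an integer"
            ) from None
        out.append(
            SampleMetadata(
                sample_id=row["sample_id"],
                strategy=row["strategy"],
                compartment=row["compartment"],
                day=day,
                pair_id=row["pair_id"],
            )
        )
    return out


def write_metadata(metadata: list[SampleMetadata], path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "strategy": m.strategy,
                "compartment": m.compartment,
                "day": m.day,
                "pair_id": m.pair_id,
            }
            for m in metadata
        ]
    ).to_csv(path, sep="\t", index=False)


def load_profile_set(counts_16s, counts_shotgun, metadata_path) -> ProfileSet:
    """Load the two strategies' count tables plus metadata into one set."""
    profiles = read_count_table(counts_16s, "16S") + read_count_table(
        counts_shotgun, "shotgun"
    )
    return ProfileSet(profiles=profiles, metadata=read_metadata(metadata_path))


def pair_profiles(pset: ProfileSet) -> tuple[list[SamplePair], list[str]]:
    """Link each pair_id's 16S and shotgun profiles.

    Returns
    -------
    pairs : list of SamplePair
        One per pair_id having a profile under both strategies.
    unpaired : list of str
        Sample ids whose mate is missing; reported, never silently dropped.
    """
    meta = {m.sample_id: m for m in pset.metadata}
    by_pair: dict[str, dict[str, TaxonomicProfile]] = {}
    for p in pset.profiles:
        m = meta[p.sample_id]
        by_pair.setdefault(m.pair_id, {})[p.strategy] = p
    pairs, unpaired = [], []
    for pid in sorted(by_pair):
        d = by_pair[pid]
        if "16S" in d and "shotgun" in d:
            pairs.append(SamplePair(pair_id=pid, amplicon=d["16S"], shotgun=d["shotgun"]))
        else:
            unpaired.extend(p.sample_id for p in d.values())
    if unpaired:
        logger.warning("unpaired samples: %s", ", ".join(sorted(unpaired)))
    return pairs, sorted(unpaired)
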