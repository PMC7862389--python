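"""Bray-Curtis beta diversity, PCoA and silhouette-scored stratification.

Samples are compared as vectors of normalized genus abundances on the
dataset-wide genus axis (zeros for undetected genera, so all samples share
one coordinate system).  Bray-Curtis dissimilarity feeds a classical PCoA
(Gower double-centering + eigendecomposition) for visualization, and the
mean silhouette score quantifies how well a labelling of the samples
(gut compartment, sampling day) matches their displacement.

Stratification is evaluated on four genus subsets: all genera detected by
shotgun ("SHOTGUN") or by 16S ("16S"), and the genera detected exclusively
by one strategy across the dataset ("SHOTGUNex", "16Sex").  Silhouettes are
computed on the Bray-Curtis distances restricted to each subset (equivalent
to silhouette in the full PCoA space when all positive axes are kept).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_samples

from .profiles import ProfileSet
from .diffabund import size_factors, normalize_counts

logger = logging.getLogger(__name__)

SUBSETS = ("SHOTGUN", "16S", "SHOTGUNex", "16Sex")


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities of a sample x genus matrix.

    ``BC(i, j) = sum_g |x_ig - x_jg| / sum_g (x_ig + x_jg)``, in [0, 1].
    All-zero sample rows are rejected (the distance is undefined for them).
    """
    x = matrix.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    zero = x.sum(axis=1) == 0
    if zero.any():
        bad = list(matrix.index[zero])
        raise ValueError(f"all-zero abundance rows for samples: {bad}")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


@dataclass
class PcoaResult:
    """Classical PCoA embedding of a distance matrix.

    Axes with negative eigenvalues (possible for non-Euclidean metrics
    such as Bray-Curtis) are dropped; their total magnitude is reported as
    ``negative_inertia``.
    """

    coordinates: pd.DataFrame       # sample x axis
    eigenvalues: np.ndarray         # retained (positive), non-increasing
    proportion_explained: np.ndarray
    negative_inertia: float


def pcoa(dist: pd.DataFrame, eps: float = 1e-9) -> PcoaResult:
    """Gower double-centering + symmetric eigendecomposition.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue); when the input
    distances are Euclidean-embeddable the embedding reproduces them
    exactly (up to rotation/reflection).
    """
    d = dist.to_numpy(dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    b = a - row - col + a.mean()
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    scale = max(abs(vals[0]), 1.0)
    pos = vals > eps * scale
    neg_inertia = float(-vals[vals < 0].sum())
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    total = vals[pos].sum()
    return PcoaResult(
        coordinates=pd.DataFrame(
            coords,
            index=dist.index,
            columns=[f"PCo{i + 1}" for i in range(int(pos.sum()))],
        ),
        eigenvalues=vals[pos],
        proportion_explained=vals[pos] / total if total > 0 else vals[pos],
        negative_inertia=neg_inertia,
    )


def mean_silhouette(dist: pd.DataFrame, labels) -> float:
    """Mean silhouette score of a labelling under precomputed distances.

    Per sample ``s = (b - a)/max(a, b)`` with ``a`` the mean intra-group
    distance and ``b`` the smallest mean distance to another group;
    singleton-group samples score 0.  Requires at least two groups.
    """
    lab = pd.Series(labels).reindex(dist.index)
    if lab.isna().any():
        raise ValueError("labels missing for some samples")
    if lab.nunique() < 2:
        raise ValueError("silhouette needs at least 2 groups")
    vals = silhouette_samples(dist.to_numpy(), lab.to_numpy(), metric="precomputed")
    return float(vals.mean())


# ---------------------------------------------------------------------------
# stratification over genus subsets
# ---------------------------------------------------------------------------

@dataclass
class StratificationReport:
    """Mean silhouettes per (genus subset, labelling)."""

    scores: pd.DataFrame  # columns: subset, labelling, mean_silhouette, n_samples, n_genera

    def summary(self) -> str:
        return (
            "Sample stratification (mean silhouette scores)\n"
            "==============================================\n"
            + self.scores.to_string(index=False, float_format=lambda v: f"{v:.3f}")
        )


def strategy_exclusive_genera(pset: ProfileSet) -> dict[str, set[str]]:
    """Dataset-level genus subsets per strategy.

    A genus is strategy-exclusive iff detected in at least one sample of
    that strategy and in no sample of the other.
    """
    sg = pset.genus_universe("shotgun")
    a16 = pset.genus_universe("16S")
    return {
        "SHOTGUN": sg,
        "16S": a16,
        "SHOTGUNex": sg - a16,
        "16Sex": a16 - sg,
    }


def stratification_analysis(
    pset: ProfileSet,
    subsets: tuple[str, ...] = SUBSETS,
) -> StratificationReport:
    """Silhouette-score the four genus subsets against the study factors.

    For each subset the normalized abundance matrix of the corresponding
    strategy's samples is restricted to the subset genera, Bray-Curtis
    distances recomputed, and the mean silhouette reported for compartment
    labels (all samples) and for day labels within each compartment.
    Samples with no reads over a subset are dropped with a warning; empty
    subsets are reported as NaN.
    """
    meta = pset.metadata_frame().set_index("sample_id")
    genus_sets = strategy_exclusive_genera(pset)
    rows = []
    for subset in subsets:
        strategy = "shotgun" if subset.startswith("SHOTGUN") else "16S"
        genera = sorted(genus_sets[subset])
        labellings = _labellings(meta, strategy)
        if not genera:
            logger.warning("subset %s is empty", subset)
            for name, _ in labellings:
                rows.append(dict(subset=subset, labelling=name,
                                 mean_silhouette=np.nan, n_samples=0, n_genera=0))
            continue
        counts = pset.counts_matrix(strategy)
        norm = normalize_counts(counts, size_factors(counts))
        sub = norm.loc[norm.index.intersection(genera)].T  # sample x genus
        nonzero = sub.sum(axis=1) > 0
        if (~nonzero).any():
            logger.warning(
                "subset %s: dropping %d sample(s) with no reads in subset",
                subset, int((~nonzero).sum()),
            )
        sub = sub[nonzero]
        dist = bray_curtis(sub)
        for name, labels in labellings:
            lab = labels.reindex(sub.index).dropna()
            ids = lab.index
            if len(ids) < 3 or lab.nunique() < 2:
                rows.append(dict(subset=subset, labelling=name,
                                 mean_silhouette=np.nan,
                                 n_samples=len(ids), n_genera=len(genera)))
                continue
            ss = mean_silhouette(dist.loc[ids, ids], lab)
            rows.append(dict(subset=subset, labelling=name, mean_silhouette=ss,
                             n_samples=len(ids), n_genera=len(genera)))
    return StratificationReport(scores=pd.DataFrame(rows))


def _labellings(meta: pd.DataFrame, strategy: str) -> list[tuple[str, pd.Series]]:
    m = meta[meta["strategy"] == strategy]
    out = [("compartment", m["compartment"])]
    for comp in sorted(m["compartment"].unique()):
        sub = m[m["compartment"] == comp]
        out.append((f"day:{comp}", sub["day"].astype(str)))
    return out
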