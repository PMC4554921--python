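"""Profile analysis over replicate-averaged fraction profiles.

Covers the comparative layer of the pipeline: hierarchical clustering of
protein abundance profiles (uncentred correlation distance with average
linkage, the classic Cluster 3.0 defaults, so heat maps open in standard
tree viewers), fraction-enrichment classification, abundance ranking and
rollups onto the closed 22-name functional-category vocabulary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .errors import FormatError, ParameterError

log = logging.getLogger(__name__)

__all__ = [
    "FUNCTIONAL_CATEGORIES",
    "ClusterResult",
    "EnrichmentCall",
    "log_transform",
    "uncentered_correlation_distance",
    "cluster",
    "classify_enrichment",
    "rank_by_abundance",
    "category_rollup",
]

#: the closed 22-name functional-category vocabulary used for rollups
FUNCTIONAL_CATEGORIES = (
    "biosynthetic cargo",
    "blood + other cells",
    "calcium transport/binding",
    "coat",
    "cytoskeleton",
    "detoxification",
    "GTPase",
    "likely contaminants",
    "lysosome",
    "metabolism",
    "mitochondria",
    "nucleus",
    "peroxisome",
    "plasma membrane",
    "proteasome/ubiquitin",
    "protein modification",
    "protein synthesis/folding",
    "signalling",
    "tethering/docking/fusion",
    "traffic",
    "trypsin",
    "unknown",
)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Row clustering of a profile matrix."""

    leaf_order: list[str]  # accessions in dendrogram order
    linkage_matrix: np.ndarray  # scipy (n-1) x 4 merge table
    row_names: list[str]  # accessions in input (matrix) order
    distance_name: str
    linkage_name: str


def log_transform(profile: pd.DataFrame) -> pd.DataFrame:
    """log10(x + p) with pseudocount p = half the smallest non-zero value.

    Percent profiles span orders of magnitude; the pseudocount keeps zero
    entries finite without dominating the smallest real values. An all-zero
    matrix is returned unchanged.
    """
    vals = profile.values
    nonzero = vals[vals > 0]
    if nonzero.size == 0:
        return profile.copy()
    p = nonzero.min() / 2.0
    return np.log10(profile + p)


def uncentered_correlation_distance(matrix: np.ndarray) -> np.ndarray:
    """Pairwise uncentred-correlation distances between rows.

    d(x, y) = 1 - (x . y) / (|x| |y|), the cosine-style similarity used by
    Cluster 3.0 (no mean centring). Rows with zero norm are at distance 1
    from everything (and 0 from themselves); a warning is logged.
    """
    X = np.asarray(matrix, dtype=float)
    if not np.isfinite(X).all():
        raise ParameterError("profile matrix must be finite")
    norms = np.sqrt((X**2).sum(axis=1))
    zero = norms == 0
    if zero.any():
        log.warning("%d zero-norm rows set to distance 1", int(zero.sum()))
    safe = np.where(zero, 1.0, norms)
    U = X / safe[:, None]
    D = 1.0 - U @ U.T
    D[zero, :] = 1.0
    D[:, zero] = 1.0
    np.fill_diagonal(D, 0.0)
    # numerical negatives from the dot product
    np.clip(D, 0.0, None, out=D)
    return (D + D.T) / 2.0


def cluster(
    profile: pd.DataFrame,
    distance: str = "uncentered",
    linkage_method: str = "average",
    log_scale: bool = True,
) -> ClusterResult:
    """Agglomerative clustering of protein rows.

    Defaults are uncentred correlation distance and average linkage; with
    ``log_scale`` the profile is log10-transformed first (heat-map
    convention). Deterministic: ties are resolved by scipy's fixed merge
    order over the given row order.
    """
    if len(profile) < 2:
        raise ParameterError("need at least 2 rows to cluster")
    data = log_transform(profile) if log_scale else profile
    if distance == "uncentered":
        D = uncentered_correlation_distance(data.values)
        condensed = squareform(D, checks=False)
    elif distance == "euclidean":
        from scipy.spatial.distance import pdist

        condensed = pdist(data.values)
    else:
        raise ParameterError(f"unknown distance {distance!r}")
    Z = linkage(condensed, method=linkage_method)
    order = [profile.index[i] for i in leaves_list(Z)]
    return ClusterResult(
        leaf_order=order,
        linkage_matrix=Z,
        row_names=list(profile.index),
        distance_name=distance,
        linkage_name=linkage_method,
    )


# ---------------------------------------------------------------------------
# enrichment classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentCall:
    """Enrichment of one group in the target fraction vs references."""

    label: str  # enriched_in_target | unique_to_target | shared_with_reference | depleted_in_target
    fold: float  # target mean % / max reference mean % (inf if unique)


def classify_enrichment(
    profile_mean: pd.DataFrame,
    target: str,
    references: Sequence[str],
    fold_threshold: float = 2.0,
) -> tuple[dict[str, EnrichmentCall], list[str]]:
    """Label each group by its target-fraction enrichment.

    ``unique_to_target`` when every reference mean is 0 and the target mean
    is positive; otherwise the fold ratio of target mean to the *maximum*
    reference mean decides: ``enriched_in_target`` at fold >= threshold,
    ``depleted_in_target`` at fold <= 1/threshold, ``shared_with_reference``
    in between. All-zero groups are excluded and returned separately.
    """
    if fold_threshold <= 1:
        raise ParameterError("fold_threshold must exceed 1")
    refs = list(references)
    if target in refs:
        raise ParameterError("target fraction cannot be a reference")
    for f in [target, *refs]:
        if f not in profile_mean.columns:
            raise ParameterError(f"fraction {f!r} not in profile")

    calls: dict[str, EnrichmentCall] = {}
    excluded: list[str] = []
    for acc in profile_mean.index:
        t = float(profile_mean.loc[acc, target])
        r = float(profile_mean.loc[acc, refs].max())
        if t == 0 and r == 0:
            excluded.append(acc)
            continue
        if r == 0:
            calls[acc] = EnrichmentCall("unique_to_target", math.inf)
            continue
        fold = t / r
        if fold >= fold_threshold:
            label = "enriched_in_target"
        elif fold <= 1.0 / fold_threshold:
            label = "depleted_in_target"
        else:
            label = "shared_with_reference"
        calls[acc] = EnrichmentCall(label, fold)
    return calls, excluded


def rank_by_abundance(profile_mean: pd.DataFrame, fraction: str) -> list[str]:
    """Accessions ordered by descending mean % in one fraction (ties by
    accession)."""
    if fraction not in profile_mean.columns:
        raise ParameterError(f"fraction {fraction!r} not in profile")
    return sorted(profile_mean.index, key=lambda a: (-profile_mean.loc[a, fraction], a))


def category_rollup(
    profile_mean: pd.DataFrame,
    annotation: Mapping[str, str],
) -> pd.DataFrame:
    """Sum mean % per functional category and fraction.

    Annotation categories must come from the closed 22-name vocabulary;
    unannotated groups are pooled under ``unknown``. Per fraction the rollup
    conserves the total percentage mass of the input profile.
    """
    bad = sorted(set(annotation.values()) - set(FUNCTIONAL_CATEGORIES))
    if bad:
        raise FormatError(f"unknown functional category {bad[0]!r}")
    cats = pd.Series(
        [annotation.get(acc, "unknown") for acc in profile_mean.index],
        index=profile_mean.index,
    )
    out = profile_mean.groupby(cats).sum()
    out = out.reindex(sorted(out.index))
    out.index.name = "category"
    return out
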