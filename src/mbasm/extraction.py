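"""Representative-ensemble extraction from the retained configuration pool.

The retained pool (typically thousands of configurations) is clustered by
k-means on the 9-component geometric descriptors, and the medoid of each
cluster - the actual configuration closest to its centroid - forms the
small ensemble handed to quantum-chemical refinement.  A seeded t-SNE
embedding of the descriptors is available for visual inspection only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

from .complexes import ComplexConfiguration
from .filtering import descriptor

__all__ = ["RepresentativeEnsemble", "extract_representatives", "embed_2d"]


@dataclass(eq=False)
class RepresentativeEnsemble:
    """Medoid ensemble over the retained pool.

    ``members[i]`` is the configuration whose descriptor is closest to the
    centroid of cluster ``i``; ``cluster_labels`` assigns every retained
    configuration to a cluster.
    """

    members: list[ComplexConfiguration]
    cluster_labels: np.ndarray
    k: int
    seed: int
    inertia: float


def _descriptor_matrix(configs: Sequence[ComplexConfiguration]) -> np.ndarray:
    return np.vstack(
        [c.descriptor if c.descriptor is not None else descriptor(c) for c in configs]
    )


def extract_representatives(
    retained: Sequence[ComplexConfiguration], k: int, seed: int = 0
) -> RepresentativeEnsemble:
    """k-means medoid selection over geometric descriptors.

    Deterministic under a fixed seed; if ``k >= len(retained)`` every
    retained configuration is its own representative.  Medoid ties are
    broken by lowest configuration index.
    """
    retained = list(retained)
    if not retained:
        raise ValueError("retained configuration list is empty")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    n = len(retained)
    if k >= n:
        return RepresentativeEnsemble(
            members=list(retained),
            cluster_labels=np.arange(n),
            k=n,
            seed=seed,
            inertia=0.0,
        )
    X = _descriptor_matrix(retained)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10, max_iter=300, tol=1e-6)
    labels = km.fit_predict(X)
    members: list[ComplexConfiguration] = []
    for cid in range(k):
        idx = np.flatnonzero(labels == cid)
        dists = np.linalg.norm(X[idx] - km.cluster_centers_[cid], axis=1)
        members.append(retained[int(idx[int(np.argmin(dists))])])
    return RepresentativeEnsemble(
        members=members,
        cluster_labels=labels,
        k=k,
        seed=seed,
        inertia=float(km.inertia_),
    )


def embed_2d(
    retained: Sequence[ComplexConfiguration],
    seed: int = 0,
    perplexity: float | None = None,
) -> np.ndarray:
    """Seeded t-SNE embedding of the descriptors, for plotting/export only.

    Returns an (n, 2) array, one row per configuration.  Carries no
    downstream semantics; default perplexity is min(30, (n - 1) / 3).
    """
    retained = list(retained)
    n = len(retained)
    if n < 5:
        raise ValueError(f"need at least 5 configurations for an embedding, got {n}")
    X = _descriptor_matrix(retained)
    if perplexity is None:
        perplexity = min(30.0, (n - 1) / 3.0)
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    return tsne.fit_transform(X)
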