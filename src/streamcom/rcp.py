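"""Region-of-common-profile (RCP) analysis.

Sites are grouped by their community content: a binary Jaccard
dissimilarity matrix is computed from the raw presence-absence data, a
cascade of K-means partitions is fitted for K = 1..10 (each the best of
many random restarts), the Calinski-Harabasz criterion selects the
number of clusters, and the resulting site groups (RCPs) are
cross-tabulated against land use.

The dissimilarity uses the square-root binary-Jaccard convention
``d = sqrt(1 - a / (a + b + c))`` (making ``d`` Euclidean-embeddable);
K-means then operates on the rows of the dissimilarity matrix as feature
vectors, emulating the common practice of chaining a dissimilarity
computation into a K-means routine that expects a data matrix. A
principal-coordinate embedding and the plain ``1 - S`` dissimilarity are
available behind flags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score

from .io import CommunityMatrix

__all__ = [
    "RCPResult",
    "jaccard_binary",
    "calinski",
    "cascade_kmeans",
    "rcp_landuse_association",
]


def jaccard_binary(cm: CommunityMatrix | np.ndarray,
                   sqrt: bool = True) -> np.ndarray:
    """Site-by-site binary Jaccard dissimilarity.

    For two sites sharing ``a`` taxa, with ``b`` and ``c`` taxa unique to
    each, the similarity is ``S = a / (a + b + c)`` and the dissimilarity
    ``sqrt(1 - S)`` (or ``1 - S`` when ``sqrt=False``).
    """
    Y = cm.occurrence if isinstance(cm, CommunityMatrix) else np.asarray(cm)
    Y = Y.astype(float)
    richness = Y.sum(axis=1)
    if (richness == 0).any():
        if isinstance(cm, CommunityMatrix):
            empty = [s for s, r in zip(cm.sites, richness) if r == 0]
        else:
            empty = list(np.flatnonzero(richness == 0))
        raise ValueError(f"site(s) with no presences: {empty}")
    a = Y @ Y.T
    union = richness[:, None] + richness[None, :] - a
    S = a / union
    d = 1.0 - S
    if sqrt:
        d = np.sqrt(np.clip(d, 0.0, None))
    np.fill_diagonal(d, 0.0)
    return d


def calinski(features: np.ndarray, labels) -> float:
    """Calinski-Harabasz criterion ``[SSB/(K-1)] / [SSW/(n-K)]``.

    Undefined (returns NaN) for K = 1 or K = n, where the ratio involves a
    division by zero.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    n = features.shape[0]
    k = len(np.unique(labels))
    if k < 2 or k >= n:
        return float("nan")
    return float(calinski_harabasz_score(features, labels))


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Renumber cluster labels to 1..K in order of first appearance."""
    mapping = {}
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


@dataclass
class RCPResult:
    """Cascading K-means output: per-K partitions and criterion values,
    the selected K, and the final site → RCP assignment."""

    partitions: dict          # K -> ndarray of labels in 1..K
    criterion: dict           # K -> Calinski value (NaN where undefined)
    selected_k: int
    assignment: pd.Series     # site_id -> RCP label
    sites: list

    def criterion_table(self) -> pd.DataFrame:
        return pd.DataFrame({"K": list(self.criterion),
                             "calinski": list(self.criterion.values())})


def cascade_kmeans(D: np.ndarray, sites=None, k_range=range(1, 11),
                   n_restarts: int = 1000, seed: int = 0,
                   use_pcoa: bool = False) -> RCPResult:
    """Best-of-``n_restarts`` K-means for each K, Calinski selection.

    ``D`` is a square symmetric dissimilarity matrix; each site is
    represented by its row of ``D`` (or, with ``use_pcoa=True``, by its
    principal-coordinate embedding). K-means restarts use uniformly random
    site initialization and keep the partition with the lowest
    within-cluster sum of squares. The selected K maximizes the Calinski
    criterion over K >= 2.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("D must be a square symmetric dissimilarity matrix")
    ks = sorted(set(int(k) for k in k_range))
    if ks[0] < 1:
        raise ValueError("k_range must start at 1 or above")
    if ks[-1] >= n:
        raise ValueError("largest K must be smaller than the number of sites")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    if sites is None:
        sites = [f"site{i + 1}" for i in range(n)]

    if use_pcoa:
        # classical MDS / PCoA of the (Euclidean-embeddable) dissimilarity
        J = np.eye(n) - np.ones((n, n)) / n
        G = -0.5 * J @ (D ** 2) @ J
        w, v = np.linalg.eigh(G)
        keep = w > 1e-10
        features = v[:, keep] * np.sqrt(w[keep])
    else:
        features = D

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(ks))
    partitions, criterion = {}, {}
    for k, kseed in zip(ks, child_seeds):
        if k == 1:
            labels = np.ones(n, dtype=int)
        else:
            km = KMeans(n_clusters=k, init="random", n_init=n_restarts,
                        max_iter=300, algorithm="lloyd",
                        random_state=int(kseed % (2 ** 31)))
            labels = _relabel(km.fit_predict(features))
        partitions[k] = labels
        criterion[k] = calinski(features, labels)

    eligible = {k: v for k, v in criterion.items() if np.isfinite(v)}
    if not eligible:
        selected = ks[0]
    else:
        selected = max(eligible, key=eligible.get)
    assignment = pd.Series(partitions[selected],
                           index=pd.Index(sites, name="site_id"), name="rcp")
    return RCPResult(partitions=partitions, criterion=criterion,
                     selected_k=selected, assignment=assignment,
                     sites=list(sites))


def rcp_landuse_association(result: RCPResult, sites: pd.DataFrame):
    """Contingency of RCP membership against land-use class.

    RCPs are renumbered so that RCP 1 has the highest agricultural
    proportion (a stable reporting convention). Returns
    ``(counts, proportions)`` as DataFrames indexed by RCP.
    """
    lu = sites.set_index("site_id")["land_use"]
    missing = [s for s in result.sites if s not in lu.index]
    if missing:
        raise ValueError(f"sites missing from site table: {missing}")
    df = pd.DataFrame({"rcp": result.assignment.to_numpy(),
                       "land_use": lu.loc[result.sites].to_numpy()})
    counts = df.groupby(["rcp", "land_use"], observed=True).size().unstack(fill_value=0)
    for col in ("agricultural", "forested"):
        if col not in counts.columns:
            counts[col] = 0
    counts = counts[["agricultural", "forested"]]
    props = counts.div(counts.sum(axis=1), axis=0)
    order = props["agricultural"].sort_values(ascending=False).index
    remap = {old: new + 1 for new, old in enumerate(order)}
    counts.index = [remap[i] for i in counts.index]
    props.index = [remap[i] for i in props.index]
    counts = counts.sort_index()
    props = props.sort_index()
    counts.index.name = props.index.name = "rcp"
    return counts, props
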