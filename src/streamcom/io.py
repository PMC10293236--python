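"""Reading, validating, and writing the tabular and tree inputs.

The pipeline consumes four kinds of files, all plain text:

* a **site table** (TSV/CSV) with one row per stream site: land-use class,
  coordinates, and five water-chemistry/physics covariates (conductivity,
  pH, temperature, total phosphorus, N:P ratio);
* a **community matrix** (TSV/CSV) of sites x taxa occurrences;
* a **trait table** (TSV/CSV) with the trophic mode (autotroph vs
  heterotroph) and domain (bacteria vs eukaryote) of each taxon;
* one **Newick phylogeny** per domain, from which a taxon-by-taxon
  correlation matrix is derived under a Brownian-motion model of trait
  evolution.

Conductivity, total phosphorus, and the N:P ratio are strongly
right-skewed in stream data and are natural-log transformed on load; pH
and temperature are kept on their measurement scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "CommunityMatrix",
    "read_site_table",
    "read_community",
    "read_trait_table",
    "filter_taxa",
    "read_newick_correlation",
    "correlation_from_tree",
    "write_site_table",
    "write_community",
    "REQUIRED_SITE_COLUMNS",
    "LOG_COLUMNS",
    "LAND_USE_LEVELS",
    "TROPHY_LEVELS",
    "DOMAIN_LEVELS",
]


class SchemaError(ValueError):
    """An input table does not conform to the expected layout."""


REQUIRED_SITE_COLUMNS = [
    "site_id",
    "land_use",
    "latitude",
    "longitude",
    "conductivity",
    "ph",
    "temperature",
    "total_phosphorus",
    "np_ratio",
]

#: columns that are natural-log transformed on load
LOG_COLUMNS = ["conductivity", "total_phosphorus", "np_ratio"]

LAND_USE_LEVELS = ("agricultural", "forested")
TROPHY_LEVELS = ("autotroph", "heterotroph")
DOMAIN_LEVELS = ("bacteria", "eukaryote")


def _detect_sep(path) -> str:
    """Auto-detect the delimiter of a text table (tab vs comma, ties -> tab)."""
    with open(path) as fh:
        header = fh.readline()
    return "," if header.count(",") > header.count("\t") else "\t"


def read_site_table(path, transform: bool = True) -> pd.DataFrame:
    """Read and validate a per-site environment table.

    Parameters
    ----------
    path
        Delimited text file with the columns listed in
        :data:`REQUIRED_SITE_COLUMNS`.
    transform
        When True (default), add ``log_<col>`` columns holding the natural
        log of conductivity, total phosphorus, and the N:P ratio.

    Returns
    -------
    pandas.DataFrame
        One row per site, validated: unique ``site_id``, land use limited
        to the two study classes, no missing values, strictly positive
        values in every column destined for a log transform.
    """
    df = pd.read_csv(path, sep=_detect_sep(path))
    df.columns = [str(c).strip() for c in df.columns]
    missing = [c for c in REQUIRED_SITE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"site table is missing required column(s): {missing}")
    df["site_id"] = df["site_id"].astype(str).str.strip()
    df["land_use"] = df["land_use"].astype(str).str.strip()
    if df["site_id"].duplicated().any():
        dups = df.loc[df["site_id"].duplicated(), "site_id"].tolist()
        raise SchemaError(f"duplicate site_id(s): {dups}")
    bad_lu = sorted(set(df["land_use"]) - set(LAND_USE_LEVELS))
    if bad_lu:
        raise SchemaError(
            f"unknown land_use level(s) {bad_lu}; expected {LAND_USE_LEVELS}"
        )
    if df[REQUIRED_SITE_COLUMNS].isna().any().any():
        raise SchemaError("site table contains missing values")
    for col in LOG_COLUMNS:
        bad = df.loc[df[col] <= 0, "site_id"].tolist()
        if bad:
            raise ValueError(
                f"non-positive {col} at site(s) {bad}: cannot log-transform"
            )
    if transform:
        for col in LOG_COLUMNS:
            df[f"log_{col}"] = np.log(df[col].to_numpy(dtype=float))
    return df.reset_index(drop=True)


@dataclass
class CommunityMatrix:
    """Binary sites x taxa occurrence matrix with optional taxon metadata.

    Attributes
    ----------
    sites : list of str
        Row labels, matching the ``site_id`` column of the site table.
    taxa : list of str
        Column labels.
    occurrence : ndarray of shape (n_sites, n_taxa)
        0/1 presence-absence entries.
    taxon_meta : pandas.DataFrame
        Indexed by taxon id; may carry ``domain`` and a taxonomic ``label``.
    """

    sites: list
    taxa: list
    occurrence: np.ndarray
    taxon_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        self.occurrence = np.asarray(self.occurrence)
        if self.occurrence.shape != (len(self.sites), len(self.taxa)):
            raise SchemaError(
                f"occurrence shape {self.occurrence.shape} does not match "
                f"{len(self.sites)} sites x {len(self.taxa)} taxa"
            )
        vals = np.unique(self.occurrence)
        if not np.isin(vals, [0, 1]).all():
            raise SchemaError("occurrence matrix must be binary (0/1)")
        self.occurrence = self.occurrence.astype(np.int8)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def prevalence(self) -> np.ndarray:
        """Per-taxon number of occupied sites (column sums)."""
        return self.occurrence.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.occurrence, index=pd.Index(self.sites, name="site_id"),
                            columns=self.taxa)


def read_community(path) -> CommunityMatrix:
    """Read a sites x taxa table; positive counts are coerced to presence."""
    sep = _detect_sep(path)
    with open(path) as fh:  # pandas mangles duplicate headers, so check raw
        header = [c.strip() for c in fh.readline().rstrip("\n").split(sep)]
    taxa = header[1:]
    if len(set(taxa)) != len(taxa):
        raise SchemaError("duplicate taxon ids in community table")
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.columns = taxa
    sites = [str(s).strip() for s in df.index]
    if len(set(sites)) != len(sites):
        raise SchemaError("duplicate site ids in community table")
    occ = (df.to_numpy(dtype=float) > 0).astype(np.int8)
    return CommunityMatrix(sites=sites, taxa=taxa, occurrence=occ)


def read_trait_table(path, taxa=None) -> pd.DataFrame:
    """Read the per-taxon trait table (trophy, domain), indexed by taxon id.

    When ``taxa`` is given, checks that every requested taxon has exactly
    one row and reorders to match.
    """
    df = pd.read_csv(path, sep=_detect_sep(path))
    df.columns = [str(c).strip() for c in df.columns]
    for col in ("taxon_id", "trophy", "domain"):
        if col not in df.columns:
            raise SchemaError(f"trait table is missing column {col!r}")
    df["taxon_id"] = df["taxon_id"].astype(str).str.strip()
    df = df.set_index("taxon_id")
    for col, levels in (("trophy", TROPHY_LEVELS), ("domain", DOMAIN_LEVELS)):
        df[col] = df[col].astype(str).str.strip()
        bad = sorted(set(df[col]) - set(levels))
        if bad:
            raise SchemaError(f"unknown {col} level(s) {bad}; expected {levels}")
    if taxa is not None:
        missing = [t for t in taxa if t not in df.index]
        if missing:
            raise SchemaError(f"trait table is missing taxa: {missing}")
        df = df.loc[list(taxa)]
    return df


def filter_taxa(cm: CommunityMatrix, min_prevalence: int = 10,
                drop_labels=(), max_prevalence=None) -> CommunityMatrix:
    """Apply the occupancy and label filters used before model fitting.

    Keeps taxa that occur at **strictly more** than ``min_prevalence``
    sites and whose taxonomic label is not in ``drop_labels`` (e.g.
    chloroplast sequences or unclassified taxa). ``max_prevalence``, when
    given, additionally drops taxa occupying strictly more than that many
    sites, which removes ubiquitous taxa whose probit intercept is not
    identifiable from presence-absence data.

    Taxon order among survivors is preserved, so the filter is idempotent.
    """
    if min_prevalence < 0:
        raise ValueError("min_prevalence must be >= 0")
    prev = cm.prevalence()
    keep = prev > min_prevalence
    if max_prevalence is not None:
        keep &= prev <= max_prevalence
    if drop_labels and "label" in cm.taxon_meta.columns:
        labels = cm.taxon_meta.reindex(cm.taxa)["label"]
        keep &= ~labels.isin(set(drop_labels)).to_numpy()
    if not keep.any():
        raise ValueError("taxon filtering removed every taxon")
    taxa = [t for t, k in zip(cm.taxa, keep) if k]
    meta = cm.taxon_meta.reindex(taxa) if len(cm.taxon_meta) else cm.taxon_meta
    return CommunityMatrix(sites=list(cm.sites), taxa=taxa,
                           occurrence=cm.occurrence[:, keep], taxon_meta=meta)


def correlation_from_tree(tree: dendropy.Tree, taxa,
                          ultrametric_rtol: float = 0.01) -> np.ndarray:
    """Taxon correlation matrix implied by a phylogeny under Brownian motion.

    For tips a, b the covariance of a Brownian trait is the root-to-MRCA
    path length; dividing by the root-to-tip path lengths turns this into
    a correlation, ``C[a, b] = depth(mrca) / sqrt(depth(a) * depth(b))``,
    with unit diagonal. For an ultrametric tree this is simply the shared
    depth over the tree height. Root-to-tip paths are effectively rescaled
    to 1, so non-ultrametric trees are accepted; a warning is emitted when
    tip depths disagree by more than ``ultrametric_rtol``.
    """
    taxa = list(taxa)
    label_to_leaf = {}
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is not None:
            label_to_leaf[leaf.taxon.label.strip()] = leaf
    missing = [t for t in taxa if t not in label_to_leaf]
    if missing:
        raise SchemaError(f"tree is missing tip(s): {missing}")

    tree.calc_node_root_distances(return_leaf_distances_only=False)
    depth = np.array([label_to_leaf[t].root_distance for t in taxa], dtype=float)
    if depth.min() <= 0:
        raise ValueError("tree has a tip at zero distance from the root")
    spread = (depth.max() - depth.min()) / depth.max()
    if spread > ultrametric_rtol:
        import warnings

        warnings.warn(
            f"tree is not ultrametric (tip depth spread {spread:.1%}); "
            "root-to-tip paths are rescaled to 1",
            stacklevel=2,
        )

    pdm = tree.phylogenetic_distance_matrix()
    n = len(taxa)
    C = np.eye(n)
    for i in range(n):
        ti = label_to_leaf[taxa[i]].taxon
        for j in range(i + 1, n):
            tj = label_to_leaf[taxa[j]].taxon
            patristic = pdm.patristic_distance(ti, tj)
            shared = 0.5 * (depth[i] + depth[j] - patristic)
            c = shared / np.sqrt(depth[i] * depth[j])
            C[i, j] = C[j, i] = max(c, 0.0)
    return C


def read_newick_correlation(path, taxa) -> np.ndarray:
    """Read a Newick tree and return the phylogenetic correlation matrix
    for ``taxa`` (see :func:`correlation_from_tree`)."""
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    return correlation_from_tree(tree, taxa)


def write_site_table(df: pd.DataFrame, path) -> None:
    """Write a site table as TSV (raw columns only; log columns are derived)."""
    cols = [c for c in df.columns if not c.startswith("log_")]
    df[cols].to_csv(path, sep="\t", index=False)


def write_community(cm: CommunityMatrix, path) -> None:
    cm.to_frame().to_csv(path, sep="\t")
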