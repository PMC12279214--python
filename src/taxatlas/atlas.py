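"""Reference-free taxonomic atlas construction over barcode groups.

The core discovery step of the pipeline: barcode groups, represented only by
their rank-level taxonomic abundance vectors (no genome alignment), are
filtered for classification rate and purity, combined into an abundance
matrix, clustered with the Leiden algorithm on a k-nearest-neighbour graph,
embedded in 2-D with UMAP for visualisation, and annotated per cluster by the
most abundant taxon. Metagenomic contigs carrying the same vectors can be
projected into an existing atlas without disturbing the single-cell labels.

Abundance fractions are used directly — no log or CLR transform — and
clustering operates on the k-NN graph, never on the 2-D coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import AbundanceVector, purity

DEFAULT_N_NEIGHBORS = 15
DEFAULT_MIN_DIST = 0.1
DEFAULT_RESOLUTION = 1.0
DEFAULT_SEED = 0
CONTIG_PURITY = 0.90   # contigs join the atlas only above 90% purity
INTEGRATE_K = 10       # neighbours used for contig label transfer


# ---------------------------------------------------------------------------
# filtering and matrix construction


def filter_vectors(vectors: list[AbundanceVector], min_mapped_fraction: float = 0.5,
                   min_purity: float = 0.8) -> list[AbundanceVector]:
    """Retain vectors with mapped_fraction >= threshold AND purity strictly
    above ``min_purity``; empty vectors (no read matched any taxon) are always
    removed. The strict inequality on purity mirrors the conventional
    '>80%' / '>90%' phrasing of the cut-offs."""
    if not (0 <= min_mapped_fraction <= 1 and 0 <= min_purity <= 1):
        raise ValueError("thresholds must be fractions in [0, 1]")
    out = []
    for v in vectors:
        if v.is_empty:
            continue
        if v.mapped_fraction >= min_mapped_fraction and purity(v) > min_purity:
            out.append(v)
    return out


def build_matrix(vectors: list[AbundanceVector],
                 batch: str = "single_cell") -> pd.DataFrame:
    """Combine abundance vectors into a row-per-barcode matrix.

    Columns are the union of taxa across vectors with zeros assigned to empty
    entries; row order is preserved. The batch label is carried in
    ``df.attrs['batch']`` per row for integration bookkeeping."""
    if not vectors:
        raise ValueError("no vectors to combine")
    ranks = {v.rank for v in vectors}
    if len(ranks) != 1:
        raise ValueError(f"vectors mix ranks: {sorted(ranks)}")
    taxa = sorted(set().union(*(v.a.keys() for v in vectors)))
    ids = []
    for i, v in enumerate(vectors):
        ids.append(v.barcode or f"row_{i}")
    data = np.zeros((len(vectors), len(taxa)))
    col = {t: j for j, t in enumerate(taxa)}
    for i, v in enumerate(vectors):
        for t, frac in v.a.items():
            data[i, col[t]] = frac
    df = pd.DataFrame(data, index=ids, columns=taxa)
    df.attrs["rank"] = ranks.pop()
    df.attrs["batch"] = {r: batch for r in ids}
    return df


# ---------------------------------------------------------------------------
# embedding and clustering


@dataclass
class AtlasResult:
    """Clustered, embedded atlas: one row per barcode/contig."""

    table: pd.DataFrame  # columns: x, y, cluster, batch
    annotation: dict[int, str] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    @property
    def labels(self) -> pd.Series:
        return self.table["cluster"]

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["annotation"] = [self.annotation.get(int(c), "") for c in out["cluster"]]
        out.to_csv(path, sep="\t", index_label="barcode")


def _knn_graph(x: np.ndarray, n_neighbors: int, seed: int):
    """Weighted k-NN graph (Euclidean) as an igraph Graph.

    Edge weights are the fuzzy-simplicial-set connectivities of the UMAP
    framework (locally scaled exponential kernel, fuzzy union) — the
    neighbourhood graph the standard single-cell toolkit hands to Leiden.
    Local scaling keeps within-population edges strong and long-range edges
    near zero regardless of dataset size.
    """
    import igraph as ig
    from scipy.sparse import coo_matrix
    from umap.umap_ import fuzzy_simplicial_set

    connectivities, _, _ = fuzzy_simplicial_set(
        x, n_neighbors=n_neighbors, random_state=np.random.RandomState(seed),
        metric="euclidean")
    coo = coo_matrix(connectivities)
    mask = coo.row < coo.col  # undirected: keep upper triangle
    edges = list(zip(coo.row[mask].tolist(), coo.col[mask].tolist()))
    weights = coo.data[mask].tolist()
    g = ig.Graph(n=x.shape[0], edges=edges)
    g.es["weight"] = weights
    return g


def embed_and_cluster(matrix: pd.DataFrame, n_neighbors: int = DEFAULT_N_NEIGHBORS,
                      min_dist: float = DEFAULT_MIN_DIST,
                      resolution: float = DEFAULT_RESOLUTION,
                      seed: int = DEFAULT_SEED,
                      batch: dict[str, str] | None = None) -> AtlasResult:
    """Cluster abundance vectors (Leiden on a k-NN graph) and embed in 2-D.

    Labels come from Leiden community detection on the Euclidean k-NN graph
    of the abundance fractions; the UMAP coordinates are for visualisation
    only. Deterministic given ``seed``.
    """
    import leidenalg

    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    if n_neighbors >= matrix.shape[0]:
        warnings.warn(f"n_neighbors={n_neighbors} >= rows={matrix.shape[0]}; reducing")
        n_neighbors = max(2, matrix.shape[0] - 1)
    x = matrix.to_numpy(dtype=float)
    graph = _knn_graph(x, n_neighbors, seed)
    partition = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition,
        weights="weight", resolution_parameter=resolution, seed=seed,
        n_iterations=-1)
    labels = np.asarray(partition.membership)
    coords = _umap_embed(x, n_neighbors, min_dist, seed)
    batch = batch or matrix.attrs.get("batch") or {}
    table = pd.DataFrame({
        "x": coords[:, 0], "y": coords[:, 1], "cluster": labels,
        "batch": [batch.get(r, "single_cell") for r in matrix.index],
    }, index=matrix.index)
    params = {"n_neighbors": n_neighbors, "min_dist": min_dist,
              "resolution": resolution, "seed": seed}
    result = AtlasResult(table=table, params=params)
    result.annotation = annotate_clusters(result, matrix)
    return result


def _umap_embed(x: np.ndarray, n_neighbors: int, min_dist: float,
                seed: int) -> np.ndarray:
    import umap

    n_neighbors = min(n_neighbors, max(2, x.shape[0] - 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns about small n / random_state
        reducer = umap.UMAP(n_neighbors=n_neighbors, min_dist=min_dist,
                            n_components=2, random_state=seed)
        return np.asarray(reducer.fit_transform(x))


def annotate_clusters(atlas: AtlasResult, matrix: pd.DataFrame) -> dict[int, str]:
    """Name each cluster by its most abundant taxon: member abundance vectors
    are summed and the arg-max column wins (lexicographic tie-break)."""
    annotation: dict[int, str] = {}
    labels = atlas.table.loc[matrix.index.intersection(atlas.table.index), "cluster"]
    for cluster in sorted(labels.unique()):
        members = labels.index[labels == cluster]
        totals = matrix.loc[members].sum(axis=0)
        best = totals.max()
        annotation[int(cluster)] = min(t for t in totals.index if totals[t] == best)
    return annotation


# ---------------------------------------------------------------------------
# metagenomic contig integration


def integrate_contigs(reference: AtlasResult, ref_matrix: pd.DataFrame,
                      contig_vectors: list[AbundanceVector],
                      min_contig_purity: float = CONTIG_PURITY,
                      k: int = INTEGRATE_K) -> tuple[AtlasResult, pd.DataFrame]:
    """Project contig abundance vectors into an existing single-cell atlas.

    Contigs are filtered for purity strictly above ``min_contig_purity``,
    columns are harmonised by union with zero fill, and each contig receives
    the majority cluster label of its ``k`` nearest single-cell rows in
    abundance space, positioned at the mean of those neighbours' 2-D
    coordinates. Reference rows keep their labels untouched.
    """
    from sklearn.neighbors import NearestNeighbors

    if ref_matrix.shape[0] == 0:
        raise ValueError("empty reference atlas")
    kept = [v for v in contig_vectors
            if not v.is_empty and purity(v) > min_contig_purity]
    if not kept:
        return reference, ref_matrix
    contig_matrix = build_matrix(kept, batch="contig")
    if contig_matrix.attrs.get("rank") != ref_matrix.attrs.get("rank"):
        raise ValueError("contig vectors are at a different rank than the atlas")
    taxa = sorted(set(ref_matrix.columns) | set(contig_matrix.columns))
    ref_full = ref_matrix.reindex(columns=taxa, fill_value=0.0)
    con_full = contig_matrix.reindex(columns=taxa, fill_value=0.0)

    k = min(k, ref_full.shape[0])
    nn = NearestNeighbors(n_neighbors=k).fit(ref_full.to_numpy(float))
    _, idx = nn.kneighbors(con_full.to_numpy(float))
    ref_labels = reference.table["cluster"].to_numpy()
    ref_coords = reference.table[["x", "y"]].to_numpy()
    rows = []
    for i, neigh in enumerate(idx):
        votes = ref_labels[neigh]
        values, counts = np.unique(votes, return_counts=True)
        label = int(values[counts == counts.max()].min())
        pos = ref_coords[neigh].mean(axis=0)
        rows.append({"x": pos[0], "y": pos[1], "cluster": label, "batch": "contig"})
    contig_table = pd.DataFrame(rows, index=con_full.index)
    joint_table = pd.concat([reference.table, contig_table])
    joint_matrix = pd.concat([ref_full, con_full])
    joint_matrix.attrs["rank"] = ref_matrix.attrs.get("rank")
    joint_matrix.attrs["batch"] = {**{r: b for r, b in
                                      zip(reference.table.index, reference.table["batch"])},
                                   **{r: "contig" for r in con_full.index}}
    joint = AtlasResult(table=joint_table, annotation=dict(reference.annotation),
                        params=dict(reference.params))
    return joint, joint_matrix


# ---------------------------------------------------------------------------
# cluster read pooling and evaluation


def pool_cluster_reads(groups: dict, atlas: AtlasResult) -> dict[int, list[tuple[str, str, str]]]:
    """Concatenate the reads of all barcode groups per cluster.

    Returns cluster -> list of (title, seq, qual) covering both mates; the
    pools partition the retained reads (every labelled group contributes all
    of its reads to exactly one pool)."""
    pools: dict[int, list] = {}
    labels = atlas.table["cluster"]
    for barcode, group in groups.items():
        if barcode not in labels.index:
            continue
        pool = pools.setdefault(int(labels[barcode]), [])
        for r1, r2 in group.read_pairs:
            pool.append(r1)
            pool.append(r2)
    return pools


def clustering_error_rate(pooled_reads: list[tuple[str, str, str]],
                          reference, max_mismatch: int = 4,
                          seed_k: int = 21) -> float | None:
    """Fraction of a cluster's pooled reads that fail to align to the
    cluster's reference genome — the clustering error rate. ``reference`` is
    (ref_id, sequence) or a prebuilt MiniAligner."""
    from .align import MiniAligner

    if not pooled_reads:
        return None
    aligner = reference if isinstance(reference, MiniAligner) \
        else MiniAligner([reference], seed_k=seed_k)
    unaligned = 0
    for title, seq, qual in pooled_reads:
        if not aligner.align_read(title, seq, qual, max_mismatch=max_mismatch):
            unaligned += 1
    return unaligned / len(pooled_reads)


def subcluster(atlas: AtlasResult, species_matrix: pd.DataFrame, cluster_id: int,
               **params) -> AtlasResult:
    """Re-cluster the members of one cluster using species-rank vectors —
    splits within-genus structure that the genus-rank atlas cannot see."""
    members = atlas.table.index[atlas.table["cluster"] == cluster_id]
    members = members.intersection(species_matrix.index)
    if len(members) < 2:
        raise ValueError(f"cluster {cluster_id} has fewer than 2 members with species vectors")
    sub = species_matrix.loc[members]
    sub.attrs["rank"] = species_matrix.attrs.get("rank", "species")
    sub.attrs["batch"] = {m: "single_cell" for m in members}
    return embed_and_cluster(sub, **params)


# ---------------------------------------------------------------------------
# coverage and metagenome comparison statistics


def genome_coverage(intervals: np.ndarray, genome_length: int) -> float:
    """Fraction of genome bases covered by >= 1 interval; intervals is an
    (n, 2) array of [start, end) pairs."""
    intervals = np.asarray(intervals)
    if intervals.size == 0:
        return 0.0
    if intervals.min() < 0 or intervals.max() > genome_length:
        raise ValueError("intervals outside [0, genome_length)")
    order = np.argsort(intervals[:, 0])
    covered = 0
    cur_start, cur_end = None, None
    for start, end in intervals[order]:
        if cur_end is None or start > cur_end:
            if cur_end is not None:
                covered += cur_end - cur_start
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    covered += cur_end - cur_start
    return covered / genome_length


def rarefaction_coverage(intervals: np.ndarray, genome_length: int,
                         step_reads: int, seed: int,
                         max_reads: int = 10000) -> pd.DataFrame:
    """Coverage accumulation curve under random read subsampling.

    Reads (aligned intervals) are sampled without replacement in random order;
    after every ``step_reads`` additional reads the covered-base fraction is
    recorded. The curve is monotone non-decreasing by construction.
    """
    intervals = np.asarray(intervals)
    rng = np.random.default_rng(seed)
    n = min(len(intervals), max_reads)
    order = rng.permutation(len(intervals))[:n]
    rows = []
    for upto in range(step_reads, n + step_reads, step_reads):
        upto = min(upto, n)
        cov = genome_coverage(intervals[order[:upto]], genome_length)
        rows.append({"n_reads": upto, "coverage": cov})
        if upto == n:
            break
    return pd.DataFrame(rows)


def compare_to_metagenome(single_cell: dict[str, float], metagenome: dict[str, float],
                          exclude: set[str] | None = None, log: bool = False
                          ) -> tuple[float | None, pd.DataFrame]:
    """Pearson correlation between pooled single-cell and metagenomic
    taxon profiles (read counts or fractions), union-aligned with zero fill.

    ``exclude`` drops taxa from both sides before correlating (e.g. lineages
    with known lysis bias). Returns (r, per-taxon table); r is None with a
    warning when fewer than 3 shared taxa remain."""
    from scipy.stats import pearsonr

    exclude = exclude or set()
    taxa = sorted((set(single_cell) | set(metagenome)) - exclude)
    table = pd.DataFrame({
        "single_cell": [single_cell.get(t, 0.0) for t in taxa],
        "metagenome": [metagenome.get(t, 0.0) for t in taxa],
    }, index=taxa)
    shared = [(t in single_cell) and (t in metagenome) for t in taxa]
    if sum(shared) < 3:
        warnings.warn("fewer than 3 shared taxa; correlation not reported")
        return None, table
    x = table["single_cell"].to_numpy()
    y = table["metagenome"].to_numpy()
    if log:
        x, y = np.log1p(x), np.log1p(y)
    r = float(pearsonr(x, y).statistic)
    return r, table
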