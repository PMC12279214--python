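"""Minimal k-mer LCA taxonomic classifier and abundance-vector construction.

A built-in Kraken-style classifier: genomes are indexed by canonical k-mer,
each k-mer mapped to the lowest common ancestor (LCA) of all genomes that
contain it; a read pair is classified to the leaf-most taxid maximising the
summed k-mer hit count along its root-to-leaf path. Per-barcode
classifications are then collapsed to a rank-level abundance vector with a
purity statistic (fraction of classified reads in the dominant taxon), the
filter that removes droplet multiplets and cell aggregates.

Adapters for external classifier reports (Kraken2 report format, Bracken
output TSV) let real pipelines plug in; the internal classifier is not a
performant replacement for them (no minimizers, no probabilistic data
structures) but is exact on the small databases used for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .demux import BarcodeGroup
from .dna import canonical_kmers, canonical_kmers_batch
from .taxonomy import TaxonomyDB

DEFAULT_K = 21  # balances specificity and sensitivity on kb-scale genomes


# ---------------------------------------------------------------------------
# index construction


@dataclass
class KmerIndex:
    """Canonical k-mer -> LCA taxid map over a genome set.

    ``kmers`` is sorted ascending; ``taxids`` is parallel. Lookup is by
    binary search (vectorised via searchsorted).
    """

    k: int
    kmers: np.ndarray   # int64, sorted
    taxids: np.ndarray  # int64, parallel

    def lookup(self, queries: np.ndarray) -> np.ndarray:
        """Taxid per query k-mer code; 0 where absent."""
        if queries.size == 0:
            return np.empty(0, dtype=np.int64)
        pos = np.searchsorted(self.kmers, queries)
        pos = np.minimum(pos, self.kmers.size - 1) if self.kmers.size else pos
        out = np.zeros(queries.size, dtype=np.int64)
        if self.kmers.size:
            hit = self.kmers[pos] == queries
            out[hit] = self.taxids[pos[hit]]
        return out

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#k={self.k}\n")
            for kmer, taxid in zip(self.kmers, self.taxids):
                fh.write(f"{kmer}\t{taxid}\n")

    @classmethod
    def from_tsv(cls, path) -> "KmerIndex":
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("#k="):
                raise ValueError("k-mer index TSV must start with '#k=' header")
            k = int(header[3:])
            data = np.loadtxt(fh, dtype=np.int64, ndmin=2)
        if data.size == 0:
            return cls(k, np.empty(0, np.int64), np.empty(0, np.int64))
        return cls(k, data[:, 0], data[:, 1])


def build_index(genomes, genome_taxids: dict[str, int], taxonomy: TaxonomyDB,
                k: int = DEFAULT_K) -> KmerIndex:
    """Index genomes by canonical k-mer, folding shared k-mers to their LCA.

    ``genomes`` is an iterable of (seq_id, sequence); ``genome_taxids`` maps
    seq_id -> taxid (all must exist in ``taxonomy``).
    """
    if not 11 <= k <= 31:
        raise ValueError("k must be in [11, 31]")
    all_kmers, all_tax = [], []
    for seq_id, seq in genomes:
        if seq_id not in genome_taxids:
            raise ValueError(f"no taxid for genome {seq_id!r}")
        taxid = genome_taxids[seq_id]
        if taxid not in taxonomy:
            raise ValueError(f"taxid {taxid} of genome {seq_id!r} not in taxonomy")
        kmers = np.unique(canonical_kmers(seq, k))
        all_kmers.append(kmers)
        all_tax.append(np.full(kmers.size, taxid, dtype=np.int64))
    if not all_kmers:
        return KmerIndex(k, np.empty(0, np.int64), np.empty(0, np.int64))
    kmers = np.concatenate(all_kmers)
    tax = np.concatenate(all_tax)
    order = np.argsort(kmers, kind="stable")
    kmers, tax = kmers[order], tax[order]
    uniq, start = np.unique(kmers, return_index=True)
    out_tax = tax[start].copy()
    # fold k-mers shared across genomes to the LCA of their sources
    boundaries = np.append(start, kmers.size)
    multi = np.flatnonzero(np.diff(boundaries) > 1)
    for i in multi:
        group = tax[boundaries[i] : boundaries[i + 1]]
        out_tax[i] = taxonomy.lca_many(group.tolist())
    return KmerIndex(k, uniq, out_tax)


# ---------------------------------------------------------------------------
# read classification


class _PathScorer:
    """Precomputed path/ancestry machinery for one (index, taxonomy) pair."""

    def __init__(self, taxonomy: TaxonomyDB, taxids: np.ndarray):
        self.taxonomy = taxonomy
        self.taxids = np.unique(taxids)
        self.local = {int(t): i for i, t in enumerate(self.taxids)}
        n = self.taxids.size
        # ancestry[a, t] = 1 if taxid a lies on the root-to-t path
        self.ancestry = np.zeros((n, n), dtype=np.float64)
        self.depth = np.zeros(n, dtype=np.int64)
        for j, t in enumerate(self.taxids):
            lineage = taxonomy.lineage(int(t))
            self.depth[j] = len(lineage) - 1
            for a in lineage:
                if a in self.local:
                    self.ancestry[self.local[a], j] = 1.0
        # column order: deepest first, then smallest taxid — so that the
        # first maximum found by argmax realises the documented tie-break
        self.column_order = np.lexsort((self.taxids, -self.depth))

    def classify_counts(self, counts: np.ndarray) -> np.ndarray:
        """Per-read taxid from a (reads x taxa) hit-count matrix; 0 = unclassified.

        Candidates are taxa with direct hits; each candidate's score is the
        summed hit count along its root-to-leaf path; the winner is the
        deepest max-scoring candidate (then smallest taxid).
        """
        scores = counts @ self.ancestry  # (R, T): score of candidate t per read
        scores = np.where(counts > 0, scores, -1.0)
        out = np.zeros(counts.shape[0], dtype=np.int64)
        ordered = scores[:, self.column_order]
        win = np.argmax(ordered, axis=1)
        best = ordered[np.arange(ordered.shape[0]), win]
        classified = best > 0
        out[classified] = self.taxids[self.column_order[win[classified]]]
        return out


def _scorer_for(index: KmerIndex, taxonomy: TaxonomyDB) -> _PathScorer:
    # cached on the index instance; invalidated when a different taxonomy
    # object is supplied
    cached = getattr(index, "_scorer", None)
    if cached is None or cached.taxonomy is not taxonomy:
        cached = _PathScorer(taxonomy, index.taxids)
        index._scorer = cached
    return cached


def classify_pairs(pairs, index: KmerIndex, taxonomy: TaxonomyDB) -> np.ndarray:
    """Classify (R1 seq, R2 seq) pairs jointly; returns taxid per pair (0 =
    unclassified). Mates are pooled: hit counts from both reads accumulate
    on one candidate path, matching paired-end classifier behaviour."""
    scorer = _scorer_for(index, taxonomy)
    pairs = list(pairs)
    n_reads = len(pairs)
    # mates are pooled per pair: both sequences carry the pair's index
    seqs, owner = [], []
    for i, (r1, r2) in enumerate(pairs):
        seqs.extend((r1, r2))
        owner.extend((i, i))
    queries, seq_idx = canonical_kmers_batch(seqs, index.k)
    if queries.size == 0:
        return np.zeros(n_reads, dtype=np.int64)
    read_idx = np.asarray(owner, dtype=np.int64)[seq_idx]
    hit_tax = index.lookup(queries)
    keep = hit_tax > 0
    if not np.any(keep):
        return np.zeros(n_reads, dtype=np.int64)
    hit_tax, read_idx = hit_tax[keep], read_idx[keep]
    local = np.searchsorted(scorer.taxids, hit_tax)
    n_tax = scorer.taxids.size
    flat = np.bincount(read_idx * n_tax + local, minlength=n_reads * n_tax)
    counts = flat.reshape(n_reads, n_tax).astype(np.float64)
    return scorer.classify_counts(counts)


def classify_read(pair: tuple[str, str], index: KmerIndex,
                  taxonomy: TaxonomyDB) -> int | None:
    """Classify a single read pair; None when no k-mer hits the index."""
    taxid = int(classify_pairs([pair], index, taxonomy)[0])
    return taxid if taxid > 0 else None


# ---------------------------------------------------------------------------
# abundance vectors


@dataclass
class AbundanceVector:
    """Per-barcode taxon -> fraction profile at a fixed rank.

    ``a`` is normalised over reads classified at or below ``rank`` (reads
    classified only above the rank are excluded from ``a`` but still count as
    classified in ``mapped_fraction``). ``mapped_fraction`` is the fraction
    of the group's read pairs classified at any level.
    """

    rank: str
    a: dict[str, float] = field(default_factory=dict)
    mapped_fraction: float = 0.0
    n_reads: int = 0
    barcode: str = ""

    def __post_init__(self):
        if self.a:
            total = sum(self.a.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"abundance vector must sum to 1, got {total}")
            if any(v < 0 for v in self.a.values()):
                raise ValueError("abundances must be non-negative")

    @property
    def is_empty(self) -> bool:
        return not self.a

    def dominant(self) -> str | None:
        """Most abundant taxon (lexicographic tie-break); None if empty."""
        if not self.a:
            return None
        best = max(self.a.values())
        return min(t for t, v in self.a.items() if v == best)


def purity(v: AbundanceVector) -> float | None:
    """Abundance of the dominant taxon; None for an empty vector (such
    groups are removed by downstream filtering)."""
    if v.is_empty:
        return None
    return max(v.a.values())


def abundance_vector(group: BarcodeGroup, index: KmerIndex, taxonomy: TaxonomyDB,
                     rank: str = "genus") -> AbundanceVector:
    """Classify a barcode group and collapse to a rank-level abundance vector."""
    pairs = group.sequences()
    if not pairs:
        return AbundanceVector(rank=rank, barcode=group.barcode)
    taxids = classify_pairs(pairs, index, taxonomy)
    return vector_from_taxids(taxids, taxonomy, rank, barcode=group.barcode)


def vector_from_taxids(taxids: np.ndarray, taxonomy: TaxonomyDB, rank: str,
                       barcode: str = "") -> AbundanceVector:
    """Collapse per-read taxids (0 = unclassified) to an AbundanceVector."""
    n = int(taxids.size)
    classified = taxids[taxids > 0]
    mapped = classified.size / n if n else 0.0
    lift_cache: dict[int, int | None] = {}
    counts: dict[str, int] = {}
    for t in classified:
        t = int(t)
        if t not in lift_cache:
            lift_cache[t] = taxonomy.ancestor_at_rank(t, rank)
        lifted = lift_cache[t]
        if lifted is None:
            continue  # classified above the working rank: excluded from a
        name = taxonomy.name(lifted)
        counts[name] = counts.get(name, 0) + 1
    total = sum(counts.values())
    a = {name: c / total for name, c in counts.items()} if total else {}
    return AbundanceVector(rank=rank, a=a, mapped_fraction=mapped, n_reads=n,
                           barcode=barcode)


# ---------------------------------------------------------------------------
# external classifier report adapters


def parse_classifier_report(path, dialect: str, rank: str = "genus") -> AbundanceVector:
    """Parse a Kraken2 report or Bracken output TSV into an AbundanceVector.

    Kraken2 dialect: the 6-column report (percent, clade reads, direct reads,
    rank code, taxid, name); rows whose rank code matches the requested rank
    are renormalised into ``a`` and the unclassified ('U') row sets
    ``mapped_fraction`` = 1 - unclassified%. Bracken dialect: headered TSV
    with ``new_est_reads``; Bracken reports only classified reads, so
    ``mapped_fraction`` is 1.0 unless the caller overrides it.
    """
    rank_code = rank[0].upper()
    counts: dict[str, float] = {}
    mapped = 1.0
    total_reads = 0
    if dialect == "kraken2":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) != 6:
                    raise ValueError(f"malformed kraken2 report line {lineno}")
                pct, clade_reads, _direct, code, _taxid, name = fields
                try:
                    pct = float(pct)
                    clade_reads = int(clade_reads)
                except ValueError as exc:
                    raise ValueError(f"malformed kraken2 report line {lineno}") from exc
                name = name.strip()
                if code == "U":
                    mapped = 1.0 - pct / 100.0
                elif code == rank_code:
                    counts[name] = counts.get(name, 0) + clade_reads
                total_reads += int(code in ("U", "R")) * clade_reads
    elif dialect == "bracken":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            try:
                name_i = header.index("name")
                reads_i = header.index("new_est_reads")
                lvl_i = header.index("taxonomy_lvl") if "taxonomy_lvl" in header else None
            except ValueError as exc:
                raise ValueError("malformed bracken header") from exc
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) != len(header):
                    raise ValueError(f"malformed bracken line {lineno}")
                if lvl_i is not None and fields[lvl_i] != rank_code:
                    continue
                counts[fields[name_i]] = counts.get(fields[name_i], 0) + float(fields[reads_i])
    else:
        raise ValueError(f"unknown classifier report dialect {dialect!r}")
    total = sum(counts.values())
    a = {k: v / total for k, v in counts.items()} if total else {}
    return AbundanceVector(rank=rank, a=a, mapped_fraction=mapped if a or dialect == "kraken2" else 0.0,
                           n_reads=int(total_reads or total))


def write_kraken_report(v: AbundanceVector, path, n_reads: int | None = None) -> None:
    """Serialise an AbundanceVector as a minimal Kraken2-style report
    (unclassified row + one row per taxon at the vector's rank)."""
    n = n_reads if n_reads is not None else (v.n_reads or 1000000)
    unclassified = round(n * (1.0 - v.mapped_fraction))
    classified = n - unclassified
    rank_code = v.rank[0].upper()
    with open(path, "w") as fh:
        fh.write(f"{100.0 * unclassified / n:.4f}\t{unclassified}\t{unclassified}\tU\t0\tunclassified\n")
        fh.write(f"{100.0 * classified / n:.4f}\t{classified}\t0\tR\t1\troot\n")
        for name in sorted(v.a):
            reads = v.a[name] * classified
            fh.write(f"{100.0 * reads / n:.4f}\t{reads:.0f}\t0\t{rank_code}\t0\t  {name}\n")
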