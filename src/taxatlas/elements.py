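"""Mobile-element and gene association over barcode groups and clusters.

Links plasmids and genes to hosts: per-barcode plasmid presence calls from
mismatch-free deduplicated alignments, per-species plasmid barcode ratios,
antibiotic-resistance-gene abundance as unique reads per million cluster
reads (RPM), a fragment-based average nucleotide identity (ANI) estimator
that explains cross-species plasmid signals via shared homology, and a
binary gene presence/absence matrix for subpopulation clustering.

Two alignment routes exist throughout: the internal mini-aligner applies the
intent of the mismatch-free criterion directly (zero mismatches, then
deduplication), while the SAM route honours the literal MAPQ >= 42 threshold
that proxies unique, mismatch-free alignment in common aligner output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import MiniAligner

MAPQ_UNIQUE = 42  # aligner-specific proxy for a unique, mismatch-free hit


@dataclass
class PlasmidCall:
    barcode: str
    plasmid_id: str
    present: bool
    supporting_reads: int  # mismatch-free alignments after deduplication

    def __post_init__(self):
        if self.present != (self.supporting_reads >= 1):
            raise ValueError("present must equal supporting_reads >= 1")


def _dedup_hits(hits) -> list:
    """Drop duplicate reads: identical alignment position + strand + read
    sequence count once (the rmdup criterion, with the sequence added for
    safety)."""
    seen = set()
    out = []
    for hit, seq in hits:
        key = (hit.strain_id, hit.position, hit.strand, seq)
        if key not in seen:
            seen.add(key)
            out.append((hit, seq))
    return out


def plasmid_presence(group, plasmids, require_zero_mismatch: bool = True,
                     aligner: MiniAligner | None = None,
                     seed_k: int = 21) -> list[PlasmidCall]:
    """Call plasmid presence in one barcode group.

    Reads are aligned to the plasmid panel; only mismatch-free alignments
    are kept (or all alignments when ``require_zero_mismatch`` is False),
    duplicates removed, and a plasmid is present iff at least one read
    survives. ``plasmids`` is an iterable of (plasmid_id, sequence)."""
    plasmids = list(plasmids)
    if aligner is None:
        aligner = MiniAligner(plasmids, seed_k=seed_k)
    max_mm = 0 if require_zero_mismatch else 4
    hits = []
    for pair_i, ((t1, s1, q1), (t2, s2, q2)) in enumerate(group.read_pairs):
        for mate, (seq, qual) in enumerate(((s1, q1), (s2, q2)), start=1):
            for hit in aligner.align_read(f"{group.barcode}:{pair_i}/{mate}",
                                          seq, qual, max_mismatch=max_mm):
                hits.append((hit, seq))
    hits = _dedup_hits(hits)
    counts: dict[str, int] = {pid: 0 for pid, _ in plasmids}
    for hit, _ in hits:
        counts[hit.strain_id] += 1
    return [PlasmidCall(group.barcode, pid, counts[pid] >= 1, counts[pid])
            for pid, _ in plasmids]


def plasmid_presence_from_sam(path, barcode_of_read, plasmid_ids,
                              min_mapq: int = MAPQ_UNIQUE) -> list[PlasmidCall]:
    """SAM route for presence calls: keep alignments with MAPQ >= 42 (the
    conventional unique/mismatch-free filter), deduplicate by position +
    strand + sequence, and call presence per (barcode, plasmid).

    ``barcode_of_read`` maps a read name to its barcode."""
    import pysam

    per_bc: dict[tuple[str, str], set] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped or aln.mapping_quality < min_mapq:
                continue
            barcode = barcode_of_read(aln.query_name)
            if barcode is None:
                continue
            key = (aln.reference_start, aln.is_reverse, aln.query_sequence)
            per_bc.setdefault((barcode, aln.reference_name), set()).add(key)
    barcodes = sorted({b for b, _ in per_bc})
    calls = []
    for barcode in barcodes:
        for pid in plasmid_ids:
            n = len(per_bc.get((barcode, pid), ()))
            calls.append(PlasmidCall(barcode, pid, n >= 1, n))
    return calls


def plasmid_host_ratio(calls: list[PlasmidCall],
                       species_of_barcode: dict[str, str]) -> pd.DataFrame:
    """Species x plasmid table of barcode ratios: the proportion of a
    species' barcodes with plasmid reads over all barcodes assigned to that
    species. NaN for species with zero barcodes."""
    for call in calls:
        if call.barcode not in species_of_barcode:
            raise ValueError(f"barcode {call.barcode} has no species label")
    df = pd.DataFrame([(c.barcode, c.plasmid_id, c.present) for c in calls],
                      columns=["barcode", "plasmid", "present"])
    df["species"] = df["barcode"].map(species_of_barcode)
    ratio = df.pivot_table(index="species", columns="plasmid", values="present",
                           aggfunc="mean")
    return ratio


# ---------------------------------------------------------------------------
# gene / ARG abundance


def arg_abundance(cluster_reads: dict[int, list[tuple[str, str, str]]],
                  genes, require_zero_mismatch: bool = True,
                  seed_k: int = 21) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster gene hit counts and reads-per-million.

    ``cluster_reads`` maps cluster -> pooled (title, seq, qual) reads (from
    :func:`taxatlas.atlas.pool_cluster_reads`); ``genes`` is an iterable of
    (gene_id, sequence), e.g. a resistance-gene FASTA with accession tokens
    in the headers. Reads are aligned to the gene panel, mismatch-free hits
    deduplicated, and RPM[cluster][gene] = unique hits x 1e6 / total cluster
    reads. Genes with zero hits anywhere are absent from the tables.
    """
    genes = list(genes)
    aligner = MiniAligner(genes, seed_k=seed_k)
    max_mm = 0 if require_zero_mismatch else 4
    count_rows, rpm_rows = {}, {}
    for cluster, reads in cluster_reads.items():
        if not reads:
            warnings.warn(f"cluster {cluster} has no reads; skipped")
            continue
        hits = []
        for title, seq, qual in reads:
            for hit in aligner.align_read(title, seq, qual, max_mismatch=max_mm):
                hits.append((hit, seq))
        hits = _dedup_hits(hits)
        counts: dict[str, int] = {}
        for hit, _ in hits:
            counts[hit.strain_id] = counts.get(hit.strain_id, 0) + 1
        total = len(reads)
        count_rows[cluster] = counts
        rpm_rows[cluster] = {g: c * 1e6 / total for g, c in counts.items()}
    hit_table = pd.DataFrame.from_dict(count_rows, orient="index").fillna(0).astype(int)
    rpm = pd.DataFrame.from_dict(rpm_rows, orient="index").fillna(0.0)
    hit_table["total_reads"] = [len(cluster_reads[c]) for c in hit_table.index]
    return hit_table, rpm


def parse_gene_ids(fasta_records) -> list[tuple[str, str]]:
    """Extract gene ids from FASTA headers, preferring accession-ontology
    tokens of the form 'ARO:<digits>' when present (CARD-style headers)."""
    out = []
    for header, seq in fasta_records:
        gene_id = header
        for token in header.replace("|", " ").split():
            if token.startswith("ARO:"):
                gene_id = token
                break
        out.append((gene_id, seq))
    return out


# ---------------------------------------------------------------------------
# fragment-based ANI


def fragment_ani(query: str, reference: str, fragment: int = 1000,
                 min_frag_identity: float = 0.7, seed_k: int = 21
                 ) -> tuple[float | None, float]:
    """Average nucleotide identity by the fragment-mapping scheme.

    The query is tiled into non-overlapping fragments (a single full-length
    fragment when the query is shorter than ``fragment``); each fragment's
    best ungapped placement on the reference gives a per-fragment identity
    (matches / fragment length); ANI is the mean identity over fragments
    exceeding ``min_frag_identity``, as a percentage. Returns (ANI, fraction
    of fragments mapped); (None, 0.0) when no fragment maps. The 1 kb default
    fragment suits kb-scale plasmids; genome-scale comparisons may prefer
    longer fragments.
    """
    if not query:
        raise ValueError("empty query")
    frags = [query[i : i + fragment] for i in range(0, len(query), fragment)]
    # drop a trailing sliver shorter than the seed: it cannot anchor
    frags = [f for f in frags if len(f) >= seed_k]
    aligner = MiniAligner([("ref", reference)], seed_k=seed_k)
    identities = []
    for i, frag in enumerate(frags):
        budget = int(len(frag) * (1.0 - min_frag_identity)) + 1
        hit = aligner.best_hit(f"frag_{i}", frag, max_mismatch=budget)
        if hit is None:
            continue
        identity = 1.0 - hit.n_mismatch / len(frag)
        if identity > min_frag_identity:
            identities.append(identity)
    if not identities:
        return None, 0.0
    return float(np.mean(identities) * 100.0), len(identities) / len(frags)


# ---------------------------------------------------------------------------
# gene presence/absence subpopulations


def gene_presence_matrix(hit_table: pd.DataFrame, min_cells_per_gene: int = 5,
                         min_genes_per_cell: int = 5) -> pd.DataFrame:
    """Binarise a barcode x gene count table and filter it for clustering.

    Counts >= 1 become presence. Genes present in fewer than
    ``min_cells_per_gene`` cells are dropped first, then cells with fewer
    than ``min_genes_per_cell`` remaining genes (single pass, genes before
    cells). The filtered binary matrix feeds
    :func:`taxatlas.atlas.embed_and_cluster` for subpopulation discovery.
    """
    if min_cells_per_gene < 0 or min_genes_per_cell < 0:
        raise ValueError("thresholds must be >= 0")
    binary = (hit_table.drop(columns=["total_reads"], errors="ignore") >= 1).astype(int)
    gene_ok = binary.sum(axis=0) >= min_cells_per_gene
    binary = binary.loc[:, gene_ok]
    cell_ok = binary.sum(axis=1) >= min_genes_per_cell
    binary = binary.loc[cell_ok]
    if binary.empty:
        raise ValueError("gene presence matrix empty after filtering")
    return binary
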