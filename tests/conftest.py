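"""Shared fixtures: synthetic communities, classifiers, and the reduced
replica of the validation simulation reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import taxatlas as tx
from taxatlas.align import MiniAligner
from taxatlas.demux import BarcodeGroup


def groups_from_records(r1_records, r2_records) -> dict[str, BarcodeGroup]:
    """Group simulator read records by the barcode encoded in their titles
    (bypasses demultiplexing when the barcode is not embedded in R1)."""
    groups: dict[str, BarcodeGroup] = {}
    for rec1, rec2 in zip(r1_records, r2_records):
        barcode = rec1[0].split("|")[0]
        groups.setdefault(barcode, BarcodeGroup(barcode)).read_pairs.append((rec1, rec2))
    return groups


@pytest.fixture(scope="session")
def toy_db():
    """5 random 10 kb genomes, their taxonomy, and a k=21 index."""
    community, taxonomy = tx.make_community(5, 10000, seed=101)
    genomes = [(g.seq_id, g.sequence) for g in community.genomes]
    taxids = {g.seq_id: g.taxid for g in community.genomes}
    index = tx.build_index(genomes, taxids, taxonomy, k=21)
    return {"community": community, "taxonomy": taxonomy, "index": index,
            "genomes": genomes, "taxids": taxids}


@pytest.fixture(scope="session")
def tda_replica():
    """Reduced replica of the validation simulation: 10 species with disjoint
    21-mer content, 20 barcodes per species, 1000-2000 read pairs, uniform
    0-49% contamination; classified, purity-filtered at 0.9, clustered."""
    community, taxonomy = tx.make_community(10, 20000, seed=11)
    r1, r2, truth, whitelist = tx.simulate_barcode_groups(
        community, 20, seed=12, reads_range=(1000, 2000), contam_range=(0.0, 0.49))
    taxids = {g.seq_id: g.taxid for g in community.genomes}
    index = tx.build_index([(g.seq_id, g.sequence) for g in community.genomes],
                           taxids, taxonomy, k=21)
    groups = groups_from_records(r1, r2)
    vectors = [tx.abundance_vector(g, index, taxonomy) for g in groups.values()]
    retained = tx.filter_vectors(vectors, min_mapped_fraction=0.5, min_purity=0.9)
    matrix = tx.build_matrix(retained)
    atlas = tx.embed_and_cluster(matrix, seed=0)
    return {"community": community, "taxonomy": taxonomy, "index": index,
            "taxids": taxids, "groups": groups, "vectors": vectors,
            "retained": retained, "matrix": matrix, "atlas": atlas,
            "truth": truth, "whitelist": whitelist}


@pytest.fixture(scope="session")
def strain_pair():
    """Two strains at divergence 0.002 over a 50 kb base genome, plus an
    aligner over the pair (the strain panel)."""
    base = tx.simulate_genome(50000, 0.5, seed=5, seq_id="sp", taxid=10)
    strains, snps = tx.derive_strains(base, 2, 0.002, seed=6)
    aligner = MiniAligner([(s.seq_id, s.sequence) for s in strains])
    return {"base": base, "strains": strains, "snps": snps, "aligner": aligner,
            "panel": [s.seq_id for s in strains]}


def strain_read_probs(strains, aligner, weights, n_pairs, seed,
                      unique_only=False):
    """Alignment probabilities for a barcode group of error-free pairs drawn
    from a strain mixture.

    With ``unique_only`` the alignment allows zero mismatches, so only reads
    overlapping a discriminating SNP (hence mapping to a single strain)
    contribute — the uniquely-mapping subset."""
    from taxatlas.strains import alignment_prob

    rng = np.random.default_rng(seed)
    probs = []
    weights = np.asarray(weights, dtype=float)
    max_mm = 0 if unique_only else 4
    for i in range(n_pairs):
        s = strains[int(rng.choice(len(strains), p=weights / weights.sum()))]
        start = int(rng.integers(0, len(s.sequence) - 400))
        frag = s.sequence[start : start + 400]
        for mate, seq in ((1, frag[:150]), (2, frag[-150:])):
            hits = aligner.align_read(f"r{i}/{mate}", seq, "I" * 150,
                                      max_mismatch=max_mm)
            if unique_only and len({h.strain_id for h in hits}) != 1:
                continue
            probs.extend(alignment_prob(h) for h in hits)
    return probs
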