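"""Seed-and-extend ungapped read aligner used across the package.

A deliberately small alignment engine: exact k-mer seeds looked up in a
reference index, ungapped extension over the full read, and *every* placement
within the mismatch budget reported (multi-mapping preserved, as an external
aligner run in report-all-matches mode would). It backs strain-mixture
estimation, pooled-cluster error rates, plasmid/gene hit calling and the
fragment ANI estimator. No indels, no clipping: reads must fit entirely
within the reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dna import encode, kmer_codes, revcomp

DEFAULT_SEED_K = 21
DEFAULT_MAX_MISMATCH = 4


@dataclass
class AlignmentRecord:
    """One ungapped placement of a read on a reference.

    ``position`` is the 0-based leftmost reference coordinate. ``quality`` and
    ``mismatch_positions`` are in reference orientation (the read is reverse
    complemented first when ``strand`` is '-'). ``mismatch_positions`` is None
    for records imported from SAM, where only the mismatch count is known.
    """

    read_id: str
    strain_id: str
    position: int
    strand: str
    n_mismatch: int
    quality: str
    read_len: int
    mismatch_positions: tuple[int, ...] | None = None


class MiniAligner:
    """Exact-seed, ungapped-extension aligner over a fixed reference panel."""

    def __init__(self, references, seed_k: int = DEFAULT_SEED_K):
        self.seed_k = seed_k
        self.ref_ids: list[str] = []
        self.ref_codes: list[np.ndarray] = []
        self.index: dict[int, list[tuple[int, int]]] = {}
        for ref_id, seq in references:
            ref_idx = len(self.ref_ids)
            self.ref_ids.append(ref_id)
            codes = encode(seq)
            self.ref_codes.append(codes)
            for pos, code in enumerate(kmer_codes(codes, seed_k)):
                self.index.setdefault(int(code), []).append((ref_idx, pos))

    def align_read(self, read_id: str, seq: str, qual: str | None = None,
                   max_mismatch: int = DEFAULT_MAX_MISMATCH) -> list[AlignmentRecord]:
        """All placements of ``seq`` (either strand) with <= max_mismatch
        mismatches; empty list when the read is unalignable."""
        k = self.seed_k
        if len(seq) < k:
            return []
        if qual is None:
            qual = "I" * len(seq)
        records: list[AlignmentRecord] = []
        for strand in "+-":
            oriented = seq if strand == "+" else revcomp(seq)
            oqual = qual if strand == "+" else qual[::-1]
            codes = encode(oriented)
            kmers = kmer_codes(codes, k)
            length = len(oriented)
            offsets = list(range(0, length - k + 1, k))
            if offsets[-1] != length - k:
                offsets.append(length - k)
            seen: set[tuple[int, int]] = set()
            for off in offsets:
                for ref_idx, pos in self.index.get(int(kmers[off]), ()):
                    start = pos - off
                    cand = (ref_idx, start)
                    if cand in seen:
                        continue
                    seen.add(cand)
                    ref = self.ref_codes[ref_idx]
                    if start < 0 or start + length > ref.size:
                        continue
                    diff = np.flatnonzero(ref[start : start + length] != codes)
                    if diff.size <= max_mismatch:
                        records.append(AlignmentRecord(
                            read_id=read_id, strain_id=self.ref_ids[ref_idx],
                            position=start, strand=strand,
                            n_mismatch=int(diff.size), quality=oqual,
                            read_len=length,
                            mismatch_positions=tuple(int(d) for d in diff)))
        return records

    def align_pair(self, read_id: str, r1: str, r2: str,
                   qual1: str | None = None, qual2: str | None = None,
                   max_mismatch: int = DEFAULT_MAX_MISMATCH) -> list[AlignmentRecord]:
        """Align both mates independently; mate suffixes /1 and /2 are
        appended to the read id."""
        return (self.align_read(read_id + "/1", r1, qual1, max_mismatch)
                + self.align_read(read_id + "/2", r2, qual2, max_mismatch))

    def best_hit(self, read_id: str, seq: str, qual: str | None = None,
                 max_mismatch: int = DEFAULT_MAX_MISMATCH) -> AlignmentRecord | None:
        """Lowest-mismatch placement (ties: first reference, leftmost)."""
        hits = self.align_read(read_id, seq, qual, max_mismatch)
        if not hits:
            return None
        return min(hits, key=lambda r: (r.n_mismatch, r.strain_id, r.position))


def brute_force_align(seq: str, references, max_mismatch: int
                      ) -> list[tuple[str, int, str, int]]:
    """Exhaustive scan of every offset and strand: (ref_id, pos, strand,
    n_mismatch) per placement. Independent oracle for MiniAligner."""
    out = []
    for ref_id, ref in references:
        for strand in "+-":
            oriented = seq if strand == "+" else revcomp(seq)
            for pos in range(len(ref) - len(oriented) + 1):
                nm = sum(a != b for a, b in zip(ref[pos : pos + len(oriented)], oriented))
                if nm <= max_mismatch:
                    out.append((ref_id, pos, strand, nm))
    return out
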