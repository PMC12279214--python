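"""Low-level DNA sequence utilities shared across the package.

Sequences are plain ``str`` over the alphabet ``ACGT`` at module boundaries;
performance-critical paths convert to 2-bit integer codes (A=0, C=1, G=2, T=3)
held in ``numpy`` arrays so that k-mer extraction and mismatch counting are
vectorised.
"""

from __future__ import annotations

import gzip
from typing import IO, Iterator

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# byte value -> 2-bit code lookup (255 marks non-ACGT)
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_LUT[_b] = _i
    _CODE_LUT[ord(chr(_b).lower())] = _i

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array of 2-bit codes."""
    codes = _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.max(initial=0) > 3:
        raise ValueError("sequence contains non-ACGT characters")
    return codes


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _BASES[codes].tobytes().decode("ascii")


def gc_content(seq: str) -> float:
    """Fraction of G+C bases."""
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of every k-mer of ``codes`` (forward strand), base-4 packed.

    Returns an empty array when the sequence is shorter than ``k``. Requires
    2*k <= 63 so values fit in int64.
    """
    if 2 * k > 63:
        raise ValueError("k too large for 64-bit packing")
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    powers = (4 ** np.arange(k - 1, -1, -1, dtype=np.int64))
    windows = np.lib.stride_tricks.sliding_window_view(codes.astype(np.int64), k)
    return windows @ powers


def canonical_kmers(seq: str, k: int) -> np.ndarray:
    """Canonical (min of forward / reverse-complement) k-mer codes of ``seq``."""
    codes = encode(seq)
    fwd = kmer_codes(codes, k)
    if fwd.size == 0:
        return fwd
    rc_codes = (3 - codes)[::-1]
    rev = kmer_codes(rc_codes, k)[::-1]
    return np.minimum(fwd, rev)


def canonical_kmers_batch(seqs: list[str], k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical k-mer codes for many sequences at once.

    Returns (kmers, seq_idx): flat canonical k-mer codes and the index of the
    originating sequence per k-mer. Sequences are batched by length so the
    whole extraction is a handful of vectorised operations.
    """
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        if len(s) >= k:
            by_len.setdefault(len(s), []).append(i)
    kmer_blocks, idx_blocks = [], []
    powers = (4 ** np.arange(k - 1, -1, -1, dtype=np.int64))
    for length, members in by_len.items():
        joined = "".join(seqs[i] for i in members)
        codes = _CODE_LUT[np.frombuffer(joined.encode("ascii"), dtype=np.uint8)]
        if codes.max(initial=0) > 3:
            raise ValueError("sequence contains non-ACGT characters")
        block = codes.reshape(len(members), length).astype(np.int64)
        fwd = np.lib.stride_tricks.sliding_window_view(block, k, axis=1) @ powers
        rc_block = (3 - block)[:, ::-1]
        rev = (np.lib.stride_tricks.sliding_window_view(rc_block, k, axis=1) @ powers)[:, ::-1]
        canon = np.minimum(fwd, rev)
        n_kmers = length - k + 1
        kmer_blocks.append(canon.ravel())
        idx_blocks.append(np.repeat(np.asarray(members, dtype=np.int64), n_kmers))
    if not kmer_blocks:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(kmer_blocks), np.concatenate(idx_blocks)


def phred_string(q: int, length: int) -> str:
    """Constant-quality Phred+33 string of the given length."""
    return chr(q + 33) * length


def phred_to_error(qual: str) -> np.ndarray:
    """Per-base error probabilities from a Phred+33 quality string."""
    q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(float) - 33.0
    return 10.0 ** (-q / 10.0)


def open_maybe_gzip(path, mode: str = "rt") -> IO:
    """Open a path, transparently gunzipping when it ends in .gz.

    Written gzip members carry mtime=0 so identical content yields
    byte-identical files (reproducible outputs)."""
    path = str(path)
    if path.endswith(".gz"):
        if "w" in mode or "a" in mode:
            import io

            raw = open(path, "wb" if "w" in mode else "ab")
            gz = gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0)
            if "b" in mode:
                return _ClosingWrapper(gz, raw)
            return _ClosingTextWrapper(gz, raw)
        return gzip.open(path, mode)
    return open(path, mode)


class _ClosingTextWrapper:
    """Text wrapper over a GzipFile that also closes the underlying file."""

    def __init__(self, gz, raw):
        import io

        self._text = io.TextIOWrapper(gz)
        self._raw = raw

    def __getattr__(self, name):
        return getattr(self._text, name)

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    def __iter__(self):
        return iter(self._text)

    def close(self):
        try:
            self._text.close()
        finally:
            if not self._raw.closed:
                self._raw.close()


class _ClosingWrapper(_ClosingTextWrapper):
    def __init__(self, gz, raw):
        self._text = gz
        self._raw = raw


def read_fasta(path) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) pairs from a FASTA file (id = first token)."""
    from Bio import SeqIO

    with open_maybe_gzip(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            yield rec.id, str(rec.seq).upper()


def write_fasta(path, records) -> None:
    """Write (id, sequence) pairs as FASTA, 80-column wrapped."""
    with open_maybe_gzip(path, "wt") as handle:
        for seq_id, seq in records:
            handle.write(f">{seq_id}\n")
            for i in range(0, len(seq), 80):
                handle.write(seq[i : i + 80] + "\n")


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield (title, sequence, quality) from a (gzipped) FASTQ file."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open_maybe_gzip(path) as handle:
        yield from FastqGeneralIterator(handle)


def write_fastq(path, records) -> None:
    """Write (title, sequence, quality) triples as 4-line FASTQ records."""
    with open_maybe_gzip(path, "wt") as handle:
        for title, seq, qual in records:
            handle.write(f"@{title}\n{seq}\n+\n{qual}\n")
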