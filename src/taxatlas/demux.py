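"""Cell-barcode extraction, correction, and demultiplexing.

Raw paired FASTQ is split into per-cell *barcode groups*: the set of read
pairs sharing one corrected droplet barcode, proxying a single microbial
cell. Barcodes are parsed from a configured window of R1, corrected against a
whitelist within Hamming distance 1 (ambiguous corrections are discarded,
never guessed), and the barcode plus a configured downstream adapter are
trimmed from R1. Groups are then filtered by read count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .dna import read_fastq, write_fastq

ReadPair = tuple[tuple[str, str, str], tuple[str, str, str]]  # (R1, R2) records


@dataclass
class BarcodeLayout:
    """Where the barcode lives in R1 and what follows it.

    ``barcode_start``/``barcode_end`` are 0-based half-open offsets into the
    R1 sequence; ``adapter`` is the constant sequence expected immediately
    after the barcode and removed together with it (matched as an exact
    prefix with at most one mismatch). All whitelist entries must have length
    ``barcode_end - barcode_start``.
    """

    whitelist: set[str]
    barcode_start: int = 0
    barcode_end: int = 18
    adapter: str = ""

    def __post_init__(self):
        self.whitelist = set(self.whitelist)
        width = self.barcode_end - self.barcode_start
        if any(len(b) != width for b in self.whitelist):
            raise ValueError("whitelist entries must match the barcode window width")

    @property
    def barcode_length(self) -> int:
        return self.barcode_end - self.barcode_start

    @classmethod
    def from_whitelist_file(cls, path, barcode_start: int = 0,
                            adapter: str = "") -> "BarcodeLayout":
        with open(path) as fh:
            entries = {line.strip() for line in fh if line.strip()}
        if not entries:
            return cls(whitelist=set(), barcode_start=barcode_start,
                       barcode_end=barcode_start, adapter=adapter)
        width = len(next(iter(entries)))
        return cls(whitelist=entries, barcode_start=barcode_start,
                   barcode_end=barcode_start + width, adapter=adapter)


@dataclass
class BarcodeGroup:
    """All read pairs attributed to one corrected cell barcode."""

    barcode: str
    read_pairs: list[ReadPair] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        """Number of read pairs in the group."""
        return len(self.read_pairs)

    def sequences(self) -> list[tuple[str, str]]:
        """(R1 seq, R2 seq) per pair — convenience for classification."""
        return [(r1[1], r2[1]) for r1, r2 in self.read_pairs]


@dataclass
class DemuxStats:
    n_pairs: int = 0
    n_valid: int = 0       # exact whitelist match
    n_corrected: int = 0   # rescued at Hamming distance 1
    n_discarded: int = 0   # uncorrectable or ambiguous

    def to_dict(self) -> dict[str, int]:
        return {"pairs": self.n_pairs, "valid": self.n_valid,
                "corrected": self.n_corrected, "discarded": self.n_discarded}


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def correct_barcode(observed: str, whitelist: set[str]) -> str | None:
    """Correct an observed barcode against the whitelist.

    Returns the exact match, or the *unique* whitelist entry at Hamming
    distance 1; ``None`` when no entry is within distance 1 or when two or
    more entries are equidistant at distance 1 (ambiguity is discarded rather
    than guessed).
    """
    if whitelist:
        length = len(next(iter(whitelist)))
        if len(observed) != length:
            raise ValueError("barcode length mismatch")
    if observed in whitelist:
        return observed
    candidate = None
    for entry in whitelist:
        if hamming(observed, entry) == 1:
            if candidate is not None:
                return None  # ambiguous
            candidate = entry
    return candidate


def _match_adapter(seq: str, adapter: str, max_mismatch: int = 1) -> bool:
    if len(seq) < len(adapter):
        return False
    return hamming(seq[: len(adapter)], adapter) <= max_mismatch


def demultiplex(r1_records, r2_records, layout: BarcodeLayout
                ) -> tuple[dict[str, BarcodeGroup], DemuxStats]:
    """Assign read pairs to barcode groups, trimming barcode and adapter.

    ``r1_records``/``r2_records`` are iterables of (title, seq, qual) in
    matching order (e.g. from :func:`taxatlas.dna.read_fastq`). Every retained
    pair lands in exactly one group; pairs whose barcode cannot be corrected
    are counted as discarded, so sum(group sizes) + discarded = input pairs.
    """
    groups: dict[str, BarcodeGroup] = {}
    stats = DemuxStats()
    r2_iter = iter(r2_records)
    exhausted = object()
    for idx, r1 in enumerate(r1_records):
        r2 = next(r2_iter, exhausted)
        if r2 is exhausted:
            raise ValueError(f"R2 exhausted at record {idx}: unequal pair counts")
        title1, seq1, qual1 = r1
        observed = seq1[layout.barcode_start : layout.barcode_end]
        if len(observed) < layout.barcode_length:
            raise ValueError(f"truncated record {idx}: R1 shorter than barcode window")
        corrected = correct_barcode(observed, layout.whitelist) if layout.whitelist else None
        if corrected is None:
            stats.n_discarded += 1
            stats.n_pairs += 1
            continue
        if corrected == observed:
            stats.n_valid += 1
        else:
            stats.n_corrected += 1
        stats.n_pairs += 1
        trim = layout.barcode_end
        rest = seq1[trim:]
        if layout.adapter and _match_adapter(rest, layout.adapter):
            trim += len(layout.adapter)
        trimmed = (title1, seq1[trim:], qual1[trim:])
        group = groups.setdefault(corrected, BarcodeGroup(corrected))
        group.read_pairs.append((trimmed, r2))
    if next(r2_iter, exhausted) is not exhausted:
        raise ValueError("R1 exhausted before R2: unequal pair counts")
    return groups, stats


def demultiplex_files(r1_path, r2_path, layout: BarcodeLayout
                      ) -> tuple[dict[str, BarcodeGroup], DemuxStats]:
    """:func:`demultiplex` over (gzipped) FASTQ files on disk."""
    return demultiplex(read_fastq(r1_path), read_fastq(r2_path), layout)


def filter_read_count(groups, min_reads: int = 1000):
    """Retain groups with at least ``min_reads`` read pairs, order preserved.

    The default mirrors the standard barcode-rank cut that excludes barcode
    groups with fewer than 1000 reads.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    if isinstance(groups, dict):
        return {b: g for b, g in groups.items() if g.n_reads >= min_reads}
    return [g for g in groups if g.n_reads >= min_reads]


def write_groups(groups: dict[str, BarcodeGroup], out_dir, gzip_fastq: bool = True,
                 stats: DemuxStats | None = None) -> dict[str, tuple[str, str]]:
    """Write each group as <barcode>_R1/R2.fastq(.gz) plus a demux_stats TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    suffix = ".fastq.gz" if gzip_fastq else ".fastq"
    paths = {}
    for barcode, group in groups.items():
        p1 = out / f"{barcode}_R1{suffix}"
        p2 = out / f"{barcode}_R2{suffix}"
        write_fastq(p1, (pair[0] for pair in group.read_pairs))
        write_fastq(p2, (pair[1] for pair in group.read_pairs))
        paths[barcode] = (str(p1), str(p2))
    with open(out / "demux_stats.tsv", "w") as fh:
        fh.write("barcode\tn_read_pairs\n")
        for barcode, group in groups.items():
            fh.write(f"{barcode}\t{group.n_reads}\n")
        if stats is not None:
            fh.write(f"#pairs={stats.n_pairs}\tvalid={stats.n_valid}\t"
                     f"corrected={stats.n_corrected}\tdiscarded={stats.n_discarded}\n")
    return paths


def read_group(barcode: str, r1_path, r2_path) -> BarcodeGroup:
    """Re-read a per-barcode FASTQ pair written by :func:`write_groups`."""
    pairs = list(zip(read_fastq(r1_path), read_fastq(r2_path)))
    return BarcodeGroup(barcode, pairs)
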