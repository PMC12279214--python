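"""Synthetic community and read-set simulator with ground truth.

Emulates the validation design used for droplet single-microbe sequencing:
per-species barcode groups of 150 bp paired-end reads drawn from 400-1000 bp
amplicons, 1000-10000 read pairs per barcode, each group carrying 0-49%
contaminating reads sampled from the other community members. Optional strain
SNP structure and plasmid carriage are generated with known truth so that
strain resolution and mobile-element association can be validated offline.

All randomness flows through a single :class:`numpy.random.Generator` seeded
explicitly; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dna import decode, revcomp, write_fasta, write_fastq
from .taxonomy import TaxonomyDB

BASES = "ACGT"

# Default simulation conditions for the paired-end barcode-group generator.
READ_LEN = 150
AMPLICON_RANGE = (400, 1000)
READS_RANGE = (1000, 10000)
CONTAM_RANGE = (0.0, 0.49)
BARCODE_LEN = 18
PLASMID_COPIES = 5
# constant adapter inserted between the cell barcode and the genomic insert
# when barcodes are embedded in R1 (mimics the common-sequence linker of
# droplet platforms)
DEFAULT_ADAPTER = "GTACTCGCAGTAGTC"


@dataclass(frozen=True)
class SyntheticGenome:
    """A simulated genome (or plasmid) tied to a taxonomy node."""

    seq_id: str
    sequence: str
    taxid: int

    def __post_init__(self):
        if len(self.sequence) < 2000:
            raise ValueError("genome too short for amplicon sampling")
        if set(self.sequence) - set(BASES):
            raise ValueError("sequence alphabet must be A/C/G/T")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CommunitySpec:
    """A mock community: members with relative abundances, plus plasmids.

    ``plasmids`` entries are (plasmid genome, set of host seq_ids, carriage
    probability): each barcode whose dominant genome is a host carries the
    plasmid independently with that probability.
    """

    members: list[tuple[SyntheticGenome, float]]
    plasmids: list[tuple[SyntheticGenome, set[str], float]] = field(default_factory=list)

    def __post_init__(self):
        total = sum(a for _, a in self.members)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"member abundances must sum to 1, got {total}")
        ids = {g.seq_id for g, _ in self.members}
        for plasmid, hosts, prob in self.plasmids:
            if not set(hosts) <= ids:
                raise ValueError(f"plasmid {plasmid.seq_id} has non-member hosts")
            if not 0.0 <= prob <= 1.0:
                raise ValueError("carriage probability must be in [0, 1]")

    @property
    def genomes(self) -> list[SyntheticGenome]:
        return [g for g, _ in self.members]

    @property
    def abundances(self) -> np.ndarray:
        return np.asarray([a for _, a in self.members])

    def member(self, seq_id: str) -> SyntheticGenome:
        for g, _ in self.members:
            if g.seq_id == seq_id:
                return g
        raise KeyError(seq_id)


def simulate_genome(length: int, gc: float, seed: int, seq_id: str = "genome",
                    taxid: int = 0) -> SyntheticGenome:
    """I.i.d.-base genome with the requested GC fraction.

    P(G) = P(C) = gc/2 and P(A) = P(T) = (1-gc)/2; deterministic given seed.
    """
    if length < 2000:
        raise ValueError("genome too short for amplicon sampling")
    if not 0.0 < gc <= 1.0:
        raise ValueError("gc must be in (0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    codes = rng.choice(4, size=length, p=probs).astype(np.uint8)
    return SyntheticGenome(seq_id, decode(codes), taxid)


def derive_strains(base: SyntheticGenome, n_strains: int, divergence: float,
                   seed: int) -> tuple[list[SyntheticGenome], pd.DataFrame]:
    """Derive strain genomes from a base by independent random substitutions.

    Each strain receives an independent Bernoulli(divergence) substitution set,
    so the expected number of SNPs per strain is divergence * length. Returns
    the strain genomes plus a SNP truth table (strain_id, position, ref, alt).
    """
    if not 0.0 < divergence < 0.2:
        raise ValueError("divergence must be in (0, 0.2): larger would not be same-species-like")
    if n_strains < 2:
        raise ValueError("need at least 2 strains")
    rng = np.random.default_rng(seed)
    seq = np.frombuffer(base.sequence.encode("ascii"), dtype=np.uint8)
    strains, rows = [], []
    for i in range(n_strains):
        strain_id = f"{base.seq_id}_s{i + 1}"
        positions = np.flatnonzero(rng.random(len(seq)) < divergence)
        mutated = seq.copy()
        for pos in positions:
            ref = chr(seq[pos])
            alt = rng.choice([b for b in BASES if b != ref])
            mutated[pos] = ord(alt)
            rows.append((strain_id, int(pos), ref, alt))
        strains.append(SyntheticGenome(strain_id, mutated.tobytes().decode("ascii"), base.taxid))
    snps = pd.DataFrame(rows, columns=["strain_id", "position", "ref", "alt"])
    return strains, snps


def apply_snps(base: SyntheticGenome, snps: pd.DataFrame, strain_id: str) -> str:
    """Replay a SNP truth table onto the base genome (inverse of derive_strains)."""
    seq = bytearray(base.sequence, "ascii")
    for _, row in snps[snps.strain_id == strain_id].iterrows():
        assert chr(seq[row.position]) == row.ref
        seq[row.position] = ord(row.alt)
    return seq.decode("ascii")


def random_barcodes(n: int, rng: np.random.Generator, length: int = BARCODE_LEN,
                    min_dist: int = 3) -> list[str]:
    """Random fixed-length barcodes with pairwise Hamming distance >= min_dist,
    so single-error correction against the whitelist is unambiguous."""
    chosen: list[np.ndarray] = []
    while len(chosen) < n:
        cand = rng.integers(0, 4, size=length)
        if all(int((cand != c).sum()) >= min_dist for c in chosen):
            chosen.append(cand)
    return ["".join(BASES[b] for b in c) for c in chosen]


def _draw_fragment(genome: str, amp_len: int, rng: np.random.Generator) -> str:
    start = int(rng.integers(0, len(genome) - amp_len + 1))
    return genome[start : start + amp_len]


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < error_rate)
    for pos in hits:
        arr[pos] = ord(rng.choice([b for b in BASES if b != chr(arr[pos])]))
    return arr.tobytes().decode("ascii")


def simulate_barcode_groups(
    community: CommunitySpec,
    n_barcodes_per_member: int,
    seed: int,
    read_len: int = READ_LEN,
    amplicon_range: tuple[int, int] = AMPLICON_RANGE,
    reads_range: tuple[int, int] = READS_RANGE,
    contam_range: tuple[float, float] = CONTAM_RANGE,
    error_rate: float = 0.0,
    strain_pools: dict[str, list[SyntheticGenome]] | None = None,
    strain_mixtures: dict[str, np.ndarray] | None = None,
    plasmid_copies: int = PLASMID_COPIES,
    embed_barcode: bool = False,
    adapter: str = DEFAULT_ADAPTER,
    barcode_error_rate: float = 0.0,
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]], pd.DataFrame, list[str]]:
    """Generate paired-end barcode-group reads with a ground-truth table.

    For every community member, ``n_barcodes_per_member`` barcode groups are
    generated. Each group draws a contamination fraction uniformly from
    ``contam_range``; every read pair is independently a contaminant with that
    probability, sourced uniformly from the *other* members. Amplicon lengths
    are uniform over ``amplicon_range`` and starts uniform over the (linear)
    genome; R1 reads the fragment 5' end forward, R2 the 3' end as the reverse
    complement. Read titles encode ``barcode|pair|source_id|origin``.

    ``strain_pools`` optionally replaces a member's chromosome with one of its
    strain genomes per barcode (or a per-barcode mixture via
    ``strain_mixtures``, a member -> probability-vector map).

    With ``embed_barcode=True`` each R1 sequence is prefixed with the cell
    barcode followed by ``adapter`` (the in-read layout the demultiplexer
    parses); ``barcode_error_rate`` is the per-pair probability of a single
    substitution inside the embedded barcode (always within Hamming distance 1
    of the whitelist entry, hence correctable).

    Returns (R1 records, R2 records, truth table, whitelist). Records are
    (title, sequence, quality) triples ready for :func:`taxatlas.dna.write_fastq`.
    """
    if not 0.0 <= contam_range[0] <= contam_range[1] <= 0.49:
        raise ValueError("contamination range must lie within [0, 0.49]")
    if len(community.members) == 1 and contam_range[1] > 0:
        raise ValueError("no contamination source available")
    shortest = min(len(g) for g in community.genomes)
    if amplicon_range[1] > shortest:
        raise ValueError("amplicon_range.max exceeds shortest genome")

    rng = np.random.default_rng(seed)
    genomes = community.genomes
    n_total = len(genomes) * n_barcodes_per_member
    whitelist = random_barcodes(n_total, rng)
    qual_q = 40 if error_rate <= 0 else max(2, round(-10 * np.log10(error_rate)))
    qual_cache: dict[int, str] = {}

    def qual(n: int) -> str:
        if n not in qual_cache:
            qual_cache[n] = chr(qual_q + 33) * n
        return qual_cache[n]

    r1_records: list[tuple[str, str, str]] = []
    r2_records: list[tuple[str, str, str]] = []
    truth_rows = []
    bc_iter = iter(whitelist)

    for member_idx, source in enumerate(genomes):
        others = [g for j, g in enumerate(genomes) if j != member_idx]
        carried_plasmids = []
        for barcode_i in range(n_barcodes_per_member):
            barcode = next(bc_iter)
            n_pairs = int(rng.integers(reads_range[0], reads_range[1] + 1))
            contam_f = float(rng.uniform(contam_range[0], contam_range[1])) \
                if contam_range[1] > contam_range[0] else contam_range[0]

            # resolve this barcode's chromosome: base genome or a strain draw
            strain_id = ""
            chromosome = source.sequence
            if strain_pools and source.seq_id in strain_pools:
                pool = strain_pools[source.seq_id]
                if strain_mixtures and source.seq_id in strain_mixtures:
                    weights = np.asarray(strain_mixtures[source.seq_id], dtype=float)
                    strain_id = "+".join(
                        f"{s.seq_id}:{w:g}" for s, w in zip(pool, weights) if w > 0)
                else:
                    pick = int(rng.integers(0, len(pool)))
                    weights = np.zeros(len(pool))
                    weights[pick] = 1.0
                    strain_id = pool[pick].seq_id

            # plasmid carriage for this barcode
            carried = []
            plasmid_weight = 0.0
            plasmid_seqs: list[tuple[str, str, float]] = []
            for plasmid, hosts, prob in community.plasmids:
                if source.seq_id in hosts and rng.random() < prob:
                    carried.append(plasmid.seq_id)
                    w = plasmid_copies * len(plasmid)
                    plasmid_seqs.append((plasmid.seq_id, plasmid.sequence, w))
            chrom_w = len(chromosome)
            total_w = chrom_w + sum(w for *_, w in plasmid_seqs)

            is_contam = rng.random(n_pairs) < contam_f
            for pair_i in range(n_pairs):
                if is_contam[pair_i]:
                    src = others[int(rng.integers(0, len(others)))]
                    origin, src_id, template = "contam", src.seq_id, src.sequence
                else:
                    u = rng.random() * total_w
                    if u < chrom_w or not plasmid_seqs:
                        origin, src_id = "src", source.seq_id
                        if strain_id and "+" in strain_id:
                            pool = strain_pools[source.seq_id]
                            pick = int(rng.choice(len(pool), p=weights / weights.sum()))
                            template = pool[pick].sequence
                            src_id = pool[pick].seq_id
                        elif strain_id:
                            template = next(s.sequence for s in strain_pools[source.seq_id]
                                            if s.seq_id == strain_id)
                            src_id = strain_id
                        else:
                            template = chromosome
                    else:
                        u -= chrom_w
                        for pid, pseq, w in plasmid_seqs:
                            if u < w:
                                origin, src_id, template = "plasmid", pid, pseq
                                break
                            u -= w
                amp_len = int(rng.integers(amplicon_range[0],
                                           min(amplicon_range[1], len(template)) + 1))
                frag = _draw_fragment(template, amp_len, rng)
                r1 = _mutate(frag[:read_len], error_rate, rng)
                r2 = _mutate(revcomp(frag)[:read_len], error_rate, rng)
                title = f"{barcode}|{pair_i}|{src_id}|{origin}"
                if embed_barcode:
                    bc = barcode
                    if barcode_error_rate > 0 and rng.random() < barcode_error_rate:
                        pos = int(rng.integers(0, len(bc)))
                        alt = rng.choice([b for b in BASES if b != bc[pos]])
                        bc = bc[:pos] + alt + bc[pos + 1 :]
                    r1 = bc + adapter + r1
                r1_records.append((title + "/1", r1, qual(len(r1))))
                r2_records.append((title + "/2", r2, qual(len(r2))))

            truth_rows.append({
                "barcode": barcode,
                "source_id": source.seq_id,
                "strain_id": strain_id,
                "contamination_fraction": contam_f,
                "n_read_pairs": n_pairs,
                "plasmids": ",".join(carried),
            })

    truth = pd.DataFrame(truth_rows)
    return r1_records, r2_records, truth, whitelist


def simulate_contigs(community: CommunitySpec, n_contigs: int,
                     length_range: tuple[int, int], seed: int
                     ) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate metagenomic contigs as verbatim substrings of member genomes.

    Sources are drawn with probability proportional to abundance x genome
    length (long, abundant genomes yield more assembled sequence). Returns
    FASTA-ready (id, seq) records and a truth table contig -> source.
    """
    shortest = min(len(g) for g in community.genomes)
    if length_range[1] > shortest:
        raise ValueError("length_range.max exceeds shortest genome")
    rng = np.random.default_rng(seed)
    weights = community.abundances * np.array([len(g) for g in community.genomes])
    weights = weights / weights.sum()
    records, rows = [], []
    for i in range(n_contigs):
        src = community.genomes[int(rng.choice(len(weights), p=weights))]
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        start = int(rng.integers(0, len(src) - length + 1))
        contig_id = f"contig_{i:05d}"
        records.append((contig_id, src.sequence[start : start + length]))
        rows.append({"contig_id": contig_id, "source_id": src.seq_id,
                     "start": start, "length": length})
    return records, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# convenience builders and file emitters


def make_community(n_members: int, genome_length: int, seed: int, gc: float = 0.5,
                   taxonomy_offset: int = 10) -> tuple[CommunitySpec, TaxonomyDB]:
    """Equal-abundance community of random genomes plus a matching taxonomy.

    Each member gets its own species node under its own genus, so genomes are
    taxonomically disjoint; at genome_length >= a few kb, random sequences
    share essentially no 21-mers.
    """
    from .taxonomy import linear_taxonomy

    genomes = []
    species = {}
    genus_of, genus_names = {}, {}
    for i in range(n_members):
        taxid = taxonomy_offset + i
        g = simulate_genome(genome_length, gc, seed=seed * 100003 + i,
                            seq_id=f"species_{i:02d}", taxid=taxid)
        genomes.append(g)
        species[taxid] = f"species_{i:02d}"
        genus_of[taxid] = taxid + 1000
        genus_names[taxid + 1000] = f"genus_{i:02d}"
    taxonomy = linear_taxonomy(species, genus_of, genus_names)
    community = CommunitySpec([(g, 1.0 / n_members) for g in genomes])
    return community, taxonomy


def write_simulation(out_dir, r1_records, r2_records, truth: pd.DataFrame,
                     whitelist: list[str], gzip_fastq: bool = True) -> dict[str, str]:
    """Write simulator output (FASTQ pair, truth TSV, whitelist) to a directory."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    suffix = ".fastq.gz" if gzip_fastq else ".fastq"
    paths = {
        "r1": str(out / f"reads_R1{suffix}"),
        "r2": str(out / f"reads_R2{suffix}"),
        "truth": str(out / "truth.tsv"),
        "whitelist": str(out / "whitelist.txt"),
    }
    write_fastq(paths["r1"], r1_records)
    write_fastq(paths["r2"], r2_records)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["whitelist"], "w") as fh:
        fh.write("\n".join(whitelist) + "\n")
    return paths


def write_genomes(path, genomes: list[SyntheticGenome]) -> None:
    write_fasta(path, [(g.seq_id, g.sequence) for g in genomes])
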