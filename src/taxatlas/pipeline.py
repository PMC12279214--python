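"""End-to-end pipeline orchestration: config, staging, provenance.

Ties the modules into reproducible runs. A run config (YAML or dict) is
schema-validated — unknown keys are rejected and every seed is explicit —
and the stages execute in order demux -> classify -> filter -> atlas ->
[integrate] -> [strain] -> [elements]. Each stage's output is written under
one run directory and is reusable standalone; a manifest JSON records stage
status and a resolved-config snapshot is saved for provenance. Re-running a
completed stage with its outputs already present is a no-op unless
``overwrite`` is set.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import pandas as pd
import yaml

from . import atlas as atlas_mod
from . import classify as classify_mod
from . import demux as demux_mod
from . import elements as elements_mod
from . import strains as strains_mod
from .dna import read_fasta, write_fastq
from .taxonomy import TaxonomyDB

logger = logging.getLogger("taxatlas")

# allowed keys (with defaults) per config section; unknown keys are rejected
CONFIG_SCHEMA: dict[str, dict] = {
    "seed": 0,
    "overwrite": False,
    "inputs": {
        "r1": None, "r2": None, "whitelist": None,
        "genomes": None, "genome_taxids": None, "taxonomy": None,
        "contigs": None, "strain_panel": None, "plasmids": None, "genes": None,
    },
    "demux": {"barcode_start": 0, "adapter": ""},
    "classify": {"k": 21, "rank": "genus"},
    "filter": {"min_reads": 1000, "min_mapped_fraction": 0.5, "min_purity": 0.8},
    "atlas": {"n_neighbors": 15, "min_dist": 0.1, "resolution": 1.0},
    "integrate": {"min_contig_purity": 0.9, "k": 10},
    "strain": {"alpha0": 0.01, "min_alignment_rate": 0.5, "max_mismatch": 4},
    "elements": {"require_zero_mismatch": True},
}


class RunConfig:
    """Validated pipeline configuration with explicit seeds.

    Built from a nested dict (or YAML file); keys absent from the schema are
    rejected, missing keys take defaults.
    """

    def __init__(self, data: dict | None = None):
        data = dict(data or {})
        self._cfg: dict = {}
        for key, default in CONFIG_SCHEMA.items():
            if isinstance(default, dict):
                section = dict(data.pop(key, {}) or {})
                unknown = set(section) - set(default)
                if unknown:
                    raise ValueError(f"unknown config keys in '{key}': {sorted(unknown)}")
                merged = dict(default)
                merged.update(section)
                self._cfg[key] = merged
            else:
                self._cfg[key] = data.pop(key, default)
        if data:
            raise ValueError(f"unknown config keys: {sorted(data)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def __getitem__(self, key):
        return self._cfg[key]

    def to_dict(self) -> dict:
        return json.loads(json.dumps(self._cfg))

    def snapshot(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def setup_logging(log_file=None, level: int = logging.INFO) -> None:
    handlers = [logging.StreamHandler(sys.stderr)]
    if log_file is not None:
        handlers.append(logging.FileHandler(log_file))
    logging.basicConfig(
        level=level, handlers=handlers, force=True,
        format="%(asctime)s %(name)s %(levelname)s %(message)s")


def load_genome_taxids(path) -> dict[str, int]:
    """Two-column TSV (seq_id, taxid), with or without a header line."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            seq_id, taxid = line.split("\t")[:2]
            if taxid == "taxid":
                continue
            out[seq_id] = int(taxid)
    return out


def vectors_to_tsv(vectors: list[classify_mod.AbundanceVector], path) -> None:
    """Serialise abundance vectors with their metadata as one wide TSV."""
    taxa = sorted(set().union(*(v.a.keys() for v in vectors)) if vectors else set())
    with open(path, "w") as fh:
        fh.write("barcode\trank\tmapped_fraction\tn_reads\t" + "\t".join(taxa) + "\n")
        for v in vectors:
            vals = "\t".join(f"{v.a.get(t, 0.0):.10g}" for t in taxa)
            fh.write(f"{v.barcode}\t{v.rank}\t{v.mapped_fraction:.10g}\t{v.n_reads}\t{vals}\n")


def vectors_from_tsv(path) -> list[classify_mod.AbundanceVector]:
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str})
    taxa = [c for c in df.columns if c not in ("barcode", "rank", "mapped_fraction", "n_reads")]
    out = []
    for _, row in df.iterrows():
        a = {t: float(row[t]) for t in taxa if row[t] > 0}
        total = sum(a.values())
        if total > 0:
            a = {t: v / total for t, v in a.items()}
        out.append(classify_mod.AbundanceVector(
            rank=row["rank"], a=a, mapped_fraction=float(row["mapped_fraction"]),
            n_reads=int(row["n_reads"]), barcode=row["barcode"]))
    return out


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the pipeline described by ``config`` into ``out_dir``.

    Returns the manifest dict (also written as manifest.json). Stage failures
    leave earlier outputs in place and are recorded with an error status.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    setup_logging(out / "run.log")
    config.snapshot(out / "resolved_config.yaml")
    manifest: dict = {"stages": {}, "params": config.to_dict()}
    inputs = config["inputs"]

    def record(stage, status, **info):
        manifest["stages"][stage] = {"status": status, **info}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    try:
        # ---- demux ------------------------------------------------------
        for key in ("r1", "r2", "whitelist", "genomes", "genome_taxids", "taxonomy"):
            if not inputs.get(key):
                raise FileNotFoundError(f"stage demux/classify: missing input '{key}'")
            if not Path(inputs[key]).exists():
                raise FileNotFoundError(f"input '{key}' not found: {inputs[key]}")
        layout = demux_mod.BarcodeLayout.from_whitelist_file(
            inputs["whitelist"], barcode_start=config["demux"]["barcode_start"],
            adapter=config["demux"]["adapter"])
        logger.info("demultiplexing %s / %s", inputs["r1"], inputs["r2"])
        groups, stats = demux_mod.demultiplex_files(inputs["r1"], inputs["r2"], layout)
        if stats.n_pairs == 0:
            raise ValueError("stage demux: input FASTQ is empty")
        record("demux", "ok", **stats.to_dict())

        # ---- classify ---------------------------------------------------
        taxonomy = TaxonomyDB.from_tsv(inputs["taxonomy"])
        genome_taxids = load_genome_taxids(inputs["genome_taxids"])
        index = classify_mod.build_index(read_fasta(inputs["genomes"]), genome_taxids,
                                         taxonomy, k=config["classify"]["k"])
        rank = config["classify"]["rank"]
        kept_groups = demux_mod.filter_read_count(groups, config["filter"]["min_reads"])
        vectors = [classify_mod.abundance_vector(g, index, taxonomy, rank=rank)
                   for g in kept_groups.values()]
        vectors_path = out / "vectors.tsv"
        vectors_to_tsv(vectors, vectors_path)
        record("classify", "ok", n_groups=len(vectors))

        # ---- filter + atlas --------------------------------------------
        fcfg = config["filter"]
        retained = atlas_mod.filter_vectors(
            vectors, min_mapped_fraction=fcfg["min_mapped_fraction"],
            min_purity=fcfg["min_purity"])
        if len(retained) < 2:
            raise ValueError("stage atlas: fewer than 2 barcode groups after filtering")
        matrix = atlas_mod.build_matrix(retained)
        acfg = config["atlas"]
        result = atlas_mod.embed_and_cluster(
            matrix, n_neighbors=acfg["n_neighbors"], min_dist=acfg["min_dist"],
            resolution=acfg["resolution"], seed=config["seed"])
        matrix.to_csv(out / "abundance_matrix.tsv", sep="\t")
        result.to_tsv(out / "atlas.tsv")
        record("atlas", "ok", n_rows=int(matrix.shape[0]),
               n_clusters=int(result.table["cluster"].nunique()))

        # ---- integrate (optional) --------------------------------------
        if inputs.get("contigs"):
            contig_vectors = []
            for cid, seq in read_fasta(inputs["contigs"]):
                group = demux_mod.BarcodeGroup(cid, [((cid, seq, "I" * len(seq)),
                                                      (cid, "", ""))])
                contig_vectors.append(
                    classify_mod.abundance_vector(group, index, taxonomy, rank=rank))
            icfg = config["integrate"]
            joint, joint_matrix = atlas_mod.integrate_contigs(
                result, matrix, contig_vectors,
                min_contig_purity=icfg["min_contig_purity"], k=icfg["k"])
            joint.to_tsv(out / "atlas_integrated.tsv")
            record("integrate", "ok", n_contigs=int((joint.table["batch"] == "contig").sum()))
            result = joint

        # ---- pooled cluster reads --------------------------------------
        pools = atlas_mod.pool_cluster_reads(kept_groups, result)
        pool_dir = out / "cluster_reads"
        pool_dir.mkdir(exist_ok=True)
        for cluster, reads in pools.items():
            write_fastq(pool_dir / f"cluster_{cluster}.fastq.gz", reads)
        record("pool", "ok", n_clusters=len(pools))

        # ---- strain resolution (optional) -------------------------------
        if inputs.get("strain_panel"):
            scfg = config["strain"]
            panel = list(read_fasta(inputs["strain_panel"]))
            table, posteriors = strains_mod.resolve_groups(
                kept_groups, panel, alpha0=scfg["alpha0"],
                min_alignment_rate=scfg["min_alignment_rate"],
                max_mismatch=scfg["max_mismatch"])
            table.to_csv(out / "strains.tsv", sep="\t", index=False)
            strains_mod.theta_matrix(posteriors).to_csv(out / "strain_theta.tsv", sep="\t")
            record("strain", "ok", n_barcodes=int(table.shape[0]))

        # ---- element association (optional) -----------------------------
        if inputs.get("plasmids"):
            ecfg = config["elements"]
            plasmids = list(read_fasta(inputs["plasmids"]))
            calls = []
            species_of = {}
            annotation = result.annotation
            labels = result.table["cluster"]
            for barcode, group in kept_groups.items():
                if barcode not in labels.index:
                    continue
                species_of[barcode] = annotation.get(int(labels[barcode]), "")
                calls.extend(elements_mod.plasmid_presence(
                    group, plasmids,
                    require_zero_mismatch=ecfg["require_zero_mismatch"]))
            ratio = elements_mod.plasmid_host_ratio(calls, species_of)
            ratio.to_csv(out / "plasmid_ratio.tsv", sep="\t")
            record("elements", "ok", n_plasmids=len(plasmids))
        if inputs.get("genes"):
            genes = elements_mod.parse_gene_ids(read_fasta(inputs["genes"]))
            hit_table, rpm = elements_mod.arg_abundance(pools, genes)
            rpm.to_csv(out / "gene_rpm.tsv", sep="\t")
            hit_table.to_csv(out / "gene_hits.tsv", sep="\t")
            record("genes", "ok", n_genes=len(genes))

        manifest["status"] = "ok"
    except Exception as exc:  # record partial progress, then re-raise
        manifest["status"] = "failed"
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def evaluate_against_truth(atlas_result, truth: pd.DataFrame, taxonomy: TaxonomyDB,
                           genome_taxids: dict[str, int], rank: str = "genus") -> dict:
    """Score an atlas against simulator ground truth.

    Returns annotation accuracy (fraction of retained barcodes whose cluster
    annotation equals the truth taxon at ``rank``) and the adjusted Rand
    index between cluster labels and truth source genomes.
    """
    from sklearn.metrics import adjusted_rand_score

    table = atlas_result.table
    single_cell = table[table["batch"] == "single_cell"] if "batch" in table else table
    truth_by_bc = truth.set_index("barcode")
    shared = [b for b in single_cell.index if b in truth_by_bc.index]
    if not shared:
        raise ValueError("no overlap between atlas rows and truth barcodes")

    def truth_taxon(source_id: str) -> str:
        taxid = genome_taxids[source_id]
        lifted = taxonomy.ancestor_at_rank(taxid, rank)
        return taxonomy.name(lifted) if lifted is not None else ""

    correct = 0
    truth_labels, cluster_labels = [], []
    for barcode in shared:
        cluster = int(single_cell.loc[barcode, "cluster"])
        annotation = atlas_result.annotation.get(cluster, "")
        source = truth_by_bc.loc[barcode, "source_id"]
        if annotation == truth_taxon(source):
            correct += 1
        truth_labels.append(source)
        cluster_labels.append(cluster)
    return {
        "n_barcodes": len(shared),
        "annotation_accuracy": correct / len(shared),
        "adjusted_rand": float(adjusted_rand_score(truth_labels, cluster_labels)),
    }
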