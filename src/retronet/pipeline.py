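"""End-to-end runs: SSN classification and LTR proliferation dynamics.

``run_classify`` wires aligned RT proteins + taxonomy into distances, the
similarity network, MC/CC partitions, an NJ tree with a branch-cut
partition, and a cluster report.  ``run_dynamics`` wires element sequences
into LTR detection, a divergence profile and an activity call.  Every run
writes a manifest with SHA-256 checksums of its outputs and a JSON echo of
the resolved configuration, so identical config + seed reproduces identical
bytes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

from . import io as rio
from .distances import distance_matrix
from .exceptions import RetronetError
from .ltr import detect_all, divergence_profile, infer_activity
from .phylo import nj_tree, taxonomy_from_tree
from .ssn import Partition, build_ssn, cluster_report, connected_components, louvain_cluster

logger = logging.getLogger("retronet")


@dataclass
class RunConfig:
    """Resolved parameters of a pipeline run; echoed to JSON in the outdir."""

    outdir: str = "retronet_out"
    alignment: str | None = None
    taxonomy: str | None = None
    elements: str | None = None
    model: str = "poisson"
    tau: float = 0.666
    w_cap: float = 1000.0
    weighted: bool = True
    rand_variant: str = "adjusted"
    seed: int = 0
    n_restarts: int = 8
    tree_cut: float = 1.0
    ltr_min_len: int = 100
    ltr_max_len: int = 1000
    ltr_seed_k: int = 20
    ltr_min_identity: float = 0.80
    bin_width: float = 0.01
    recent_cutoff: float = 0.01
    min_recent_fraction: float = 0.05

    def validate(self) -> None:
        if self.model not in ("p", "poisson", "k2p"):
            raise RetronetError(f"unknown distance model {self.model!r}")
        if self.tau <= 0 or self.w_cap <= 0 or self.tree_cut <= 0:
            raise RetronetError("tau, w_cap and tree_cut must be positive")
        if self.rand_variant not in ("adjusted", "unadjusted", "both"):
            raise RetronetError(f"unknown rand variant {self.rand_variant!r}")


def _setup_logging(outdir: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (logging.StreamHandler(sys.stderr), logging.FileHandler(outdir / "run.log")):
        handler.setFormatter(fmt)
        logger.addHandler(handler)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _finalize(outdir: Path, config: RunConfig, outputs: list[Path]) -> dict:
    manifest = {
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    (outdir / "config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2) + "\n"
    )
    return manifest


def run_classify(config: RunConfig) -> dict:
    """SSN classification: distances -> network -> MC/CC -> report + NJ tree."""
    config.validate()
    for name in ("alignment", "taxonomy"):
        path = getattr(config, name)
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"{name} file not found: {path}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    logger.info(
        "classify: model=%s tau=%s seed=%d restarts=%d",
        config.model, config.tau, config.seed, config.n_restarts,
    )
    aln = rio.read_fasta(config.alignment, alphabet="protein")
    taxonomy = rio.read_taxonomy(config.taxonomy)

    dm = distance_matrix(aln, model=config.model)
    if dm.undefined_pairs:
        logger.warning("%d undefined distance pair(s)", len(dm.undefined_pairs))
    rio.write_phylip_matrix(dm, outdir / "distances.phylip")

    g = build_ssn(dm, tau=config.tau, w_cap=config.w_cap)
    rio.write_edge_list(g, outdir / "edges.tsv")
    logger.info("SSN: %d nodes, %d edges", g.number_of_nodes(), g.number_of_edges())

    cc = connected_components(g)
    mc = louvain_cluster(
        g, seed=config.seed, weighted=config.weighted, n_restarts=config.n_restarts
    )
    rio.write_partition(cc, outdir / "partition_cc.tsv")
    rio.write_partition(mc, outdir / "partition_mc.tsv")

    tree = nj_tree(dm)
    rio.write_newick(tree, outdir / "tree.nwk")
    tree_part = taxonomy_from_tree(tree, cut=config.tree_cut)
    rio.write_partition(tree_part, outdir / "partition_tree.tsv")

    report, contingency = cluster_report(
        g, [mc, cc, tree_part], taxonomy, weighted=config.weighted
    )
    report.to_csv(outdir / "cluster_report.tsv", sep="\t", index=False)
    contingency.to_csv(outdir / "contingency_mc.tsv", sep="\t")
    for _, row in report.iterrows():
        logger.info(
            "%s: %d clusters, rand_adjusted=%.4f rand_unadjusted=%.4f",
            row["method"], row["n_clusters"], row["rand_adjusted"], row["rand_unadjusted"],
        )
    outputs = [
        outdir / name
        for name in (
            "distances.phylip", "edges.tsv", "partition_cc.tsv", "partition_mc.tsv",
            "tree.nwk", "partition_tree.tsv", "cluster_report.tsv", "contingency_mc.tsv",
        )
    ]
    manifest = _finalize(outdir, config, outputs)
    return {"report": report, "contingency": contingency, "manifest": manifest,
            "mc": mc, "cc": cc, "tree_partition": tree_part, "graph": g}


def run_dynamics(config: RunConfig) -> dict:
    """LTR dynamics: detect pairs -> divergence profile -> activity call."""
    config.validate()
    if config.elements is None or not Path(config.elements).exists():
        raise FileNotFoundError(f"elements file not found: {config.elements}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    logger.info("dynamics: detector k=%d min_identity=%.2f", config.ltr_seed_k, config.ltr_min_identity)
    elements = rio.read_fasta(config.elements, alphabet="nucleotide")
    records = detect_all(
        elements,
        min_len=config.ltr_min_len,
        max_len=config.ltr_max_len,
        seed_k=config.ltr_seed_k,
        min_identity=config.ltr_min_identity,
    )
    logger.info("detected LTR pairs in %d / %d elements", len(records), len(elements))
    if not records:
        raise RetronetError("no LTR pairs detected")
    rio.write_gff3(records, outdir / "ltr_features.gff3")
    with open(outdir / "ltr_divergence.tsv", "w") as fh:
        fh.write(
            "element\tltr5_start\tltr5_end\tltr3_start\tltr3_end\t"
            "length\tidentity\tP\tQ\tk2p\tsaturated\n"
        )
        for r in records:
            k2p = "NA" if r.k2p is None else f"{r.k2p:.6f}"
            fh.write(
                f"{r.element_id}\t{r.ltr5[0]}\t{r.ltr5[1]}\t{r.ltr3[0]}\t{r.ltr3[1]}\t"
                f"{r.ltr_length}\t{r.identity:.6f}\t{r.P:.6f}\t{r.Q:.6f}\t{k2p}\t"
                f"{int(r.saturated)}\n"
            )
    hist, summary = divergence_profile(
        records, bin_width=config.bin_width, recent_cutoff=config.recent_cutoff
    )
    hist.to_csv(outdir / "ltr_histogram.tsv", sep="\t", index=False)
    activity = infer_activity(
        records,
        recent_cutoff=config.recent_cutoff,
        min_recent_fraction=config.min_recent_fraction,
    )
    (outdir / "activity.json").write_text(json.dumps({**summary, **activity}, indent=2) + "\n")
    logger.info(
        "activity=%s recent_fraction=%.3f (n=%d, saturated=%d)",
        activity["call"], activity["recent_fraction"], summary["n"], summary["n_saturated"],
    )
    outputs = [
        outdir / name
        for name in ("ltr_features.gff3", "ltr_divergence.tsv", "ltr_histogram.tsv", "activity.json")
    ]
    manifest = _finalize(outdir, config, outputs)
    return {"records": records, "histogram": hist, "summary": summary,
            "activity": activity, "manifest": manifest}
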