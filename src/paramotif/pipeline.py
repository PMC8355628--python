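"""End-to-end pipeline: motifs -> scan -> filter -> cluster -> annotate [-> phase]."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

from . import annotate as ann
from . import io as pio
from .cluster import clusters_to_tsv, collapse_profiles, greedy_cluster
from .config import RunConfig
from .filters import apply_filters
from .phase import build_allele_matrix, cluster_haplotypes, emit_phased_vcf
from .refs import find_motifs, motifs_to_tsv
from .scan import profile_read, profiles_to_tsv

logger = logging.getLogger("paramotif")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def run_pipeline(
    config: RunConfig,
    gene_fa: str,
    pseudo_fa: str,
    reads_path: str,
    outdir: str,
    sites=None,
    breakpoint_table: Sequence = (),
) -> dict:
    """Run every stage in order, writing the report bundle into ``outdir``.

    Emits motifs.tsv, profiles.tsv, clusters.tsv, calls.tsv, summary.json and
    (when variant ``sites`` are supplied) one phased VCF per strong
    normal-gene cluster.  Returns the summary dictionary.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    prov = pio.provenance_lines(
        config, {"gene": gene_fa, "pseudo": pseudo_fa, "reads": reads_path}
    )

    # stage: motifs
    try:
        pair = pio.load_reference_pair(gene_fa, pseudo_fa)
        motifs = find_motifs(pair, k=config.k, min_identity=config.min_identity)
    except Exception as exc:
        raise StageError("motifs", str(exc)) from exc
    with open(out / "motifs.tsv", "w") as fh:
        motifs_to_tsv(motifs, fh, prov)
    logger.info("motifs: %d gene, %d pseudogene", len(motifs.gene), len(motifs.pseudo))
    if not motifs.gene and not motifs.pseudo:
        raise StageError(
            "scan",
            "motif set is empty: the references are identical or share every "
            "candidate k-mer; nothing can be scanned",
        )

    # stage: scan
    params = config.scan_params()
    reads = {}
    profiles = []
    try:
        for rec in pio.read_reads(reads_path):
            reads[rec.id] = rec.seq
            profiles.append(profile_read(rec.id, rec.seq, rec.quals, motifs, params))
    except ValueError as exc:
        raise StageError("scan", str(exc)) from exc
    with open(out / "profiles.tsv", "w") as fh:
        profiles_to_tsv(profiles, fh, prov)

    # stage: filter
    kept, report = apply_filters(
        profiles, motifs.k, config.max_palindrome_frac, config.max_unexplained_frac
    )
    for rid, reason in report.decisions.items():
        logger.debug("filter %s -> %s", rid, reason)
    logger.info("filter: %s", report.as_dict())

    # stage: cluster
    table = collapse_profiles(kept)
    if len(table) == 0:
        raise StageError("cluster", "no reads survived filtering")
    cluster_set = greedy_cluster(
        table,
        alpha=config.alpha,
        beta=config.beta,
        beta_basis=config.beta_basis,
        min_reads=config.min_reads,
    )
    with open(out / "clusters.tsv", "w") as fh:
        clusters_to_tsv(cluster_set, fh, prov)

    # stage: annotate
    calls = ann.annotate_clusters(
        cluster_set,
        total_copies=config.total_copies,
        breakpoint_table=breakpoint_table,
        pcr_chimera_frac=config.pcr_chimera_frac,
        vaf_tol=config.vaf_tol,
    )
    with open(out / "calls.tsv", "w") as fh:
        ann.calls_to_tsv(calls, fh, prov)

    # stage: phase (optional)
    phased_files = []
    if sites:
        assignments = cluster_set.read_assignments()
        for call in calls:
            if call.category != ann.CATEGORY_NORMAL_GENE or "weak" in call.flags:
                continue
            members = [p for p in kept if assignments.get(p.read_id) == call.cluster_id]
            if len(members) < 2:
                continue
            matrix = build_allele_matrix(
                reads, members, pair.gene_seq, sites, motifs, window=config.phase_window
            )
            try:
                labels, consensus = cluster_haplotypes(matrix, config.n_haplotypes)
            except ValueError as exc:
                logger.warning("phase: cluster %d skipped (%s)", call.cluster_id, exc)
                continue
            vcf_path = out / f"phased_cluster{call.cluster_id}.vcf"
            with open(vcf_path, "w") as fh:
                emit_phased_vcf(
                    consensus, sites, pair.gene_name, len(pair.gene_seq), fh,
                    phase_set=call.cluster_id, provenance=prov,
                )
            phased_files.append(str(vcf_path))

    summary = {
        "provenance": prov,
        "config": json.loads(config.to_json()),
        "n_motifs": {"gene": len(motifs.gene), "pseudo": len(motifs.pseudo)},
        "filters": report.as_dict(),
        "clusters": [
            {
                "cluster_id": c.cluster_id,
                "category": c.category,
                "n_reads": c.n_reads,
                "copy_number": c.copy_number,
                "chimera_label": c.chimera_label,
                "flags": c.flags,
            }
            for c in calls
        ],
        "phased_vcfs": phased_files,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
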