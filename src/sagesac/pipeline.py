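"""End-to-end pipeline orchestration with a reproducible run manifest.

Stages communicate through plain text files in the output directory, so
each stage is resumable: when a stage's recorded input and output
checksums match the files on disk it is skipped.  The manifest
(``manifest.json``) records the config hash, seed, per-stage checksums and
summary statistics; two runs with identical config and inputs are
byte-identical.

Stage order: simulate (optional) -> build-ref -> preprocess -> count ->
qc (drop flagged samples) -> normalize/filter -> de -> cluster ->
separate -> subset-de.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from typing import Callable, Optional

import numpy as np
import pandas as pd

from . import (
    cell_type_separation,
    differential_expression as de,
    normalization,
    qc_outliers,
    read_processing,
    synthetic_data,
    tag_alignment,
    tag_reference,
    temporal_clustering,
)

logger = logging.getLogger("sagesac.pipeline")

DEFAULT_PARAMS = {
    "motif": "CATG",
    "tag_length": 23,
    "min_mean_q": 20.0,
    "max_mismatches": 2,
    "max_mismatch_qual_sum": 70,
    "max_hits": 10,
    "min_mean": 8.0,
    "fdr": 0.05,
    "contrast_fdr": 0.10,
    "cuts": [3, 8, 21],
    "pca_components": 2,
    "z_cut": 3.0,
    "marker_fraction": 0.5,   # fraction of true erythroid genes exposed as markers
    "marker_seed_offset": 97,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


class Runner:
    """Executes stages, tracking checksums and skipping cached stages."""

    def __init__(self, outdir: str, config: dict, resume: bool = True):
        self.outdir = outdir
        os.makedirs(outdir, exist_ok=True)
        self.manifest_path = os.path.join(outdir, "manifest.json")
        self.config = config
        self.manifest = {
            "config_hash": _config_hash(config),
            "seed": config.get("seed", 0),
            "stages": {},
        }
        self.previous = None
        if resume and os.path.exists(self.manifest_path):
            with open(self.manifest_path) as fh:
                prev = json.load(fh)
            if prev.get("config_hash") == self.manifest["config_hash"]:
                self.previous = prev

    def path(self, name: str) -> str:
        return os.path.join(self.outdir, name)

    def _cached(self, stage: str, inputs: list[str], outputs: list[str]):
        if self.previous is None:
            return None
        rec = self.previous.get("stages", {}).get(stage)
        if rec is None:
            return None
        try:
            if rec["inputs"] != {p: _sha256(p) for p in inputs}:
                return None
            if rec["outputs"] != {p: _sha256(p) for p in outputs}:
                return None
        except FileNotFoundError:
            return None
        return rec

    def stage(
        self,
        name: str,
        inputs: list[str],
        outputs: list[str],
        fn: Callable[[], dict],
    ) -> dict:
        rec = self._cached(name, inputs, outputs)
        if rec is not None:
            logger.info("stage %s: cached, skipping", name)
            self.manifest["stages"][name] = rec
            return rec.get("stats", {})
        logger.info("stage %s: running", name)
        try:
            stats = fn() or {}
        except PipelineError:
            raise
        except Exception as exc:  # tag the failing stage
            raise PipelineError(name, str(exc)) from exc
        missing = [p for p in outputs if not os.path.exists(p)]
        if missing:
            raise PipelineError(name, f"missing declared outputs: {missing}")
        self.manifest["stages"][name] = {
            "inputs": {p: _sha256(p) for p in inputs},
            "outputs": {p: _sha256(p) for p in outputs},
            "stats": stats,
        }
        return stats

    def write_manifest(self) -> None:
        with open(self.manifest_path, "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_pipeline(config: dict, outdir: str, resume: bool = True) -> dict:
    """Run the full pipeline; returns the manifest dict.

    ``config`` keys: ``seed``; either ``simulate`` (SimulationConfig
    fields) or ``inputs`` (``fasta``, ``metadata``, ``fastq_dir``);
    ``params`` overriding :data:`DEFAULT_PARAMS`; optional ``markers`` (path
    to a one-column erythroid marker list; for simulated runs a marker list
    is drawn from the planted truth instead).
    """
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    seed = int(config.get("seed", 0))
    runner = Runner(outdir, config, resume=resume)
    P = runner.path

    # -- stage: simulate (optional) -----------------------------------------
    if "simulate" in config:
        sim_cfg = synthetic_data.SimulationConfig(
            **{**config["simulate"], "seed": seed}
        )
        sample_ids = sim_cfg.sample_ids()
        sim_outputs = [P("ref.fa"), P("samples.tsv"), P("truth.tsv"),
                       P("true_counts.tsv"), P("expected_statuses.tsv")] + [
                           P(f"{s}.fq") for s in sample_ids]

        def _simulate():
            ds = synthetic_data.simulate_dataset(sim_cfg)
            synthetic_data.write_dataset(ds, outdir)
            expected = ds.expected_statuses
            expected.to_csv(P("expected_statuses.tsv"), sep="\t")
            return {
                "n_genes": sim_cfg.n_genes,
                "n_retained": len(ds.reference.retained_genes),
                "reads": int(sum(len(r) for r in ds.reads.values())),
            }

        runner.stage("simulate", [], sim_outputs, _simulate)
        fasta, meta_path = P("ref.fa"), P("samples.tsv")
        fastq_of = {s: P(f"{s}.fq") for s in sample_ids}
    else:
        inputs = config.get("inputs")
        if not inputs:
            raise PipelineError("setup", "config needs 'simulate' or 'inputs'")
        fasta, meta_path = inputs["fasta"], inputs["metadata"]
        for p in (fasta, meta_path):
            if not os.path.exists(p):
                raise PipelineError("setup", f"missing input file {p}")
        meta = tag_alignment.read_sample_metadata(meta_path)
        fastq_of = {
            s: os.path.join(inputs["fastq_dir"], f"{s}.fq") for s in meta.index
        }
        missing = [p for p in fastq_of.values() if not os.path.exists(p)]
        if missing:
            raise PipelineError("setup", f"missing FASTQ file(s): {missing}")

    metadata = tag_alignment.read_sample_metadata(meta_path)
    sample_ids = list(metadata.index)

    # -- stage: build-ref ----------------------------------------------------
    def _build_ref():
        ref = tag_reference.build_from_fasta(
            fasta, motif=params["motif"], tag_length=params["tag_length"]
        )
        ref.to_tsv(P("ref.tags.tsv"))
        return {"status_counts": ref.status_counts()}

    runner.stage("build_ref", [fasta], [P("ref.tags.tsv")], _build_ref)

    # -- stage: preprocess ---------------------------------------------------
    trimmed_of = {s: P(f"{s}.trimmed.fq") for s in sample_ids}

    def _preprocess():
        stats = {}
        for s in sample_ids:
            reads = read_processing.read_fastq(fastq_of[s])
            kept, st = read_processing.preprocess(
                reads, target_length=params["tag_length"],
                min_mean_q=params["min_mean_q"],
            )
            read_processing.write_fastq(kept, trimmed_of[s])
            stats[s] = st
        return stats

    runner.stage(
        "preprocess", list(fastq_of.values()), list(trimmed_of.values()), _preprocess
    )

    # -- stage: count --------------------------------------------------------
    def _count():
        ref = tag_reference.TagReference.from_tsv(P("ref.tags.tsv"))
        matcher = tag_alignment.TagMatcher.from_reference(ref)
        assignments = {}
        for s in sample_ids:
            reads = read_processing.read_fastq(trimmed_of[s])
            assignments[s] = matcher.match_all(
                reads,
                max_mismatches=params["max_mismatches"],
                max_mismatch_qual_sum=params["max_mismatch_qual_sum"],
                max_hits=params["max_hits"],
            )
        cm, stats = tag_alignment.count_assignments(
            assignments, metadata, ref.retained_genes
        )
        cm.to_tsv(P("counts.tsv"))
        with open(P("mapping_stats.json"), "w") as fh:
            json.dump(stats, fh, indent=2, sort_keys=True)
        return stats

    runner.stage(
        "count",
        [P("ref.tags.tsv"), meta_path] + list(trimmed_of.values()),
        [P("counts.tsv"), P("mapping_stats.json")],
        _count,
    )

    # -- stage: qc -----------------------------------------------------------
    def _qc():
        cm = tag_alignment.CountMatrix.from_tsv(P("counts.tsv"), meta_path)
        norm = normalization.normalize(cm)
        scores, flagged = qc_outliers.screen_outliers(
            norm.values, cm.metadata,
            k=params["pca_components"], z_cut=params["z_cut"],
        )
        scores.to_csv(P("qc_scores.tsv"), sep="\t", index_label="sample_id")
        kept = cm.drop_samples(flagged)
        kept.to_tsv(P("counts.qc.tsv"))
        kept.metadata.reset_index().to_csv(P("samples.qc.tsv"), sep="\t", index=False)
        return {"flagged": flagged, "samples_kept": len(kept.samples)}

    runner.stage(
        "qc", [P("counts.tsv"), meta_path],
        [P("qc_scores.tsv"), P("counts.qc.tsv"), P("samples.qc.tsv")], _qc,
    )

    def _load_qc_counts():
        return tag_alignment.CountMatrix.from_tsv(P("counts.qc.tsv"), P("samples.qc.tsv"))

    # -- stage: normalize ----------------------------------------------------
    def _normalize():
        cm = _load_qc_counts()
        norm = normalization.normalize(cm)
        norm.values.to_csv(P("normalized.tsv"), sep="\t", index_label="gene_id")
        norm.norm_counts.to_csv(P("norm_counts.tsv"), sep="\t", index_label="gene_id")
        norm.scale_factors.to_frame().to_csv(
            P("scale_factors.tsv"), sep="\t", index_label="sample_id"
        )
        retained = normalization.low_count_filter(
            norm.norm_counts, threshold=params["min_mean"]
        )
        with open(P("retained_genes.txt"), "w") as fh:
            fh.writelines(f"{g}\n" for g in retained)
        return {
            "genes_total": len(norm.genes),
            "genes_retained": len(retained),
        }

    runner.stage(
        "normalize", [P("counts.qc.tsv")],
        [P("normalized.tsv"), P("norm_counts.tsv"), P("scale_factors.tsv"),
         P("retained_genes.txt")],
        _normalize,
    )

    # -- stage: de -----------------------------------------------------------
    def _de():
        cm = _load_qc_counts()
        factors = pd.read_csv(P("scale_factors.tsv"), sep="\t", index_col=0)[
            "scale_factor"
        ]
        retained = [l.strip() for l in open(P("retained_genes.txt")) if l.strip()]
        table = de.run_de(
            cm, factors, genes=retained,
            fdr=params["fdr"], contrast_fdr=params["contrast_fdr"],
        )
        table.to_csv(P("de_results.tsv"), sep="\t")
        return {
            "genes_tested": len(table),
            "significant": int(table["significant"].sum()),
        }

    runner.stage(
        "de",
        [P("counts.qc.tsv"), P("scale_factors.tsv"), P("retained_genes.txt")],
        [P("de_results.tsv")],
        _de,
    )

    # -- stage: cluster ------------------------------------------------------
    def _cluster():
        values = pd.read_csv(P("normalized.tsv"), sep="\t", index_col="gene_id")
        meta = tag_alignment.read_sample_metadata(P("samples.qc.tsv"))
        table = pd.read_csv(P("de_results.tsv"), sep="\t", index_col="gene_id")
        sig = table.index[table["significant"].fillna(False)]
        cuts = tuple(params["cuts"])
        if len(sig) < max(cuts):
            raise PipelineError(
                "cluster",
                f"only {len(sig)} significant genes; need >= {max(cuts)}",
            )
        profiles = temporal_clustering.day_mean_profiles(values, meta, genes=sig)
        z, constant = temporal_clustering.standardize_profiles(profiles)
        assignment = temporal_clustering.hierarchical_cluster(z, cuts=cuts)
        temporal_clustering.assert_nested(assignment)
        profiles.to_csv(P("profiles.tsv"), sep="\t", index_label="gene_id")
        z.to_csv(P("zprofiles.tsv"), sep="\t", index_label="gene_id")
        assignment.labels.to_csv(P("clusters.tsv"), sep="\t", index_label="gene_id")
        with open(P("dendrogram.nwk"), "w") as fh:
            fh.write(temporal_clustering.to_newick(assignment) + "\n")
        temporal_clustering.export_cluster_lists(assignment, P("cluster_lists"))
        return {"genes_clustered": len(z), "constant_profiles": int(constant.sum())}

    runner.stage(
        "cluster",
        [P("normalized.tsv"), P("samples.qc.tsv"), P("de_results.tsv")],
        [P("profiles.tsv"), P("zprofiles.tsv"), P("clusters.tsv"),
         P("dendrogram.nwk")],
        _cluster,
    )

    # -- stage: separate -----------------------------------------------------
    def _markers() -> list[str]:
        if "markers" in config and config["markers"]:
            with open(config["markers"]) as fh:
                return [l.strip() for l in fh if l.strip()]
        if "simulate" in config:
            # Emulate partial marker knowledge (GO-style): a seeded random
            # subset of the planted erythroid genes.
            truth = pd.read_csv(P("truth.tsv"), sep="\t", index_col="gene_id")
            ery = list(truth.index[truth["class"] == "erythroid"])
            rng = np.random.default_rng(seed + params["marker_seed_offset"])
            k = max(1, int(round(params["marker_fraction"] * len(ery))))
            return sorted(rng.choice(ery, size=k, replace=False)) if ery else []
        return []

    def _separate():
        labels = pd.read_csv(P("clusters.tsv"), sep="\t", index_col="gene_id")
        cuts = tuple(params["cuts"])
        assignment = temporal_clustering.ClusterAssignment(
            labels, np.empty((0, 4)), cuts
        )
        markers = _markers()
        with open(P("markers.txt"), "w") as fh:
            fh.writelines(f"{m}\n" for m in markers)
        partition = cell_type_separation.classify_genes(assignment, markers)
        partition.classes.to_frame().to_csv(
            P("partition.tsv"), sep="\t", index_label="gene_id"
        )
        partition.cluster_evidence.to_csv(P("partition_evidence.tsv"), sep="\t")
        return {
            "epithelial": len(partition.epithelial_genes),
            "erythropoietic": len(partition.erythropoietic_genes),
            "n_markers": len(markers),
        }

    runner.stage(
        "separate", [P("clusters.tsv")],
        [P("partition.tsv"), P("partition_evidence.tsv"), P("markers.txt")],
        _separate,
    )

    # -- stage: subset-de ----------------------------------------------------
    def _subset_de():
        cm = _load_qc_counts()
        partition = pd.read_csv(P("partition.tsv"), sep="\t", index_col="gene_id")
        epithelial = [
            g for g in partition.index[partition["class"] == "epithelial"]
        ]
        subset_norm = cell_type_separation.renormalize_subset(cm, epithelial)
        subset_norm.values.to_csv(
            P("subset_normalized.tsv"), sep="\t", index_label="gene_id"
        )
        table = de.run_de(
            cm.subset_genes(epithelial), subset_norm.scale_factors,
            fdr=params["fdr"], contrast_fdr=params["contrast_fdr"],
        )
        table.to_csv(P("subset_de_results.tsv"), sep="\t")
        sig_cols = [c for c in table.columns if c.startswith("sig_")]
        return {
            "genes": len(table),
            "contrast_significant": {
                c: int(table[c].sum()) for c in sig_cols
            },
        }

    runner.stage(
        "subset_de", [P("counts.qc.tsv"), P("partition.tsv")],
        [P("subset_normalized.tsv"), P("subset_de_results.tsv")],
        _subset_de,
    )

    runner.write_manifest()
    return runner.manifest
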