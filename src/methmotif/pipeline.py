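"""End-to-end pipeline: selection → discovery → annotation → clustering →
TF matching → regulation analysis.

The pipeline reads a directory of inputs (as produced by
``methmotif simulate`` or assembled from real data in the same formats),
runs each stage, writes per-stage TSV/Newick/JSON outputs into a run
directory and records a manifest with parameters, per-stage row counts and
content checksums.  Given the same inputs and seed, reruns are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as mio
from .clustering import hierarchical_cluster, linkage_to_newick, motif_distance_matrix
from .discovery import discover_motifs
from .motif_stats import direction_enrichment, genomic_distribution, motif_cpg_set
from .records import CGI_REGIONS, CpGRecord, GENE_REGIONS
from .regulation import regulation_calls, summarize_contingency, wilcoxon_de
from .selection import compute_variance, select_by_percentile, split_idmc
from .tfbs import scan_database

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    input_dir: str
    out_dir: str
    mode: str = "cancer-idmc"  # or "normal-tissue"
    low_pct: float = 1.0
    high_pct: float = 99.0
    min_len: int = 3
    max_len: int = 8
    e_threshold: float = 0.05
    max_rounds: int = 10
    n_seeds: int = 100
    direction_threshold: float = 0.70
    alpha: float = 0.05
    min_overlap: int = 5
    e_max: float = 10.0
    n_shuffles: int = 1000
    linkage_method: str = "average"
    cut_height: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("cancer-idmc", "normal-tissue"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 < self.e_threshold:
            raise ValueError("e_threshold must be positive")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_motif_results(results, path) -> None:
    rows = [
        (
            r.consensus,
            len(r.motif),
            r.pos_with,
            r.pos_total,
            r.neg_with,
            r.neg_total,
            f"{r.fisher_p:.6g}",
            f"{r.e_value:.6g}",
            r.n_candidates,
            r.iteration,
        )
        for r in results
    ]
    pd.DataFrame(
        rows,
        columns=[
            "consensus",
            "length",
            "pos_with",
            "pos_total",
            "neg_with",
            "neg_total",
            "fisher_p",
            "e_value",
            "n_candidates",
            "round",
        ],
    ).to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written as JSON)."""
    indir = Path(config.input_dir)
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": dataclasses.asdict(config),
        "stages": [],
        "outputs": {},
    }
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    def stage_done(name: str, **counts) -> None:
        logger.info("stage %s done: %s", name, counts)
        manifest["stages"].append({"name": name, "counts": counts})

    try:
        flanks = mio.read_fasta(indir / "flanks.fa")
        annotation = mio.read_annotation_tsv(indir / "annotation.tsv")
        records = [
            CpGRecord(
                cpg_id=cid,
                sequence=seq,
                gene_regions=tuple(annotation.at[cid, "gene_regions"])
                if cid in annotation.index
                else (),
                cgi_region=annotation.at[cid, "cgi_region"]
                if cid in annotation.index
                else "OpenSea",
            )
            for cid, seq in flanks.items()
        ]

        # ---- stage 1: CpG set selection ----------------------------------
        hyper_ids: frozenset[str] = frozenset()
        hypo_ids: frozenset[str] = frozenset()
        if config.mode == "cancer-idmc":
            idmc = mio.read_idmc_tsv(indir / "idmc.tsv")
            hyper_sel, hypo_sel, all_sel = split_idmc(idmc, background=set(flanks))
            hyper_ids, hypo_ids = hyper_sel.members, hypo_sel.members
            selections = {"hyper_idmc": hyper_sel, "hypo_idmc": hypo_sel}
            discovery_sets = {"idmc_all": all_sel}
            stage_done(
                "select",
                n_hyper=len(hyper_ids),
                n_hypo=len(hypo_ids),
                n_background=len(flanks),
            )
        else:
            beta = mio.read_beta_tsv(indir / "beta.tsv")
            variances = compute_variance(beta)
            stable_sel, unstable_sel = select_by_percentile(
                variances, config.low_pct, config.high_pct
            )
            selections = {"stable": stable_sel, "unstable": unstable_sel}
            discovery_sets = selections
            stage_done(
                "select",
                n_stable=len(stable_sel.members),
                n_unstable=len(unstable_sel.members),
                n_background=len(variances),
            )
        sel_rows = [
            (kind, cpg)
            for kind, sel in sorted(selections.items())
            for cpg in sorted(sel.members)
        ]
        pd.DataFrame(sel_rows, columns=["kind", "cpg_id"]).to_csv(
            outdir / "selections.tsv", sep="\t", index=False
        )

        # ---- stage 2: motif discovery ------------------------------------
        all_results = []
        for set_name, sel in sorted(discovery_sets.items()):
            positives = {cid: flanks[cid] for cid in sorted(sel.members) if cid in flanks}
            bg = {cid: flanks[cid] for cid in sorted(sel.background) if cid in flanks}
            results = discover_motifs(
                positives,
                bg,
                min_len=config.min_len,
                max_len=config.max_len,
                e_threshold=config.e_threshold,
                max_rounds=config.max_rounds,
                n_seeds=config.n_seeds,
            )
            for r in results:
                all_results.append((set_name, r))
        _write_motif_results([r for _, r in all_results], outdir / "motifs.tsv")
        mio.write_meme_motifs(
            mio.discovered_motifs_to_tfmotifs([r.motif for _, r in all_results]),
            outdir / "motifs.meme",
        )
        stage_done("discover", n_motifs=len(all_results))

        # ---- stage 3: direction labels + genomic annotation --------------
        label_rows = []
        dist_rows = []
        motif_labels: dict[str, str] = {}
        direction_bg = hyper_ids | hypo_ids
        for set_name, r in all_results:
            members_all = motif_cpg_set(r.motif, records)
            if config.mode == "cancer-idmc" and direction_bg:
                members_dir = members_all & direction_bg
                if members_dir:
                    lab = direction_enrichment(
                        r.motif,
                        members_dir,
                        hyper_ids,
                        hypo_ids,
                        direction_bg,
                        threshold=config.direction_threshold,
                        alpha=config.alpha,
                    )
                    motif_labels[r.consensus] = lab.label
                    label_rows.append(
                        (
                            set_name,
                            r.consensus,
                            lab.n_cpgs,
                            f"{lab.frac_hyper:.4f}",
                            lab.label,
                            f"{lab.p_hyper:.6g}",
                            f"{lab.p_hypo:.6g}",
                            int(lab.significant_hyper),
                            int(lab.significant_hypo),
                        )
                    )
            dist = genomic_distribution(members_all, annotation)
            dist_rows.append(
                (set_name, r.consensus, len(members_all))
                + tuple(dist.gene_region_counts[g] for g in GENE_REGIONS)
                + tuple(dist.cgi_region_counts[c] for c in CGI_REGIONS)
            )
        pd.DataFrame(
            label_rows,
            columns=[
                "set",
                "consensus",
                "n_cpgs",
                "frac_hyper",
                "label",
                "p_hyper",
                "p_hypo",
                "significant_hyper",
                "significant_hypo",
            ],
        ).to_csv(outdir / "motif_labels.tsv", sep="\t", index=False)
        pd.DataFrame(
            dist_rows,
            columns=["set", "consensus", "n_cpgs"]
            + list(GENE_REGIONS)
            + list(CGI_REGIONS),
        ).to_csv(outdir / "genomic_distribution.tsv", sep="\t", index=False)
        stage_done("annotate", n_labeled=len(label_rows), n_annotated=len(dist_rows))

        # ---- stage 4: motif clustering -----------------------------------
        motifs = [r.motif for _, r in all_results]
        labels = [f"{set_name}:{r.consensus}" for set_name, r in all_results]
        if motifs:
            dm = motif_distance_matrix(motifs, labels)
            dm.to_frame().to_csv(outdir / "distance_matrix.tsv", sep="\t")
            assignment, Z = hierarchical_cluster(
                dm, method=config.linkage_method, cut_height=config.cut_height
            )
            pd.DataFrame(
                {"label": labels, "cluster": assignment}
            ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
            (outdir / "tree.nwk").write_text(linkage_to_newick(Z, labels))
            n_clusters = int(assignment.max()) if len(assignment) else 0
        else:
            n_clusters = 0
        stage_done("cluster", n_motifs=len(motifs), n_clusters=n_clusters)

        # ---- stage 5: TF matching ----------------------------------------
        classes = mio.read_classes_tsv(indir / "tf_classes.tsv")
        tf_db = mio.read_meme_motifs(indir / "tf_db.meme", classes=classes)
        match_rows = []
        pairs = []
        for set_name, r in all_results:
            matches = scan_database(
                r.motif,
                tf_db,
                min_overlap=config.min_overlap,
                e_max=config.e_max,
                n_shuffles=config.n_shuffles,
                seed=config.seed,
            )
            for m in matches:
                match_rows.append(
                    (
                        set_name,
                        r.consensus,
                        m.tf.tf_name,
                        m.tf.methyl_class,
                        m.offset,
                        m.overlap,
                        f"{m.score:.4f}",
                        f"{m.p:.6g}",
                        f"{m.e:.6g}",
                        m.strand,
                    )
                )
                label = motif_labels.get(r.consensus)
                if label in ("hyper", "hypo"):
                    pairs.append((r.motif, m.tf.tf_name, label))
        pd.DataFrame(
            match_rows,
            columns=[
                "set",
                "consensus",
                "tf_name",
                "methyl_class",
                "offset",
                "overlap",
                "score",
                "p",
                "e",
                "strand",
            ],
        ).to_csv(outdir / "tf_matches.tsv", sep="\t", index=False)
        stage_done("tfmatch", n_matches=len(match_rows), n_tfs=len(tf_db))

        # ---- stage 6: regulation analysis --------------------------------
        if config.mode == "cancer-idmc":
            targets = mio.read_targets_tsv(indir / "tf_targets.tsv")
            expression = mio.read_expression_tsv(indir / "expression.tsv")
            expr_labels = mio.read_sample_labels_tsv(indir / "sample_labels.tsv")
            calls = regulation_calls(
                pairs, classes, targets, expression, expr_labels, alpha=config.alpha
            )
            call_rows = [
                (
                    c.motif.consensus,
                    c.tf_name,
                    c.motif_label,
                    c.methyl_class,
                    c.concordance,
                    c.regulation,
                    c.n_de_targets,
                )
                for c in calls
            ]
            pd.DataFrame(
                call_rows,
                columns=[
                    "consensus",
                    "tf_name",
                    "motif_label",
                    "methyl_class",
                    "concordance",
                    "regulation",
                    "n_de_targets",
                ],
            ).to_csv(outdir / "regulation_calls.tsv", sep="\t", index=False)
            for by in ("pairs", "genes"):
                summarize_contingency(calls, by=by).to_csv(
                    outdir / f"contingency_{by}.tsv", sep="\t", index_label="concordance"
                )
            # per-gene DE table for audit
            de_rows = sorted(
                {
                    (r.gene, f"{r.median_tumor:.4f}", f"{r.median_normal:.4f}",
                     f"{r.p:.6g}", r.direction)
                    for c in calls
                    for r in c.de_results
                }
            )
            pd.DataFrame(
                de_rows,
                columns=["gene", "median_tumor", "median_normal", "p", "direction"],
            ).to_csv(outdir / "de_genes.tsv", sep="\t", index=False)
            stage_done("regulate", n_pairs=len(calls), n_de_genes=len(de_rows))
        else:
            stage_done("regulate", skipped=1)

        for f in sorted(outdir.iterdir()):
            if f.name != "manifest.json" and f.is_file():
                manifest["outputs"][f.name] = _sha256(f)
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True)
        )
        return manifest
    except Exception as exc:
        stage = manifest["stages"][-1]["name"] if manifest["stages"] else "load"
        failed_marker.write_text(f"failed after stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed after stage {stage!r}: {exc}") from exc
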