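"""End-to-end pipeline: synthesize -> search -> cluster -> domains ->
conserved -> duplicates/Ka-Ks -> orthologs -> expression -> phenotype.

Every stage writes plain TSV/JSON under the run directory and the manifest
records the effective configuration, package version and a content digest,
so identical config + seed reruns are byte-identical.
"""
from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import pandas as pd

import famforge
from famforge import domain_annot, evolution, expression, phenotype
from famforge import synthetic_data as synth
from famforge.io_cli.config import RunConfig
from famforge.io_cli.fasta import write_fasta_dict
from famforge.io_cli.gff import FeatureTable, write_gff
from famforge.profile_search import greedy_identity_cluster, iterative_expand

log = logging.getLogger("famforge")


def _setup_logging() -> None:
    if not log.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(message)s")
        )
        log.addHandler(handler)
        log.setLevel(logging.INFO)


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage on synthetic inputs; returns the manifest dict."""
    _setup_logging()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("effective config: %s", json.dumps(config.to_dict(), sort_keys=True))
    manifest: dict = {
        "version": famforge.__version__,
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "seed": config.seed,
        "stages": {},
    }

    def stage(name: str):
        log.info("stage %s", name)

    try:
        # ------------------------------------------------ synth
        stage("synth")
        fam_spec = synth.SynthFamilySpec(
            n_background_proteins=config.n_background_proteins,
            n_family_members=config.n_family_members,
            domain_length=config.domain_length,
            domain_identity_to_seed=config.domain_identity,
            cterm_domain_mix={"Kelch": 0.3, "LRR": 0.2, "unknown": 0.5},
            seed=config.seed,
        )
        family = synth.make_family_proteome(fam_spec)
        write_fasta_dict(family.proteome, out / "proteome.fasta", "protein")
        family.truth.to_csv(out / "truth_family.tsv", sep="\t", index=False)

        dup_spec = synth.SynthDupSpec(
            n_pairs=config.n_dup_pairs,
            omega=config.dup_omega,
            target_identity=config.dup_identity,
            tandem_fraction=config.tandem_fraction,
            tandem_max_gap=config.tandem_max_gap,
            n_chromosomes=config.n_chromosomes,
            n_codons=config.dup_codons,
            seed=config.seed,
        )
        dups = synth.make_duplicate_set(dup_spec)
        write_fasta_dict(dups.cds, out / "duplicates.cds.fasta", "dna")
        table = FeatureTable()
        for locus in dups.loci.values():
            table.add(locus)
        write_gff(table, out / "duplicates.gff3")
        dups.truth.to_csv(out / "truth_duplicates.tsv", sep="\t", index=False)

        expr_spec = synth.SynthExprSpec(
            n_genes=config.n_expr_genes,
            n_samples=config.n_expr_samples,
            k_clusters=config.k_clusters,
            dispersion=config.expr_dispersion,
            seed=config.seed,
        )
        counts, expr_truth = synth.make_expression_matrix(expr_spec)
        counts.to_csv(out / "counts.tsv", sep="\t", index_label="gene")

        grades = synth.make_grade_table(
            config.n_plants, tuple(config.grade_probs), config.seed
        )

        # ------------------------------------------------ search
        stage("search")
        history = iterative_expand(
            family.seed_msa,
            family.proteome,
            evalue=config.evalue,
            inclusion=config.inclusion,
            max_iter=config.max_iter,
            pseudocount_weight=config.pseudocount,
        )
        final = history[-1]
        hits_frame = pd.DataFrame(
            [
                {
                    "protein": h.protein_id,
                    "start": h.start,
                    "end": h.end,
                    "score": h.raw_score,
                    "evalue": h.evalue,
                }
                for h in final.members
            ]
        )
        _write_tsv(hits_frame, out / "hits.tsv")
        true_ids = set(family.truth.loc[family.truth.is_family, "protein_id"])
        manifest["stages"]["search"] = {
            "iterations": final.iteration,
            "converged": final.converged,
            "family_size": len(final.members),
            "true_family_size": len(true_ids),
            "recall": (
                len(true_ids & set(final.member_ids)) / len(true_ids)
                if true_ids
                else 1.0
            ),
        }

        # ------------------------------------------------ redundancy cluster
        stage("cluster")
        segments = {
            h.protein_id: h.aligned_columns.replace("-", "") for h in final.members
        }
        segments = {k: v for k, v in segments.items() if v}
        clusters = greedy_identity_cluster(segments, config.redundancy_identity)
        _write_tsv(
            pd.DataFrame(
                [
                    {"representative": c.representative, "member": m}
                    for c in clusters
                    for m in c.member_ids
                ]
            ),
            out / "clusters.tsv",
        )
        manifest["stages"]["cluster"] = {"n_clusters": len(clusters)}

        # ------------------------------------------------ domain annotation
        stage("domains")
        library = domain_annot.DomainLibrary.from_seed_msas(
            family.cterm_library,
            list(family.proteome.values()),
        )
        member_hits = {h.protein_id: h for h in final.members}
        annotations = [
            domain_annot.annotate_cterm_domains(
                pid,
                family.proteome[pid],
                hit,
                library,
                evalue_threshold=config.domain_evalue,
            )
            for pid, hit in sorted(member_hits.items())
        ]
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "protein": a.protein_id,
                        "architecture": a.architecture,
                        "domains": ";".join(
                            f"{h.name}:{h.start}-{h.end}" for h in a.domains
                        ),
                    }
                    for a in annotations
                ]
            ),
            out / "architectures.tsv",
        )
        census = domain_annot.domain_census({"synthetic": annotations})
        census.to_csv(out / "domain_census.tsv", sep="\t", index_label="domain")
        manifest["stages"]["domains"] = {
            "n_annotated": len(annotations),
            "n_fbxu": sum(1 for a in annotations if a.architecture == "FBXU"),
        }

        # ------------------------------------------------ conserved sites
        stage("conserved")
        member_msa = domain_annot.Msa(
            ids=[h.protein_id for h in final.members],
            rows=[h.aligned_columns for h in final.members],
        )
        sites = domain_annot.conserved_sites(member_msa)
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "column": s.column,
                        "top_residue": s.top_residue,
                        "top_count": s.top_count,
                        "second_residue": s.second_residue or "",
                        "second_count": s.second_count,
                        "percent": s.percent,
                    }
                    for s in sites
                ]
            ),
            out / "conserved_sites.tsv",
        )
        manifest["stages"]["conserved"] = {"n_sites": len(sites)}

        # ------------------------------------------------ duplicates / Ka-Ks
        stage("dups")
        dup_proteins = {
            gid: evolution._translate(cds, gid) for gid, cds in dups.cds.items()
        }
        pairs = evolution.analyze_duplicate_pairs(
            dups.cds,
            dup_proteins,
            dups.loci,
            dups.pairs,
            max_gap=config.tandem_max_gap,
        )
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "gene_a": p.gene_a,
                        "gene_b": p.gene_b,
                        "identity": p.identity,
                        "ka": p.ka,
                        "ks": p.ks,
                        "ratio": p.ratio,
                        "flag": p.flag.value,
                        "class": p.dup_class.value,
                    }
                    for p in pairs
                ]
            ),
            out / "duplicate_pairs.tsv",
        )
        summary = evolution.selection_summary(pairs)
        (out / "selection_summary.json").write_text(
            json.dumps(summary.__dict__, indent=2, sort_keys=True) + "\n"
        )
        manifest["stages"]["dups"] = {
            "n_pairs": summary.n,
            "n_tandem": sum(1 for p in pairs if p.dup_class is evolution.DupClass.TANDEM),
        }

        # ------------------------------------------------ orthologs
        stage("orthologs")
        proteome_a = {g: s for g, s in dup_proteins.items() if g.endswith("A")}
        proteome_b = {g: s for g, s in dup_proteins.items() if g.endswith("B")}
        orthologs = evolution.rbh_orthologs(proteome_a, proteome_b)
        _write_tsv(
            pd.DataFrame(
                [
                    {"gene_a": o.gene_a, "gene_b": o.gene_b, "score": o.score}
                    for o in orthologs
                ]
            ),
            out / "orthologs.tsv",
        )
        manifest["stages"]["orthologs"] = {"n_pairs": len(orthologs)}

        # ------------------------------------------------ expression
        stage("expression")
        normalized = expression.median_of_ratios(counts)
        normalized.values.to_csv(out / "normalized.tsv", sep="\t", index_label="gene")
        assignment = expression.hcluster(
            normalized.values, config.k_clusters, row_scaling=config.row_scaling
        )
        assignment.labels.to_frame().to_csv(
            out / "expression_clusters.tsv", sep="\t", index_label="gene"
        )
        assignment.profiles.to_csv(
            out / "cluster_profiles.tsv", sep="\t", index_label="cluster"
        )
        breadth = expression.breadth_classify(
            normalized.values,
            config.expressed_threshold,
            config.ubiquitous_fraction,
            config.tau_specific,
        )
        breadth.to_frame().to_csv(out / "breadth.tsv", sep="\t", index_label="gene")
        agreement = float(
            (assignment.labels.groupby(expr_truth.clusters).nunique() == 1).mean()
        )
        manifest["stages"]["expression"] = {
            "k": config.k_clusters,
            "cluster_purity": agreement,
        }

        # ------------------------------------------------ phenotype
        stage("phenotype")
        score = phenotype.score(grades)
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "treatment": grades.treatment,
                        "day": grades.day,
                        "n_plants": grades.n_plants,
                        "morbidity": score.morbidity,
                        "disease_index": score.index,
                    }
                ]
            ),
            out / "disease_scores.tsv",
        )
        manifest["stages"]["phenotype"] = {
            "morbidity": score.morbidity,
            "disease_index": score.index,
        }
    except Exception as exc:  # annotate failures with the stage that died
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        raise

    digest = hashlib.sha256()
    for path in sorted(out.glob("*.tsv")) + sorted(out.glob("*.fasta")):
        digest.update(path.read_bytes())
    manifest["output_digest"] = digest.hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
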