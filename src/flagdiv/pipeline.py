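"""End-to-end orchestration: curate -> dedup -> cluster -> forest -> HVR -> diversity -> selection.

Each stage is a thin call into the corresponding module; the pipeline adds
funnel bookkeeping (records in = accepted + rejected at every stage, the
multi-version accounting of a curated database build) and writes per-stage
tables plus a machine-readable run manifest.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import clustering, curation, diversity, hvr_typing, selection
from .pairwise_align import DEFAULT_SCHEME, ScoringScheme
from .sequence_model import (SequenceRecord, attach_taxonomy, deduplicate,
                             read_fasta, read_taxonomy_table, write_fasta)
from .synthetic_data import Panel, PanelConfig, generate_panel


@dataclass
class PipelineConfig:
    """Flat configuration: stage toggles, thresholds, seeds and paths."""

    out_dir: str = "flagdiv_out"
    protein_fasta: str | None = None
    cds_fasta: str | None = None
    taxonomy_tsv: str | None = None
    pssm_dir: str | None = None
    pool_fasta: str | None = None
    exclusion_file: str | None = None
    simulate: bool = False
    rng_seed: int = 0
    # thresholds
    min_bsr: float = 0.4
    cluster_min_identity: float = 0.3
    cluster_min_coverage: float = 0.8
    hvr_min_identity: float = 0.35
    hvr_min_coverage: float = 0.5
    link_threshold: float = 0.1
    hvr_species: str | None = None
    selection_reference: str | None = None
    # stage toggles
    run_curate: bool = True
    run_cluster: bool = True
    run_mstree: bool = True
    run_hvr: bool = True
    run_diversity: bool = True
    run_selection: bool = True

    @classmethod
    def from_json(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _log(stage: str, msg: str) -> None:
    print(f"[flagdiv:{stage}] {msg}", file=sys.stderr)


def run_pipeline(config: PipelineConfig, panel: Panel | None = None,
                 scheme: ScoringScheme = DEFAULT_SCHEME) -> dict:
    """Execute the enabled stages in order and return the run manifest.

    ``panel`` short-circuits file input with an in-memory synthetic panel
    (records, taxonomy and domain models); with ``config.simulate`` a
    default panel is generated from ``config.rng_seed``.  Any stage error
    aborts with the stage name and cause; outputs of completed stages are
    retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {},
                      "started": time.strftime("%Y-%m-%dT%H:%M:%S")}

    # ---- inputs --------------------------------------------------------
    try:
        if panel is None and config.simulate:
            panel = generate_panel(PanelConfig(rng_seed=config.rng_seed))
        if panel is not None:
            proteins = panel.proteins
            cds_records = panel.cds
            models = panel.models
            pool: list[SequenceRecord] = []
            exclusion: set[str] = set()
        else:
            if not config.protein_fasta:
                raise ValueError("no input: provide protein_fasta or simulate")
            proteins = read_fasta(config.protein_fasta, kind="protein")
            if config.taxonomy_tsv:
                proteins = attach_taxonomy(
                    proteins, read_taxonomy_table(config.taxonomy_tsv))
            cds_records = (read_fasta(config.cds_fasta, kind="dna")
                           if config.cds_fasta else [])
            models = []
            if config.pssm_dir:
                models = [curation.read_pssm(p)
                          for p in sorted(Path(config.pssm_dir).glob("*.tsv"))]
            pool = (read_fasta(config.pool_fasta, kind="protein")
                    if config.pool_fasta else [])
            exclusion = set()
            if config.exclusion_file:
                exclusion = {line.strip()
                             for line in open(config.exclusion_file)
                             if line.strip()}
        if not proteins:
            raise ValueError("empty input: no protein records")
    except Exception as exc:
        raise StageError("input", exc) from exc
    manifest["stages"]["input"] = {"n_records": len(proteins),
                                   "n_cds": len(cds_records)}
    _log("input", f"{len(proteins)} protein records")

    # ---- curation ------------------------------------------------------
    accepted = proteins
    if config.run_curate:
        try:
            report = curation.curate(proteins, models,
                                     exclusion_ids=exclusion,
                                     pool=pool or None,
                                     min_bsr=config.min_bsr, scheme=scheme)
            by_id = {r.id: r for r in proteins}
            for rid in report.fished:
                for rec in pool:
                    if rec.id == rid:
                        by_id[rid] = rec
            accepted = [by_id[rid] for rid in report.accepted]
            with open(out / "curation_report.tsv", "w") as fh:
                fh.write("record_id\tstatus\tstage\tdetail\n")
                for rid, cat in report.accepted.items():
                    fished = "fished" if rid in report.fished else "input"
                    fh.write(f"{rid}\taccepted\t{fished}\t{cat}\n")
                for rid, stage, reason in report.rejected:
                    fh.write(f"{rid}\trejected\t{stage}\t{reason}\n")
            manifest["stages"]["curate"] = {
                "n_in": len(proteins),
                "n_accepted": len(report.accepted),
                "n_rejected": len(report.rejected),
                "n_fished": len(report.fished),
                "rejected_by_stage": _count_by(report.rejected, 1),
            }
            _log("curate", f"accepted {len(report.accepted)} / {len(proteins)}")
        except Exception as exc:
            raise StageError("curate", exc) from exc

    # ---- deduplication -------------------------------------------------
    try:
        uniques = deduplicate(accepted)
        write_fasta([SequenceRecord(id=ids[0], residues=seq)
                     for seq, ids in sorted(uniques.members.items(),
                                            key=lambda kv: kv[1][0])],
                    out / "unique_proteins.fasta")
        manifest["stages"]["dedup"] = {"n_total": uniques.n_total,
                                       "n_unique": uniques.n_unique}
        _log("dedup", f"{uniques.n_unique} unique of {uniques.n_total}")
    except Exception as exc:
        raise StageError("dedup", exc) from exc

    tax_by_id = {rec.id: rec.taxonomy for rec in accepted if rec.taxonomy}
    phylum_by_key = {}
    king_by_key = {}
    for seq, ids in uniques.members.items():
        tax = tax_by_id.get(ids[0])
        phylum_by_key[seq] = tax.phylum if tax else "Unknown"
        king_by_key[seq] = tax.superkingdom if tax else "Unknown"

    # ---- clustering ----------------------------------------------------
    clusters = []
    if config.run_cluster and uniques.n_unique:
        try:
            clusters = clustering.greedy_cluster(
                uniques, config.cluster_min_identity,
                config.cluster_min_coverage, scheme)
            clustering.attach_phyla(clusters, phylum_by_key)
            clustering.write_cluster_table(clusters, uniques,
                                           out / "clusters.tsv")
            table, multi_frac = clustering.summarize_composition(clusters)
            table.to_csv(out / "cluster_composition.tsv", sep="\t",
                         index=False)
            manifest["stages"]["cluster"] = {
                "n_clusters": len(clusters),
                "multi_phylum_fraction": multi_frac,
                "multi_phylum_percent": clustering.multi_phylum_percent(
                    round(multi_frac * len(clusters)), len(clusters)),
            }
            _log("cluster", f"{len(clusters)} clusters")
        except Exception as exc:
            raise StageError("cluster", exc) from exc

    # ---- minimum spanning forest ---------------------------------------
    if config.run_mstree and clusters:
        try:
            graph = clustering.build_cluster_graph(clusters, scheme)
            graph = clustering.minimum_spanning_forest(
                graph, config.link_threshold)
            clustering.write_graph(graph, out / "mst_edges.tsv",
                                   out / "mst.graphml")
            kingdoms_per_component = []
            for comp in graph.components:
                kings = set()
                for cid in comp:
                    cl = graph.cluster(cid)
                    kings.update(king_by_key.get(k, "Unknown")
                                 for k in cl.members)
                kingdoms_per_component.append(sorted(kings))
            manifest["stages"]["mstree"] = {
                "n_components": len(graph.components),
                "n_mst_edges": len(graph.mst_edges),
                "component_superkingdoms": kingdoms_per_component,
            }
            _log("mstree", f"{len(graph.components)} superclusters")
        except Exception as exc:
            raise StageError("mstree", exc) from exc

    # ---- HVR typing ----------------------------------------------------
    if config.run_hvr:
        try:
            species_of = {rec.id: (rec.taxonomy.species if rec.taxonomy
                                   else "Unknown") for rec in accepted}
            target = config.hvr_species
            if target is None:
                counts: dict[str, int] = {}
                for rec in accepted:
                    sp = species_of[rec.id]
                    counts[sp] = counts.get(sp, 0) + 1
                target = max(sorted(counts), key=lambda s: counts[s])
            focal = [rec for rec in accepted if species_of[rec.id] == target]
            partitions = {rec.id: hvr_typing.partition_gene(rec)
                          for rec in focal}
            regions: dict[str, list[str]] = {}
            for rid, part in partitions.items():
                regions.setdefault(part.variable, []).append(rid)
            forms = hvr_typing.assign_hvr_forms(
                regions, config.hvr_min_identity, config.hvr_min_coverage,
                scheme)
            hvr_typing.write_form_table(forms, partitions, out / "hvr_forms.tsv")
            if len(forms) >= 3:
                reps = {f.form_id: f.representative for f in forms}
                ids, dmat = hvr_typing.score_distance_matrix(reps, scheme)
                (out / "hvr_forms.nwk").write_text(
                    hvr_typing.nj_tree(ids, dmat) + "\n")
            manifest["stages"]["hvr"] = {
                "species": target,
                "n_records": len(focal),
                "n_forms": len(forms),
                "n_isoforms": sum(len(f.isoforms) for f in forms),
            }
            _log("hvr", f"{target}: {len(forms)} forms")
        except Exception as exc:
            raise StageError("hvr", exc) from exc

    # ---- diversity -----------------------------------------------------
    if config.run_diversity:
        try:
            per_phylum: dict[str, list[SequenceRecord]] = {}
            for rec in accepted:
                ph = rec.taxonomy.phylum if rec.taxonomy else "Unknown"
                per_phylum.setdefault(ph, []).append(rec)
            points = []
            for ph, recs in sorted(per_phylum.items()):
                uq = deduplicate(recs)
                points.append(diversity.TaxonDiversity(
                    taxon=ph, n_total=uq.n_total, n_unique=uq.n_unique))
            stage: dict = {"n_taxa": len(points)}
            if len(points) >= 3 and len({p.n_total for p in points}) > 1:
                fit = diversity.fit_loglog(points)
                diversity.diversity_table(points, fit).to_csv(
                    out / "diversity.tsv", sep="\t", index=False)
                (out / "diversity_fit.json").write_text(json.dumps({
                    "slope": fit.slope, "intercept": fit.intercept,
                    "r_squared": fit.r_squared, "p_value": fit.p_value,
                }, indent=2))
                stage.update(slope=fit.slope, r_squared=fit.r_squared,
                             p_value=fit.p_value)
            manifest["stages"]["diversity"] = stage
            _log("diversity", f"{len(points)} taxa")
        except Exception as exc:
            raise StageError("diversity", exc) from exc

    # ---- selection -----------------------------------------------------
    if config.run_selection and cds_records:
        try:
            cds_by_id = {rec.id: rec for rec in cds_records}
            group = None
            if config.run_hvr and "hvr" in manifest["stages"]:
                # largest form with >= 2 CDS-backed members
                best_ids: list[str] = []
                for form in forms:
                    ids = [rid for iso in form.isoforms
                           for rid in iso.member_ids if rid in cds_by_id]
                    if len(ids) > len(best_ids):
                        best_ids = ids
                group = [cds_by_id[rid] for rid in best_ids]
            if not group or len(group) < 2:
                group = list(cds_by_id.values())[:20]
            aln = selection.codon_align(group)
            curves = selection.cumulative_curves(
                aln, reference_id=config.selection_reference,
                rng_seed=config.rng_seed)
            selection.write_curves(curves, out / "selection_curves.tsv")
            manifest["stages"]["selection"] = {
                "n_sequences": len(group),
                "reference": curves.reference_id,
                "final_cum_syn": float(curves.cum_syn[-1]),
                "final_cum_nonsyn": float(curves.cum_nonsyn[-1]),
                "final_cum_indel": float(curves.cum_indel[-1]),
            }
            _log("selection", f"{len(group)} sequences, "
                              f"reference {curves.reference_id}")
        except Exception as exc:
            raise StageError("selection", exc) from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _count_by(rows: list[tuple], index: int) -> dict[str, int]:
    out: dict[str, int] = {}
    for row in rows:
        key = row[index]
        out[key] = out.get(key, 0) + 1
    return out
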