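"""Configuration, the synthetic fixture bundle, and the chained pipeline.

``simulate`` writes a complete synthetic input bundle (sequences,
alignment table, expression matrices, GO tables, promoters, CT table) with
JSON truth sidecars and a YAML config pointing at it; ``run_pipeline``
executes the stages in order — identify, properties, pancore, kaks,
motifs, cisscan, enrich, network, tendency, ddct — writing one TSV per
stage plus a machine-readable ``summary.json`` of stage counts. Both are
deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional

import pandas as pd
import yaml

from . import __version__, io, synthetic
from .comparative import (
    DEFAULT_LAMBDA,
    filter_alignments,
    ng86_kaks,
    pan_core,
    presence_matrix,
)
from .family import classify_family_member, protein_properties
from .motifs import (
    chi_square_enrichment,
    go_venn,
    load_cis_catalog,
    scan_cis_elements,
    scan_named_motifs,
)
from .network import (
    DEFAULT_CUTOFFS,
    build_network,
    connected_components,
    correlation_pvalues,
    hub_genes,
    tendency_test,
)
from .qpcr import ddct
from .types import (
    HubCriteria,
    ParameterError,
    SelectionBand,
    WITHIN_SPECIES,
    CROSS_SPECIES,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters for one chained analysis run."""

    output_dir: str
    proteins_fasta: str
    cds_pairs_fasta: str
    alignments_tsv: str
    family_expression_tsv: str
    background_expression_tsv: str
    go_family_tsv: str
    go_background_tsv: str
    promoters_fasta: str
    ct_tsv: str
    reference_gene: str = "CYP"
    calibrator_condition: str = "0mM"
    seed: int = 0
    min_fingers: int = 1
    threshold_profile: str = "within_species"
    lambda_rate: float = DEFAULT_LAMBDA
    band_half_width: float = 0.1
    cutoffs: List[float] = field(default_factory=lambda: list(DEFAULT_CUTOFFS))
    n_reps: int = 20
    subsample_size: Optional[int] = None
    network_p_cutoff: float = 5e-2
    hub_p_cutoff: float = 0.001
    hub_min_connectivity: int = 30
    hub_max_fraction: float = 0.05
    cis_catalog_tsv: Optional[str] = None

    def validate(self) -> None:
        if self.lambda_rate <= 0:
            raise ParameterError("lambda_rate must be > 0")
        if self.band_half_width <= 0:
            raise ParameterError("band_half_width must be > 0")
        if self.min_fingers < 1:
            raise ParameterError("min_fingers must be >= 1")
        if self.n_reps < 2:
            raise ParameterError("n_reps must be >= 2")
        if not all(0 < c < 1 for c in self.cutoffs):
            raise ParameterError("cutoffs must lie in (0, 1)")
        if self.threshold_profile not in ("within_species", "cross_species"):
            raise ParameterError(
                f"unknown threshold profile {self.threshold_profile!r}"
            )

    def profile(self):
        return WITHIN_SPECIES if self.threshold_profile == "within_species" \
            else CROSS_SPECIES

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def save_config(cfg: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))


def simulate(output_dir, seed: int = 0) -> PipelineConfig:
    """Write a full synthetic input bundle plus truth sidecars and config.

    The bundle mirrors the shapes of the study conditions at desk scale:
    24 family proteins with 1-6 planted fingers (plus fingerless decoys),
    10 paralogous CDS pairs spanning low-to-moderate synonymous divergence,
    a 3-assembly presence map, a 40-transcript family module at pairwise
    correlation 0.9 over 42 genotype samples with 120 independent
    background transcripts, GO tables, promoters with planted elements,
    and a CT table for 4 genes x 4 NaCl doses with known fold changes.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(seed) % (2**31)

    # proteins: family members with 1..6 fingers + fingerless decoys
    proteins, finger_truth = [], synthetic.SyntheticTruth()
    for i in range(24):
        n_fingers = (i % 6) + 1
        rec, tr = synthetic.generate_protein_with_fingers(
            n_fingers, linker_len=15, seed=rng_seed + i,
            seq_id=f"ZFP{i + 1:03d}",
        )
        proteins.append(rec)
        finger_truth.planted_finger_positions.extend(tr.planted_finger_positions)
    for i in range(6):
        rec, _ = synthetic.generate_protein_with_fingers(
            0, linker_len=120, seed=rng_seed + 100 + i, seq_id=f"decoy{i + 1:02d}",
        )
        proteins.append(rec)
    # plant the conserved named motifs into the first three family proteins
    proteins[0] = synthetic.plant_motif(proteins[0], "QALGGH", 3, "QALGGH",
                                        finger_truth)
    proteins[1] = synthetic.plant_motif(proteins[1], "FDLNLP", 3, "EAR",
                                        finger_truth)
    proteins[2] = synthetic.plant_motif(proteins[2], "EAEAAAACLAAL", 3, "L-box",
                                        finger_truth)
    io.write_fasta(proteins, out / "proteins.fasta")
    io.write_truth(finger_truth, out / "proteins.truth.json")

    # paralogous CDS pairs (consecutive records: a then b)
    cds_records, kaks_truth = [], []
    for i in range(10):
        a, b, tr = synthetic.generate_paralog_pair(
            200, n_syn=3 + 3 * i, n_nonsyn=i, seed=rng_seed + 200 + i,
        )
        cds_records.append(
            synthetic.SequenceRecord(f"pair{i:02d}_a", a.sequence, "nucleotide")
        )
        cds_records.append(
            synthetic.SequenceRecord(f"pair{i:02d}_b", b.sequence, "nucleotide")
        )
        kaks_truth.append({"pair": f"pair{i:02d}", "n_syn": tr.n_syn,
                           "n_nonsyn": tr.n_nonsyn})
    io.write_fasta(cds_records, out / "cds_pairs.fasta")
    (out / "cds_pairs.truth.json").write_text(json.dumps(kaks_truth, indent=2))

    # alignment table over 3 assemblies with a planted presence map
    genes = [p.id for p in proteins if p.id.startswith("ZFP")]
    rng = synthetic.np.random.default_rng(rng_seed + 300)
    presence = {
        asm: {g for g in genes if rng.random() < keep}
        for asm, keep in (("asmA", 0.65), ("asmB", 0.65), ("asmC", 0.65))
    }
    for asm in presence:  # a small shared core
        presence[asm] |= set(genes[:4])
    aln, aln_truth = synthetic.generate_alignment_table(
        genes, presence, seed=rng_seed + 301
    )
    io.write_outfmt6(aln, out / "alignments.tsv")
    io.write_truth(aln_truth, out / "alignments.truth.json")

    # expression matrices: planted family module vs independent background
    fam_mat, fam_truth = synthetic.generate_expression_matrix(
        40, 0, samples=synthetic.GENOTYPE_SAMPLES,
        module_correlation=0.9, seed=rng_seed + 400,
    )
    bg_mat, _ = synthetic.generate_expression_matrix(
        0, 120, samples=synthetic.GENOTYPE_SAMPLES,
        module_correlation=0.9, seed=rng_seed + 401,
    )
    io.write_tsv(fam_mat, out / "family_expression.tsv", index=True,
                 meta={"seed": rng_seed})
    io.write_tsv(bg_mat, out / "background_expression.tsv", index=True,
                 meta={"seed": rng_seed})
    io.write_truth(fam_truth, out / "family_expression.truth.json")

    # GO tables: family skewed toward binding/regulation vs flat background
    subcats = ["binding", "catalytic activity", "transcription regulator activity",
               "metabolic process", "cellular process", "response to stimulus",
               "nucleus", "membrane"]
    fam_rows, bg_rows = [], []
    fam_weights = [0.34, 0.04, 0.22, 0.08, 0.08, 0.09, 0.10, 0.05]
    bg_weights = [0.18, 0.27, 0.04, 0.18, 0.13, 0.08, 0.07, 0.05]
    cat_of = {"binding": "MF", "catalytic activity": "MF",
              "transcription regulator activity": "MF",
              "metabolic process": "BP", "cellular process": "BP",
              "response to stimulus": "BP",
              "nucleus": "CC", "membrane": "CC"}
    rng = synthetic.np.random.default_rng(rng_seed + 500)
    for i in range(120):
        sub = subcats[int(rng.choice(len(subcats), p=fam_weights))]
        fam_rows.append((f"ZFP{(i % 24) + 1:03d}.t{i // 24 + 1}",
                         cat_of[sub], sub))
    for i in range(2000):
        sub = subcats[int(rng.choice(len(subcats), p=bg_weights))]
        bg_rows.append((f"bgtx_{i:05d}", cat_of[sub], sub))
    cols = ["transcript_id", "primary_category", "level2_subcategory"]
    io.write_tsv(pd.DataFrame(fam_rows, columns=cols), out / "go_family.tsv")
    io.write_tsv(pd.DataFrame(bg_rows, columns=cols), out / "go_background.tsv")

    # promoters with planted ABRE (hormone) and MBS (stress) sites
    promoters = []
    for i, gene in enumerate(genes[:8]):
        rec, _ = synthetic.generate_promoter_with_elements(
            [("ABRE", "ACGTGGC", 101), ("ABRE", "ACGTGGC", 501),
             ("MBS", "CAACTG", 901)],
            length=1500, seed=rng_seed + 600 + i, seq_id=f"{gene}_prom",
        )
        promoters.append(rec)
    io.write_fasta(promoters, out / "promoters.fasta")

    # qPCR CT table: four salt-responsive genes + reference, 4 NaCl doses
    conditions = ["0mM", "20mM", "40mM", "80mM"]
    fold = {
        "ZFP031": {"20mM": 1.6, "40mM": 2.5, "80mM": 4.0},
        "ZFP078": {"20mM": 1.2, "40mM": 2.0, "80mM": 3.0},
        "ZFP038": {"20mM": 1.4, "40mM": 1.8, "80mM": 2.6},
        "ZFP039": {"20mM": 1.1, "40mM": 1.7, "80mM": 2.2},
    }
    ct, ct_truth = synthetic.generate_qpcr_table(
        ["CYP"] + list(fold), conditions, fold, reference_gene="CYP",
        calibrator_condition="0mM", n_reps=3, noise_sd=0.1,
        seed=rng_seed + 700,
    )
    io.write_tsv(ct, out / "ct_table.tsv")
    io.write_truth(ct_truth, out / "ct_table.truth.json")

    cfg = PipelineConfig(
        output_dir=str(out / "results"),
        proteins_fasta=str(out / "proteins.fasta"),
        cds_pairs_fasta=str(out / "cds_pairs.fasta"),
        alignments_tsv=str(out / "alignments.tsv"),
        family_expression_tsv=str(out / "family_expression.tsv"),
        background_expression_tsv=str(out / "background_expression.tsv"),
        go_family_tsv=str(out / "go_family.tsv"),
        go_background_tsv=str(out / "go_background.tsv"),
        promoters_fasta=str(out / "promoters.fasta"),
        ct_tsv=str(out / "ct_table.tsv"),
        seed=rng_seed,
        n_reps=10,
        subsample_size=30,
    )
    cfg.validate()
    save_config(cfg, out / "config.yaml")
    return cfg


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage in order and write per-stage TSVs plus summary.json.

    Returns the summary dict (stage counts). Deterministic given the seed;
    any stage failure is re-raised annotated with the stage name.
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": cfg.seed, "config": cfg.config_hash(),
            "version": __version__}
    summary: dict = {"version": __version__, "seed": cfg.seed,
                     "config_hash": cfg.config_hash(), "stages": {}}

    def stage(name):
        logger.info("stage %s", name)
        return name

    try:
        name = stage("identify")
        proteins = [p for p in io.read_fasta(cfg.proteins_fasta)
                    if p.alphabet == "protein"]
        members, hit_rows, prop_rows = [], [], []
        for p in proteins:
            ok, hits = classify_family_member(p, cfg.min_fingers)
            if ok:
                members.append(p)
            for h in hits:
                hit_rows.append((p.id, h.start, h.end, h.gap1_len, h.gap2_len,
                                 h.matched_subsequence))
            props = protein_properties(p)
            prop_rows.append((p.id, len(p), ok, len(hits),
                              round(props.molecular_weight, 2),
                              round(props.isoelectric_point, 2),
                              round(props.gravy, 4),
                              round(props.instability_index, 2),
                              round(props.aliphatic_index, 2),
                              props.is_hydrophilic, props.is_unstable))
        io.write_tsv(pd.DataFrame(hit_rows, columns=[
            "sequence_id", "start", "end", "gap1_len", "gap2_len", "match"]),
            out / "zinc_finger_hits.tsv", meta)
        io.write_tsv(pd.DataFrame(prop_rows, columns=[
            "sequence_id", "length", "is_member", "n_fingers", "mw", "pi",
            "gravy", "instability", "aliphatic", "hydrophilic", "unstable"]),
            out / "protein_properties.tsv", meta)
        summary["stages"]["identify"] = {
            "proteins": len(proteins), "members": len(members),
            "finger_hits": len(hit_rows),
        }

        name = stage("pancore")
        records = io.read_outfmt6(cfg.alignments_tsv)
        kept = filter_alignments(records, cfg.profile())
        pres = presence_matrix(kept)
        pan, core, disp, regions = pan_core(pres)
        io.write_tsv(pres.astype(int), out / "presence_matrix.tsv", meta,
                     index=True)
        summary["stages"]["pancore"] = {
            "alignments_in": len(records), "alignments_kept": len(kept),
            "pan": pan, "core": core, "dispensable": disp,
            "regions": regions,
        }

        name = stage("kaks")
        cds = io.read_fasta(cfg.cds_pairs_fasta)
        if len(cds) % 2:
            raise ParameterError("cds_pairs_fasta must hold records in pairs")
        band = SelectionBand(half_width=cfg.band_half_width)
        kaks_rows = []
        for a, b in zip(cds[::2], cds[1::2]):
            res = ng86_kaks(a, b, band=band, lambda_rate=cfg.lambda_rate)
            kaks_rows.append((a.id, b.id, round(res.ka, 6), round(res.ks, 6),
                              None if res.ratio is None else round(res.ratio, 4),
                              round(res.syn_sites, 2), round(res.nonsyn_sites, 2),
                              round(res.divergence_time_mya, 2),
                              res.selection_mode))
        io.write_tsv(pd.DataFrame(kaks_rows, columns=[
            "id_a", "id_b", "ka", "ks", "ratio", "syn_sites", "nonsyn_sites",
            "divergence_time_mya", "selection_mode"]),
            out / "kaks.tsv", meta)
        summary["stages"]["kaks"] = {
            "pairs": len(kaks_rows),
            "modes": pd.Series([r[-1] for r in kaks_rows])
                       .value_counts().to_dict(),
        }

        name = stage("motifs")
        motif_rows = []
        for p in proteins:
            for mname, start, text in scan_named_motifs(p):
                motif_rows.append((p.id, mname, start, text))
        io.write_tsv(pd.DataFrame(motif_rows, columns=[
            "sequence_id", "motif", "start", "match"]),
            out / "named_motifs.tsv", meta)
        summary["stages"]["motifs"] = {"hits": len(motif_rows)}

        name = stage("cisscan")
        catalog = load_cis_catalog(cfg.cis_catalog_tsv)
        promoters = io.read_fasta(cfg.promoters_fasta)
        cis_rows, class_totals = [], {}
        for prom in promoters:
            hits, tallies = scan_cis_elements(prom, catalog)
            for nm, s, e, strand in hits:
                cis_rows.append((prom.id, nm, s, e, strand))
            for cls, n in tallies.items():
                class_totals[cls] = class_totals.get(cls, 0) + n
        io.write_tsv(pd.DataFrame(cis_rows, columns=[
            "promoter", "element", "start", "end", "strand"]),
            out / "cis_elements.tsv", meta)
        summary["stages"]["cisscan"] = {
            "promoters": len(promoters), "hits": len(cis_rows),
            "class_totals": class_totals,
        }

        name = stage("enrich")
        fam_go = io.read_go_tsv(cfg.go_family_tsv)
        bg_go = io.read_go_tsv(cfg.go_background_tsv)
        regions_go, totals_go = go_venn(fam_go)
        fam_counts = pd.Series(
            [a.level2_subcategory for a in fam_go]).value_counts().to_dict()
        bg_counts = pd.Series(
            [a.level2_subcategory for a in bg_go]).value_counts().to_dict()
        enrich = chi_square_enrichment(fam_counts, bg_counts)
        io.write_tsv(pd.DataFrame(
            [(r.subcategory, r.observed, round(r.expected, 2),
              round(r.chi_square, 4), r.p_value, r.direction,
              r.significance, r.reliable) for r in enrich],
            columns=["subcategory", "observed", "expected", "chi_square",
                     "p_value", "direction", "significance", "reliable"]),
            out / "go_enrichment.tsv", meta)
        summary["stages"]["enrich"] = {
            "venn_regions": regions_go, "category_totals": totals_go,
            "significant": sum(r.significance != "ns" for r in enrich),
        }

        name = stage("network")
        fam_mat = io.read_expression_tsv(cfg.family_expression_tsv)
        corr = correlation_pvalues(fam_mat)
        g = build_network(corr, cfg.network_p_cutoff)
        labels, n_comp = connected_components(g)
        crit = HubCriteria(cfg.hub_p_cutoff, cfg.hub_min_connectivity,
                           cfg.hub_max_fraction)
        hubs = hub_genes(corr, crit)
        edge_rows = [(a, b, round(d["r"], 4), d["p"])
                     for a, b, d in g.edges(data=True)]
        io.write_tsv(pd.DataFrame(edge_rows,
                                  columns=["id_a", "id_b", "r", "p"]),
                     out / "network_edges.tsv", meta)
        io.write_tsv(pd.DataFrame(hubs, columns=["gene", "connectivity"]),
                     out / "hub_genes.tsv", meta)
        summary["stages"]["network"] = {
            "nodes": g.number_of_nodes(), "edges": g.number_of_edges(),
            "components": n_comp, "hubs": len(hubs),
        }

        name = stage("tendency")
        bg_mat = io.read_expression_tsv(cfg.background_expression_tsv)
        tres = tendency_test(
            fam_mat, bg_mat, subsample_size=cfg.subsample_size,
            cutoffs=cfg.cutoffs, n_reps=cfg.n_reps, seed=cfg.seed,
        )
        io.write_tsv(pd.DataFrame({
            "cutoff": tres.cutoffs,
            "family_mean_nodes": tres.family_node_counts.mean(axis=0),
            "control_mean_nodes": tres.control_node_counts.mean(axis=0),
            "family_mean_edges": tres.family_edge_counts.mean(axis=0),
            "control_mean_edges": tres.control_edge_counts.mean(axis=0),
            "node_t": tres.node_t_stats, "node_p": tres.node_p_values,
            "edge_t": tres.edge_t_stats, "edge_p": tres.edge_p_values,
        }), out / "tendency.tsv", meta)
        summary["stages"]["tendency"] = {
            "cutoffs": len(tres.cutoffs),
            "edge_p_max": float(max(tres.edge_p_values)),
        }

        name = stage("ddct")
        ct = io.read_tsv(cfg.ct_tsv)
        rel = ddct(ct, cfg.reference_gene, cfg.calibrator_condition)
        io.write_tsv(pd.DataFrame(
            [(r.gene, r.condition, round(r.delta_ct, 4),
              round(r.delta_delta_ct, 4), round(r.fold_change, 4),
              r.p_value, r.flag) for r in rel],
            columns=["gene", "condition", "delta_ct", "delta_delta_ct",
                     "fold_change", "p_value", "flag"]),
            out / "relative_expression.tsv", meta)
        summary["stages"]["ddct"] = {
            "rows": len(rel),
            "significant": sum(r.flag != "ns" for r in rel),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_jsonable) + "\n")
    return summary


def _jsonable(obj):
    """Coerce numpy scalars to plain Python for JSON serialisation."""
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
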