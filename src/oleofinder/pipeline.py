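"""End-to-end candidate-gene pipeline on synthetic inputs.

Chains the full analysis the package implements: lineage classification
of ortholog groups, expressed-gene filtering, MCL expression clustering
with selection of the clusters peaking in the oil-accumulation window,
GO filtering to processes of interest, PLC candidate prediction,
up-regulation filters on core-pathway enzymes, TF screens, Fisher-exact
differential expression between the high-oil accession and each low-oil
accession, and the final validation intersections.  Every derived gene
set is stored in a :class:`CandidateLedger` with its rule and thresholds
so each intersection can be recomputed from its operands.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from oleofinder import coexpression, diffexpr, enrichment, expression
from oleofinder import orthology, simulate
from oleofinder.expression import ExpressionMatrix
from oleofinder.simulate import (ACCESSIONS, DE_STAGES, PROCESSES_OF_INTEREST,
                                 STAGE_WINDOW, SimulationConfig,
                                 SimulationTruth)

__all__ = ["CandidateLedger", "SyntheticInputs", "simulate_inputs",
           "run_pipeline", "make_report", "percent"]


@dataclass
class CandidateLedger:
    """Named gene sets with provenance (rule + thresholds)."""

    sets: dict = field(default_factory=dict)   # name -> sorted list
    provenance: dict = field(default_factory=dict)  # name -> str

    def add(self, name: str, members, provenance: str) -> None:
        self.sets[name] = sorted(set(members), key=str)
        self.provenance[name] = provenance

    def __getitem__(self, name: str) -> set:
        return set(self.sets[name])

    def counts(self) -> dict:
        return {name: len(v) for name, v in self.sets.items()}

    def to_json(self, path=None) -> str:
        payload = {"sets": {k: self.sets[k] for k in sorted(self.sets)},
                   "provenance": {k: self.provenance[k]
                                  for k in sorted(self.provenance)}}
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "CandidateLedger":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(sets=payload["sets"], provenance=payload["provenance"])


@dataclass
class SyntheticInputs:
    """Everything one pipeline run consumes, plus the planted truth."""

    ogs: list
    gene_meta: pd.DataFrame
    expr: ExpressionMatrix
    counts: dict
    libs: dict
    ontology: object
    annotations: dict
    promoters: list
    families: dict
    truth: SimulationTruth
    config: SimulationConfig


def simulate_inputs(config: SimulationConfig) -> SyntheticInputs:
    """Generate a coherent synthetic study from one configuration.

    Focal-species genes are drawn from the simulated OG table; a slice
    of them carries pathway / core-enzyme / TF / seed-specific-TF flags.
    Flagged genes are planted preferentially in the clusters that peak
    inside the oil-accumulation window, and planted DE genes are
    enriched among flagged genes, so the downstream intersections are
    exercised with non-trivial overlaps.
    """
    truth = SimulationTruth()
    ogs, og_truth = simulate.simulate_og_table(config)
    truth.update(og_truth)
    focal = config.panel.focal_species
    focal_genes = sorted(g for og in ogs for sp, g in og.members
                         if sp == focal)
    rng = config.rng("lengths")
    n_expr = config.n_genes_expr
    if len(focal_genes) < n_expr:
        extra = [f"{focal}_x{i + 1:05d}"
                 for i in range(n_expr - len(focal_genes))]
        focal_genes = sorted(focal_genes + extra)
    gene_ids = sorted(str(g) for g in
                      rng.choice(focal_genes, size=n_expr, replace=False))

    lengths = np.exp(rng.uniform(np.log(300.0), np.log(10000.0),
                                 size=len(gene_ids))).round().astype(int)
    n = len(gene_ids)
    pathway = np.zeros(n, dtype=bool)
    pathway[rng.choice(n, size=max(n // 10, 1), replace=False)] = True
    core = np.zeros(n, dtype=bool)
    p_idx = np.nonzero(pathway)[0]
    core[rng.choice(p_idx, size=max(len(p_idx) // 5, 1), replace=False)] = True
    tf = np.zeros(n, dtype=bool)
    non_pathway = np.nonzero(~pathway)[0]
    tf[rng.choice(non_pathway, size=max(n // 12, 1), replace=False)] = True
    seed_tf = np.zeros(n, dtype=bool)
    t_idx = np.nonzero(tf)[0]
    seed_tf[rng.choice(t_idx, size=max(len(t_idx) // 10, 1),
                       replace=False)] = True
    gene_meta = pd.DataFrame(
        {"species": focal, "length_bp": lengths, "pathway": pathway,
         "core_enzyme": core, "tf": tf, "seed_specific_tf": seed_tf},
        index=pd.Index(gene_ids, name="gene_id"))
    truth.pathway_member_flags = {g: bool(f)
                                  for g, f in zip(gene_ids, pathway)}

    # flagged genes land in the window-peaking clusters (archetypes 3-5)
    window_clusters = np.array([2, 3, 4])
    labels = rng.integers(0, config.n_clusters, size=n)
    flagged = pathway | tf
    labels[flagged] = window_clusters[
        rng.integers(0, len(window_clusters), size=int(flagged.sum()))]
    expr, expr_truth = simulate.simulate_expression(
        config, gene_ids=gene_ids, cluster_labels=labels)
    truth.update(expr_truth)

    n_de = min(config.n_genes_de, n)
    de_gene_ids = gene_ids[:n_de]
    de_flags = np.zeros(n_de, dtype=bool)
    flagged_de = np.nonzero(flagged[:n_de])[0]
    n_from_flagged = min(config.n_de_genes // 2, len(flagged_de))
    de_flags[rng.choice(flagged_de, size=n_from_flagged, replace=False)] = True
    remaining = np.nonzero(~de_flags)[0]
    n_rest = min(config.n_de_genes - n_from_flagged, len(remaining))
    de_flags[rng.choice(remaining, size=n_rest, replace=False)] = True
    counts, libs, de_truth = simulate.simulate_counts_de(
        config, gene_ids=de_gene_ids, de_flags=de_flags)
    truth.update(de_truth)

    ontology = simulate.toy_ontology()
    ann_rng = config.rng("annotations")
    annotations = simulate.simulate_annotations(gene_meta, ann_rng)

    promoter_pool = sorted(gene_meta.index[core])
    extra_needed = config.n_promoters - len(promoter_pool)
    if extra_needed > 0:
        others = [g for g in gene_ids if g not in set(promoter_pool)]
        promoter_pool += [str(g) for g in
                          rng.choice(others, size=min(extra_needed,
                                                      len(others)),
                                     replace=False)]
    promoters, prom_truth = simulate.simulate_promoters(
        config, gene_ids=sorted(promoter_pool[:config.n_promoters]))
    truth.update(prom_truth)

    families, fam_truth = simulate.simulate_families(config)
    truth.update(fam_truth)

    return SyntheticInputs(ogs=ogs, gene_meta=gene_meta, expr=expr,
                           counts=counts, libs=libs, ontology=ontology,
                           annotations=annotations, promoters=promoters,
                           families=families, truth=truth, config=config)


def run_pipeline(
    config: SimulationConfig | None = None,
    inputs: SyntheticInputs | None = None,
    min_rpkm: float = 1.0,
    corr_threshold: float = 0.7,
    plc_p: float = 1e-4,
    plc_min_partners: int = 2,
    tf_loose_p: float = 0.05,
    tf_loose_partners: int = 11,
    de_alpha: float = 0.01,
    processes_of_interest: Sequence[str] = PROCESSES_OF_INTEREST,
) -> tuple[CandidateLedger, SyntheticInputs]:
    """Run the full candidate-gene chain and return the ledger.

    Either a :class:`SimulationConfig` (inputs are generated) or
    pre-built :class:`SyntheticInputs` must be given.
    """
    if inputs is None:
        if config is None:
            raise ValueError("provide a config or prebuilt inputs")
        inputs = simulate_inputs(config)
    meta = inputs.gene_meta
    panel = inputs.config.panel
    ledger = CandidateLedger()

    # 1. lineage classification
    by_class = orthology.lineage_specific_genes(
        inputs.ogs, panel, "dicot_specific")
    dicot_specific = set(by_class[panel.focal_species])
    ledger.add("dicot_specific", dicot_specific,
               "focal-species genes in OGs present in all dicots and no grass")

    pathway_orthologs = set(meta.index[meta["pathway"]])
    ledger.add("pathway_orthologs", pathway_orthologs,
               "genes flagged as acyl-lipid pathway orthologs")
    ledger.add("pathway_dicot_specific",
               pathway_orthologs & dicot_specific,
               "pathway_orthologs ∩ dicot_specific")

    # 2. expressed filter and clustering of dicot-specific genes
    expressed = expression.expressed_filter(
        inputs.expr, min_rpkm=min_rpkm, require_both_replicates=True)
    ledger.add("expressed", expressed,
               f"abundance >= {min_rpkm} in >=1 stage, both replicates")
    universe = sorted(set(inputs.expr.values.index))
    ds_expressed = sorted(dicot_specific & expressed)
    sub = ExpressionMatrix(values=inputs.expr.values.loc[ds_expressed],
                           samples=inputs.expr.samples)
    clusters, cluster_profiles = expression.cluster_expression(
        sub, threshold=corr_threshold)
    window_genes: set = set()
    window_cluster_ids = []
    for i, members in enumerate(clusters.clusters):
        profile = cluster_profiles.iloc[i].to_numpy()
        if int(profile.argmax()) in STAGE_WINDOW:
            window_genes.update(members)
            window_cluster_ids.append(i)
    ledger.add("clusters_3_5", window_genes,
               "members of expression clusters whose mean profile peaks in "
               f"stage window {STAGE_WINDOW} (clusters {window_cluster_ids})")

    # 3. GO filter to processes of interest
    closure = enrichment.propagate_annotations(inputs.annotations,
                                               inputs.ontology)
    interesting = set(processes_of_interest)
    go_filtered = {g for g in window_genes - pathway_orthologs
                   if closure.get(g, frozenset()) & interesting}
    ledger.add("go_filtered", go_filtered,
               "clusters_3_5 minus pathway genes, annotated to processes "
               "of interest " + ",".join(sorted(interesting)))

    # 4. PLC candidate prediction
    profiles = inputs.expr.stage_profiles(log2=True)
    plc = coexpression.plc_candidates(
        sorted(go_filtered), sorted(pathway_orthologs & expressed), profiles,
        p_thresh=plc_p, min_partners=plc_min_partners)
    plc_pass = {r.gene for r in plc if r.passes}
    ledger.add("plc_candidates", plc_pass,
               f"go_filtered genes co-expressed with >={plc_min_partners} "
               f"pathway genes at p<{plc_p:g}")

    # 5. up-regulation of core enzymes in the oil window
    core = sorted(set(meta.index[meta["core_enzyme"]]) & set(universe))
    up1, up2 = set(), set()
    for gene in core:
        prof = profiles.loc[gene].to_numpy()
        if expression.upregulated(prof, STAGE_WINDOW, fold=1.0):
            up1.add(gene)
        if expression.upregulated(prof, STAGE_WINDOW, fold=2.0):
            up2.add(gene)
    ledger.add("core_upregulated_1x", up1,
               "core enzymes above their all-stage mean in the window")
    ledger.add("core_upregulated_2x", up2,
               "core enzymes above twice their all-stage mean in the window")

    # 6. TF screens
    tfs = sorted(set(meta.index[meta["tf"]]) & expressed)
    tf_res = coexpression.tf_screen(tfs, core, profiles,
                                    p_thresh=plc_p,
                                    min_partners=plc_min_partners)
    tf_plc = {r.gene for r in tf_res if r.passes}
    ledger.add("tf_plc", tf_plc,
               f"TFs with >={plc_min_partners} core-enzyme partners at "
               f"p<{plc_p:g}")
    known_res = coexpression.tf_screen(tfs, core, profiles,
                                       p_thresh=tf_loose_p,
                                       min_partners=tf_loose_partners)
    ledger.add("tf_many_partners", {r.gene for r in known_res if r.passes},
               f"TFs with >={tf_loose_partners} core-enzyme partners at "
               f"p<{tf_loose_p:g}")
    ledger.add("tf_dicot_specific", tf_plc & dicot_specific,
               "tf_plc ∩ dicot_specific")
    tf_up = set()
    for gene in sorted(tf_plc):
        if gene in profiles.index and expression.upregulated(
                profiles.loc[gene].to_numpy(), STAGE_WINDOW, fold=2.0):
            tf_up.add(gene)
    ledger.add("tf_upregulated", tf_up,
               "tf_plc with window peak >= 2x all-stage mean")
    seed_specific = set(meta.index[meta["seed_specific_tf"]])
    ledger.add("tf_seed_specific", tf_up & seed_specific,
               "tf_upregulated ∩ seed-specific TF list")

    # 7. differential expression between accessions
    high, low1, low2 = ACCESSIONS
    degs1, _ = diffexpr.call_degs(inputs.counts[high], inputs.libs[high],
                                  inputs.counts[low1], inputs.libs[low1],
                                  alpha=de_alpha)
    degs2, _ = diffexpr.call_degs(inputs.counts[high], inputs.libs[high],
                                  inputs.counts[low2], inputs.libs[low2],
                                  alpha=de_alpha)
    common = diffexpr.common_degs(degs1, degs2)
    ledger.add("degs_pair1", degs1,
               f"Fisher exact p<{de_alpha:g} in >=1 stage, {high} vs {low1}")
    ledger.add("degs_pair2", degs2,
               f"Fisher exact p<{de_alpha:g} in >=1 stage, {high} vs {low2}")
    ledger.add("degs_common", common, "degs_pair1 ∩ degs_pair2")

    # 8. validation intersections
    ledger.add("validated_candidates", plc_pass & common,
               "plc_candidates ∩ degs_common")
    ledger.add("validated_tfs", tf_plc & common, "tf_plc ∩ degs_common")
    return ledger, inputs


def percent(part: int, whole: int) -> str:
    """Set/universe ratio printed to two decimals, e.g. '5.27%'."""
    if whole <= 0:
        return "0.00%"
    return f"{100.0 * part / whole:.2f}%"


def make_report(ledger: CandidateLedger,
                universes: Mapping[str, tuple] | None = None) -> str:
    """Human-readable per-set summary with counts and percentages.

    ``universes`` optionally maps a set name to (universe name, size) so
    the line reports the ratio, e.g. ``dicot_specific: 154 (5.13% of
    3000 genes)``.
    """
    lines = ["candidate-gene ledger", "=" * 21]
    universes = universes or {}
    for name in ledger.sets:
        n = len(ledger.sets[name])
        if name in universes:
            uname, usize = universes[name]
            lines.append(f"{name}: {n} ({percent(n, usize)} of {usize} "
                         f"{uname})")
        else:
            lines.append(f"{name}: {n}")
        lines.append(f"    rule: {ledger.provenance[name]}")
    return "\n".join(lines) + "\n"
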