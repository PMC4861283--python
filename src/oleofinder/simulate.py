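"""Synthetic inputs with planted truth for the whole pipeline.

Everything the analysis chain consumes can be generated here with a
known ground truth: ortholog-group tables with controlled
species-composition classes over a 4-dicot + 3-grass panel, a
seven-stage seed transcriptome with two biological replicates built from
eight cluster archetypes, Poisson read counts for one high-oil and two
low-oil accessions at four developmental stages with planted
fold-changes, promoters with planted AW-boxes, gene families evolved
along a fixed species tree with duplications and losses, and a toy GO
ontology with flag-consistent gene annotations.

The archetype profiles are qualitative reconstructions of the canonical
seed-development shapes (three monotone-declining profiles, an early
peak, single-stage peaks at each of stages 4-7); they are illustrative,
not calibrated against any measured dataset.  Counts are Poisson — the
sampling model under which the Fisher exact test is exact — rather than
negative binomial; overdispersion can be layered on for robustness
experiments but is not the default.

Every output is a deterministic function of the configuration seed:
independent substreams are derived per generator, so regenerating one
input never perturbs another.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from oleofinder.enrichment import Ontology
from oleofinder.expression import ExpressionMatrix
from oleofinder.motifs import AW_BOX, iupac_regex, scan_awbox
from oleofinder.orthology import DEFAULT_PANEL, OrthoGroup, SpeciesPanel
from oleofinder.phylo import DistanceMatrix, Node, path_length_matrix

__all__ = ["SimulationConfig", "SimulationTruth", "simulate_og_table",
           "simulate_expression", "simulate_counts_de", "simulate_promoters",
           "simulate_family", "simulate_families", "toy_ontology",
           "simulate_annotations", "default_species_tree",
           "STAGES", "STAGE_WINDOW", "DE_STAGES", "ACCESSIONS", "ARCHETYPES"]

#: Seven stages of seed development, ordered: three early whole-seed
#: timepoints, seed fresh-weight classes through filling, and dry seed.
STAGES = ("4DAF", "12-14DAF", "22-24DAF", "5-6mg", "100-200mg",
          "400-500mg", "dry_seed")

#: 0-based indices of the oil rapid-accumulation window (5-6 mg through
#: 400-500 mg).
STAGE_WINDOW = (3, 4, 5)

#: Sampling points of the accession count data (days after flowering).
DE_STAGES = ("15DAF", "25DAF", "35DAF", "55DAF")

#: One high-oil accession followed by two low-oil accessions.
ACCESSIONS = ("HO1", "LO1", "LO2")

# Eight cluster archetypes, log2 abundance by stage.  Rows 3-5 peak
# inside the oil-accumulation window; rows 1, 7, 8 decline monotonically;
# row 2 peaks early; row 6 peaks in dry seed.  Pairwise |r| < 0.7 so the
# correlation-graph clustering can separate them.
ARCHETYPES = np.array([
    [7, 2, 2, 2, 2, 2, 2],   # 1: steep early decline
    [2, 7, 2, 2, 2, 2, 2],   # 2: early peak
    [2, 2, 2, 7, 2, 2, 2],   # 3: peak at 5-6 mg
    [2, 2, 2, 2, 7, 2, 2],   # 4: peak at 100-200 mg
    [2, 2, 2, 2, 2, 7, 2],   # 5: peak at 400-500 mg
    [2, 2, 2, 2, 2, 2, 7],   # 6: dry-seed peak
    [7, 7, 7, 2, 2, 2, 2],   # 7: decline after early filling
    [7, 7, 7, 7, 7, 2, 2],   # 8: late decline
], dtype=float)

DEFAULT_COMPOSITION = {
    "shared": 0.55,
    "dicot_specific": 0.05,
    "grass_specific": 0.05,
    "dicot_partial": 0.12,
    "grass_partial": 0.08,
    "other": 0.15,
}

_SUBSTREAM = {"ogs": 11, "expr": 23, "counts": 37, "promoters": 41,
              "families": 53, "annotations": 67, "lengths": 71}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with realistic defaults.

    The seed fully determines every output.
    """

    seed: int = 0
    # ortholog groups
    n_ogs: int = 5000
    composition_probs: dict = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION))
    mean_extra_members: float = 1.0   # geometric tail above 1 per species
    # expression (7 stages x 2 replicates)
    n_genes_expr: int = 3000
    n_clusters: int = 8
    archetype_table: np.ndarray = field(
        default_factory=lambda: ARCHETYPES.copy())
    sigma_gene: float = 0.2
    sigma_rep: float = 0.1
    sigma_offset: float = 0.5
    n_replicates: int = 2
    # accession read counts (3 accessions x 4 stages)
    n_genes_de: int = 2000
    n_de_genes: int = 100
    fold_change: float = 4.0
    lib_size: float = 2e5
    # promoters
    n_promoters: int = 200
    promoter_length: int = 2000
    planted_motifs_per_promoter: int = 2
    # gene families
    n_families: int = 20
    family_dup_rate: float = 0.5
    family_loss_rate: float = 0.2
    family_seq_len: int = 200
    distance_noise: float = 0.0
    panel: SpeciesPanel = field(default_factory=lambda: DEFAULT_PANEL)

    def __post_init__(self):
        total = sum(self.composition_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition_probs sums to {total}, not 1")
        unknown = set(self.composition_probs) - set(DEFAULT_COMPOSITION)
        if unknown:
            raise ValueError(f"unknown composition classes: {sorted(unknown)}")
        if min(self.composition_probs.values()) < 0:
            raise ValueError("negative composition probability")
        for name in ("sigma_gene", "sigma_rep", "sigma_offset",
                     "distance_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be > 0")
        if self.lib_size <= 0:
            raise ValueError("lib_size must be > 0")
        self.archetype_table = np.asarray(self.archetype_table, dtype=float)
        if self.archetype_table.shape != (self.n_clusters, len(STAGES)):
            raise ValueError(
                f"archetype_table must be {self.n_clusters} x {len(STAGES)}")
        if self.promoter_length < len(AW_BOX):
            raise ValueError("promoter_length shorter than the motif")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _SUBSTREAM[stream]])


@dataclass
class SimulationTruth:
    """Planted ground truth, one record per generated entity."""

    og_class_by_id: dict = field(default_factory=dict)
    cluster_label_by_gene: dict = field(default_factory=dict)
    pathway_member_flags: dict = field(default_factory=dict)
    de_gene_flags: dict = field(default_factory=dict)
    motif_positions_by_promoter: dict = field(default_factory=dict)
    duplication_nodes_by_family: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        def clean(obj):
            if isinstance(obj, dict):
                return {str(k): clean(v) for k, v in sorted(obj.items())}
            if isinstance(obj, (list, tuple, set, frozenset)):
                items = [clean(v) for v in obj]
                return sorted(items, key=str) if isinstance(
                    obj, (set, frozenset)) else items
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            return obj

        text = json.dumps(clean(asdict(self)), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def update(self, other: "SimulationTruth") -> None:
        for name in self.__dataclass_fields__:
            getattr(self, name).update(getattr(other, name))


# ---------------------------------------------------------------------------
# ortholog groups

def _draw_presence(cls: str, panel: SpeciesPanel, rng) -> list:
    dicots = sorted(panel.lineage_species("dicot"))
    grasses = sorted(panel.lineage_species("grass"))
    if cls == "dicot_specific":
        return dicots
    if cls == "grass_specific":
        return grasses
    if cls == "shared":
        d = [s for s in dicots if rng.random() < 0.6]
        g = [s for s in grasses if rng.random() < 0.6]
        if not d:
            d = [dicots[rng.integers(len(dicots))]]
        if not g:
            g = [grasses[rng.integers(len(grasses))]]
        return sorted(d + g)
    if cls == "dicot_partial":
        size = int(rng.integers(2, len(dicots)))
        return sorted(rng.choice(dicots, size=size, replace=False))
    if cls == "grass_partial":
        size = int(rng.integers(2, len(grasses))) if len(grasses) > 2 else 2
        return sorted(rng.choice(grasses, size=size, replace=False))
    if cls == "other":
        pool = dicots + grasses
        return [pool[rng.integers(len(pool))]]
    raise ValueError(f"unknown class {cls!r}")


def simulate_og_table(
    config: SimulationConfig,
) -> tuple[list[OrthoGroup], SimulationTruth]:
    """Ortholog groups with planted species-composition classes.

    Class is drawn per OG from ``composition_probs``; each present
    species contributes 1 + Geometric members.  Gene identifiers are
    globally unique (``<species>_g<serial>``).
    """
    rng = config.rng("ogs")
    classes = sorted(config.composition_probs)
    probs = np.array([config.composition_probs[c] for c in classes])
    truth = SimulationTruth()
    ogs: list[OrthoGroup] = []
    serial = {sp: 0 for sp in config.panel.species}
    draw = rng.choice(len(classes), size=config.n_ogs, p=probs)
    p_geo = 1.0 / (1.0 + config.mean_extra_members)
    for i in range(config.n_ogs):
        cls = classes[draw[i]]
        present = _draw_presence(cls, config.panel, rng)
        members = []
        for sp in present:
            k = 1 + int(rng.geometric(p_geo)) - 1
            for _ in range(max(k, 1)):
                serial[sp] += 1
                members.append((sp, f"{sp}_g{serial[sp]:06d}"))
        og_id = f"OG{i + 1:05d}"
        ogs.append(OrthoGroup(og_id=og_id, members=tuple(members)))
        truth.og_class_by_id[og_id] = cls
    return ogs, truth


# ---------------------------------------------------------------------------
# expression

def simulate_expression(
    config: SimulationConfig,
    gene_ids: Sequence[str] | None = None,
    cluster_labels: Sequence[int] | None = None,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Seed-development abundances from planted cluster archetypes.

    log2 abundance of gene g in stage s, replicate t is

        archetype[c(g), s] + offset_g + eps_{g,s} + eta_{g,s,t}

    with offset_g ~ N(0, sigma_offset^2), eps ~ N(0, sigma_gene^2) and
    eta ~ N(0, sigma_rep^2); abundance = 2 ** log2-value.  Cluster labels
    are drawn uniformly unless supplied.
    """
    rng = config.rng("expr")
    if gene_ids is None:
        focal = config.panel.focal_species
        gene_ids = [f"{focal}_e{i + 1:05d}" for i in range(config.n_genes_expr)]
    gene_ids = list(gene_ids)
    n = len(gene_ids)
    if cluster_labels is None:
        cluster_labels = rng.integers(0, config.n_clusters, size=n)
    cluster_labels = np.asarray(cluster_labels)
    if cluster_labels.shape != (n,) or cluster_labels.max(initial=0) >= config.n_clusters:
        raise ValueError("cluster_labels must give one label < n_clusters "
                         "per gene")
    n_stage, n_rep = len(STAGES), config.n_replicates
    base = config.archetype_table[cluster_labels]          # n x stages
    offset = rng.normal(0.0, config.sigma_offset, size=(n, 1))
    eps = rng.normal(0.0, config.sigma_gene, size=(n, n_stage))
    log2_mean = base + offset + eps
    eta = rng.normal(0.0, config.sigma_rep, size=(n, n_stage, n_rep))
    log2_vals = log2_mean[:, :, None] + eta
    values = 2.0 ** log2_vals

    sample_ids, stage_col, order_col, rep_col = [], [], [], []
    for si, stage in enumerate(STAGES):
        for rep in range(1, n_rep + 1):
            sample_ids.append(f"{stage}_r{rep}")
            stage_col.append(stage)
            order_col.append(si)
            rep_col.append(rep)
    flat = values.reshape(n, n_stage * n_rep)
    frame = pd.DataFrame(flat, index=pd.Index(gene_ids, name="gene_id"),
                         columns=sample_ids)
    samples = pd.DataFrame(
        {"stage": stage_col, "stage_order": order_col, "replicate": rep_col,
         "accession": "reference"},
        index=pd.Index(sample_ids, name="sample_id"))
    truth = SimulationTruth(cluster_label_by_gene={
        g: int(c) for g, c in zip(gene_ids, cluster_labels)})
    return ExpressionMatrix(values=frame, samples=samples), truth


# ---------------------------------------------------------------------------
# accession read counts

def simulate_counts_de(
    config: SimulationConfig,
    gene_ids: Sequence[str] | None = None,
    de_flags: Sequence[bool] | None = None,
) -> tuple[dict, dict, SimulationTruth]:
    """Poisson read counts per accession and stage with planted DEGs.

    Gene abundance proportions are log-normal and shared across
    accessions; planted DE genes have their expected count multiplied by
    ``fold_change`` in the high-oil accession (first of ``ACCESSIONS``).
    Returns (counts, library_sizes, truth) where counts maps accession ->
    genes x stages DataFrame and library_sizes maps accession ->
    {stage: nominal depth}.

    The recorded library size is the nominal sequencing depth
    ``lib_size`` for every library (a spike-in-like design): non-planted
    genes then have identical expected proportions in all accessions and
    are exact nulls under the Fisher test, while realised totals exceed
    the nominal depth in the high-oil accession by the planted mass.
    """
    rng = config.rng("counts")
    if gene_ids is None:
        focal = config.panel.focal_species
        gene_ids = [f"{focal}_e{i + 1:05d}" for i in range(config.n_genes_de)]
    gene_ids = list(gene_ids)
    n = len(gene_ids)
    if de_flags is None:
        flags = np.zeros(n, dtype=bool)
        flags[rng.choice(n, size=min(config.n_de_genes, n), replace=False)] = True
    else:
        flags = np.asarray(de_flags, dtype=bool)
        if flags.shape != (n,):
            raise ValueError("de_flags must align with gene_ids")
    weights = rng.lognormal(0.0, 1.0, size=n)
    props = weights / weights.sum()
    counts: dict = {}
    libs: dict = {}
    for acc in ACCESSIONS:
        lam = config.lib_size * props
        if acc == ACCESSIONS[0]:
            lam = lam * np.where(flags, config.fold_change, 1.0)
        table = {}
        lib_row = {}
        for stage in DE_STAGES:
            c = rng.poisson(lam)
            table[stage] = c
            lib_row[stage] = int(config.lib_size)
        counts[acc] = pd.DataFrame(
            table, index=pd.Index(gene_ids, name="gene_id"))
        libs[acc] = lib_row
    truth = SimulationTruth(de_gene_flags={
        g: bool(f) for g, f in zip(gene_ids, flags)})
    return counts, libs, truth


# ---------------------------------------------------------------------------
# promoters

_AW_FIXED = {0: "C", 2: "T", 4: "G", 12: "C", 13: "G"}
_BASES = np.array(list("ACGT"))


def _plant_instance(rng) -> str:
    site = rng.choice(_BASES, size=len(AW_BOX))
    for pos, base in _AW_FIXED.items():
        site[pos] = base
    return "".join(site)


def simulate_promoters(
    config: SimulationConfig,
    gene_ids: Sequence[str] | None = None,
) -> tuple[list[tuple[str, str]], SimulationTruth]:
    """Random promoters with AW-boxes planted at recorded positions.

    Background sequence is uniform ACGT with chance forward-strand
    matches scrubbed away, so the forward scan of each promoter recovers
    exactly the planted instances.  Positions are 0-based.
    """
    rng = config.rng("promoters")
    if gene_ids is None:
        focal = config.panel.focal_species
        gene_ids = [f"{focal}_p{i + 1:04d}" for i in range(config.n_promoters)]
    L = config.promoter_length
    w = len(AW_BOX)
    k = config.planted_motifs_per_promoter
    if k * (2 * w - 1) > L:
        raise ValueError(
            f"cannot place {k} non-overlapping {w}-mers in {L} bp")
    records, truth = [], SimulationTruth()
    for gene in gene_ids:
        positions = _nonoverlapping_positions(rng, L, w, k)
        seq = rng.choice(_BASES, size=L)
        for pos in positions:
            seq[pos:pos + w] = list(_plant_instance(rng))
        seq = _scrub_background(seq, positions, w, rng)
        records.append((gene, "".join(seq)))
        truth.motif_positions_by_promoter[gene] = sorted(positions)
    return records, truth


def _nonoverlapping_positions(rng, L, w, k) -> list:
    # spacing of 2w-1 guarantees a stray background match can overlap at
    # most one planted site, so scrubbing always has a free fixed base
    for _ in range(1000):
        pos = sorted(int(p) for p in rng.integers(0, L - w + 1, size=k))
        if all(b - a >= 2 * w - 1 for a, b in zip(pos, pos[1:])):
            return pos
    raise RuntimeError("could not place non-overlapping motifs")


def _scrub_background(seq, planted, w, rng, max_rounds: int = 50):
    """Destroy chance forward-strand matches outside the planted sites."""
    covered = set()
    for p in planted:
        covered.update(range(p, p + w))
    planted_set = set(planted)
    for _ in range(max_rounds):
        hits = [h.start for h in scan_awbox("".join(seq))
                if h.start not in planted_set]
        if not hits:
            return seq
        for s in hits:
            free = [o for o in _AW_FIXED if s + o not in covered]
            if not free:
                continue  # fully inside planted sites; cannot happen for
                # non-overlapping plants, but stay safe
            o = free[0]
            current = seq[s + o]
            choices = [b for b in "ACGT" if b != _AW_FIXED[o] and b != current]
            seq[s + o] = choices[int(rng.integers(len(choices)))]
    raise RuntimeError("background scrub did not converge")


# ---------------------------------------------------------------------------
# gene families

def default_species_tree(panel: SpeciesPanel) -> Node:
    """A fixed bifurcating species tree: dicot clade vs grass clade."""

    def clade(species: list, depth: float) -> Node:
        if len(species) == 1:
            return Node(name=species[0], length=0.15 + depth, event="leaf")
        mid = len(species) // 2
        left = clade(species[:mid], 0.0)
        right = clade(species[mid:], 0.0)
        return Node(length=0.1 + depth, children=[left, right])

    dicots = sorted(panel.lineage_species("dicot"))
    grasses = sorted(panel.lineage_species("grass"))
    return Node(children=[clade(dicots, 0.15), clade(grasses, 0.15)])


def simulate_family(
    config: SimulationConfig,
    family_id: str = "fam1",
    rng: np.random.Generator | None = None,
    species_tree: Node | None = None,
) -> tuple[dict, SimulationTruth]:
    """One gene family evolved along the species tree.

    Duplications arise as a Poisson process at ``family_dup_rate`` per
    unit branch length; each lineage entering a species branch is lost
    with probability 1 - exp(-loss_rate * branch length).  Returns a dict
    with the true gene tree (duplication nodes labeled), the additive
    leaf distance matrix (exact when ``distance_noise`` is 0), and an
    alignment evolved along the tree, plus the planted truth.

    Raises ``RuntimeError`` when the family keeps going extinct.
    """
    if rng is None:
        rng = config.rng("families")
    sp_tree = species_tree or default_species_tree(config.panel)
    for _ in range(200):
        counter: dict = {}
        tree = _evolve_lineage(sp_tree, 0.1, rng, config, family_id, counter)
        if tree is not None and len(tree.leaves()) >= 3:
            break
    else:
        raise RuntimeError(f"family {family_id} went extinct in every draw")
    tree.length = None
    dups = [sorted(n.leaf_names()) for n in tree.postorder()
            if n.event == "duplication"]
    dm = path_length_matrix(tree)
    if config.distance_noise > 0:
        noise = np.exp(rng.normal(0.0, config.distance_noise,
                                  size=dm.values.shape))
        sym = np.triu(noise, 1)
        v = dm.values * (sym + sym.T)
        dm = DistanceMatrix(labels=dm.labels, values=v)
    alignment = _evolve_alignment(tree, config.family_seq_len, rng)
    truth = SimulationTruth(
        duplication_nodes_by_family={family_id: dups})
    out = {"tree": tree, "distances": dm, "alignment": alignment,
           "n_duplications": len(dups)}
    return out, truth


def simulate_families(
    config: SimulationConfig,
) -> tuple[dict, SimulationTruth]:
    rng = config.rng("families")
    truth = SimulationTruth()
    families = {}
    for i in range(config.n_families):
        fam_id = f"fam{i + 1:03d}"
        fam, t = simulate_family(config, family_id=fam_id, rng=rng)
        families[fam_id] = fam
        truth.update(t)
    return families, truth


def _evolve_lineage(sp_node: Node, remaining: float, rng,
                    config: SimulationConfig, fam: str,
                    counter: dict) -> Node | None:
    rate = config.family_dup_rate
    t = rng.exponential(1.0 / rate) if rate > 0 else math.inf
    if t < remaining:
        a = _evolve_lineage(sp_node, remaining - t, rng, config, fam, counter)
        b = _evolve_lineage(sp_node, remaining - t, rng, config, fam, counter)
        if a is None and b is None:
            return None
        if a is None or b is None:
            survivor = a if b is None else b
            survivor.length = (survivor.length or 0.0) + t
            return survivor
        return Node(length=t, event="duplication", children=[a, b])
    if sp_node.is_leaf:
        sp = sp_node.name
        counter[sp] = counter.get(sp, 0) + 1
        return Node(name=f"{sp}_{fam}_{counter[sp]}", length=remaining,
                    event="leaf")
    kids = []
    for child in sp_node.children:
        p_loss = 1.0 - math.exp(-config.family_loss_rate * (child.length or 0))
        if rng.random() < p_loss:
            continue
        k = _evolve_lineage(child, child.length or 0.0, rng, config, fam,
                            counter)
        if k is not None:
            kids.append(k)
    if not kids:
        return None
    if len(kids) == 1:
        kids[0].length = (kids[0].length or 0.0) + remaining
        return kids[0]
    return Node(length=remaining, event="speciation", children=kids)


_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _evolve_alignment(tree: Node, seq_len: int, rng) -> list[tuple[str, str]]:
    root_seq = rng.choice(_AA, size=seq_len)
    out: list[tuple[str, str]] = []

    def walk(node: Node, seq: np.ndarray):
        if node.length:
            p = 1.0 - math.exp(-float(node.length))
            mask = rng.random(seq_len) < p
            if mask.any():
                seq = seq.copy()
                seq[mask] = _AA[rng.integers(0, len(_AA), size=int(mask.sum()))]
        if node.is_leaf:
            out.append((node.name, "".join(seq)))
        for c in node.children:
            walk(c, seq)

    walk(tree, root_seq)
    return out


# ---------------------------------------------------------------------------
# toy ontology and annotations

_SLIM_TERMS = {
    "GO:0005975": "carbohydrate metabolic process",
    "GO:0006629": "lipid metabolic process",
    "GO:0006810": "transport",
    "GO:0007165": "signal transduction",
    "GO:0009056": "catabolic process",
    "GO:0019538": "protein metabolic process",
    "GO:0015979": "photosynthesis",
    "GO:0006950": "response to stress",
}

_LEAF_TERMS = {
    # term: (name, direct parents)
    "GO:0006633": ("fatty acid biosynthetic process", ("GO:0006629",)),
    "GO:0019432": ("triglyceride biosynthetic process", ("GO:0006629",)),
    "GO:0005983": ("starch catabolic process",
                   ("GO:0005975", "GO:0009056")),
    "GO:0015712": ("hexose phosphate transport", ("GO:0006810",)),
    "GO:0009755": ("hormone-mediated signaling pathway", ("GO:0007165",)),
    "GO:0006508": ("proteolysis", ("GO:0019538", "GO:0009056")),
    "GO:0009765": ("photosynthesis, light harvesting", ("GO:0015979",)),
    "GO:0009409": ("response to cold", ("GO:0006950",)),
}

ROOT_BP = "GO:0008150"

#: slim ids of the processes screened as "of interest" downstream
PROCESSES_OF_INTEREST = ("GO:0005975", "GO:0006629", "GO:0006810",
                         "GO:0007165", "GO:0009056", "GO:0019538")


def toy_ontology() -> Ontology:
    """A small biological-process DAG with a slim layer under one root."""
    terms = {ROOT_BP: {"name": "biological_process",
                       "namespace": "biological_process"}}
    parents: dict = {}
    for term, name in _SLIM_TERMS.items():
        terms[term] = {"name": name, "namespace": "biological_process"}
        parents[term] = (ROOT_BP,)
    for term, (name, ps) in _LEAF_TERMS.items():
        terms[term] = {"name": name, "namespace": "biological_process"}
        parents[term] = tuple(ps)
    return Ontology(terms=terms, parents=parents,
                    slim=frozenset(_SLIM_TERMS))


def simulate_annotations(
    gene_flags: pd.DataFrame,
    rng: np.random.Generator,
    annotated_fraction: float = 0.9,
) -> dict:
    """Flag-consistent gene -> GO assignments on the toy ontology.

    Pathway genes annotate to lipid-synthesis leaves; other genes draw a
    random leaf term.  A slice of genes stays unannotated, so the
    enrichment universe (annotated genes) is a proper subset.
    ``gene_flags`` must be indexed by gene id with a boolean ``pathway``
    column.
    """
    lipid_leaves = ["GO:0006633", "GO:0019432"]
    other_leaves = [t for t in _LEAF_TERMS if t not in lipid_leaves]
    out: dict = {}
    for gene, row in gene_flags.iterrows():
        if rng.random() > annotated_fraction:
            continue
        if bool(row.get("pathway", False)):
            terms = {lipid_leaves[int(rng.integers(2))]}
        else:
            terms = {other_leaves[int(rng.integers(len(other_leaves)))]}
        if rng.random() < 0.3:
            terms.add(other_leaves[int(rng.integers(len(other_leaves)))])
        out[gene] = terms
    return out
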