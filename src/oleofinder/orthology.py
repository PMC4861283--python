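"""Ortholog-group (OG) tables and lineage-specificity classification.

The central rule: an OG is *dicot-specific* when it contains genes from
every dicot species of the panel and none from any grass (and symmetrically
for *grass-specific*).  OGs spanning both lineages are *shared*; OGs
confined to one lineage but missing at least one of its species are
*partial*; single-species OGs fall into *other*.  The partial/other labels
extend the published dicot/grass-specific definition so that the
classification is total over all presence patterns.

OG tables are read and written in the OrthoMCL ``groups.txt`` dialect::

    OG0001: gma|Glyma01g00100 ath|AT1G01010 ...
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from oleofinder.mcl import mcl as _run_mcl

__all__ = [
    "SpeciesPanel", "OrthoGroup", "DEFAULT_PANEL", "classify_og",
    "lineage_specific_genes", "build_ogs", "select_longest_isoform",
    "read_groups", "write_groups", "read_species_panel_tsv",
]

OG_CLASSES = ("dicot_specific", "grass_specific", "shared",
              "dicot_partial", "grass_partial", "other")


@dataclass(frozen=True)
class SpeciesPanel:
    """The species under comparison and their lineage assignment."""

    lineage_of: dict  # species code -> "dicot" | "grass"
    focal_species: str

    def __post_init__(self):
        lineages = set(self.lineage_of.values())
        if not lineages <= {"dicot", "grass"}:
            raise ValueError(f"unknown lineage(s): {lineages - {'dicot', 'grass'}}")
        for lin in ("dicot", "grass"):
            if lin not in lineages:
                raise ValueError(f"panel has no {lin} species")
        if self.focal_species not in self.lineage_of:
            raise ValueError(f"focal species {self.focal_species!r} not in panel")

    @property
    def species(self) -> tuple:
        return tuple(sorted(self.lineage_of))

    def lineage_species(self, lineage: str) -> frozenset:
        return frozenset(s for s, l in self.lineage_of.items() if l == lineage)


#: Default 7-species panel: four high-oil dicots (soybean focal, cotton,
#: castor bean, Arabidopsis) and three low-oil grasses (sorghum, foxtail
#: millet, rice).
DEFAULT_PANEL = SpeciesPanel(
    lineage_of={
        "gma": "dicot", "gra": "dicot", "rco": "dicot", "ath": "dicot",
        "sbi": "grass", "sit": "grass", "osa": "grass",
    },
    focal_species="gma",
)


@dataclass(frozen=True)
class OrthoGroup:
    og_id: str
    members: tuple  # of (species, gene_id)

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"OG {self.og_id} is empty")
        object.__setattr__(self, "members", tuple(self.members))

    def species_present(self) -> frozenset:
        return frozenset(sp for sp, _ in self.members)

    def genes(self, species: str | None = None) -> list:
        return [g for sp, g in self.members if species is None or sp == species]


def classify_og(og: OrthoGroup, panel: SpeciesPanel) -> str:
    """Classify an OG's species-presence pattern.

    Pure function of the set of species present; invariant to member order
    and per-species gene multiplicity.
    """
    present = og.species_present()
    unknown = present - set(panel.lineage_of)
    if unknown:
        raise ValueError(f"species not in panel: {sorted(unknown)}")
    dicots = panel.lineage_species("dicot")
    grasses = panel.lineage_species("grass")
    d, g = present & dicots, present & grasses
    if d and g:
        return "shared"
    if len(present) == 1:
        return "other"
    if not g:
        return "dicot_specific" if d == dicots else "dicot_partial"
    return "grass_specific" if g == grasses else "grass_partial"


def lineage_specific_genes(
    ogs: Iterable[OrthoGroup], panel: SpeciesPanel, target_class: str
) -> dict:
    """Per-species gene lists over all OGs of ``target_class``."""
    if target_class not in OG_CLASSES:
        raise ValueError(f"unknown OG class {target_class!r}")
    out: dict = {sp: [] for sp in panel.species}
    for og in ogs:
        if classify_og(og, panel) == target_class:
            for sp, gene in og.members:
                out[sp].append(gene)
    return {sp: sorted(set(genes)) for sp, genes in out.items()}


def build_ogs(
    similarity: nx.Graph,
    panel: SpeciesPanel,
    sep: str = "|",
    **mcl_params,
) -> tuple[list[OrthoGroup], list]:
    """Group genes into OGs by MCL on a symmetric similarity graph.

    Node identifiers must be ``species|gene`` strings.  MCL clusters of
    size >= 2 become OGs; singleton and unclustered genes are returned
    separately.  The reciprocal-best-hit and BLASTP steps that produce the
    similarity graph are upstream of this package.
    """
    if similarity.number_of_nodes() == 0:
        return [], []
    clusters = _run_mcl(similarity, **mcl_params)
    ogs, singletons = [], list(clusters.unclustered)
    counter = 0
    for c in clusters.clusters:
        if len(c) < 2:
            singletons.extend(c)
            continue
        counter += 1
        members = []
        for node in c:
            sp, _, gene = str(node).partition(sep)
            if not gene:
                raise ValueError(f"node {node!r} is not 'species{sep}gene'")
            members.append((sp, gene))
        ogs.append(OrthoGroup(og_id=f"OG{counter:04d}", members=tuple(members)))
    return ogs, sorted(singletons, key=str)


def select_longest_isoform(records: Iterable) -> list:
    """Keep one protein per gene: the longest isoform.

    ``records`` are objects with ``gene``, ``transcript`` and ``seq``
    attributes (or (gene, transcript, seq) tuples).  Ties on length are
    broken toward the lexicographically smaller transcript id.  Output is
    ordered by gene id.
    """
    best: dict = {}
    for rec in records:
        if isinstance(rec, tuple):
            gene, transcript, seq = rec
        else:
            gene, transcript, seq = rec.gene, rec.transcript, rec.seq
        if len(seq) == 0:
            warnings.warn(f"empty sequence for {gene}/{transcript}; skipped",
                          stacklevel=2)
            continue
        key = (-len(seq), str(transcript))
        if gene not in best or key < best[gene][0]:
            best[gene] = (key, rec)
    return [best[g][1] for g in sorted(best, key=str)]


# ---------------------------------------------------------------------------
# groups.txt dialect I/O

def read_groups(path, sep: str = "|") -> list[OrthoGroup]:
    ogs = []
    seen_genes: set = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            og_id, _, rest = line.partition(":")
            if not rest.strip():
                raise ValueError(f"{path}:{ln}: OG with no members")
            members = []
            for token in rest.split():
                sp, _, gene = token.partition(sep)
                if not gene:
                    raise ValueError(f"{path}:{ln}: bad member token {token!r}")
                if gene in seen_genes:
                    raise ValueError(f"{path}:{ln}: gene {gene!r} in multiple OGs")
                seen_genes.add(gene)
                members.append((sp, gene))
            ogs.append(OrthoGroup(og_id=og_id.strip(), members=tuple(members)))
    return ogs


def write_groups(ogs: Iterable[OrthoGroup], path, sep: str = "|") -> None:
    with open(path, "w") as fh:
        for og in ogs:
            tokens = " ".join(f"{sp}{sep}{g}" for sp, g in og.members)
            fh.write(f"{og.og_id}: {tokens}\n")


def read_species_panel_tsv(path, focal_species: str) -> SpeciesPanel:
    """2-column TSV (species, lineage) -> SpeciesPanel."""
    lineage_of = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sp, lin = line.split("\t")
            lineage_of[sp] = lin
    return SpeciesPanel(lineage_of=lineage_of, focal_species=focal_species)
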