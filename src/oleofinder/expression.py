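"""Seed-transcriptome expression handling.

Abundances are held as a genes x samples table plus a sample-metadata
sidecar (stage label, stage order, replicate, accession).  Stage profiles
average replicates per stage; clustering builds a graph connecting genes
whose stage profiles correlate with |r| above a threshold (0.7 by
default) and partitions it with MCL — genes falling outside every
cluster are reported separately.  Up-regulation filters compare the
maximum over a stage window against a multiple of the gene's overall
stage-mean average.

Profiles for clustering default to log2(abundance + 1), which tames the
orders-of-magnitude dynamic range of RPKM without dropping zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from oleofinder.mcl import ClusterSet, mcl

__all__ = ["ExpressionMatrix", "rpkm", "expressed_filter", "upregulated",
           "correlation_graph", "cluster_expression", "sample_hclust"]


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance with per-sample stage/replicate metadata.

    ``values``: DataFrame indexed by gene id with sample-id columns.
    ``samples``: DataFrame indexed by sample id with columns
    ``stage`` (label), ``stage_order`` (int, total order), ``replicate``
    and optionally ``accession``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in ("stage", "stage_order", "replicate")
                   if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample metadata lacks columns {missing}")
        unknown = [s for s in self.values.columns if s not in self.samples.index]
        if unknown:
            raise ValueError(f"samples without metadata: {unknown}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative abundance values")

    @property
    def stages(self) -> list:
        """Stage labels in stage order."""
        meta = self.samples.loc[list(self.values.columns)]
        pairs = sorted(set(zip(meta["stage_order"], meta["stage"])))
        return [s for _, s in pairs]

    def stage_profiles(self, log2: bool = False) -> pd.DataFrame:
        """Per-stage replicate means, columns ordered by stage."""
        meta = self.samples.loc[list(self.values.columns)]
        vals = np.log2(self.values + 1.0) if log2 else self.values
        grouped = vals.T.groupby(meta["stage"]).mean().T
        return grouped[self.stages]

    def write_tsv(self, values_path, samples_path) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="gene_id",
                           float_format="%.6g")
        self.samples.to_csv(samples_path, sep="\t", index_label="sample_id")

    @classmethod
    def read_tsv(cls, values_path, samples_path) -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col="gene_id")
        samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
        return cls(values=values, samples=samples)


def rpkm(count, gene_length, library_size):
    """Reads per kilobase of gene model per million mapped reads.

    rpkm = 1e9 * count / (gene_length * library_size); linear in counts
    and invariant when counts and library size scale together.  Accepts
    scalars or aligned arrays.
    """
    count = np.asarray(count, dtype=float)
    gene_length = np.asarray(gene_length, dtype=float)
    library_size = np.asarray(library_size, dtype=float)
    if (gene_length <= 0).any() or (library_size <= 0).any():
        raise ValueError("gene_length and library_size must be positive")
    if (count < 0).any():
        raise ValueError("negative counts")
    out = 1e9 * count / (gene_length * library_size)
    return float(out) if out.ndim == 0 else out


def expressed_filter(
    matrix: ExpressionMatrix,
    min_rpkm: float = 1.0,
    require_both_replicates: bool = True,
) -> set:
    """Genes expressed in the developing-seed series.

    A gene is kept when its abundance reaches ``min_rpkm`` in at least one
    stage — in every replicate of that stage when
    ``require_both_replicates`` is set, in any single sample otherwise.
    """
    meta = matrix.samples.loc[list(matrix.values.columns)]
    hit = matrix.values >= min_rpkm
    by_stage = hit.T.groupby(meta["stage"])
    per_stage = by_stage.all() if require_both_replicates else by_stage.any()
    keep = per_stage.any(axis=0)
    return set(keep.index[keep])


def upregulated(
    profile: Sequence[float],
    window: Sequence[int],
    fold: float = 1.0,
) -> bool:
    """Is the profile's peak inside the stage window >= fold x its mean?

    ``profile`` is the gene's per-stage means in stage order; ``window``
    holds 0-based stage indices.  The reference average is the mean over
    *all* stages.  Monotone in ``fold``: raising the fold can only shrink
    the selected set.
    """
    prof = np.asarray(profile, dtype=float)
    window = list(window)
    if not window:
        raise ValueError("empty stage window")
    if min(window) < 0 or max(window) >= prof.size:
        raise ValueError("window index out of range")
    if fold < 1:
        raise ValueError("fold must be >= 1")
    return bool(prof[window].max() >= fold * prof.mean())


def correlation_graph(
    profiles: pd.DataFrame,
    threshold: float = 0.7,
) -> nx.Graph:
    """Graph joining genes whose stage profiles satisfy |r| > threshold.

    Edge weights carry |r|; anti-correlated pairs connect too (the
    absolute-value rule).  Constant profiles have undefined correlation
    and are skipped with a warning; they still appear as isolated nodes.
    """
    if profiles.shape[1] < 3:
        raise ValueError("need at least 3 stages to correlate profiles")
    vals = profiles.to_numpy(dtype=float)
    genes = list(profiles.index)
    g = nx.Graph()
    g.add_nodes_from(genes)
    sd = vals.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant profile(s) skipped in "
            "correlation graph", stacklevel=2)
    live = np.nonzero(~constant)[0]
    if live.size < 2:
        return g
    m = vals[live]
    z = m - m.mean(axis=1, keepdims=True)
    z /= np.sqrt((z * z).sum(axis=1, keepdims=True))
    corr = np.clip(z @ z.T, -1.0, 1.0)
    absr = np.abs(corr)
    ii, jj = np.nonzero(np.triu(absr > threshold, k=1))
    for i, j in zip(ii, jj):
        g.add_edge(genes[live[i]], genes[live[j]], weight=float(absr[i, j]))
    return g


def cluster_expression(
    matrix: ExpressionMatrix,
    threshold: float = 0.7,
    log2: bool = True,
    inflation: float = 1.5,
    **mcl_params,
) -> tuple[ClusterSet, pd.DataFrame]:
    """Cluster genes by stage-profile similarity via MCL.

    Returns the partition (clusters ordered by size descending, then by
    smallest member id) and the per-cluster mean stage profile, on the
    same scale the clustering used.  Apply :func:`expressed_filter`
    upstream; silent genes produce spurious flat profiles.

    Inflation defaults to 1.5 here (the classic ortholog-clustering
    setting) rather than the graph-level default 2.0: expression
    correlation graphs carry stray between-cluster edges from sampling
    noise in the correlations, and the gentler inflation absorbs those
    bridges instead of splintering the dense clusters they touch.
    """
    profiles = matrix.stage_profiles(log2=log2)
    graph = correlation_graph(profiles, threshold=threshold)
    part = mcl(graph, inflation=inflation, **mcl_params)
    ordered = sorted(part.clusters, key=lambda c: (-len(c), str(c[0])))
    part = ClusterSet(clusters=ordered, unclustered=part.unclustered)
    # ClusterSet canonicalises order internally; keep the size ranking
    part.clusters = ordered
    means = pd.DataFrame(
        {f"cluster_{i + 1}": profiles.loc[c].mean(axis=0)
         for i, c in enumerate(part.clusters)}
    ).T
    means.columns = profiles.columns
    return part, means


def sample_hclust(
    matrix: ExpressionMatrix,
    gene_set: Iterable | None = None,
) -> tuple[np.ndarray, list, str]:
    """Average-linkage clustering of samples on correlation distance.

    Samples are described by log2(abundance + 1) vectors over a gene set
    (all genes by default); distance is 1 - Pearson r.  Returns the scipy
    linkage matrix, the sample order, and a newick serialisation whose
    branch lengths are merge-height increments.
    """
    vals = matrix.values
    if gene_set is not None:
        vals = vals.loc[sorted(set(gene_set) & set(vals.index), key=str)]
    if vals.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    m = np.log2(vals.to_numpy(dtype=float) + 1.0).T  # samples x genes
    sd = m.std(axis=1)
    if (sd == 0).any():
        bad = [s for s, flat in zip(vals.columns, sd == 0) if flat]
        raise ValueError(f"constant sample vector(s): {bad}")
    z = m - m.mean(axis=1, keepdims=True)
    z /= np.sqrt((z * z).sum(axis=1, keepdims=True))
    dist = np.clip(1.0 - z @ z.T, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = list(vals.columns)
    newick = _linkage_to_newick(link, labels)
    return link, labels, newick


def _linkage_to_newick(link: np.ndarray, labels: list) -> str:
    n = len(labels)
    height = {i: 0.0 for i in range(n)}

    def render(idx: int) -> str:
        if idx < n:
            return str(labels[idx])
        a, b, h, _ = link[idx - n]
        height[idx] = h
        la = render(int(a))
        lb = render(int(b))
        ha = h - height[int(a)]
        hb = h - height[int(b)]
        return f"({la}:{ha:.6g},{lb}:{hb:.6g})"

    return render(n + len(link) - 1) + ";"
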