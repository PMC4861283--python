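"""Fisher-exact differential expression between two RNA-seq libraries.

For a gene with ``count_a`` reads out of a library of ``lib_a`` and
``count_b`` out of ``lib_b``, the 2x2 table

    [[count_a, lib_a - count_a],
     [count_b, lib_b - count_b]]

is tested with Fisher's exact test; the two-sided p-value is the sum of
hypergeometric point probabilities not exceeding that of the observed
table (with a 1 + 1e-7 relative slack to absorb floating-point ties —
the convention of the common Fisher implementations).  This is the
replicate-free test suited to deeply sequenced single libraries; it is
exact under Poisson sampling and conservative in practice.

Genes are tested per stage; by default a gene is a DEG when it is
significant in at least one stage (an "all stages" rule is available).
Replicates within an accession, if present, are pooled by summation
before testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DEResult", "fisher_de", "fisher_de_many", "call_degs",
           "common_degs"]

_TIE_SLACK = 1.0 + 1e-7


@dataclass(frozen=True)
class DEResult:
    gene: str
    stage: str
    count_a: int
    count_b: int
    lib_a: int
    lib_b: int
    p: float

    def __post_init__(self):
        if self.count_a > self.lib_a or self.count_b > self.lib_b:
            raise ValueError(f"count exceeds library size for {self.gene}")
        if not (0 < self.p <= 1):
            raise ValueError("p outside (0, 1]")


def fisher_de(count_a: int, lib_a: int, count_b: int, lib_b: int) -> float:
    """Two-sided Fisher exact p for one gene in two libraries."""
    for name, v in (("count_a", count_a), ("lib_a", lib_a),
                    ("count_b", count_b), ("lib_b", lib_b)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer")
    if lib_a == 0 or lib_b == 0:
        raise ValueError("zero library size")
    if count_a > lib_a or count_b > lib_b:
        raise ValueError("count exceeds library size")
    return _fisher_p(int(count_a), int(lib_a), int(count_b), int(lib_b))


def _fisher_p(a: int, la: int, b: int, lb: int) -> float:
    m = a + b
    lo = max(0, m - lb)
    hi = min(la, m)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, la + lb, la, m)
    p_obs = pmf[a - lo]
    mask = pmf <= p_obs * _TIE_SLACK
    if mask.all():
        return 1.0
    p = float(pmf[mask].sum())
    return min(max(p, np.nextafter(0, 1)), 1.0)


def fisher_de_many(
    counts_a: np.ndarray, lib_a: int, counts_b: np.ndarray, lib_b: int
) -> np.ndarray:
    """Vectorised :func:`fisher_de` for many genes sharing two libraries.

    Tables with equal column totals share one hypergeometric family, so
    genes are grouped by total count; this keeps genome-scale scans fast.
    """
    a = np.asarray(counts_a, dtype=np.int64)
    b = np.asarray(counts_b, dtype=np.int64)
    if a.shape != b.shape:
        raise ValueError("count vectors differ in length")
    if lib_a <= 0 or lib_b <= 0:
        raise ValueError("zero library size")
    if (a < 0).any() or (b < 0).any() or a.max(initial=0) > lib_a \
            or b.max(initial=0) > lib_b:
        raise ValueError("counts must be within [0, library size]")
    out = np.empty(a.shape, dtype=float)
    totals = a + b
    for m in np.unique(totals):
        idx = np.nonzero(totals == m)[0]
        lo = max(0, int(m) - lib_b)
        hi = min(lib_a, int(m))
        support = np.arange(lo, hi + 1)
        pmf = stats.hypergeom.pmf(support, lib_a + lib_b, lib_a, int(m))
        order = np.argsort(pmf, kind="stable")
        csum = np.cumsum(pmf[order])
        sorted_pmf = pmf[order]
        obs = pmf[a[idx] - lo]
        pos = np.searchsorted(sorted_pmf, obs * _TIE_SLACK, side="right")
        vals = csum[np.maximum(pos, 1) - 1]
        vals[pos >= len(support)] = 1.0  # nothing excluded: p is exactly 1
        out[idx] = vals
    return np.clip(out, np.nextafter(0, 1), 1.0)


def call_degs(
    counts_a: pd.DataFrame,
    libs_a: Mapping[str, int],
    counts_b: pd.DataFrame,
    libs_b: Mapping[str, int],
    alpha: float = 0.01,
    rule: str = "any",
) -> tuple[set, pd.DataFrame]:
    """Call DEGs between two accessions across matched stages.

    ``counts_a``/``counts_b`` are genes x stages integer tables;
    ``libs_a``/``libs_b`` give the per-stage library sizes.  Under rule
    ``"any"`` (default) a gene is a DEG when p < alpha in at least one
    shared stage; under ``"all"`` it must be significant in every one.
    Returns the DEG set and the full per-stage p table.
    """
    if rule not in ("any", "all"):
        raise ValueError("rule must be 'any' or 'all'")
    stages = [s for s in counts_a.columns if s in set(counts_b.columns)]
    if not stages:
        raise ValueError("no shared stages between the two accessions")
    genes = counts_a.index.intersection(counts_b.index)
    pvals = pd.DataFrame(index=genes, columns=stages, dtype=float)
    for stage in stages:
        pvals[stage] = fisher_de_many(
            counts_a.loc[genes, stage].to_numpy(),
            int(libs_a[stage]),
            counts_b.loc[genes, stage].to_numpy(),
            int(libs_b[stage]),
        )
    sig = pvals < alpha
    flags = sig.any(axis=1) if rule == "any" else sig.all(axis=1)
    return set(genes[flags]), pvals


def common_degs(set_1: Iterable, set_2: Iterable) -> set:
    """DEGs shared by two accession comparisons."""
    return set(set_1) & set(set_2)
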