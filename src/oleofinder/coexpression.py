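"""Pathway-level co-expression (PLC) candidate prediction.

A query gene is nominated as a candidate pathway member when its stage
profile is significantly correlated (two-sided, sign-agnostic) with at
least ``min_partners`` known pathway genes at a stringent p threshold
(default 1e-4).  Significance of a Pearson correlation r over n stage
means uses the exact two-sided t-test with n-2 degrees of freedom:

    t = |r| * sqrt((n-2) / (1-r^2)),   p = 2 * P(T_{n-2} > t)

Strongly anti-correlated partners count: repression of a pathway step is
as informative as co-activation, so the screen is on |r|.

No multiple-testing correction is applied to PLC p-values by default; the
stringent 1e-4 threshold is the screen itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CoexpressionEdge", "PLCResult", "pearson_r", "corr_pvalue",
           "plc_candidates", "tf_screen", "edges_to_frame",
           "candidates_to_frame"]


@dataclass(frozen=True)
class CoexpressionEdge:
    gene_a: str
    gene_b: str
    r: float
    p: float
    n: int

    def __post_init__(self):
        if not (abs(self.r) <= 1 + 1e-12):
            raise ValueError(f"|r| > 1 for ({self.gene_a}, {self.gene_b})")
        if not (0 <= self.p <= 1):
            raise ValueError("p outside [0, 1]")
        if self.n < 3:
            raise ValueError("n < 3")


@dataclass
class PLCResult:
    gene: str
    partners: list[CoexpressionEdge] = field(default_factory=list)
    min_partners: int = 2

    @property
    def n_partners(self) -> int:
        return len(self.partners)

    @property
    def passes(self) -> bool:
        return self.n_partners >= self.min_partners

    @property
    def min_p(self) -> float:
        return min((e.p for e in self.partners), default=1.0)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two equal-length profiles."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("profiles must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for a constant profile")
    r = float((xc * yc).sum() / (sx * sy))
    return max(-1.0, min(1.0, r))


def corr_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation r over n points.

    Exact under bivariate-normal independence; df = n - 2.  Monotone
    decreasing in |r| at fixed n, with p(0) = 1 and p(+-1) = 0.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    a = abs(float(r))
    if a > 1 + 1e-12:
        raise ValueError("|r| > 1")
    a = min(a, 1.0)
    if a == 1.0:
        return 0.0
    t = a * np.sqrt((n - 2) / (1.0 - a * a))
    return float(2.0 * stats.t.sf(t, df=n - 2))


def _correlate_all(
    queries: Sequence[str],
    targets: Sequence[str],
    profiles: Mapping[str, Sequence[float]] | pd.DataFrame,
) -> tuple[np.ndarray, list[str], list[str], int]:
    """|r| matrix between query and target profiles, constants dropped."""
    if isinstance(profiles, pd.DataFrame):
        table = {g: profiles.loc[g].to_numpy(dtype=float) for g in profiles.index}
    else:
        table = {g: np.asarray(v, dtype=float) for g, v in profiles.items()}

    def usable(genes):
        out = []
        for g in genes:
            v = table.get(g)
            if v is None:
                warnings.warn(f"no profile for {g}; skipped", stacklevel=3)
            elif np.ptp(v) == 0:
                warnings.warn(f"constant profile for {g}; skipped", stacklevel=3)
            else:
                out.append(g)
        return out

    q = usable(queries)
    t = usable(targets)
    if not q or not t:
        return np.empty((len(q), len(t))), q, t, 0
    n = len(table[q[0]])
    qm = np.vstack([table[g] for g in q])
    tm = np.vstack([table[g] for g in t])
    qz = (qm - qm.mean(1, keepdims=True))
    qz /= np.sqrt((qz * qz).sum(1, keepdims=True))
    tz = (tm - tm.mean(1, keepdims=True))
    tz /= np.sqrt((tz * tz).sum(1, keepdims=True))
    r = np.clip(qz @ tz.T, -1.0, 1.0)
    return r, q, t, n


def _pvalues(r: np.ndarray, n: int) -> np.ndarray:
    a = np.minimum(np.abs(r), 1.0)
    with np.errstate(divide="ignore"):
        t = a * np.sqrt((n - 2) / np.maximum(1.0 - a * a, 0.0))
    p = 2.0 * stats.t.sf(t, df=n - 2)
    p[a >= 1.0] = 0.0
    return p


def plc_candidates(
    query_genes: Sequence[str],
    pathway_genes: Sequence[str],
    profiles: Mapping[str, Sequence[float]] | pd.DataFrame,
    p_thresh: float = 1e-4,
    min_partners: int = 2,
) -> list[PLCResult]:
    """Screen query genes for co-expression with known pathway members.

    For every query gene, all pathway partners with p < ``p_thresh`` are
    collected (self-pairs excluded); the gene passes when it has at least
    ``min_partners`` of them.  Results are returned for every usable query
    gene, passing or not, with the full partner edge list for audit.
    """
    r, q, t, n = _correlate_all(query_genes, pathway_genes, profiles)
    results = []
    if n == 0:
        return [PLCResult(gene=g, partners=[], min_partners=min_partners)
                for g in q]
    p = _pvalues(r, n)
    tidx = {g: j for j, g in enumerate(t)}
    for i, gene in enumerate(q):
        partners = []
        for partner in t:
            if partner == gene:
                continue
            j = tidx[partner]
            if p[i, j] < p_thresh:
                partners.append(CoexpressionEdge(
                    gene_a=gene, gene_b=partner,
                    r=float(r[i, j]), p=float(p[i, j]), n=n))
        partners.sort(key=lambda e: (e.p, e.gene_b))
        results.append(PLCResult(gene=gene, partners=partners,
                                 min_partners=min_partners))
    return results


def tf_screen(
    tf_genes: Sequence[str],
    core_genes: Sequence[str],
    profiles: Mapping[str, Sequence[float]] | pd.DataFrame,
    p_thresh: float = 1e-4,
    min_partners: int = 2,
) -> list[PLCResult]:
    """PLC screen of transcription factors against core pathway enzymes.

    Same machinery as :func:`plc_candidates`; two conventional presets are
    the stringent screen (1e-4, >=2 partners) for novel TFs and the loose
    screen (0.05, >=11 partners) for known regulators.  Output is ranked
    by partner count (descending) then minimum p.
    """
    results = plc_candidates(tf_genes, core_genes, profiles,
                             p_thresh=p_thresh, min_partners=min_partners)
    results.sort(key=lambda res: (-res.n_partners, res.min_p, res.gene))
    return results


def edges_to_frame(results: Iterable[PLCResult]) -> pd.DataFrame:
    rows = [
        {"gene_a": e.gene_a, "gene_b": e.gene_b, "r": e.r, "p": e.p, "n": e.n}
        for res in results for e in res.partners
    ]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "p", "n"])


def candidates_to_frame(results: Iterable[PLCResult]) -> pd.DataFrame:
    rows = [
        {"gene": res.gene, "n_partners": res.n_partners,
         "min_p": res.min_p, "passes": res.passes,
         "partner_list": ",".join(e.gene_b for e in res.partners)}
        for res in results
    ]
    return pd.DataFrame(
        rows, columns=["gene", "n_partners", "min_p", "passes", "partner_list"])
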