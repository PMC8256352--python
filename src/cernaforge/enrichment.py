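"""Hub-gene functional validation: over-representation and targeted GSEA.

Two complementary statistics are provided. Over-representation analysis
(ORA) asks whether a hit list overlaps a gene set more than chance via the
upper-tail hypergeometric test (the same kernel as the shared-miRNA test),
with BH adjustment across sets. The targeted GSEA statistic ranks the
whole transcriptome by Pearson correlation with a hub gene and scores a
gene set by the weighted Kolmogorov–Smirnov enrichment score (ES): a
running sum that climbs by |metric|^p (normalised) at set members and
falls by 1/(n − n_set) elsewhere; ES is the signed extremum. Significance
comes from a gene-label permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneSetCollection, ValidationError
from .diffexpr import bh_adjust
from .network import shared_mirna_test


@dataclass
class RankedList:
    """Gene ids ordered by a real ranking metric, descending."""

    genes: list[str]
    metric: np.ndarray

    def __post_init__(self) -> None:
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.genes) != len(self.metric):
            raise ValidationError("genes and metric lengths differ")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene ids in ranked list")
        if not np.isfinite(self.metric).all():
            raise ValidationError("non-finite ranking metric")
        if np.any(np.diff(self.metric) > 0):
            raise ValidationError("ranking metric must be non-increasing")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentResult:
    set_name: str
    es: float = float("nan")
    p_value: float = float("nan")
    q_value: float = float("nan")
    n_hits: int = 0
    direction: str = "none"
    overlap: int = 0


def ora_test(hits: set[str], gene_set: set[str], universe: set[str]) -> EnrichmentResult:
    """Upper-tail hypergeometric over-representation p for one gene set."""
    if not universe:
        raise ValidationError("empty universe")
    hits = hits & universe
    gene_set = gene_set & universe
    overlap = len(hits & gene_set)
    p = shared_mirna_test(
        K=len(gene_set), N=len(hits), M=len(universe), x=overlap
    )
    return EnrichmentResult(
        set_name="", p_value=p, overlap=overlap, n_hits=len(hits),
        direction="positive" if overlap else "none",
    )


def ora_collection(
    hits: set[str], collection: GeneSetCollection, universe: set[str]
) -> pd.DataFrame:
    """ORA across a gene-set collection with BH adjustment; one row per set."""
    rows = []
    for name, members in sorted(collection.items()):
        res = ora_test(hits, members, universe)
        rows.append({"set": name, "overlap": res.overlap, "p": res.p_value})
    df = pd.DataFrame(rows, columns=["set", "overlap", "p"])
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
    else:
        df["q"] = []
    return df


def rank_by_correlation(hub: str, m: ExpressionMatrix) -> RankedList:
    """Rank every other gene by Pearson correlation with the hub's profile."""
    if hub not in m.values.index:
        raise ValidationError(f"hub gene {hub!r} absent from matrix")
    if m.values.shape[1] < 3:
        raise ValidationError("need at least 3 samples to rank by correlation")
    x = m.values.loc[hub].to_numpy(dtype=float)
    if x.std() == 0:
        raise ValidationError(f"hub gene {hub!r} has zero variance")
    others = m.values.drop(index=hub)
    vals = others.to_numpy(dtype=float)
    xc = x - x.mean()
    vc = vals - vals.mean(axis=1, keepdims=True)
    denom = np.sqrt((vc**2).sum(axis=1)) * np.sqrt((xc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (vc @ xc) / denom
    r = np.where(np.isfinite(r), r, 0.0)  # zero-variance genes rank mid-list
    order = np.argsort(-r, kind="stable")
    return RankedList(genes=[others.index[i] for i in order], metric=r[order])


def gsea_es(
    ranked: RankedList, gene_set: set[str], weight_p: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted Kolmogorov–Smirnov enrichment score and running-sum profile.

    Hits increment by |metric|^weight_p normalised over the set's total
    weight; misses decrement by 1/(n − n_set). ES is the running sum's
    signed extremum. The set must hit the list but not cover it entirely.
    """
    in_set = np.array([g in gene_set for g in ranked.genes])
    n = len(ranked)
    n_hits = int(in_set.sum())
    if n_hits == 0:
        raise ValidationError("gene set does not overlap the ranked list")
    if n_hits == n:
        raise ValidationError("gene set covers the entire ranked list")
    w = np.abs(ranked.metric) ** weight_p
    hit_w = np.where(in_set, w, 0.0)
    total = hit_w.sum()
    if total == 0:
        # all hit metrics are exactly 0 (possible at weight > 0): fall back
        # to equal weights so the statistic stays defined
        hit_w = in_set.astype(float)
        total = hit_w.sum()
    steps = np.where(in_set, hit_w / total, -1.0 / (n - n_hits))
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), running


def gsea_permutation_p(
    ranked: RankedList,
    gene_set: set[str],
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
) -> EnrichmentResult:
    """Gene-label permutation p-value for the enrichment score.

    p = (1 + #{|ES_perm| >= |ES_obs|}) / (1 + n_perm); deterministic under
    ``seed``. The null permutes which positions of the (fixed) ranking
    belong to the set.
    """
    if n_perm < 100:
        raise ValidationError("need n_perm >= 100")
    es_obs, _ = gsea_es(ranked, gene_set, weight_p)
    in_set = np.array([g in gene_set for g in ranked.genes])
    n_hits = int(in_set.sum())
    n = len(ranked)
    w = np.abs(ranked.metric) ** weight_p
    rng = np.random.default_rng(seed)
    count = 0
    idx = np.arange(n)
    for _ in range(n_perm):
        perm = rng.permutation(idx)[:n_hits]
        mask = np.zeros(n, dtype=bool)
        mask[perm] = True
        hw = np.where(mask, w, 0.0)
        tot = hw.sum()
        if tot == 0:
            hw = mask.astype(float)
            tot = hw.sum()
        steps = np.where(mask, hw / tot, -1.0 / (n - n_hits))
        running = np.cumsum(steps)
        if np.max(np.abs(running)) >= abs(es_obs) - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return EnrichmentResult(
        set_name="", es=es_obs, p_value=p, n_hits=n_hits,
        direction="positive" if es_obs >= 0 else "negative",
    )
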