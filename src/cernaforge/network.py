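"""Triple-network assembly and shared-miRNA ceRNA calling.

The scaffold ("triple network") links differentially expressed miRNAs to
their predicted mRNA and lncRNA targets, keeping only interactions whose
pairing score clears a threshold (0.8 by default). Candidate mRNA–lncRNA
pairs are screened for positive co-expression (Pearson r > 0.4 by default)
and then tested for a larger-than-chance overlap between the miRNA sets
targeting each partner:

    P = P(X >= x),   X ~ Hypergeometric(M, K, N)

where K miRNAs interact with the mRNA, N with the lncRNA, M is the miRNA
universe and x the observed shared count. Pairs with p below the threshold
(0.05) and at least one shared miRNA are called competing endogenous pairs;
each shared miRNA yields one output triple.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    CeRNANetwork,
    CeRNAPair,
    ExpressionMatrix,
    InteractionTable,
    TripleNetwork,
    ValidationError,
)


@dataclass
class CeRNAParams:
    """Gates and conventions for ceRNA calling.

    score_threshold filters predicted miRNA-target interactions;
    r_threshold is the (signed) lncRNA-mRNA Pearson co-expression gate;
    p_threshold gates the shared-miRNA hypergeometric test. M_policy picks
    the miRNA universe: ``triple_network`` (default: miRNA nodes of the
    scaffold — the universe both partners' miRNA sets are actually drawn
    from, which keeps the test calibrated), ``total_mirnas_in_tables``
    (distinct miRNAs across both interaction tables, supplied to
    :func:`call_cerna_pairs` as ``mirna_universe``) or ``user_supplied``
    via ``M``. ``tail``: ``upper_inclusive`` computes P(X >= x) (default);
    ``as_printed`` the strict P(X > x). ``use_abs_r`` gates on |r| instead
    of signed r; ``adjust_pairs`` applies BH across pairs.
    """

    score_threshold: float = 0.8
    r_threshold: float = 0.4
    p_threshold: float = 0.05
    M_policy: str = "triple_network"
    M: int | None = None
    tail: str = "upper_inclusive"
    use_abs_r: bool = False
    adjust_pairs: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.score_threshold <= 1:
            raise ValidationError("score_threshold must be in [0, 1]")
        if self.p_threshold <= 0 or self.p_threshold > 1:
            raise ValidationError("p_threshold must be in (0, 1]")
        if self.M_policy not in (
            "triple_network", "total_mirnas_in_tables", "user_supplied",
        ):
            raise ValidationError(f"unknown M_policy {self.M_policy!r}")
        if self.M_policy == "user_supplied" and (self.M is None or self.M < 1):
            raise ValidationError("user_supplied M_policy requires a positive M")
        if self.tail not in ("upper_inclusive", "as_printed"):
            raise ValidationError(f"unknown tail {self.tail!r}")


def shared_mirna_test(K: int, N: int, M: int, x: int, tail: str = "upper_inclusive") -> float:
    """Hypergeometric p-value for x shared miRNAs between an mRNA (K
    interacting miRNAs) and a lncRNA (N interacting miRNAs) out of M.

    ``upper_inclusive`` returns P(X >= x) = 1 − Σ_{t<x} pmf(t); the
    ``as_printed`` variant returns the strict tail P(X > x), which sums the
    pmf through t = x before complementing. Computed via scipy's log-gamma
    hypergeometric survival function, stable for M up to ~1e5.
    """
    if not (0 <= x <= min(K, N)):
        raise ValidationError(f"need 0 <= x <= min(K, N); got x={x}, K={K}, N={N}")
    if K > M or N > M:
        raise ValidationError(f"K={K} and N={N} must not exceed M={M}")
    rv = stats.hypergeom(M, K, N)
    k = x - 1 if tail == "upper_inclusive" else x
    if tail not in ("upper_inclusive", "as_printed"):
        raise ValidationError(f"unknown tail {tail!r}")
    return float(min(1.0, max(0.0, rv.sf(k))))


def build_triple_network(
    de_mirnas: Iterable[str],
    mrna_targets: InteractionTable,
    lncrna_targets: InteractionTable,
    params: CeRNAParams | None = None,
) -> TripleNetwork:
    """Assemble the miRNA-bridged scaffold from DE miRNAs and their targets.

    Edges below ``score_threshold`` are dropped. miRNAs with surviving
    targets in both classes form the ``bridge`` subset; miRNAs left with a
    single target class stay in the network but are flagged.
    """
    params = params or CeRNAParams()
    de_mirnas = set(de_mirnas)
    if not de_mirnas:
        raise ValidationError("no DE miRNAs supplied")

    g = nx.Graph()
    has_mrna: set[str] = set()
    has_lncrna: set[str] = set()
    for table, cls, seen in (
        (mrna_targets, "mRNA", has_mrna),
        (lncrna_targets, "lncRNA", has_lncrna),
    ):
        r = table.records
        keep = r[(r["mirna"].isin(de_mirnas)) & (r["score"] >= params.score_threshold)]
        for mirna, target, score in keep[["mirna", "target", "score"]].itertuples(index=False):
            g.add_node(mirna, rna_class="miRNA")
            g.add_node(target, rna_class=cls)
            g.add_edge(mirna, target, pairing_score=float(score))
            seen.add(mirna)

    if g.number_of_edges() == 0:
        raise ValidationError("triple network is empty after score filtering")
    bridge = has_mrna & has_lncrna
    single = (has_mrna | has_lncrna) - bridge
    return TripleNetwork(graph=g, bridge_mirnas=bridge, single_class_mirnas=single)


def pearson_filter(
    pairs: Sequence[tuple[str, str]],
    mrna_expr: ExpressionMatrix,
    lncrna_expr: ExpressionMatrix,
    r_threshold: float = 0.4,
    use_abs: bool = False,
) -> list[tuple[str, str, float]]:
    """Keep candidate (mRNA, lncRNA) pairs whose expression profiles are
    positively correlated (r > r_threshold across shared samples).

    Pairs involving a zero-variance gene are dropped (no defined r). With
    ``use_abs`` the gate is on |r|.
    """
    shared = [s for s in mrna_expr.sample_ids if s in set(lncrna_expr.sample_ids)]
    if len(shared) < 3:
        raise ValidationError("need at least 3 shared samples for correlation")
    mv = mrna_expr.values[shared]
    lv = lncrna_expr.values[shared]
    out: list[tuple[str, str, float]] = []
    for mr, ln in pairs:
        if mr not in mv.index:
            raise ValidationError(f"mRNA {mr!r} absent from its expression matrix")
        if ln not in lv.index:
            raise ValidationError(f"lncRNA {ln!r} absent from its expression matrix")
        x = mv.loc[mr].to_numpy(dtype=float)
        y = lv.loc[ln].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            continue  # undefined correlation: drop, not error
        r = float(np.corrcoef(x, y)[0, 1])
        stat = abs(r) if use_abs else r
        if stat > r_threshold:
            out.append((mr, ln, r))
    return out


def call_cerna_pairs(
    net: TripleNetwork,
    corr_pairs: Sequence[tuple[str, str, float]],
    params: CeRNAParams | None = None,
    mirna_universe: int | None = None,
) -> CeRNANetwork:
    """Run the shared-miRNA test over correlation-surviving candidates and
    assemble the called ceRNA network.

    For each candidate, K and N are the miRNA neighbourhoods of the mRNA
    and lncRNA in the scaffold, x their overlap, M per ``M_policy``
    (``mirna_universe`` supplies the table-wide miRNA count for the
    ``total_mirnas_in_tables`` policy). A pair is called iff
    p < p_threshold and x >= 1; each shared miRNA becomes one triple row.
    """
    params = params or CeRNAParams()
    if params.M_policy == "user_supplied":
        M = int(params.M)  # type: ignore[arg-type]
    elif params.M_policy == "total_mirnas_in_tables":
        if mirna_universe is None:
            raise ValidationError(
                "total_mirnas_in_tables policy needs mirna_universe"
            )
        M = int(mirna_universe)
    else:
        M = len(net.nodes_of_class("miRNA"))

    cand: list[tuple[CeRNAPair, set[str]]] = []
    for mr, ln, r in corr_pairs:
        if mr not in net.graph or ln not in net.graph:
            continue
        mi_m = net.mirnas_targeting(mr)
        mi_l = net.mirnas_targeting(ln)
        K, N = len(mi_m), len(mi_l)
        if K > M or N > M:
            raise ValidationError(
                f"user-supplied M={M} smaller than observed K={K} or N={N}"
            )
        shared = mi_m & mi_l
        x = len(shared)
        if x == 0:
            continue
        p = shared_mirna_test(K, N, M, x, tail=params.tail)
        cand.append(
            (
                CeRNAPair(
                    mrna=mr, lncrna=ln, shared_mirnas=frozenset(shared),
                    x=x, K=K, N=N, M=M, p_value=p, pearson_r=r,
                ),
                shared,
            )
        )

    if params.adjust_pairs and cand:
        from .diffexpr import bh_adjust

        qs = bh_adjust([c[0].p_value for c in cand])
        keep = [c for c, q in zip(cand, qs) if q < params.p_threshold]
    else:
        keep = [c for c in cand if c[0].p_value < params.p_threshold]

    rows = []
    pairs = []
    for pair, shared in keep:
        pairs.append(pair)
        for mi in sorted(shared):
            rows.append({"mrna": pair.mrna, "mirna": mi, "lncrna": pair.lncrna})
    triples = pd.DataFrame(rows, columns=["mrna", "mirna", "lncrna"])
    return CeRNANetwork(triples=triples, pairs=pairs)


def pairs_from_triples(triples: pd.DataFrame) -> dict[tuple[str, str], set[str]]:
    """Rebuild the (mRNA, lncRNA) → shared-miRNA map from triple rows.

    Inverse of the triple expansion performed by :func:`call_cerna_pairs`;
    used to verify the expansion is lossless.
    """
    out: dict[tuple[str, str], set[str]] = {}
    for mr, mi, ln in triples[["mrna", "mirna", "lncrna"]].itertuples(index=False):
        out.setdefault((mr, ln), set()).add(mi)
    return out
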