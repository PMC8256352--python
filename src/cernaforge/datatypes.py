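"""Core domain types for ceRNA network inference.

The pipeline moves between a small set of typed containers:

* :class:`ExpressionMatrix` — genes × samples log2 abundance with a
  two-group (control vs case) design.
* :class:`InteractionTable` — scored miRNA→target prediction records.
* :class:`TripleNetwork` — the miRNA-bridged scaffold of miRNA–mRNA and
  miRNA–lncRNA regulatory edges.
* :class:`CeRNAPair` / :class:`CeRNANetwork` — called competing-endogenous
  mRNA–lncRNA pairs with their shared-miRNA statistics, and the typed
  tripartite graph they induce.
* :class:`GeneSetCollection` — named gene sets for enrichment.

Invariants are checked eagerly at construction so downstream stages can
assume well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

RNA_CLASSES = ("mRNA", "lncRNA", "miRNA")
GROUPS = ("control", "case")


class ValidationError(ValueError):
    """An input violated a structural invariant of a domain type."""


@dataclass
class ExpressionMatrix:
    """Log2 expression values for one RNA class under a two-group design.

    Parameters
    ----------
    values
        DataFrame of log2 abundance, genes as rows (index = gene ids),
        samples as columns.
    group
        Series mapping sample id -> ``"control"`` or ``"case"``; must cover
        every column of ``values``.
    rna_class
        One of ``"mRNA"``, ``"lncRNA"``, ``"miRNA"``.
    """

    values: pd.DataFrame
    group: pd.Series
    rna_class: str

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise ValidationError(
                f"rna_class must be one of {RNA_CLASSES}, got {self.rna_class!r}"
            )
        if self.values.empty:
            raise ValidationError("expression matrix is empty")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene ids: {list(dupes)[:5]}")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        missing = [s for s in self.values.columns if s not in self.group.index]
        if missing:
            raise ValidationError(f"samples without a group label: {missing}")
        self.group = self.group.loc[self.values.columns]
        bad = set(self.group.unique()) - set(GROUPS)
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")
        for g in GROUPS:
            if (self.group == g).sum() == 0:
                raise ValidationError(f"group {g!r} has no samples")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValidationError("non-finite expression values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return list(self.group.index[self.group == group])

    @property
    def n_control(self) -> int:
        return int((self.group == "control").sum())

    @property
    def n_case(self) -> int:
        return int((self.group == "case").sum())


@dataclass
class InteractionTable:
    """Scored miRNA→target records for one target class.

    ``records`` has columns ``mirna``, ``target``, ``score`` with scores in
    [0, 1]; (mirna, target) pairs are unique (duplicates keep max score).
    """

    records: pd.DataFrame
    target_class: str

    def __post_init__(self) -> None:
        if self.target_class not in ("mRNA", "lncRNA"):
            raise ValidationError(
                f"target_class must be mRNA or lncRNA, got {self.target_class!r}"
            )
        req = {"mirna", "target", "score"}
        if not req.issubset(self.records.columns):
            raise ValidationError(f"interaction table needs columns {sorted(req)}")
        s = self.records["score"].to_numpy(dtype=float)
        if len(s) and (np.isnan(s).any() or (s < 0).any() or (s > 1).any()):
            raise ValidationError("pairing scores must lie in [0, 1]")
        # dedupe: keep max score per (mirna, target)
        self.records = (
            self.records.sort_values("score", kind="stable")
            .drop_duplicates(["mirna", "target"], keep="last")
            .sort_index()
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.records)

    def mirnas(self) -> set[str]:
        return set(self.records["mirna"])

    def targets_of(self, mirna: str, min_score: float = 0.0) -> set[str]:
        r = self.records
        return set(r.loc[(r["mirna"] == mirna) & (r["score"] >= min_score), "target"])


@dataclass
class TripleNetwork:
    """miRNA-bridged scaffold: miRNA–mRNA and miRNA–lncRNA edges only.

    ``graph`` is a simple undirected :class:`networkx.Graph` with node
    attribute ``rna_class`` and edge attribute ``pairing_score``.
    ``bridge_mirnas`` are the miRNAs with at least one surviving target in
    BOTH classes; miRNAs targeting a single class are kept but flagged in
    ``single_class_mirnas``.
    """

    graph: nx.Graph
    bridge_mirnas: set[str] = field(default_factory=set)
    single_class_mirnas: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for n, d in self.graph.nodes(data=True):
            if d.get("rna_class") not in RNA_CLASSES:
                raise ValidationError(f"node {n!r} lacks a valid rna_class")
        for u, v in self.graph.edges():
            cu = self.graph.nodes[u]["rna_class"]
            cv = self.graph.nodes[v]["rna_class"]
            if "miRNA" not in (cu, cv):
                raise ValidationError(
                    f"edge {u!r}–{v!r} does not involve a miRNA (direct "
                    "mRNA–lncRNA edges are not allowed in the triple network)"
                )
            if u == v:
                raise ValidationError(f"self-loop at {u!r}")
        for n, d in self.graph.nodes(data=True):
            if d["rna_class"] == "miRNA" and self.graph.degree(n) == 0:
                raise ValidationError(f"isolated miRNA node {n!r}")

    def nodes_of_class(self, rna_class: str) -> set[str]:
        return {
            n for n, d in self.graph.nodes(data=True) if d["rna_class"] == rna_class
        }

    def mirnas_targeting(self, node: str) -> set[str]:
        return {
            m
            for m in self.graph.neighbors(node)
            if self.graph.nodes[m]["rna_class"] == "miRNA"
        }


@dataclass(frozen=True)
class CeRNAPair:
    """One called mRNA–lncRNA competing pair with its shared-miRNA statistics.

    ``x`` = number of shared miRNAs, ``K`` = miRNAs interacting with the
    mRNA, ``N`` = miRNAs interacting with the lncRNA, ``M`` = miRNA universe
    size; ``p_value`` from the shared-miRNA hypergeometric test and
    ``pearson_r`` the lncRNA–mRNA co-expression correlation.
    """

    mrna: str
    lncrna: str
    shared_mirnas: frozenset[str]
    x: int
    K: int
    N: int
    M: int
    p_value: float
    pearson_r: float = float("nan")

    def __post_init__(self) -> None:
        if not (0 <= self.x <= min(self.K, self.N)):
            raise ValidationError(
                f"x={self.x} must satisfy 0 <= x <= min(K={self.K}, N={self.N})"
            )
        if self.K > self.M or self.N > self.M:
            raise ValidationError(f"K={self.K}, N={self.N} must not exceed M={self.M}")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")
        if len(self.shared_mirnas) != self.x:
            raise ValidationError("shared miRNA set size disagrees with x")


@dataclass
class CeRNANetwork:
    """Called ceRNA network: triples, pair records, and the induced graph.

    ``triples`` is a DataFrame with columns ``mrna``, ``mirna``, ``lncrna``
    — one row per (pair, shared miRNA), the layout of a published triple
    table. ``pairs`` carries the per-pair statistics. The graph is the
    simple undirected union of the deduplicated miRNA–mRNA and
    miRNA–lncRNA links of the triples.
    """

    triples: pd.DataFrame
    pairs: list[CeRNAPair] = field(default_factory=list)

    def __post_init__(self) -> None:
        req = {"mrna", "mirna", "lncrna"}
        if not req.issubset(self.triples.columns):
            raise ValidationError(f"triples need columns {sorted(req)}")
        if self.pairs:
            by_pair: dict[tuple[str, str], set[str]] = {}
            for _, row in self.triples.iterrows():
                by_pair.setdefault((row["mrna"], row["lncrna"]), set()).add(
                    row["mirna"]
                )
            for p in self.pairs:
                shared = by_pair.get((p.mrna, p.lncrna), set())
                if not shared <= set(p.shared_mirnas):
                    raise ValidationError(
                        f"triple miRNAs for ({p.mrna}, {p.lncrna}) not in the "
                        "pair's shared set"
                    )

    def __len__(self) -> int:
        return len(self.triples)

    @property
    def mrnas(self) -> set[str]:
        return set(self.triples["mrna"])

    @property
    def lncrnas(self) -> set[str]:
        return set(self.triples["lncrna"])

    @property
    def mirnas(self) -> set[str]:
        return set(self.triples["mirna"])

    def to_graph(self) -> nx.Graph:
        """Undirected simple graph of the triples' regulatory links."""
        g = nx.Graph()
        for _, row in self.triples.iterrows():
            mr, mi, ln = row["mrna"], row["mirna"], row["lncrna"]
            g.add_node(mr, rna_class="mRNA")
            g.add_node(mi, rna_class="miRNA")
            g.add_node(ln, rna_class="lncRNA")
            g.add_edge(mi, mr, relation="targets")
            g.add_edge(mi, ln, relation="targets")
        return g

    def called_pairs(self) -> set[tuple[str, str]]:
        return {(p.mrna, p.lncrna) for p in self.pairs} or {
            (r["mrna"], r["lncrna"]) for _, r in self.triples.iterrows()
        }


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. pathways) with optional descriptions."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def items(self) -> Iterable[tuple[str, set[str]]]:
        return self.sets.items()


def design_from_mapping(design: Mapping[str, str]) -> pd.Series:
    """Normalise a sample→group mapping into a validated Series."""
    s = pd.Series(dict(design), dtype=object)
    bad = set(s.unique()) - set(GROUPS)
    if bad:
        raise ValidationError(f"unknown group labels: {sorted(bad)}")
    return s
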