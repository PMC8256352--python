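"""Readers and writers for every external format the pipeline touches.

TSV (UTF-8, header row) for expression matrices, interaction tables, DE
tables and ceRNA pair/triple tables; GMT for gene-set collections; SIF and
GraphML for networks. The packaged 99-triple published ceRNA network is
loaded via :func:`load_table2_fixture`.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

from .datatypes import (
    CeRNANetwork,
    ExpressionMatrix,
    GeneSetCollection,
    InteractionTable,
    ValidationError,
    design_from_mapping,
)

#: Mean log2-abundance floor below which genes are discarded on read.
#: Default log2(4) = 2: transcripts with average abundance under four
#: units on the raw scale carry too little signal for two-group testing.
DEFAULT_ABUNDANCE_FLOOR = 2.0


def read_expression_matrix(
    path: str | Path,
    rna_class: str,
    design: Mapping[str, str] | pd.Series,
    abundance_floor: float | None = DEFAULT_ABUNDANCE_FLOOR,
) -> ExpressionMatrix:
    """Read a genes × samples log2 expression TSV.

    The first column holds gene ids, remaining columns are samples named in
    the header. Duplicate gene ids are collapsed to the row with the larger
    mean abundance (ties keep the first occurrence). Genes whose mean log2
    value falls below ``abundance_floor`` are removed; pass ``None`` to
    disable the floor.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValidationError(f"{path}: empty expression matrix")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric expression cell ({exc})") from exc
    if not isinstance(design, pd.Series):
        design = design_from_mapping(design)
    missing = [s for s in df.columns if s not in design.index]
    if missing:
        raise ValidationError(f"{path}: samples missing from design: {missing}")

    if df.index.has_duplicates:
        means = df.mean(axis=1)
        keep = []
        # stable: among equal means the earliest row wins
        best: dict[str, tuple[float, int]] = {}
        for pos, (gene, mu) in enumerate(zip(df.index, means)):
            cur = best.get(gene)
            if cur is None or mu > cur[0]:
                best[gene] = (mu, pos)
        keep = sorted(pos for _, pos in best.values())
        df = df.iloc[keep]

    if abundance_floor is not None:
        df = df.loc[df.mean(axis=1) >= abundance_floor]
    if df.empty:
        raise ValidationError(f"{path}: no genes left after abundance filtering")
    return ExpressionMatrix(values=df, group=design.loc[df.columns], rna_class=rna_class)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene")


def read_interaction_table(path: str | Path, target_class: str) -> InteractionTable:
    """Read a miRNA→target TSV with columns ``mirna``, ``target``, ``score``."""
    df = pd.read_csv(path, sep="\t")
    req = {"mirna", "target", "score"}
    if not req.issubset(df.columns):
        raise ValidationError(f"{path}: interaction table needs columns {sorted(req)}")
    try:
        df["score"] = df["score"].astype(float)
    except ValueError as exc:
        raise ValidationError(f"{path}: malformed score ({exc})") from exc
    return InteractionTable(records=df[["mirna", "target", "score"]], target_class=target_class)


def write_interaction_table(t: InteractionTable, path: str | Path) -> None:
    t.records.to_csv(path, sep="\t", index=False)


def load_table2_fixture() -> CeRNANetwork:
    """Load the packaged 99-triple published ceRNA network.

    The fixture is the printed mRNA–miRNA–lncRNA triple table of the
    source study, transcribed verbatim: 99 rows over 27 mRNAs, 25 miRNAs
    and 15 lncRNAs.
    """
    ref = importlib.resources.files("cernaforge").joinpath("data/table2_triples.tsv")
    with importlib.resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t")
    if len(df) != 99:
        raise ValidationError(f"triple-table fixture has {len(df)} rows, expected 99")
    return CeRNANetwork(triples=df[["mrna", "mirna", "lncrna"]].copy())


def packaged_gmt_path() -> Path:
    """Path to the packaged synthetic demonstration GMT."""
    ref = importlib.resources.files("cernaforge").joinpath(
        "data/toy_pathways_synthetic.gmt"
    )
    with importlib.resources.as_file(ref) as p:
        return Path(p)


# ---------------------------------------------------------------------------
# network export / import

def export_network(graph: nx.Graph, path: str | Path, format: str) -> None:
    """Write a typed network as SIF or GraphML.

    SIF rows are ``source<TAB>targets<TAB>target`` with the miRNA as
    source. GraphML keeps the ``rna_class`` node attribute and any
    ``pairing_score`` edge attribute; re-importing reproduces the graph.
    """
    if graph.number_of_nodes() == 0:
        raise ValidationError("refusing to export an empty network")
    path = Path(path)
    if format == "sif":
        with open(path, "w") as fh:
            for u, v in sorted(graph.edges()):
                # orient miRNA -> target when types are known
                if graph.nodes[u].get("rna_class") != "miRNA" and (
                    graph.nodes[v].get("rna_class") == "miRNA"
                ):
                    u, v = v, u
                fh.write(f"{u}\ttargets\t{v}\n")
    elif format == "graphml":
        nx.write_graphml(graph, path)
    else:
        raise ValidationError(f"unknown network format {format!r}")


def import_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)


# ---------------------------------------------------------------------------
# gene sets (GMT)

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name<TAB>description<TAB>member1<TAB>member2..."""
    sets: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: GMT row needs >= 3 fields")
            name, d, *members = parts
            members = [m for m in members if m]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = set(members)
            desc[name] = d
    return GeneSetCollection(sets=sets, descriptions=desc)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in coll.items():
            d = coll.descriptions.get(name, "")
            fh.write("\t".join([name, d, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# DE / pair / triple tables

def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    de.to_csv(path, sep="\t", index_label="gene")


def read_de_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    df["is_de"] = df["is_de"].astype(bool)
    return df


def write_cerna_tables(net: CeRNANetwork, pairs_path: str | Path, triples_path: str | Path) -> None:
    rows = [
        {
            "mrna": p.mrna,
            "lncrna": p.lncrna,
            "x": p.x,
            "K": p.K,
            "N": p.N,
            "M": p.M,
            "p_value": p.p_value,
            "pearson_r": p.pearson_r,
            "shared_mirnas": ",".join(sorted(p.shared_mirnas)),
        }
        for p in net.pairs
    ]
    pd.DataFrame(
        rows,
        columns=[
            "mrna", "lncrna", "x", "K", "N", "M", "p_value", "pearson_r", "shared_mirnas",
        ],
    ).to_csv(pairs_path, sep="\t", index=False)
    net.triples.to_csv(triples_path, sep="\t", index=False)
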