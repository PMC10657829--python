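"""Target-set overlap, interaction-network hubs, and pathway enrichment.

Covers the network-pharmacology arm of the pipeline: ADME screening of
herbal ingredients (oral bioavailability and drug-likeness thresholds),
three-way intersection of herb / microbe-metabolite / disease target sets,
degree-based hub ranking on a score-thresholded protein interaction network,
hypergeometric pathway over-representation with Benjamini-Hochberg
adjustment, and the microbe -> metabolite -> target -> pathway linkage table
behind a Sankey view.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

TARGET_LABELS = ("herb", "microbe_metabolite", "disease")


def _norm_gene(g: str) -> str:
    return str(g).strip().upper()


@dataclass(frozen=True)
class IngredientRecord:
    herb: str
    compound: str
    oral_bioavailability: float  # percent
    drug_likeness: float         # unitless [0, 1]
    targets: frozenset[str]

    def __post_init__(self) -> None:
        if self.oral_bioavailability < 0:
            raise ValueError("OB must be >= 0")
        if not 0.0 <= self.drug_likeness <= 1.0:
            raise ValueError("DL must be in [0, 1]")


@dataclass(frozen=True)
class TargetSet:
    label: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"target set {self.label!r} is empty")

    @classmethod
    def from_genes(cls, label: str, genes: Iterable[str]) -> "TargetSet":
        return cls(label, frozenset(_norm_gene(g) for g in genes if str(g).strip()))


@dataclass(frozen=True)
class EdgeList:
    """Undirected scored gene-gene edges (interaction-database export layout)."""

    edges: frozenset[tuple[str, str, float]]  # (a, b, score) with a < b
    score_cutoff: float = 0.4

    @classmethod
    def from_tuples(
        cls, tuples: Iterable[tuple[str, str, float]], score_cutoff: float = 0.4
    ) -> "EdgeList":
        edges = set()
        for a, b, s in tuples:
            a, b = _norm_gene(a), _norm_gene(b)
            if a == b:
                raise ValueError(f"self-loop on {a}")
            if not 0.0 <= float(s) <= 1.0:
                raise ValueError(f"score {s} outside [0, 1] for edge {a}-{b}")
            edges.add((min(a, b), max(a, b), float(s)))
        return cls(frozenset(edges), score_cutoff)


@dataclass(frozen=True)
class LinkageRow:
    microbe: str
    metabolite: str
    target: str
    pathway: str


# ---------------------------------------------------------------------------


def adme_filter(
    records: Sequence[IngredientRecord], ob_min: float = 30.0, dl_min: float = 0.18
) -> list[IngredientRecord]:
    """Keep ingredients with OB >= ob_min and DL >= dl_min (boundaries kept)."""
    return [
        r
        for r in records
        if r.oral_bioavailability >= ob_min and r.drug_likeness >= dl_min
    ]


def cross_targets(sets: Sequence[TargetSet]) -> dict:
    """Exact three-way intersection report (UpSet-style exclusive regions).

    Returns a dict with the seven exclusive region gene lists keyed by the
    sorted tuple of member labels, their cardinalities, and the full
    three-way intersection under ``core``.
    """
    if len(sets) != 3:
        raise ValueError("expected exactly three labeled target sets")
    by_label = {s.label: s.genes for s in sets}
    if len(by_label) != 3:
        raise ValueError("target set labels must be distinct")
    labels = tuple(by_label)
    regions: dict[tuple[str, ...], frozenset[str]] = {}
    for r in range(1, 4):
        for combo in combinations(labels, r):
            inside = frozenset.intersection(*(by_label[l] for l in combo))
            outside = frozenset.union(
                *(by_label[l] for l in labels if l not in combo), frozenset()
            )
            regions[tuple(sorted(combo))] = inside - outside
    core = frozenset.intersection(*by_label.values())
    return {
        "regions": regions,
        "cardinalities": {k: len(v) for k, v in regions.items()},
        "core": core,
        "n_core": len(core),
        "union": frozenset.union(*by_label.values()),
    }


def hub_ranking(
    edges: EdgeList, nodes: Iterable[str] | None = None, top_k: int | None = None
) -> list[tuple[str, int]]:
    """Degree ranking after applying the edge-score cutoff.

    Degree counts retained incident edges among ``nodes`` (default: every
    node in the edge list); descending with lexicographic tie-break.
    """
    g = nx.Graph()
    node_set = {_norm_gene(n) for n in nodes} if nodes is not None else None
    for a, b, s in edges.edges:
        if s >= edges.score_cutoff:
            if node_set is None or (a in node_set and b in node_set):
                g.add_edge(a, b)
    universe = node_set if node_set is not None else set(g.nodes)
    ranked = sorted(
        ((n, g.degree(n) if n in g else 0) for n in universe),
        key=lambda kv: (-kv[1], kv[0]),
    )
    return ranked[:top_k] if top_k is not None else ranked


def pathway_enrichment(
    gene_set: Iterable[str],
    pathway_map: Mapping[str, Iterable[str]],
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation per pathway with BH adjustment.

    p is the upper-tail probability of drawing at least the observed overlap
    when |gene_set| genes are sampled from the universe without replacement.
    The universe defaults to the union of all pathway members; pathways with
    no universe members are skipped with a warning.
    """
    genes = {_norm_gene(g) for g in gene_set}
    pmap = {p: {_norm_gene(g) for g in gs} for p, gs in pathway_map.items()}
    if not pmap:
        raise ValueError("pathway map is empty")
    if universe is None:
        uni = set().union(*pmap.values())
    else:
        uni = {_norm_gene(g) for g in universe}
    extra = genes - uni
    if extra:
        raise ValueError(f"gene set not contained in universe: {sorted(extra)[:5]}...")

    rows = []
    m = len(uni)
    n_draw = len(genes)
    for pw, members in pmap.items():
        members_u = members & uni
        if not members_u:
            logger.warning("pathway %s has no members in the universe; skipped", pw)
            continue
        k = len(genes & members_u)
        p = float(hypergeom.sf(k - 1, m, len(members_u), n_draw))
        rows.append({"pathway": pw, "overlap": k, "pathway_size": len(members_u), "p": p})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
        df = df.sort_values(["p", "pathway"]).reset_index(drop=True)
    return df


def linkage_table(
    core_targets: Iterable[str],
    microbe_metabolite_map: Sequence[tuple[str, str]],
    metabolite_target_map: Sequence[tuple[str, str]],
    target_pathway_map: Sequence[tuple[str, str]],
) -> list[LinkageRow]:
    """Join microbe -> metabolite -> target -> pathway, restricted to core targets.

    Row multiplicity is preserved so downstream Sankey widths can weight by
    the number of supporting chains.  Metabolites or targets that never join
    (dangling keys) are reported in the log.
    """
    core = {_norm_gene(t) for t in core_targets}
    mt = [(m, _norm_gene(t)) for m, t in metabolite_target_map]
    tp = [(_norm_gene(t), p) for t, p in target_pathway_map]

    metabolites_with_target = {m for m, _ in mt}
    dangling = [m for _, m in microbe_metabolite_map if m not in metabolites_with_target]
    if dangling:
        logger.warning("metabolites with no target mapping: %s", sorted(set(dangling)))

    rows: list[LinkageRow] = []
    for microbe, metabolite in microbe_metabolite_map:
        for m2, target in mt:
            if m2 != metabolite or target not in core:
                continue
            for t2, pathway in tp:
                if t2 == target:
                    rows.append(LinkageRow(microbe, metabolite, target, pathway))
    return rows


# ---------------------------------------------------------------------------
# file formats


def read_target_sets(path: str | Path) -> list[TargetSet]:
    """Two-column TSV (label, gene) -> one TargetSet per distinct label."""
    df = pd.read_csv(path, sep="\t", comment="#", names=["label", "gene"], header=0)
    return [
        TargetSet.from_genes(label, grp["gene"])
        for label, grp in df.groupby("label", sort=False)
    ]


def read_edge_list(path: str | Path, score_cutoff: float = 0.4) -> EdgeList:
    """TSV gene_a, gene_b, combined_score."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return EdgeList.from_tuples(
        df.itertuples(index=False, name=None), score_cutoff=score_cutoff
    )


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: pathway name, description, then member genes, tab-separated."""
    out: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        out[parts[0]] = {_norm_gene(g) for g in parts[2:] if g.strip()}
    return out
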