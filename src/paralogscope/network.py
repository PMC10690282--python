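"""Interaction-network features of paralog pairs and enrichment statistics.

Consumes generic gene-gene edge tables (physical or genetic interactions
with score epsilon and p-value), computes the network features used to
stratify redistribution scores — shared-interactor counts binned at the
cohort median, shortest-path-length bins, colocalization Jaccard indices —
and tests whether redistributed paralogs are enriched for private
interactors localized in the sister paralog's compartment (Fisher's exact
test with odds ratio).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .abundance import rank_sum_test

#: genetic-interaction stringency classes: p-value gate and epsilon rule
GI_CLASSES = ("lenient", "intermediate", "stringent", "stringent_neg", "synthetic_lethal")


@dataclass
class InteractionNetwork:
    """Undirected, deduplicated gene-gene interaction network.

    Edges carry ``type`` ("ppi" or "gi") and, for genetic interactions, the
    interaction score ``epsilon`` and its ``p``. Duplicate edges collapse to
    the strongest evidence (largest |epsilon|, then smallest p).
    """

    graph: nx.Graph

    @classmethod
    def from_edges(cls, edges: Sequence[tuple]) -> "InteractionNetwork":
        """Build from (geneA, geneB, type[, epsilon, p]) tuples."""
        g = nx.Graph()
        for edge in edges:
            a, b, etype = edge[0], edge[1], edge[2]
            eps = edge[3] if len(edge) > 3 else None
            p = edge[4] if len(edge) > 4 else None
            if a == b:
                continue  # self-loops removed during cleaning
            if g.has_edge(a, b):
                old = g.edges[a, b]
                if eps is not None and (
                    old.get("epsilon") is None or abs(eps) > abs(old["epsilon"])
                ):
                    old.update(epsilon=eps, p=p)
                continue
            g.add_edge(a, b, type=etype, epsilon=eps, p=p)
        return cls(graph=g)

    @classmethod
    def from_table(cls, table: pd.DataFrame | str) -> "InteractionNetwork":
        """Read a TSV/DataFrame with columns geneA, geneB, type[, epsilon, p]."""
        if isinstance(table, str):
            table = pd.read_csv(table, sep="\t")
        rows = []
        for _, r in table.iterrows():
            rows.append(
                (
                    r["geneA"],
                    r["geneB"],
                    r.get("type", "ppi"),
                    r.get("epsilon", None) if pd.notna(r.get("epsilon", np.nan)) else None,
                    r.get("p", None) if pd.notna(r.get("p", np.nan)) else None,
                )
            )
        return cls.from_edges(rows)

    def neighbors(self, gene: str) -> set[str]:
        if gene not in self.graph:
            return set()
        return set(self.graph.neighbors(gene))


def filter_ppi_table(table: pd.DataFrame) -> pd.DataFrame:
    """Physical high-throughput edge filter on a BioGRID-style table.

    Keeps rows whose ``experimental_system_type`` is ``physical`` and whose
    ``throughput`` contains ``High`` (column filters; no downloading).
    Missing columns are treated as passing.
    """
    mask = pd.Series(True, index=table.index)
    if "experimental_system_type" in table.columns:
        mask &= table["experimental_system_type"].str.lower() == "physical"
    if "throughput" in table.columns:
        mask &= table["throughput"].str.contains("High", case=False, na=False)
    return table[mask]


def filter_gi(network: InteractionNetwork, gi_class: str) -> list[tuple[str, str]]:
    """Genetic-interaction edges passing one of the stringency classes.

    lenient: p < 0.05; intermediate: p < 0.05 and |eps| > 0.08; stringent:
    p < 0.05 and (eps > 0.16 or eps < -0.12); stringent_neg: p < 0.05 and
    eps < -0.12; synthetic_lethal: p < 0.05 and eps < -0.35. Edges missing
    epsilon or p are skipped.
    """
    if gi_class not in GI_CLASSES:
        raise ValueError(f"unknown GI class {gi_class!r}; choose from {GI_CLASSES}")
    kept = []
    for a, b, d in network.graph.edges(data=True):
        if d.get("type") != "gi":
            continue
        eps, p = d.get("epsilon"), d.get("p")
        if eps is None or p is None:
            continue
        if p >= 0.05:
            continue
        ok = {
            "lenient": True,
            "intermediate": abs(eps) > 0.08,
            "stringent": eps > 0.16 or eps < -0.12,
            "stringent_neg": eps < -0.12,
            "synthetic_lethal": eps < -0.35,
        }[gi_class]
        if ok:
            kept.append((a, b))
    return kept


def shared_interactor_count(network: InteractionNetwork, gene: str, paralog: str) -> int:
    """|N(gene) ∩ N(paralog)|, excluding the pair members themselves."""
    shared = network.neighbors(gene) & network.neighbors(paralog)
    shared.discard(gene)
    shared.discard(paralog)
    return len(shared)


def shared_interactor_bin(
    network: InteractionNetwork,
    gene: str,
    paralog: str,
    all_pairs: Sequence[tuple[str, str]],
) -> tuple[str, int]:
    """Bin a pair's shared-interactor count against the cohort median.

    The cohort is every pair in ``all_pairs`` whose members are both present
    in the network. Counts strictly above the median bin ``high``; ties at
    the median go to ``low`` (the split is "fewer or more than the median").
    """
    cohort = [
        shared_interactor_count(network, a, b)
        for a, b in all_pairs
        if a in network.graph and b in network.graph
    ]
    if not cohort:
        raise ValueError("no cohort pairs present in the network")
    if gene not in network.graph or paralog not in network.graph:
        raise KeyError(f"{gene} or {paralog} absent from the network")
    count = shared_interactor_count(network, gene, paralog)
    med = float(np.median(cohort))
    return ("high" if count > med else "low"), count


def path_length_bin(
    network: InteractionNetwork, gene: str, paralog: str
) -> tuple[str, float]:
    """Unweighted shortest path between the pair, binned as "1" vs "1+".

    A direct edge gives bin "1"; length >= 2 or disconnected (raw length
    inf) gives "1+".
    """
    g = network.graph
    if gene not in g or paralog not in g:
        return "1+", float("inf")
    try:
        length = float(nx.shortest_path_length(g, gene, paralog))
    except nx.NetworkXNoPath:
        length = float("inf")
    return ("1" if length == 1 else "1+"), length


def coloc_jaccard(loc_a: set[str], loc_b: set[str]) -> tuple[float, bool]:
    """Colocalization Jaccard index: 100 * |A∩B| / |A∪B|, colocalized at >= 50."""
    if not loc_a or not loc_b:
        raise ValueError("localization sets must be non-empty")
    value = 100.0 * len(loc_a & loc_b) / len(loc_a | loc_b)
    return value, value >= 50.0


def private_interactors(
    network: InteractionNetwork, gene: str, paralog: str
) -> set[str]:
    """Neighbors of ``gene`` that are not neighbors of its sister paralog."""
    priv = network.neighbors(gene) - network.neighbors(paralog)
    priv.discard(paralog)
    return priv


def fisher_exact_2x2(table: np.ndarray) -> tuple[float | None, float]:
    """Odds ratio (Haldane 0.5 correction iff any zero cell) and two-sided
    Fisher exact p-value from the hypergeometric distribution.

    Degenerate margins (an empty row or column) give p = 1 and an undefined
    odds ratio (None).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a nonnegative 2x2 table")
    a, b, c, d = t.ravel()
    if min(a + b, c + d, a + c, b + d) == 0:
        return None, 1.0
    if min(a, b, c, d) == 0:
        orat = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orat = (a * d) / (b * c)
    _, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
    return float(orat), float(p)


def private_interactor_enrichment(
    redistributed: Sequence[bool], private_in_paralog_compartment: Sequence[bool]
) -> tuple[float | None, float, np.ndarray]:
    """Association between redistribution and having a private interactor in
    the sister paralog's compartment.

    Returns (odds ratio, two-sided Fisher p, the 2x2 table). Table rows are
    redistributed yes/no, columns private-in-paralog-compartment yes/no.
    """
    r = np.asarray(redistributed, dtype=bool)
    f = np.asarray(private_in_paralog_compartment, dtype=bool)
    if r.shape != f.shape:
        raise ValueError("flag vectors must align")
    table = np.array(
        [
            [int(np.sum(r & f)), int(np.sum(r & ~f))],
            [int(np.sum(~r & f)), int(np.sum(~r & ~f))],
        ]
    )
    orat, p = fisher_exact_2x2(table)
    return orat, p, table


def boxplot_stats(values: Sequence[float]) -> dict[str, float]:
    """Median, quartiles (linear interpolation) and 1.5 IQR whisker fences."""
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(q1 - 1.5 * iqr),
        "whisker_high": float(q3 + 1.5 * iqr),
    }


def compare_score_bins(
    scores: Sequence[float], bin_labels: Sequence[str]
) -> dict:
    """Two-sided rank-sum comparison of redistribution scores between two bins,
    with per-bin boxplot summaries."""
    s = np.asarray(scores, dtype=float)
    labels = np.asarray(bin_labels)
    uniq = sorted(set(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError(f"need exactly two bins, got {uniq}")
    a = s[labels == uniq[0]]
    b = s[labels == uniq[1]]
    if a.size == 0 or b.size == 0:
        raise ValueError("both bins must be non-empty")
    return {
        "bins": uniq,
        "p": rank_sum_test(a, b),
        uniq[0]: boxplot_stats(a),
        uniq[1]: boxplot_stats(b),
    }


def read_localization_table(path: str) -> dict[str, set[str]]:
    """Gene -> compartment set from a TSV with semicolon-separated labels."""
    table = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for _, row in table.iterrows():
        comps = {c.strip() for c in str(row["compartments"]).split(";") if c.strip()}
        if comps:
            out[row["gene"]] = comps
    return out
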