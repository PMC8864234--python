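"""Species co-use association rules and the derived network.

Each informant's cited species form one basket (an itemset); for every
ordered species pair (A → B) the *support* is the number of informants
citing both and the *confidence* is the conditional probability of B
given A, i.e. support / count(A).  Pairs meeting the support and
confidence thresholds become rules, and the rules collapse into an
undirected co-use graph whose edges carry the pair support and both
directed confidences.  Only pairwise rules are mined — the published
co-prescription style of network is pairwise — so plain enumeration
over observed pairs is both exact and fast at survey scale.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .indices import SpeciesIndexRow
from .survey_model import SurveyDataset

__all__ = [
    "Basket",
    "Rule",
    "build_baskets",
    "mine_rules",
    "to_network",
    "export_network",
    "import_network",
]


@dataclass(frozen=True)
class Basket:
    informant_id: str
    species: frozenset[str]


@dataclass(frozen=True)
class Rule:
    antecedent: str
    consequent: str
    support_count: int
    support_frac: float
    confidence: float


def build_baskets(ds: SurveyDataset) -> list[Basket]:
    """One deduplicated species set per included informant.

    Informants with no reports keep an empty basket so that basket count
    equals informant count (the support denominator N).
    """
    per_informant: dict[str, set[str]] = {
        i.informant_id: set() for i in ds.informants if i.included
    }
    for rep in ds.reports:
        if rep.informant_id in per_informant:
            per_informant[rep.informant_id].add(rep.species_id)
    return [
        Basket(informant_id=iid, species=frozenset(sp))
        for iid, sp in per_informant.items()
    ]


def mine_rules(
    baskets: Sequence[Basket],
    min_support: int = 2,
    min_confidence: float = 0.5,
) -> list[Rule]:
    """All ordered species pairs meeting the support/confidence floors.

    ``min_support`` is an informant count (co-citing informants);
    ``min_confidence`` a probability.  Output order is deterministic:
    support descending, then antecedent, then consequent.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if not 0 <= min_confidence <= 1:
        raise ValueError("min_confidence must be in [0, 1]")
    n = len(baskets)
    item_count: dict[str, int] = defaultdict(int)
    pair_count: dict[tuple[str, str], int] = defaultdict(int)
    for basket in baskets:
        for sp in basket.species:
            item_count[sp] += 1
        for a, b in combinations(sorted(basket.species), 2):
            pair_count[(a, b)] += 1
    rules: list[Rule] = []
    for (a, b), support in pair_count.items():
        if support < min_support:
            continue
        for ante, cons in ((a, b), (b, a)):
            confidence = support / item_count[ante]
            if confidence >= min_confidence:
                rules.append(
                    Rule(
                        antecedent=ante,
                        consequent=cons,
                        support_count=support,
                        support_frac=support / n if n else 0.0,
                        confidence=confidence,
                    )
                )
    rules.sort(key=lambda r: (-r.support_count, r.antecedent, r.consequent))
    return rules


def to_network(rules: Sequence[Rule], index_rows: Sequence[SpeciesIndexRow]) -> nx.Graph:
    """Collapse directed rules into an undirected co-use graph.

    Nodes are all indexed (cited) species weighted by global FC; each
    unordered pair with at least one rule becomes one edge carrying the
    pair support and the confidence in each direction (0.0 when that
    direction fell below the confidence floor).
    """
    by_id = {row.species_id: row for row in index_rows}
    g = nx.Graph(kind="co-use")
    for row in index_rows:
        g.add_node(row.species_id, canonical_name=row.canonical_name, fc=row.fc)
    for rule in rules:
        for sp in (rule.antecedent, rule.consequent):
            if sp not in by_id:
                raise ValueError(f"rule references species {sp!r} absent from index rows")
        a, b = sorted((rule.antecedent, rule.consequent))
        if not g.has_edge(a, b):
            g.add_edge(a, b, support=rule.support_count, confidence_ab=0.0, confidence_ba=0.0)
        key = "confidence_ab" if rule.antecedent == a else "confidence_ba"
        g.edges[a, b][key] = rule.confidence
    return g


def export_network(net: nx.Graph, path: str | Path, format: str = "graphml") -> Path:
    """Write the network as GraphML or an edge-list CSV (lossless)."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net, path)
    elif format == "edge-csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["species_a", "species_b", "support", "confidence_ab", "confidence_ba"])
            for a, b, data in sorted(net.edges(data=True)):
                writer.writerow([a, b, data["support"], data["confidence_ab"], data["confidence_ba"]])
    else:
        raise ValueError(f"unknown network format {format!r}")
    return path


def import_network(path: str | Path, format: str = "graphml") -> nx.Graph:
    """Read back a network written by :func:`export_network`."""
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        for _, _, data in g.edges(data=True):
            data["support"] = int(data["support"])
        return g
    if format == "edge-csv":
        g = nx.Graph(kind="co-use")
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                g.add_edge(
                    row["species_a"],
                    row["species_b"],
                    support=int(row["support"]),
                    confidence_ab=float(row["confidence_ab"]),
                    confidence_ba=float(row["confidence_ba"]),
                )
        return g
    raise ValueError(f"unknown network format {format!r}")
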