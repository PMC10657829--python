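"""Apriori frequent-itemset mining and association rules over prescriptions.

Level-wise Apriori with the downward-closure prune, single-item consequents,
and the standard support / confidence / lift metrics:

    support(A => c)    = P(A and c)
    confidence(A => c) = P(A and c) / P(A)
    lift(A => c)       = confidence / P(c)

Herbs below a frequency floor (e.g. used in 10 or fewer prescriptions) are
removed from the transactions before mining, matching how high-frequency
herb subsets are selected for rule analysis.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd


@dataclass(frozen=True)
class RuleConfig:
    min_support: float = 0.16
    min_confidence: float = 0.9
    max_itemset_size: int = 4
    frequency_floor: int = 0  # keep items with count strictly greater

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_support <= 1.0:
            raise ValueError("min_support must be in [0, 1]")
        if not 0.0 <= self.min_confidence <= 1.0:
            raise ValueError("min_confidence must be in [0, 1]")
        if self.max_itemset_size < 2:
            raise ValueError("max_itemset_size must be >= 2")


@dataclass(frozen=True)
class AssociationRule:
    antecedent: frozenset[str]
    consequent: str
    support: float
    confidence: float
    lift: float

    def __post_init__(self) -> None:
        if not self.antecedent:
            raise ValueError("empty antecedent not allowed")
        if self.consequent in self.antecedent:
            raise ValueError("consequent must be disjoint from antecedent")


def _apply_floor(
    transactions: Sequence[Iterable[str]], floor: int
) -> list[frozenset[str]]:
    ts = [frozenset(t) for t in transactions]
    counts = Counter(item for t in ts for item in t)
    keep = {item for item, c in counts.items() if c > floor}
    return [t & keep for t in ts]


def frequent_itemsets(
    transactions: Sequence[Iterable[str]], config: RuleConfig
) -> dict[frozenset[str], float]:
    """Mine frequent itemsets by level-wise candidate generation.

    Candidates of size k+1 are joins of frequent k-itemsets sharing a
    (k-1)-prefix; any candidate with an infrequent subset is pruned before
    counting (anti-monotonicity of support).  Output is identical to
    exhaustive enumeration on any corpus.
    """
    ts = _apply_floor(transactions, config.frequency_floor)
    ts = [t for t in ts]
    if not any(ts):
        raise ValueError("no transactions left after applying frequency floor")
    n = len(ts)

    counts = Counter(item for t in ts for item in t)
    current = {
        frozenset([i]): c / n
        for i, c in counts.items()
        if c / n >= config.min_support
    }
    result = dict(current)
    k = 1
    while current and k < config.max_itemset_size:
        # join step: unions of frequent k-itemsets that differ in one item
        items = sorted({i for s in current for i in s})
        prev = set(current)
        candidates = set()
        for s in current:
            for i in items:
                if i not in s:
                    cand = s | {i}
                    if len(cand) == k + 1 and all(
                        frozenset(sub) in prev for sub in combinations(cand, k)
                    ):
                        candidates.add(cand)
        ccounts = {c: 0 for c in candidates}
        for t in ts:
            for c in candidates:
                if c <= t:
                    ccounts[c] += 1
        current = {
            c: cnt / n for c, cnt in ccounts.items() if cnt / n >= config.min_support
        }
        result.update(current)
        k += 1
    return result


def generate_rules(
    itemsets: Mapping[frozenset[str], float], config: RuleConfig
) -> list[AssociationRule]:
    """All rules with a single-item consequent meeting the confidence bar.

    Sorted by support descending, then lexicographically on (antecedent,
    consequent) so ties are reported stably and in full.
    """
    rules = []
    for itemset, supp in itemsets.items():
        if len(itemset) < 2:
            continue
        for consequent in itemset:
            antecedent = itemset - {consequent}
            supp_a = itemsets.get(antecedent)
            supp_c = itemsets.get(frozenset([consequent]))
            if supp_a is None or supp_c is None:
                raise KeyError(
                    f"missing subset support for rule {sorted(antecedent)} => {consequent}"
                )
            conf = supp / supp_a
            if conf >= config.min_confidence:
                rules.append(
                    AssociationRule(antecedent, consequent, supp, conf, conf / supp_c)
                )
    rules.sort(key=lambda r: (-r.support, sorted(r.antecedent), r.consequent))
    return rules


def rule_network_table(rules: Sequence[AssociationRule]) -> pd.DataFrame:
    """Long-format parallel-coordinates table, one row per (rule, antecedent item).

    The ``hub_rank`` helper below ranks items by how many rules they take
    part in (antecedent or consequent), the criterion used to call out hub
    herbs in a parallel-coordinates rule plot.
    """
    if not rules:
        raise ValueError("need at least one rule")
    rows = []
    for ridx, r in enumerate(rules):
        for item in sorted(r.antecedent):
            rows.append(
                {
                    "rule": ridx,
                    "antecedent_item": item,
                    "consequent": r.consequent,
                    "support": r.support,
                    "confidence": r.confidence,
                    "lift": r.lift,
                }
            )
    return pd.DataFrame(rows)


def hub_rank(rules: Sequence[AssociationRule]) -> list[tuple[str, int]]:
    """Items ranked by the number of rules they participate in."""
    c: Counter[str] = Counter()
    for r in rules:
        for item in r.antecedent:
            c[item] += 1
        c[r.consequent] += 1
    return sorted(c.items(), key=lambda kv: (-kv[1], kv[0]))


def rules_frame(rules: Sequence[AssociationRule]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "antecedent": [";".join(sorted(r.antecedent)) for r in rules],
            "consequent": [r.consequent for r in rules],
            "support": [r.support for r in rules],
            "confidence": [r.confidence for r in rules],
            "lift": [r.lift for r in rules],
        }
    )
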