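import numpy as np
import pytest

from phytomr.mr import HarmonizedSnp


def make_snp(
    beta_exp: float,
    beta_out: float,
    se_out: float = 0.01,
    se_exp: float = 0.01,
    rsid: str = "rs1",
    eaf: float = 0.3,
) -> HarmonizedSnp:
    return HarmonizedSnp(
        rsid=rsid,
        beta_exp=beta_exp,
        se_exp=se_exp,
        beta_out=beta_out,
        se_out=se_out,
        eaf_exp=eaf,
        eaf_out=eaf,
        palindromic=False,
        action_taken="kept",
    )


@pytest.fixture
def snp_factory():
    counter = {"n": 0}

    def factory(beta_exp, beta_out, se_out=0.01, se_exp=0.01):
        counter["n"] += 1
        return make_snp(beta_exp, beta_out, se_out, se_exp, rsid=f"rs{counter['n']}")

    return factory


@pytest.fixture
def five_transactions():
    """The worked 5-transaction corpus used for rule-mining examples."""
    return [
        frozenset("AB"),
        frozenset("ABC"),
        frozenset("AC"),
        frozenset("BC"),
        frozenset("ABC"),
    ]


def brute_force_itemsets(transactions, min_support, max_size=4):
    """Exhaustive enumeration oracle for frequent-itemset mining."""
    from itertools import combinations

    ts = [frozenset(t) for t in transactions]
    items = sorted({i for t in ts for i in t})
    n = len(ts)
    out = {}
    for k in range(1, max_size + 1):
        for combo in combinations(items, k):
            s = frozenset(combo)
            supp = sum(1 for t in ts if s <= t) / n
            if supp >= min_support:
                out[s] = supp
    return out
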