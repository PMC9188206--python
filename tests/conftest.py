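"""Shared fixtures and independent oracles.

The oracles here deliberately share no code with the package: the deR
oracle ranks by explicit sort-and-scan, and the signature oracle
recounts support by exhaustive enumeration.
"""

import math

import numpy as np
import pandas as pd
import pytest

from teadscore.signature import DEExperiment


# ---------------------------------------------------------------------------
# Independent deR oracle (sort-based, no shared code with teadscore.scoring)
# ---------------------------------------------------------------------------

def brute_force_der(values: dict, pos, neg):
    """deR by explicit sort: mean-tie integer ranks / n, then Rp - Rn.

    ``values`` maps gene -> abundance (NaN = missing); ranks are computed
    over the measured members of pos | neg only.
    """
    members = set(pos) | set(neg)
    measured = [(g, v) for g, v in values.items()
                if g in members and not (isinstance(v, float) and math.isnan(v))]
    measured.sort(key=lambda kv: kv[1])
    n = len(measured)
    ranks = {}
    i = 0
    while i < n:
        j = i
        while j < n and measured[j][1] == measured[i][1]:
            j += 1
        mean_int_rank = sum(range(i + 1, j + 1)) / (j - i)
        for k in range(i, j):
            ranks[measured[k][0]] = mean_int_rank / n
        i = j
    rp = sum(ranks[g] for g in pos if g in ranks) / sum(g in ranks for g in pos)
    rn = sum(ranks[g] for g in neg if g in ranks) / sum(g in ranks for g in neg)
    return rp, rn, rp - rn


def brute_force_signature(experiments, alpha, min_support, conflict_policy):
    """Exhaustive support recount over every gene in every experiment."""
    genes = set()
    for e in experiments:
        genes |= set(e.table["gene"])
    pos, neg = set(), set()
    for g in sorted(genes):
        n_pos = n_neg = 0
        for e in experiments:
            rows = e.table[e.table["gene"] == g]
            for row in rows.itertuples(index=False):
                if row.p < alpha and row.effect != 0:
                    oriented = e.perturbation_sign * (1 if row.effect > 0 else -1)
                    if oriented > 0:
                        n_pos += 1
                    else:
                        n_neg += 1
        if conflict_policy == "strict":
            if n_pos >= min_support and n_neg == 0:
                pos.add(g)
            elif n_neg >= min_support and n_pos == 0:
                neg.add(g)
        else:
            if n_pos >= min_support and n_pos > n_neg:
                pos.add(g)
            elif n_neg >= min_support and n_neg > n_pos:
                neg.add(g)
    return pos, neg


@pytest.fixture
def der_oracle():
    return brute_force_der


@pytest.fixture
def signature_oracle():
    return brute_force_signature


# ---------------------------------------------------------------------------
# The three-experiment toy derivation fixture
# ---------------------------------------------------------------------------
# G1: significant concordant +1 in 2 of 3   -> positive effector
# G2: significant concordant -1 in 2 of 3   -> negative effector
# G3: significant in exactly 1              -> excluded (below min_support)
# G4: significant +1 once and -1 once       -> excluded under strict policy
# G5: zero-effect significant + noise       -> never counted

def _exp(exp_id, sign, rows):
    return DEExperiment(
        experiment_id=exp_id, perturbation_sign=sign,
        table=pd.DataFrame(rows, columns=["gene", "effect", "p"]))


@pytest.fixture
def toy_experiments():
    e1 = _exp("E1_YAP1_KO", -1, [
        ("G1", -2.0, 0.001), ("G2", 1.5, 0.001), ("G3", -2.0, 0.001),
        ("G4", -2.0, 0.005), ("G5", 0.1, 0.8),
    ])
    e2 = _exp("E2_LATS2_KO", +1, [
        ("G1", 1.8, 0.002), ("G2", -1.2, 0.004), ("G3", 1.0, 0.5),
        ("G4", -1.4, 0.003), ("G5", 0.0, 0.001),
    ])
    e3 = _exp("E3_YAP1_S127A", +1, [
        ("G1", 0.5, 0.2), ("G2", -0.3, 0.3), ("G3", 0.2, 0.9),
        ("G4", 1.0, 0.5), ("G5", -0.05, 0.9),
    ])
    return [e1, e2, e3]


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
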