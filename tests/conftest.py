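"""Shared fixtures and independent brute-force oracles.

The oracles are deliberately naive re-derivations (exact rational
enumeration, pairwise counting, greedy Lance-Williams agglomeration) kept
independent of the library code paths they check.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

import escreen as es


# ---------------------------------------------------------------------------
# Oracles


def fisher_oracle(TP: int, FP: int, FN: int, TN: int) -> float:
    """Two-sided Fisher exact p by exact rational hypergeometric enumeration.

    Conditions on both margins; sums P(x) over all tables whose probability
    does not exceed the observed table's (exact comparison in Q).
    """
    r1, r2 = TP + FP, FN + TN
    k = TP + FN
    n = r1 + r2
    denom = comb(n, k)

    def pmf(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, k - x), denom)

    p_obs = pmf(TP)
    total = Fraction(0)
    for x in range(max(0, k - r2), min(r1, k) + 1):
        if pmf(x) <= p_obs:
            total += pmf(x)
    return float(min(total, Fraction(1)))


def auc_oracle(scores, labels) -> float:
    """AUC as the pairwise concordance fraction, ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


def ward_oracle(points: np.ndarray):
    """Greedy Ward agglomeration via explicit centroid/size bookkeeping.

    Returns the merge sequence [(frozenset_a, frozenset_b, height), ...]
    with the scipy height convention (singleton pairs merge at their
    Euclidean distance).
    """
    points = np.asarray(points, dtype=float)
    clusters = {i: (frozenset([i]), points[i], 1) for i in range(len(points))}
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(sorted(clusters), 2):
            _, ca, na = clusters[a]
            _, cb, nb = clusters[b]
            d = np.sqrt(2.0 * na * nb / (na + nb)) * np.linalg.norm(ca - cb)
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        sa, ca, na = clusters.pop(a)
        sb, cb, nb = clusters.pop(b)
        merged = sa | sb
        centroid = (na * ca + nb * cb) / (na + nb)
        key = min(merged)
        clusters[key] = (merged, centroid, na + nb)
        merges.append((sa, sb, d))
    return merges


def hill_response(conc, ac50, slope, max_effect, direction):
    """Direct evaluation of the generating Hill response (test-side copy)."""
    conc = np.asarray(conc, dtype=float)
    frac = max_effect * (conc / ac50) ** slope / (1.0 + (conc / ac50) ** slope)
    return 1.0 - frac if direction == "down" else 1.0 + frac


def recovery_table(truth: pd.DataFrame, calls: pd.DataFrame) -> pd.DataFrame:
    """Truly-active truth rows joined to calls, with the 0.15-dex hit flag."""
    tr = truth[truth["endpoint"].isin(es.doseresponse.ENDPOINTS)
               & truth["ac50_change_uM"].notna()]
    merged = tr.merge(calls, on=["chemical", "endpoint"], how="left")
    with np.errstate(divide="ignore", invalid="ignore"):
        merged["log_ratio"] = np.log10(merged["ac50_uM"] / merged["ac50_change_uM"])
    merged["hit"] = merged["active"].fillna(False).astype(bool) & (
        merged["log_ratio"].abs() <= 0.15
    )
    return merged


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture(scope="session")
def table1():
    return es.load_table1()


@pytest.fixture(scope="session")
def zero_noise_screen():
    wells, truth = es.generate_screen(30, noise=es.simulate.ZERO_NOISE)
    responses = es.process_screen(wells)
    calls = es.call_screen(responses)
    return wells, truth, responses, calls


@pytest.fixture(scope="session")
def screen50():
    """The recovery experiment screen: 50 chemicals, 5% CV noise, seed 7."""
    wells, truth = es.generate_screen(50, noise=es.NoiseModel(seed=7))
    responses = es.process_screen(wells)
    calls = es.call_screen(responses)
    return wells, truth, responses, calls
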