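"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest

from aimpanel import (
    FrequencyTable,
    GenotypeMatrix,
    LocusRecord,
    SimulationSpec,
    simulate_genotypes,
    table2_fixture,
)


@pytest.fixture(scope="session")
def table2() -> FrequencyTable:
    return table2_fixture()


@pytest.fixture()
def two_group_panel() -> tuple[GenotypeMatrix, FrequencyTable, "object"]:
    """Two divergent unadmixed groups, 60 individuals, 40 loci."""
    spec = SimulationSpec(
        groups=[("grpA", 30), ("grpB", 30)], n_loci=40, divergence_scale=0.35, seed=101
    )
    return simulate_genotypes(spec)


@pytest.fixture()
def three_group_panel():
    spec = SimulationSpec(
        groups=[("P1", 20), ("P2", 20), ("P3", 20)],
        n_loci=48,
        divergence_scale=0.35,
        seed=77,
    )
    return simulate_genotypes(spec)


def make_loci(n: int, chrom: str = "1", start: int = 1_000_000, step: int = 20_000_000):
    return [
        LocusRecord(f"L{i}", "A", "G", chrom, start + i * step, intronic=True)
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# independent oracles

def hwe_exact_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact-rational enumeration oracle for the conditional HWE test.

    Enumerates every heterozygote configuration compatible with the
    observed allele counts, computes each configuration's conditional
    probability with exact Fractions, and sums those not exceeding the
    observed configuration's probability.  NaN under the same convention
    as the implementation (monomorphic or single-copy minor allele).
    """
    n = n_aa + n_ab + n_bb
    n_a, n_b = 2 * n_aa + n_ab, 2 * n_bb + n_ab
    if min(n_a, n_b) <= 1:
        return float("nan")
    fact = math.factorial

    def weight(h: int) -> Fraction:
        # P(h | n, n_a) ∝ n! 2^h / ((n_a-h)/2)! h! ((n_b-h)/2)!
        return Fraction(2**h, fact((n_a - h) // 2) * fact(h) * fact((n_b - h) // 2))

    hs = range(min(n_a, n_b) % 2, min(n_a, n_b) + 1, 2)
    weights = {h: weight(h) for h in hs}
    total = sum(weights.values())
    obs = weights[n_ab]
    p = sum(w for w in weights.values() if w <= obs)
    return float(Fraction(p, total))


def in_statistic_oracle(freq_rows: np.ndarray, weights: np.ndarray) -> float:
    """Direct scalar evaluation of the informativeness formula for one locus.

    Accumulates the entropy terms allele by allele and group by group in
    plain Python floats — no vectorisation shared with the library path.
    """

    def xlogx(p: float) -> float:
        return p * math.log(p) if p > 0 else 0.0

    total = 0.0
    for allele_freqs in (list(freq_rows), [1.0 - p for p in freq_rows]):
        pbar = sum(w * p for w, p in zip(weights, allele_freqs))
        total += -xlogx(pbar)
        for w, p in zip(weights, allele_freqs):
            total += w * xlogx(p)
    return total


def naive_bayes_loglik_oracle(
    dosages: np.ndarray, p_corrected: np.ndarray
) -> np.ndarray:
    """Per-group log-likelihood of one individual, locus-by-locus product."""
    n_groups = p_corrected.shape[1]
    out = np.zeros(n_groups)
    for k in range(n_groups):
        ll = 0.0
        for j, g in enumerate(dosages):
            if g < 0:
                continue
            p = p_corrected[j, k]
            if g == 2:
                ll += math.log(p * p)
            elif g == 1:
                ll += math.log(2 * p * (1 - p))
            else:
                ll += math.log((1 - p) * (1 - p))
        out[k] = ll
    return out
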