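"""Per-locus population statistics.

Implements the statistics an AIM-panel study runs per locus:

* pooled ancestral-allele frequencies per continental group,
* the exact conditional Hardy-Weinberg test with Bonferroni correction,
* pairwise allele-frequency differentials,
* Rosenberg's informativeness for assignment (In), both over all K groups
  and "population-specific" one-vs-rest, with cumulative sums and
  threshold counts.

The In statistic for K groups with weights :math:`w_j` is

.. math::

    I_n = \\sum_{a \\in \\{anc, der\\}} \\Big( -\\bar p_a \\log \\bar p_a
          + \\sum_j w_j\\, p_{aj} \\log p_{aj} \\Big),
    \\qquad \\bar p_a = \\sum_j w_j p_{aj},

with natural logarithms and :math:`0 \\log 0 \\equiv 0`.  It is zero when
every group has the same frequency and bounded by :math:`\\log K`.

The one-vs-rest ("population-specific") In of a target group is the
two-group In between that group's frequency and the pooled frequency of
the remaining groups.  By default the pooled rest is weighted by group
sample sizes when the table carries them (pooling individuals, the way a
combined reference sample would be counted) and unweighted otherwise; the
two sides of the two-group statistic carry equal weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .containers import FrequencyTable, GenotypeMatrix, GroupAssignment, MISSING

__all__ = [
    "HWEResult",
    "InResult",
    "allele_frequencies",
    "hwe_exact",
    "hwe_scan",
    "bonferroni_alpha",
    "freq_differential",
    "informativeness_multigroup",
    "informativeness_onevsrest",
    "compute_in",
    "cumulative_in",
    "count_high_in",
]


# ---------------------------------------------------------------------------
# allele frequencies

def allele_frequencies(
    geno: GenotypeMatrix,
    groups: GroupAssignment | None = None,
    mode: Literal["pooled", "mean_of_populations"] = "pooled",
) -> FrequencyTable:
    """Ancestral-allele frequencies per group.

    ``pooled`` (default) counts alleles over all individuals of a group:
    ``freq[i, j] = sum(dosages in group j at locus i) / (2 * n_called)``.
    ``mean_of_populations`` averages the per-population frequencies within
    each group instead (populations weighted equally regardless of size).
    Cells with no non-missing calls are NaN.

    The returned table carries per-group diploid counts as sample sizes.
    """
    if groups is None:
        groups = GroupAssignment.identity(geno.population_labels)
    labels = np.asarray(groups.groups_for(geno))
    group_names = groups.group_names
    d = geno.dosage_float()

    def _pooled(rows: np.ndarray) -> np.ndarray:
        sub = d[rows]
        called = np.sum(~np.isnan(sub), axis=0)
        with np.errstate(invalid="ignore"):
            return np.nansum(sub, axis=0) / (2.0 * np.where(called > 0, called, np.nan))

    cols = []
    sizes: dict[str, int] = {}
    pops = np.asarray(geno.population_labels)
    for g in group_names:
        rows = np.flatnonzero(labels == g)
        sizes[g] = len(rows)
        if mode == "pooled":
            cols.append(_pooled(rows))
        elif mode == "mean_of_populations":
            per_pop = [
                _pooled(rows[pops[rows] == p]) for p in dict.fromkeys(pops[rows])
            ]
            cols.append(np.nanmean(np.vstack(per_pop), axis=0))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    freq = np.column_stack(cols)
    return FrequencyTable(geno.loci, group_names, freq, sample_sizes=sizes)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test

@dataclass(frozen=True)
class HWEResult:
    """Exact HWE test of one locus in one population."""

    locus: str
    population: str
    counts: tuple[int, int, int]  # (hom ancestral, het, hom derived)
    p_value: float  # NaN when the test is undefined


def hwe_exact(counts: Sequence[int]) -> float:
    """Exact conditional Hardy-Weinberg test for a bi-allelic locus.

    Given genotype counts ``(n_AA, n_Aa, n_aa)``, conditions on the allele
    counts and sums the probabilities of every heterozygote configuration
    whose conditional probability does not exceed that of the observed one
    (exact probability test, no mid-p).

    Returns NaN when fewer than two alleles are effectively observed: the
    locus is monomorphic, or the minor allele is present in a single copy
    (only one configuration exists, so the test carries no information).
    """
    n_aa_, n_ab, n_bb = (int(c) for c in counts)
    if n_aa_ < 0 or n_ab < 0 or n_bb < 0:
        raise ValueError(f"negative genotype count in {counts}")
    n = n_aa_ + n_ab + n_bb
    n_a = 2 * n_aa_ + n_ab
    n_b = 2 * n_bb + n_ab
    minor = min(n_a, n_b)
    if minor <= 1:
        return float("nan")

    # log P(het = h | allele counts) up to a shared constant:
    #   P ∝ 2^h / (n_AA! n_Aa! n_aa!)   with n_AA=(n_a-h)/2, n_aa=(n_b-h)/2
    hets = np.arange(minor % 2, minor + 1, 2)
    log2 = math.log(2.0)
    logp = np.array(
        [
            h * log2
            - math.lgamma((n_a - h) // 2 + 1)
            - math.lgamma(h + 1)
            - math.lgamma((n_b - h) // 2 + 1)
            for h in hets
        ]
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[np.flatnonzero(hets == n_ab)[0]]
    # tolerance absorbs floating-point ties between equally likely configs
    p = probs[probs <= obs * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def hwe_scan(
    geno: GenotypeMatrix, populations: Sequence[str] | None = None
) -> list[HWEResult]:
    """Exact HWE test of every locus in every (or the named) population."""
    pops = np.asarray(geno.population_labels)
    which = list(dict.fromkeys(pops)) if populations is None else list(populations)
    out: list[HWEResult] = []
    for p in which:
        sub = geno.geno[pops == p]
        for j, rec in enumerate(geno.loci):
            col = sub[:, j]
            col = col[col != MISSING]
            c = (int(np.sum(col == 2)), int(np.sum(col == 1)), int(np.sum(col == 0)))
            out.append(HWEResult(rec.rs_id, p, c, hwe_exact(c)))
    return out


def bonferroni_alpha(alpha: float, n_tests: int) -> float:
    """Family-wise significance level alpha / n_tests."""
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# frequency differentials

def freq_differential(freqs: FrequencyTable, rs_id: str) -> tuple[dict[tuple[str, str], float], float]:
    """All pairwise |p_j - p_k| for one locus, and their maximum.

    Pairs involving a NaN frequency are NaN; the maximum is taken over
    defined pairs (NaN if none are defined).
    """
    row = freqs.row(rs_id)
    names = freqs.group_names
    pairs: dict[tuple[str, str], float] = {}
    for j in range(len(names)):
        for k in range(j + 1, len(names)):
            pairs[(names[j], names[k])] = abs(row[j] - row[k])
    vals = np.array(list(pairs.values()))
    mx = float(np.nanmax(vals)) if np.any(~np.isnan(vals)) else float("nan")
    return pairs, mx


def max_differential(freqs: FrequencyTable) -> pd.Series:
    """Per-locus maximum pairwise frequency differential."""
    f = freqs.freq
    diffs = np.abs(f[:, :, None] - f[:, None, :])
    with np.errstate(all="ignore"):
        mx = np.nanmax(diffs.reshape(f.shape[0], -1), axis=1)
    return pd.Series(mx, index=freqs.rs_ids)


# ---------------------------------------------------------------------------
# informativeness for assignment

def _xlogx(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        v = p * np.log(p)
    return np.where(np.asarray(p) > 0, v, np.where(np.isnan(p), np.nan, 0.0))


def _in_from_matrix(p: np.ndarray, w: np.ndarray) -> np.ndarray:
    """In per locus for a loci x groups frequency matrix with group weights."""
    total = np.zeros(p.shape[0])
    for q in (p, 1.0 - p):
        pbar = q @ w
        total = total - _xlogx(pbar) + _xlogx(q) @ w
    # clip tiny negative round-off; an exact zero stays zero
    return np.where(total < 0, np.where(total > -1e-12, 0.0, total), total)


def informativeness_multigroup(
    freqs: FrequencyTable,
    weights: Sequence[float] | None = None,
    log_base: float = math.e,
) -> pd.Series:
    """Rosenberg's In over all K groups, per locus.

    ``weights`` default to equal; they must sum to 1.  Loci with a NaN
    frequency in any group get NaN.
    """
    if freqs.n_groups < 2:
        raise ValueError("informativeness requires at least 2 groups")
    if weights is None:
        w = np.full(freqs.n_groups, 1.0 / freqs.n_groups)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (freqs.n_groups,) or not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("weights must have one entry per group and sum to 1")
    vals = _in_from_matrix(freqs.freq, w)
    if log_base != math.e:
        vals = vals / math.log(log_base)
    return pd.Series(vals, index=freqs.rs_ids)


def informativeness_onevsrest(
    freqs: FrequencyTable,
    target_group: str,
    rest_weights: Literal["sample_size", "equal"] | Sequence[float] = "sample_size",
) -> pd.Series:
    """Population-specific In: target group versus the pooled rest.

    The rest frequency is a weighted mean of the other groups' frequencies:
    by sample size when the table carries sizes (``"sample_size"``, the
    default, falling back to equal weights when it does not), unweighted
    (``"equal"``), or explicit weights over the non-target groups.  The
    two-group In then uses equal weights on target and rest.
    """
    if freqs.n_groups < 2:
        raise ValueError("one-vs-rest requires at least 2 groups")
    j = freqs.group_index(target_group)
    rest_names = [g for g in freqs.group_names if g != target_group]
    if isinstance(rest_weights, str):
        if rest_weights == "equal" or freqs.sample_sizes is None:
            w = np.full(len(rest_names), 1.0 / len(rest_names))
        elif rest_weights == "sample_size":
            w = freqs.group_weights(rest_names)
        else:
            raise ValueError(f"unknown rest_weights {rest_weights!r}")
    else:
        w = np.asarray(rest_weights, dtype=float)
        if w.shape != (len(rest_names),):
            raise ValueError("explicit rest_weights must cover the non-target groups")
        w = w / w.sum()
    rest_idx = [freqs.group_index(g) for g in rest_names]
    p_target = freqs.freq[:, j]
    p_rest = freqs.freq[:, rest_idx] @ w
    two = np.column_stack([p_target, p_rest])
    vals = _in_from_matrix(two, np.array([0.5, 0.5]))
    return pd.Series(vals, index=freqs.rs_ids)


@dataclass
class InResult:
    """Per-locus informativeness summary over a panel.

    ``in_onevsrest`` is a loci x groups DataFrame of population-specific
    In values; ``cumulative`` its per-group column sums; ``counts`` the
    number of loci at or above ``threshold`` per group.
    """

    in_multigroup: pd.Series
    in_onevsrest: pd.DataFrame
    cumulative: pd.Series
    counts_ge_threshold: pd.Series
    threshold: float

    def summary(self, decimals: int = 4) -> pd.DataFrame:
        df = self.in_onevsrest.round(decimals).copy()
        df.insert(0, "In_all_groups", self.in_multigroup.round(decimals))
        return df


def compute_in(
    freqs: FrequencyTable,
    threshold: float = 0.1,
    rest_weights: Literal["sample_size", "equal"] | Sequence[float] = "sample_size",
) -> InResult:
    """Multigroup and one-vs-rest In for every locus, with panel summaries."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    ovr = pd.DataFrame(
        {
            g: informativeness_onevsrest(freqs, g, rest_weights=rest_weights)
            for g in freqs.group_names
        }
    )
    return InResult(
        in_multigroup=informativeness_multigroup(freqs),
        in_onevsrest=ovr,
        cumulative=ovr.sum(axis=0, skipna=False),
        counts_ge_threshold=(ovr >= threshold).sum(axis=0),
        threshold=threshold,
    )


def cumulative_in(result: InResult, group: str) -> float:
    """Sum of one-vs-rest In over loci for one group (NaN-propagating)."""
    if group not in result.in_onevsrest.columns:
        raise KeyError(f"group {group!r} not in In result")
    return float(result.in_onevsrest[group].sum(skipna=False))


def count_high_in(result: InResult, group: str, threshold: float = 0.1) -> int:
    """Number of loci whose one-vs-rest In for ``group`` is >= threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if group not in result.in_onevsrest.columns:
        raise KeyError(f"group {group!r} not in In result")
    return int((result.in_onevsrest[group] >= threshold).sum())
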