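"""Synthetic genotype and candidate-locus generation.

The generator produces the data structures the analyses assume: unlinked
bi-allelic SNPs, populations in Hardy-Weinberg equilibrium with divergent
allele frequencies, optionally admixed individuals with Dirichlet
ancestry proportions, and candidate-locus tables engineered to violate
specific selection criteria.

All sampling is allele-wise: each of an individual's two allele copies
draws its source group from the individual's ancestry vector q_i (a
point mass for unadmixed individuals) and then its allele from that
source's frequency.  Unadmixed dosages are therefore Binomial(2, p) by
construction, and one-hot admixture proportions reduce *exactly* to the
unadmixed sampling path.

A single integer seed drives named sub-streams (frequencies, ancestry,
genotypes, missingness), so generation is a pure function of the spec
and adding a stream does not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import MISSING, FrequencyTable, GenotypeMatrix, LocusRecord
from .datasets import table2_fixture  # re-exported for convenience

__all__ = [
    "SimulationSpec",
    "simulate_genotypes",
    "simulate_candidates",
    "table2_fixture",
]

_STREAMS = {"freqs": 1, "ancestry": 2, "genotypes": 3, "missing": 4, "candidates": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), _STREAMS[stream]])
    )


@dataclass
class SimulationSpec:
    """Parameters of one synthetic genotype panel.

    ``freq_model`` is either an explicit :class:`FrequencyTable` (group
    names must match ``groups``), or a divergence draw: a shared baseline
    frequency ~ Uniform(0.1, 0.9) per locus perturbed independently per
    group.  ``divergence`` selects additive Gaussian perturbations
    (``"perturb"``, scale ``divergence_scale``) or the Balding-Nichols
    model (``"balding_nichols"``, Beta draws with differentiation
    ``fst``); frequencies are truncated to [0.01, 0.99].

    ``admixture`` optionally makes individuals admixed: either an
    explicit per-individual Q matrix (rows on the simplex, one column per
    group) or a symmetric Dirichlet concentration ``alpha`` from which Q
    rows are drawn.
    """

    groups: Sequence[tuple[str, int]]
    n_loci: int = 48
    loci: Sequence[LocusRecord] | None = None
    freq_model: FrequencyTable | None = None
    divergence: Literal["perturb", "balding_nichols"] = "perturb"
    divergence_scale: float = 0.2
    fst: float = 0.15
    admixture: np.ndarray | float | None = None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group is required")
        for name, n in self.groups:
            if n < 1:
                raise ValueError(f"group {name!r} needs n_individuals >= 1, got {n}")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.loci is not None:
            self.n_loci = len(self.loci)
        if self.freq_model is not None:
            names = [g for g, _ in self.groups]
            if self.freq_model.group_names != names:
                raise ValueError(
                    "freq_model group names must match spec groups "
                    f"({self.freq_model.group_names} vs {names})"
                )
        if isinstance(self.admixture, np.ndarray):
            n_total = sum(n for _, n in self.groups)
            if self.admixture.shape != (n_total, len(self.groups)):
                raise ValueError("explicit Q must be individuals x groups")
            if not np.allclose(self.admixture.sum(axis=1), 1.0):
                raise ValueError("Q rows must sum to 1")
        elif self.admixture is not None and self.admixture <= 0:
            raise ValueError("Dirichlet alpha must be positive")

    @property
    def group_names(self) -> list[str]:
        return [g for g, _ in self.groups]

    @property
    def n_individuals(self) -> int:
        return sum(n for _, n in self.groups)


def _default_loci(n_loci: int) -> list[LocusRecord]:
    # synthetic map: cycle chromosomes 1-22, 20 Mb apart within a chromosome
    out = []
    for j in range(n_loci):
        chrom = str(j % 22 + 1)
        pos = 1_000_000 + (j // 22) * 20_000_000
        out.append(LocusRecord(f"snp{j:04d}", "A", "G", chrom, pos, intronic=True))
    return out


def _draw_frequencies(spec: SimulationSpec) -> FrequencyTable:
    if spec.freq_model is not None:
        return spec.freq_model
    rng = _rng(spec.seed, "freqs")
    K = len(spec.groups)
    base = rng.uniform(0.1, 0.9, size=spec.n_loci)
    if spec.divergence == "perturb":
        p = base[:, None] + rng.normal(0.0, spec.divergence_scale, size=(spec.n_loci, K))
    elif spec.divergence == "balding_nichols":
        c = (1.0 - spec.fst) / spec.fst
        p = rng.beta(base[:, None] * c, (1.0 - base[:, None]) * c, size=(spec.n_loci, K))
    else:
        raise ValueError(f"unknown divergence model {spec.divergence!r}")
    p = np.clip(p, 0.01, 0.99)
    loci = list(spec.loci) if spec.loci is not None else _default_loci(spec.n_loci)
    sizes = {g: n for g, n in spec.groups}
    return FrequencyTable(loci, spec.group_names, p, sample_sizes=sizes)


def simulate_genotypes(
    spec: SimulationSpec,
) -> tuple[GenotypeMatrix, FrequencyTable, pd.DataFrame]:
    """Generate genotypes plus the true frequencies and true Q.

    Returns ``(geno, true_freqs, true_Q)``; ``true_Q`` is an
    individuals x groups DataFrame (one-hot for unadmixed individuals).
    """
    freqs = _draw_frequencies(spec)
    K = len(spec.groups)
    n = spec.n_individuals

    labels: list[str] = []
    ids: list[str] = []
    for g, cnt in spec.groups:
        for i in range(cnt):
            labels.append(g)
            ids.append(f"{g}_{i:03d}")

    if spec.admixture is None:
        Q = np.zeros((n, K))
        start = 0
        for k, (_, cnt) in enumerate(spec.groups):
            Q[start : start + cnt, k] = 1.0
            start += cnt
    elif isinstance(spec.admixture, np.ndarray):
        Q = spec.admixture.astype(float)
    else:
        Q = _rng(spec.seed, "ancestry").dirichlet(
            np.full(K, float(spec.admixture)), size=n
        )

    rng = _rng(spec.seed, "genotypes")
    # two allele copies: source ~ Categorical(q_i), allele ~ Bernoulli(p_source)
    geno = np.zeros((n, spec.n_loci), dtype=np.int8)
    cum = np.cumsum(Q, axis=1)
    for copy in range(2):
        u = rng.random(size=(n, 1))
        src = (u > cum[:, :-1]).sum(axis=1) if K > 1 else np.zeros(n, dtype=int)
        p_ind = freqs.freq[:, src].T  # individuals x loci
        geno += (rng.random(size=(n, spec.n_loci)) < p_ind).astype(np.int8)

    if spec.missing_rate > 0:
        miss = _rng(spec.seed, "missing").random(size=geno.shape) < spec.missing_rate
        geno = np.where(miss, MISSING, geno).astype(np.int8)

    gm = GenotypeMatrix(ids, labels, list(freqs.loci), geno)
    true_q = pd.DataFrame(Q, index=ids, columns=spec.group_names)
    return gm, freqs, true_q


# ---------------------------------------------------------------------------
# candidate tables with planned criterion violations

def simulate_candidates(
    spec: SimulationSpec,
    violation_plan: Mapping[str, int] | None = None,
) -> tuple[list[LocusRecord], FrequencyTable, pd.DataFrame, pd.DataFrame]:
    """Candidate loci engineered to violate exactly the planned criteria.

    ``violation_plan`` counts per criterion: ``spacing_pairs`` (pairs of
    loci placed < 10 Mb apart on one chromosome), ``low_diff`` (loci whose
    group frequencies are near-identical), ``hwe`` (loci given an
    all-heterozygote genotype configuration in one reference population),
    ``non_intronic``.  Violations are assigned to disjoint loci.

    Returns ``(loci, freqs, hwe_pvalue_frame, audit)`` where ``audit``
    has one row per locus with a boolean column per planned violation.
    """
    plan = {"spacing_pairs": 0, "low_diff": 0, "hwe": 0, "non_intronic": 0}
    plan.update(violation_plan or {})
    neg = [k for k, v in plan.items() if v < 0]
    if neg:
        raise ValueError(f"negative violation counts: {neg}")

    n_violating = 2 * plan["spacing_pairs"] + plan["low_diff"] + plan["hwe"] + plan["non_intronic"]
    if n_violating > spec.n_loci:
        raise ValueError(
            f"plan needs {n_violating} loci but the spec provides only {spec.n_loci}"
        )

    freqs = _draw_frequencies(spec)
    # guarantee clean candidates pass the differential criterion
    f = freqs.freq.copy()
    K = f.shape[1]
    spread = np.abs(f.max(axis=1) - f.min(axis=1))
    for i in np.flatnonzero(spread < 0.35):
        f[i, 0], f[i, -1] = 0.9, 0.2 if K > 1 else 0.9
    loci = [
        LocusRecord(r.rs_id, r.allele_ancestral, r.allele_derived, r.chromosome,
                    r.position_bp, intronic=True)
        for r in freqs.loci
    ]

    audit = pd.DataFrame(
        False,
        index=[r.rs_id for r in loci],
        columns=["spacing", "low_diff", "hwe", "non_intronic"],
    )
    cursor = 0

    # spacing pairs: place both loci of a pair 1 Mb apart on one chromosome
    for pair in range(plan["spacing_pairs"]):
        a, b = loci[cursor], loci[cursor + 1]
        chrom = str(pair % 22 + 1)
        base = 200_000_000 + pair * 50_000_000
        loci[cursor] = LocusRecord(a.rs_id, a.allele_ancestral, a.allele_derived, chrom, base, True)
        loci[cursor + 1] = LocusRecord(b.rs_id, b.allele_ancestral, b.allele_derived, chrom, base + 1_000_000, True)
        audit.loc[[a.rs_id, b.rs_id], "spacing"] = True
        cursor += 2

    for _ in range(plan["low_diff"]):
        f[cursor] = 0.5  # identical in every group -> differential 0
        audit.iloc[cursor, audit.columns.get_loc("low_diff")] = True
        cursor += 1

    hwe_frame = pd.DataFrame(
        1.0, index=[r.rs_id for r in loci], columns=["reference_pop"]
    )
    from .popstats import hwe_exact

    for _ in range(plan["hwe"]):
        # all-heterozygote configuration: gross excess heterozygosity
        hwe_frame.iloc[cursor, 0] = hwe_exact((0, 100, 0))
        audit.iloc[cursor, audit.columns.get_loc("hwe")] = True
        cursor += 1

    for _ in range(plan["non_intronic"]):
        r = loci[cursor]
        loci[cursor] = LocusRecord(r.rs_id, r.allele_ancestral, r.allele_derived,
                                   r.chromosome, r.position_bp, intronic=False)
        audit.iloc[cursor, audit.columns.get_loc("non_intronic")] = True
        cursor += 1

    out_freqs = FrequencyTable(loci, freqs.group_names, f, freqs.sample_sizes)
    return loci, out_freqs, hwe_frame, audit
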