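"""SNP panel selection by explicit filter criteria.

A candidate locus enters the panel when it

1. is flagged intronic (metadata; no annotation lookup),
2. is bi-allelic,
3. keeps >= ``min_spacing_bp`` (default 10 Mb) from every other retained
   locus on the same chromosome (different chromosomes never conflict),
4. shows a maximum pairwise ancestral-allele frequency differential of at
   least ``min_freq_diff`` (default 0.3) in at least one of the group
   sets in scope (e.g. continental groups OR regional subpopulations —
   OR semantics encode the deliberate retention of loci differentiated in
   either set), and
5. conforms to Hardy-Weinberg equilibrium (exact-test p >= the
   Bonferroni-corrected alpha) in every reference population; an
   undefined test (NaN, effectively monomorphic) counts as conforming.

Criteria are checked in the order biallelic, intronic, differential,
HWE, spacing; the first failure is recorded as the removing criterion so
the audit partitions candidates cleanly.  Spacing conflicts are resolved
greedily in favour of the locus with the larger maximum differential
(ties by smaller position), which keeps the most ancestry-informative
locus of each conflicting cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import FrequencyTable, LocusRecord
from .popstats import max_differential

__all__ = [
    "SelectionCriteria",
    "SelectionAudit",
    "filter_panel",
    "spacing_conflicts",
]


@dataclass
class SelectionCriteria:
    """Thresholds for the five selection filters."""

    require_intronic: bool = True
    require_biallelic: bool = True
    min_spacing_bp: int = 10_000_000
    min_freq_diff: float = 0.3
    hwe_alpha: float = 0.05 / 48
    diff_scope: tuple[str, ...] | None = None  # group-set names; None = all provided

    def __post_init__(self) -> None:
        if self.min_spacing_bp < 0:
            raise ValueError("min_spacing_bp must be >= 0")
        if not 0.0 <= self.min_freq_diff <= 1.0:
            raise ValueError("min_freq_diff must be in [0, 1]")


@dataclass
class SelectionAudit:
    """Per-locus record of each criterion's outcome.

    ``table`` has one row per candidate with boolean pass columns, the
    single removing criterion (empty string if retained) and, for spacing
    removals, the retained competitor's rs_id.
    """

    table: pd.DataFrame
    selected: list[str] = field(default_factory=list)

    @property
    def removed(self) -> list[str]:
        return list(self.table.index[self.table["removed_by"] != ""])

    def counts(self) -> pd.Series:
        """Number of loci removed per criterion."""
        r = self.table["removed_by"]
        return r[r != ""].value_counts()


def spacing_conflicts(
    loci: Sequence[LocusRecord], min_spacing_bp: int
) -> list[tuple[str, str]]:
    """All same-chromosome pairs closer than ``min_spacing_bp``.

    Symmetric pairs are reported once, ordered by position; no self-pairs.
    """
    out: list[tuple[str, str]] = []
    by_chrom: dict[str, list[LocusRecord]] = {}
    for rec in loci:
        by_chrom.setdefault(str(rec.chromosome), []).append(rec)
    for chrom_loci in by_chrom.values():
        chrom_loci = sorted(chrom_loci, key=lambda r: (r.position_bp, r.rs_id))
        for i in range(len(chrom_loci)):
            for j in range(i + 1, len(chrom_loci)):
                if chrom_loci[j].position_bp - chrom_loci[i].position_bp < min_spacing_bp:
                    out.append((chrom_loci[i].rs_id, chrom_loci[j].rs_id))
                else:
                    break  # sorted: later loci are farther still
    return out


def _hwe_pass(
    rs_id: str, hwe_pvalues: Mapping[str, Mapping[str, float]] | pd.DataFrame | None, alpha: float
) -> bool:
    if hwe_pvalues is None:
        return True
    if isinstance(hwe_pvalues, pd.DataFrame):
        if rs_id not in hwe_pvalues.index:
            return True
        vals = hwe_pvalues.loc[rs_id].to_numpy(dtype=float)
    else:
        vals = np.array(list(hwe_pvalues.get(rs_id, {}).values()), dtype=float)
    vals = vals[~np.isnan(vals)]  # undefined test => conforming
    return bool(np.all(vals >= alpha)) if vals.size else True


def filter_panel(
    candidates: Sequence[LocusRecord],
    freq_tables: Mapping[str, FrequencyTable] | FrequencyTable,
    criteria: SelectionCriteria | None = None,
    hwe_pvalues: Mapping[str, Mapping[str, float]] | pd.DataFrame | None = None,
) -> tuple[list[LocusRecord], SelectionAudit]:
    """Apply the selection criteria to a candidate table.

    ``freq_tables`` maps group-set name to a :class:`FrequencyTable`
    covering all candidates (a bare table is treated as one unnamed set);
    the differential criterion is satisfied in at least ONE set named by
    ``criteria.diff_scope`` (all sets by default).  ``hwe_pvalues`` maps
    rs_id to per-reference-population exact-test p-values (or is a
    loci x populations DataFrame).

    Returns the retained loci (input order) and a :class:`SelectionAudit`.
    """
    crit = criteria or SelectionCriteria()
    if isinstance(freq_tables, FrequencyTable):
        freq_tables = {"default": freq_tables}
    scope = list(crit.diff_scope) if crit.diff_scope else list(freq_tables)
    for name in scope:
        if name not in freq_tables:
            raise KeyError(f"diff_scope names unknown frequency table {name!r}")

    maxdiff: dict[str, pd.Series] = {name: max_differential(freq_tables[name]) for name in scope}
    for name in scope:
        missing = [rec.rs_id for rec in candidates if rec.rs_id not in maxdiff[name].index]
        if missing:
            raise KeyError(
                f"candidates missing from frequency table {name!r}: {missing[:5]}"
            )

    rows = {}
    for rec in candidates:
        ok_bi = rec.is_biallelic if crit.require_biallelic else True
        ok_intr = rec.intronic if crit.require_intronic else True
        diffs = [float(maxdiff[name][rec.rs_id]) for name in scope]
        best = max((d for d in diffs if not math.isnan(d)), default=float("nan"))
        ok_diff = any(
            (not math.isnan(d)) and d >= crit.min_freq_diff for d in diffs
        )
        ok_hwe = _hwe_pass(rec.rs_id, hwe_pvalues, crit.hwe_alpha)
        removed_by = ""
        if not ok_bi:
            removed_by = "biallelic"
        elif not ok_intr:
            removed_by = "intronic"
        elif not ok_diff:
            removed_by = "freq_diff"
        elif not ok_hwe:
            removed_by = "hwe"
        rows[rec.rs_id] = {
            "biallelic": ok_bi,
            "intronic": ok_intr,
            "freq_diff": ok_diff,
            "hwe": ok_hwe,
            "max_differential": best,
            "spacing": True,
            "removed_by": removed_by,
            "spacing_competitor": "",
        }

    survivors = {rec.rs_id: rec for rec in candidates if rows[rec.rs_id]["removed_by"] == ""}

    # greedy spacing resolution: repeatedly drop the conflicted locus with
    # the smallest differential (ties -> larger position goes first)
    while True:
        conflicts = spacing_conflicts(list(survivors.values()), crit.min_spacing_bp)
        if not conflicts:
            break
        conflicted = sorted({r for pair in conflicts for r in pair})
        loser = min(
            conflicted,
            key=lambda r: (
                rows[r]["max_differential"],
                -survivors[r].position_bp,
                r,
            ),
        )
        partner = next(a if b == loser else b for a, b in conflicts if loser in (a, b))
        rows[loser]["spacing"] = False
        rows[loser]["removed_by"] = "spacing"
        rows[loser]["spacing_competitor"] = partner
        del survivors[loser]

    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "rs_id"
    selected = [rec for rec in candidates if rec.rs_id in survivors]
    audit = SelectionAudit(table=table, selected=[rec.rs_id for rec in selected])
    return selected, audit
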