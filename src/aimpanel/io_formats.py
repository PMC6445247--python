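"""Readers and writers for the on-disk formats the pipeline touches.

Supported formats:

* TSV frequency tables (header ``rs_id  alleles  chromosome  position_bp
  [intronic]  <group> ...``; an optional ``#sample_sizes`` comment line
  carries per-group diploid counts),
* dosage TSV genotype matrices with a ``.loci.tsv`` metadata sidecar,
* PLINK-style PED/MAP pairs,
* VCF (read-only, bi-allelic SNP records),
* admixture-style whitespace-delimited ``.Q`` / ``.P`` files.

Genotypes are always re-coded to ancestral-allele dosage against the
locus metadata; an allele in a file that matches neither declared allele
is an error naming the locus and individual, never a silent strand flip.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import MISSING, FrequencyTable, GenotypeMatrix, LocusRecord

if TYPE_CHECKING:  # pragma: no cover
    from .structure import AdmixtureResults

logger = logging.getLogger(__name__)

__all__ = [
    "read_frequency_table",
    "write_frequency_table",
    "read_genotypes",
    "write_genotypes",
    "write_admixture_outputs",
    "read_admixture_outputs",
]

_META_COLS = ("rs_id", "alleles", "chromosome", "position_bp")


class ParseError(ValueError):
    """Malformed input file."""


def _parse_locus(fields: Mapping[str, str], line_no: int, path: str) -> LocusRecord:
    alleles = str(fields["alleles"]).split("/")
    if len(alleles) != 2:
        raise ParseError(f"{path}:{line_no}: alleles must be 'anc/der', got {fields['alleles']!r}")
    try:
        pos = int(fields["position_bp"])
    except (TypeError, ValueError):
        raise ParseError(f"{path}:{line_no}: bad position {fields['position_bp']!r}") from None
    intronic = str(fields.get("intronic", "1")).strip().lower() in {"1", "true", "yes"}
    rec = LocusRecord(
        rs_id=str(fields["rs_id"]),
        allele_ancestral=alleles[0],
        allele_derived=alleles[1],
        chromosome=str(fields["chromosome"]),
        position_bp=pos,
        intronic=intronic,
    )
    try:
        rec.validate()
    except ValueError as e:
        raise ParseError(f"{path}:{line_no}: {e}") from None
    return rec


def read_frequency_table(path: str | os.PathLike) -> FrequencyTable:
    """Read a TSV frequency table, preserving row and column order."""
    path = Path(path)
    sample_sizes: dict[str, int] | None = None
    header: list[str] | None = None
    loci: list[LocusRecord] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#sample_sizes"):
                sample_sizes = {}
                for tok in line.split("\t")[1:]:
                    name, _, val = tok.partition("=")
                    sample_sizes[name.strip()] = int(val)
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                if header[: len(_META_COLS)] != list(_META_COLS):
                    raise ParseError(
                        f"{path}:{line_no}: header must start with {_META_COLS}, got {header[:4]}"
                    )
                continue
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}:{line_no}: expected {len(header)} fields, got {len(fields)}"
                )
            rec_fields = dict(zip(header, fields))
            loci.append(_parse_locus(rec_fields, line_no, str(path)))
            n_meta = 5 if "intronic" in header else 4
            vals = []
            for name, tok in zip(header[n_meta:], fields[n_meta:]):
                tok = tok.strip()
                if tok in {"", "NA", "nan", "."}:
                    vals.append(float("nan"))
                    continue
                try:
                    v = float(tok)
                except ValueError:
                    raise ParseError(f"{path}:{line_no}: bad frequency {tok!r} in column {name}") from None
                if not 0.0 <= v <= 1.0:
                    raise ParseError(f"{path}:{line_no}: frequency {v} outside [0,1] in column {name}")
                vals.append(v)
            rows.append(vals)
    if header is None:
        raise ParseError(f"{path}: empty frequency table")
    n_meta = 5 if "intronic" in header else 4
    groups = header[n_meta:]
    if not groups:
        raise ParseError(f"{path}: no group columns in header")
    if sample_sizes is not None:
        sample_sizes = {g: sample_sizes[g] for g in groups if g in sample_sizes} or None
        if sample_sizes is not None and len(sample_sizes) != len(groups):
            sample_sizes = None
    return FrequencyTable(loci, groups, np.array(rows, dtype=float), sample_sizes)


def write_frequency_table(freqs: FrequencyTable, path: str | os.PathLike, decimals: int = 6) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if freqs.sample_sizes is not None:
            toks = "\t".join(f"{g}={n}" for g, n in freqs.sample_sizes.items())
            fh.write(f"#sample_sizes\t{toks}\n")
        fh.write("\t".join(list(_META_COLS) + ["intronic"] + freqs.group_names) + "\n")
        for rec, row in zip(freqs.loci, freqs.freq):
            vals = "\t".join("NA" if np.isnan(v) else f"{v:.{decimals}f}".rstrip("0").rstrip(".") for v in row)
            fh.write(
                f"{rec.rs_id}\t{rec.alleles}\t{rec.chromosome}\t{rec.position_bp}\t"
                f"{int(rec.intronic)}\t{vals}\n"
            )


# ---------------------------------------------------------------------------
# genotypes

def _loci_sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".loci.tsv")


def _read_loci_tsv(path: Path) -> list[LocusRecord]:
    loci = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line_no, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            loci.append(_parse_locus(dict(zip(header, raw.rstrip("\n").split("\t"))), line_no, str(path)))
    return loci


def _write_loci_tsv(loci: Sequence[LocusRecord], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(list(_META_COLS) + ["intronic"]) + "\n")
        for rec in loci:
            fh.write(
                f"{rec.rs_id}\t{rec.alleles}\t{rec.chromosome}\t{rec.position_bp}\t{int(rec.intronic)}\n"
            )


def _placeholder_loci(rs_ids: Sequence[str]) -> list[LocusRecord]:
    logger.warning(
        "no locus metadata available; substituting placeholder alleles/positions "
        "for %d loci", len(rs_ids)
    )
    return [
        LocusRecord(r, "A", "G", "1", j + 1, intronic=False) for j, r in enumerate(rs_ids)
    ]


def read_genotypes(
    path: str | os.PathLike,
    format: str = "tsv",
    loci: Sequence[LocusRecord] | None = None,
    populations: Mapping[str, str] | None = None,
) -> GenotypeMatrix:
    """Read genotypes as ancestral-allele dosages.

    ``format`` is ``"tsv"`` (dosage matrix; ``path.loci.tsv`` sidecar read
    if present), ``"ped_map"`` (``path`` is the shared PED/MAP prefix) or
    ``"vcf"``.  ``loci`` supplies the ancestral/derived declaration where
    the format does not carry it; ``populations`` maps individual id to
    population label for VCF input.
    """
    if format == "tsv":
        return _read_geno_tsv(Path(path), loci)
    if format == "ped_map":
        return _read_ped_map(Path(path), loci)
    if format == "vcf":
        return _read_vcf(Path(path), loci, populations)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_geno_tsv(path: Path, loci: Sequence[LocusRecord] | None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str, "population": str})
    if df.columns[0] != "individual_id" or df.columns[1] != "population":
        raise ParseError(f"{path}: first columns must be individual_id, population")
    rs_ids = list(df.columns[2:])
    if loci is None:
        sidecar = _loci_sidecar(path)
        loci = _read_loci_tsv(sidecar) if sidecar.exists() else _placeholder_loci(rs_ids)
    by_id = {rec.rs_id: rec for rec in loci}
    missing = [r for r in rs_ids if r not in by_id]
    if missing:
        raise ParseError(f"{path}: loci missing from metadata: {missing[:5]}")
    geno = df[rs_ids].to_numpy(dtype=float)
    bad = ~(np.isnan(geno) | np.isin(geno, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: invalid dosage {geno[i, j]} for {df['individual_id'].iloc[i]} at {rs_ids[j]}"
        )
    return GenotypeMatrix(
        list(df["individual_id"]), list(df["population"]), [by_id[r] for r in rs_ids], geno
    )


def _read_ped_map(prefix: Path, loci: Sequence[LocusRecord] | None) -> GenotypeMatrix:
    ped = prefix.with_suffix(".ped")
    map_ = prefix.with_suffix(".map")
    map_rows = []
    with open(map_) as fh:
        for line_no, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            f = raw.split()
            if len(f) < 4:
                raise ParseError(f"{map_}:{line_no}: expected 4 fields, got {len(f)}")
            map_rows.append((f[0], f[1], int(f[3])))
    by_id = {rec.rs_id: rec for rec in loci} if loci is not None else {}

    ids, pops, rows = [], [], []
    with open(ped) as fh:
        ped_lines = [raw.split() for raw in fh if raw.strip()]
    # resolve ancestral alleles: declared metadata, else alphabetically first
    # observed allele (deterministic fallback; derived completed from ACGT)
    resolved: list[LocusRecord] = []
    for j, (chrom, rs, pos) in enumerate(map_rows):
        if rs in by_id:
            resolved.append(by_id[rs])
            continue
        seen = set()
        for f in ped_lines:
            seen.update(f[6 + 2 * j : 8 + 2 * j])
        seen.discard("0")
        alleles = sorted(seen)
        if len(alleles) > 2:
            raise ParseError(f"{ped}: locus {rs} shows more than two alleles: {alleles}")
        anc = alleles[0] if alleles else "A"
        der = alleles[1] if len(alleles) == 2 else next(a for a in "ACGT" if a != anc)
        resolved.append(LocusRecord(rs, anc, der, chrom, pos, intronic=False))

    for line_no, f in enumerate(ped_lines, start=1):
        if len(f) != 6 + 2 * len(map_rows):
            raise ParseError(
                f"{ped}:{line_no}: expected {6 + 2 * len(map_rows)} fields, got {len(f)}"
            )
        fid, iid = f[0], f[1]
        ids.append(iid)
        pops.append(fid)
        row = np.empty(len(map_rows), dtype=np.int8)
        for j, rec in enumerate(resolved):
            a1, a2 = f[6 + 2 * j], f[7 + 2 * j]
            if a1 == "0" or a2 == "0":
                row[j] = MISSING
                continue
            dose = 0
            for a in (a1, a2):
                if a == rec.allele_ancestral:
                    dose += 1
                elif a != rec.allele_derived:
                    raise ParseError(
                        f"{ped}:{line_no}: allele {a!r} of individual {iid} at "
                        f"{rec.rs_id} matches neither declared allele {rec.alleles}"
                    )
            row[j] = dose
        rows.append(row)
    return GenotypeMatrix(ids, pops, resolved, np.array(rows))


def _read_vcf(
    path: Path,
    loci: Sequence[LocusRecord] | None,
    populations: Mapping[str, str] | None,
) -> GenotypeMatrix:
    from cyvcf2 import VCF

    by_id = {rec.rs_id: rec for rec in loci} if loci is not None else {}
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    out_loci: list[LocusRecord] = []
    cols: list[np.ndarray] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            logger.warning("skipping non-bi-allelic record %s at %s:%s", var.ID, var.CHROM, var.POS)
            continue
        ref, alt = var.REF, var.ALT[0]
        rid = var.ID or f"{var.CHROM}:{var.POS}"
        rec = by_id.get(rid)
        if rec is None:
            rec = LocusRecord(rid, ref, alt, str(var.CHROM).removeprefix("chr"), var.POS, intronic=False)
        else:
            if {ref, alt} != {rec.allele_ancestral, rec.allele_derived}:
                raise ParseError(
                    f"{path}: {rid} REF/ALT {ref}/{alt} do not match declared alleles {rec.alleles}"
                )
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = var.gt_types
        alt_dose = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        dose = np.where(alt_dose == MISSING, MISSING,
                        alt_dose if alt == rec.allele_ancestral else 2 - alt_dose)
        out_loci.append(rec)
        cols.append(dose.astype(np.int8))
    if n_skipped:
        logger.warning("skipped %d non-bi-allelic VCF records", n_skipped)
    geno = np.column_stack(cols) if cols else np.empty((len(samples), 0), dtype=np.int8)
    pops = [populations.get(s, "unknown") if populations else "unknown" for s in samples]
    return GenotypeMatrix(samples, pops, out_loci, geno)


def write_genotypes(geno: GenotypeMatrix, path: str | os.PathLike, format: str = "tsv") -> None:
    """Write genotypes; ``tsv`` also writes a ``.loci.tsv`` metadata sidecar."""
    path = Path(path)
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("individual_id\tpopulation\t" + "\t".join(geno.rs_ids) + "\n")
            for i, (iid, pop) in enumerate(zip(geno.individual_ids, geno.population_labels)):
                vals = "\t".join(
                    "NA" if v == MISSING else str(int(v)) for v in geno.geno[i]
                )
                fh.write(f"{iid}\t{pop}\t{vals}\n")
        _write_loci_tsv(geno.loci, _loci_sidecar(path))
    elif format == "ped":
        with open(path.with_suffix(".map"), "w") as fh:
            for rec in geno.loci:
                fh.write(f"{rec.chromosome}\t{rec.rs_id}\t0\t{rec.position_bp}\n")
        with open(path.with_suffix(".ped"), "w") as fh:
            for i, (iid, pop) in enumerate(zip(geno.individual_ids, geno.population_labels)):
                toks = [pop, iid, "0", "0", "0", "-9"]
                for rec, v in zip(geno.loci, geno.geno[i]):
                    if v == MISSING:
                        toks += ["0", "0"]
                    else:
                        toks += [rec.allele_ancestral] * int(v) + [rec.allele_derived] * (2 - int(v))
                fh.write(" ".join(toks) + "\n")
    else:
        raise ValueError(f"unknown genotype output format {format!r}")


# ---------------------------------------------------------------------------
# admixture outputs

def write_admixture_outputs(fit: "AdmixtureResults", prefix: str | os.PathLike) -> tuple[Path, Path]:
    """Write Q (individuals x K) and P (loci x K) in admixture file layout."""
    if fit.Q.shape[0] == 0:
        raise ValueError("cannot write an admixture fit with zero individuals")
    prefix = Path(prefix)
    qpath = prefix.with_suffix(f".{fit.K}.Q")
    ppath = prefix.with_suffix(f".{fit.K}.P")
    np.savetxt(qpath, fit.Q, fmt="%.6f", delimiter=" ")
    np.savetxt(ppath, fit.F, fmt="%.6f", delimiter=" ")
    return qpath, ppath


def read_admixture_outputs(qpath: str | os.PathLike, ppath: str | os.PathLike) -> tuple[np.ndarray, np.ndarray]:
    Q = np.loadtxt(qpath, ndmin=2)
    P = np.loadtxt(ppath, ndmin=2)
    return Q, P
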