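"""PLINK-text PED/MAP and TSV readers/writers.

Genotypes are stored as A (major) / B (minor) allele characters; phenotype is
coded 1=control, 2=case, 0 or -9 = missing. Dosage counts copies of the
per-SNP minor allele, determined from the pooled sample frequency (ties at
MAF exactly 0.5 broken lexicographically: the alphabetically later allele is
called minor).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import MISSING, GenotypeMatrix
from .pairtests import PairTestResult
from .selection import SnpRecord

__all__ = ["read_ped_map", "write_ped_map", "read_annotation",
           "write_annotation", "write_results", "read_results",
           "write_pairs", "read_pairs"]

RESULT_COLUMNS = ["snp_a", "snp_b", "method", "stat", "df", "p",
                  "beta_int", "se_int", "feasible", "reason"]


def read_ped_map(prefix: str | Path) -> tuple[GenotypeMatrix, list[SnpRecord]]:
    """Read ``prefix.ped`` + ``prefix.map`` into a dosage matrix.

    The two files must agree on SNP count; ragged PED lines raise with the
    offending line number. ``0 0`` genotypes become missing.
    """
    prefix = Path(prefix)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    records: list[SnpRecord] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise ValueError(f"{map_path}:{lineno}: expected 4 columns")
            chrom, snp_id, _cm, pos = parts[:4]
            records.append(SnpRecord(id=snp_id, chrom=chrom, pos=int(pos)))
    m = len(records)

    rows: list[np.ndarray] = []
    phenos: list[int] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields "
                    f"(6 + 2 x {m} alleles), got {len(parts)}")
            pheno = parts[5]
            phenos.append({"1": 0, "2": 1}.get(pheno, -1))
            rows.append(np.array(parts[6:], dtype="U2").reshape(m, 2))
    alleles = np.stack(rows)  # (n, m, 2)
    phenotype = np.array(phenos, dtype=np.int8)
    if (phenotype == -1).any():
        phenotype = np.where(phenotype == -1, MISSING, phenotype).astype(np.int8)

    n = alleles.shape[0]
    dosages = np.full((n, m), MISSING, dtype=np.int8)
    for j, rec in enumerate(records):
        col = alleles[:, j, :]
        obs = col != "0"
        uniq, counts = np.unique(col[obs], return_counts=True)
        if len(uniq) == 0:
            continue
        if len(uniq) > 2:
            raise ValueError(f"{rec.id}: more than 2 alleles {list(uniq)}")
        if len(uniq) == 1:
            major, minor = uniq[0], None
        else:
            # minor = rarer allele; at exactly 0.5 the lexicographically
            # later allele is called minor
            if counts[0] != counts[1]:
                minor = uniq[np.argmin(counts)]
            else:
                minor = max(uniq)
            major = uniq[0] if uniq[1] == minor else uniq[1]
        ok = obs.all(axis=1)
        if minor is None:
            dosages[ok, j] = 0
        else:
            dosages[ok, j] = (col[ok] == minor).sum(axis=1)
        rec.alleles = (str(major), str(minor) if minor is not None else "?")
        d = dosages[dosages[:, j] != MISSING, j]
        rec.maf = float(d.mean() / 2.0) if d.size else np.nan

    g = GenotypeMatrix(dosages, [r.id for r in records], phenotype)
    return g, records


def write_ped_map(g: GenotypeMatrix, prefix: str | Path,
                  records: list[SnpRecord] | None = None) -> None:
    """Write PED/MAP; alleles A=major, B=minor; missing genotype -> ``0 0``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for j, snp in enumerate(g.snp_ids):
            rec = records[j] if records else None
            chrom = rec.chrom if rec else "1"
            pos = rec.pos if rec and rec.pos else j + 1
            fh.write(f"{chrom}\t{snp}\t0\t{pos}\n")
    geno_str = {0: "A A", 1: "A B", 2: "B B", MISSING: "0 0"}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i in range(g.n_samples):
            if g.phenotype is None:
                ph = "0"
            else:
                ph = {0: "1", 1: "2"}.get(int(g.phenotype[i]), "0")
            cells = " ".join(geno_str[int(d)] for d in g.dosages[i])
            fh.write(f"F{i + 1} I{i + 1} 0 0 0 {ph} {cells}\n")


def write_annotation(records: list[SnpRecord], path: str | Path) -> None:
    df = pd.DataFrame({"snp_id": [r.id for r in records],
                       "tier": [r.tier for r in records],
                       "category": [r.tier for r in records]})
    df.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["snp_id"].astype(str), df["tier"].astype(str)))


def _header(seed: int | None, config: dict | None) -> str:
    h = [f"# episcreen v{__version__}"]
    if seed is not None:
        h.append(f"# seed: {seed}")
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]
        h.append(f"# config_sha256: {digest}")
    return "\n".join(h) + "\n"


def write_results(results: list[PairTestResult], path: str | Path,
                  seed: int | None = None, config: dict | None = None) -> None:
    """Fixed-column TSV with a '#' provenance header; p-values at 6+
    significant digits."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(seed, config))
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in results:
            fh.write("\t".join([
                r.snp_a, r.snp_b, r.method,
                f"{r.statistic:.8g}", str(r.df), f"{r.p:.8g}",
                f"{r.beta_int:.8g}", f"{r.se_int:.8g}",
                str(int(r.feasible)), r.reason or ".",
            ]) + "\n")


def read_results(path: str | Path) -> list[PairTestResult]:
    out: list[PairTestResult] = []
    with open(path) as fh:
        rows = [ln for ln in fh if not ln.startswith("#")]
    df = pd.read_csv(pd.io.common.StringIO("".join(rows)), sep="\t")
    for _, row in df.iterrows():
        out.append(PairTestResult(
            snp_a=str(row.snp_a), snp_b=str(row.snp_b), method=str(row.method),
            statistic=float(row.stat), df=int(row.df), p=float(row.p),
            beta_int=float(row.beta_int), se_int=float(row.se_int),
            feasible=bool(int(row.feasible)),
            reason="" if str(row.reason) == "." else str(row.reason)))
    return out


def write_pairs(pairs: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("snp_a\tsnp_b\n")
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")


def read_pairs(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return [(str(a), str(b)) for a, b in zip(df["snp_a"], df["snp_b"])]
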