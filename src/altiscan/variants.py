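"""Two-population variant data model, hard-quality and MAC filters, VCF I/O.

A :class:`VariantRecord` is one biallelic site with the four GATK-style
site annotations (DP, QD, MQ, SOR) and per-sample alternate-allele
counts.  The hard filter removes a record when DP < 10, QD < 5, MQ < 40
or SOR > 3 (strict inequalities; boundary values are retained).  The MAC
filter retains a record when the minor allele count over all called
chromosomes of both populations combined is at least 8.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HardFilterThresholds:
    """Removal thresholds: fail iff DP < dp_min, QD < qd_min, MQ < mq_min or SOR > sor_max."""

    dp_min: float = 10.0
    qd_min: float = 5.0
    mq_min: float = 40.0
    sor_max: float = 3.0

    def __post_init__(self):
        if min(self.dp_min, self.qd_min, self.mq_min, self.sor_max) <= 0:
            raise ValueError("all thresholds must be positive")


@dataclass(frozen=True)
class FilterVerdict:
    passed: bool
    reasons: tuple[str, ...] = ()


@dataclass
class VariantRecord:
    """One biallelic site: position, annotations, per-sample alt-allele counts."""

    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    dp: float | None = None
    qd: float | None = None
    mq: float | None = None
    sor: float | None = None
    genotypes: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int8))
    # per-sample alt-allele count in {0,1,2}; -1 encodes missing

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be 1-based, got {self.pos}")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)


class PopulationAssignment:
    """Mapping sample_id -> population label, with the VCF sample order.

    Both populations must be non-empty.  Once a sample order is bound
    (from the VCF header), every sample must be assigned exactly once.
    """

    def __init__(self, mapping: Mapping[str, str], samples: Sequence[str] | None = None):
        self.mapping = dict(mapping)
        if len(set(self.mapping.values())) < 2:
            raise ValueError("need at least two non-empty populations")
        self.samples: list[str] = []
        if samples is not None:
            self.bind_samples(samples)

    @classmethod
    def from_table(cls, path: str | Path, samples: Sequence[str] | None = None):
        """Read a two-column (sample_id, population) tab-separated table."""
        df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                         comment="#", dtype=str)
        dup = df["sample"][df["sample"].duplicated()]
        if not dup.empty:
            raise ValueError(f"sample assigned more than once: {dup.iloc[0]!r}")
        return cls(dict(zip(df["sample"], df["population"])), samples)

    def bind_samples(self, samples: Sequence[str]) -> None:
        for s in samples:
            if s not in self.mapping:
                raise ValueError(f"sample {s!r} missing from population table")
        self.samples = list(samples)

    def population_indices(self, population: str) -> np.ndarray:
        if not self.samples:
            raise ValueError("no sample order bound (read a VCF first)")
        return np.array(
            [i for i, s in enumerate(self.samples) if self.mapping[s] == population],
            dtype=int,
        )

    @property
    def populations(self) -> list[str]:
        return sorted(set(self.mapping.values()))


def hard_filter(record: VariantRecord,
                thresholds: HardFilterThresholds = HardFilterThresholds()) -> FilterVerdict:
    """GATK-style hard filter; returns all violated conditions as reasons.

    A missing annotation fails its filter (conservative: an unannotated
    site cannot be shown to pass).  Boundary values DP=10, QD=5, MQ=40,
    SOR=3 pass.
    """
    reasons = []
    for name, value, bad in (
        ("DP", record.dp, lambda v: v < thresholds.dp_min),
        ("QD", record.qd, lambda v: v < thresholds.qd_min),
        ("MQ", record.mq, lambda v: v < thresholds.mq_min),
        ("SOR", record.sor, lambda v: v > thresholds.sor_max),
    ):
        if value is None or bad(value):
            reasons.append(name if value is not None else f"{name}_missing")
    return FilterVerdict(passed=not reasons, reasons=tuple(reasons))


def minor_allele_count(record: VariantRecord) -> int | None:
    """min(alt, total - alt) over called genotypes; None if nothing called."""
    g = record.genotypes
    called = g[g >= 0]
    if called.size == 0:
        return None
    alt = int(called.sum())
    total = 2 * called.size
    return min(alt, total - alt)


def mac_filter(records: Sequence[VariantRecord], pops: PopulationAssignment,
               mac_min: int = 8) -> list[VariantRecord]:
    """Retain records with minor allele count >= mac_min (boundary retained)."""
    kept = []
    for rec in records:
        mac = minor_allele_count(rec)
        if mac is None:
            logger.info("dropping %s:%d: no called genotypes", rec.contig, rec.pos)
            continue
        if mac >= mac_min:
            kept.append(rec)
    return kept


def filter_variants(
    records: Sequence[VariantRecord],
    pops: PopulationAssignment,
    thresholds: HardFilterThresholds = HardFilterThresholds(),
    mac_min: int = 8,
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Hard filter then MAC filter, with a removal ledger.

    The two filters are order-independent (each depends only on the
    record), so this composition equals the reverse order.  The ledger
    has one row per removal-reason set plus a ``retained`` row; counts
    sum to the input count (a record failing k hard-filter conditions
    counts once under its full reason set).
    """
    counts: dict[str, int] = {}
    kept: list[VariantRecord] = []
    for rec in records:
        verdict = hard_filter(rec, thresholds)
        mac = minor_allele_count(rec)
        reasons = list(verdict.reasons)
        if mac is None:
            reasons.append("no_called_genotypes")
        elif mac < mac_min:
            reasons.append(f"MAC<{mac_min}")
        if reasons:
            key = "+".join(reasons)
            counts[key] = counts.get(key, 0) + 1
        else:
            kept.append(rec)
    rows = [{"reason": k, "count": v} for k, v in sorted(counts.items())]
    rows.append({"reason": "retained", "count": len(kept)})
    return kept, pd.DataFrame(rows, columns=["reason", "count"])


def read_variants(
    vcf_path: str | Path, pop_table_path: str | Path
) -> tuple[list[VariantRecord], PopulationAssignment]:
    """Read a VCF and its population table.

    Multi-allelic records are dropped (the scan is defined on biallelic
    SNPs; their count is logged).  Records are returned sorted by
    (contig, position).  Raises if a VCF sample is absent from the
    population table, naming the sample.
    """
    vcf = pysam.VariantFile(str(vcf_path))
    samples = list(vcf.header.samples)
    pops = PopulationAssignment.from_table(pop_table_path)
    pops.bind_samples(samples)

    records: list[VariantRecord] = []
    n_multi = 0
    for rec in vcf:
        alts = rec.alts or ()
        if len(alts) != 1:
            n_multi += 1
            continue
        geno = np.full(len(samples), -1, dtype=np.int8)
        for i, s in enumerate(samples):
            alleles = rec.samples[s]["GT"]
            if alleles is None or any(a is None for a in alleles):
                continue
            geno[i] = sum(alleles)

        def _info(key):
            v = rec.info.get(key)
            if v is None:
                return None
            if isinstance(v, tuple):
                v = v[0]
            return float(v)

        records.append(
            VariantRecord(
                contig=rec.contig, pos=rec.pos, ref=rec.ref, alt=alts[0],
                dp=_info("DP"), qd=_info("QD"), mq=_info("MQ"), sor=_info("SOR"),
                genotypes=geno,
            )
        )
    if n_multi:
        logger.info("dropped %d multi-allelic records", n_multi)
    records.sort(key=lambda r: (r.contig, r.pos))
    return records, pops


def contig_lengths_from_vcf(vcf_path: str | Path) -> dict[str, int]:
    vcf = pysam.VariantFile(str(vcf_path))
    return {name: c.length for name, c in vcf.header.contigs.items() if c.length}


_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(
    records: Sequence[VariantRecord],
    samples: Sequence[str],
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write a minimal, deterministic VCF 4.2 (unphased diploid GT).

    INFO carries DP/QD/MQ/SOR as floats; genotypes are 0/0, 0/1, 1/1
    or ./. for missing.  Byte-identical output for identical input.
    """
    contig_lengths = contig_lengths or {}
    seen: list[str] = []
    for rec in records:
        if rec.contig not in seen:
            seen.append(rec.contig)
    for c in contig_lengths:
        if c not in seen:
            seen.append(c)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=altiscan\n")
        for c in seen:
            length = contig_lengths.get(c)
            fh.write(f"##contig=<ID={c},length={length}>\n" if length
                     else f"##contig=<ID={c}>\n")
        for k, desc in (("DP", "Combined depth"), ("QD", "Quality by depth"),
                        ("MQ", "RMS mapping quality"), ("SOR", "Strand odds ratio")):
            fh.write(f'##INFO=<ID={k},Number=1,Type=Float,Description="{desc}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for rec in records:
            info = ";".join(
                f"{k}={v:.4f}" for k, v in
                (("DP", rec.dp), ("QD", rec.qd), ("MQ", rec.mq), ("SOR", rec.sor))
                if v is not None
            ) or "."
            gts = "\t".join(_GT[int(g)] for g in rec.genotypes)
            fh.write(f"{rec.contig}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t"
                     f"{info}\tGT\t{gts}\n")
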