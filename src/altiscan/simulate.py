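"""Synthetic two-population genotype datasets and neutral alignments.

The genotype simulator draws per-gene SNP clusters under the
Balding-Nichols model: each SNP has an ancestral frequency
p ~ Uniform(0.05, 0.95) and per-population alternate-allele frequencies

    p_pop ~ Beta(p (1-F)/F, (1-p) (1-F)/F),

so E[p_pop] = p and E[F_ST] ~ F.  Neutral genes use ``f_neutral``;
a ``frac_selected`` fraction of genes uses ``f_selected > f_neutral``
and additionally pushes the high-altitude frequency toward the nearer
boundary with the power transform

    p_HA <- 1 - (1 - p_HA)^(1/d)  if p_HA > 0.5
    p_HA <- p_HA^(1/d)            otherwise,   d = ha_diversity_factor,

which monotonically depresses expected HA heterozygosity without any
sweep machinery.  Diploid genotypes are Binomial(2, p_pop) per
individual, fully called by default.  DP/QD/MQ/SOR annotations straddle
the hard-filter thresholds: a configurable fraction of records violates
exactly one threshold, and boundary values (DP=9/10, SOR=3.0/3.01, ...)
occur so filter inequality semantics are pinned by data.

The alignment simulator drops S ~ Poisson(theta * L * a1(n)) segregating
sites onto distinct columns with derived-allele counts following the
neutral frequency spectrum (P(i) proportional to 1/i).

Identical config + seed produces byte-identical output files.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .diversity import AlignmentMatrix, harmonic_constants
from .variants import VariantRecord, write_vcf

logger = logging.getLogger(__name__)

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class AnnotationModel:
    """Generator for DP/QD/MQ/SOR values straddling the hard-filter thresholds.

    ``violation_frac`` is the per-field probability that a record is
    made to violate exactly that field's threshold (at most one field
    per record); ``boundary_frac`` is the chance a passing value sits
    exactly on the threshold boundary.
    """

    violation_frac: float = 0.05
    boundary_frac: float = 0.05

    def __post_init__(self):
        if not 0 <= 4 * self.violation_frac <= 1:
            raise ValueError("violation_frac must be in [0, 0.25]")

    def draw(self, rng: np.random.Generator) -> dict[str, float]:
        values = {
            "DP": float(rng.integers(10, 101)),
            "QD": float(rng.uniform(5.0, 40.0)),
            "MQ": float(rng.uniform(40.0, 60.0)),
            "SOR": float(rng.uniform(0.0, 3.0)),
        }
        boundary = {"DP": 10.0, "QD": 5.0, "MQ": 40.0, "SOR": 3.0}
        for k in values:
            if rng.random() < self.boundary_frac:
                values[k] = boundary[k]
        if rng.random() < 4 * self.violation_frac:
            k = ["DP", "QD", "MQ", "SOR"][rng.integers(4)]
            values[k] = {
                "DP": float(rng.integers(1, 10)),
                "QD": float(rng.uniform(0.0, 4.99)),
                "MQ": float(rng.uniform(20.0, 39.99)),
                "SOR": float(rng.uniform(3.01, 6.0)),
            }[k]
        return values


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the two-population genotype simulation.

    Defaults match the scan's recovery benchmark: 1,000 genes, 5%
    selected, 20 + 20 diploids, weak neutral differentiation
    (F = 0.05) against strong selected differentiation (F = 0.5) with a
    strong push of HA frequencies toward fixation (factor 0.3).
    """

    seed: int = 0
    n_genes: int = 1000
    frac_selected: float = 0.05
    snps_per_gene_mean: float = 10.0
    n_ha: int = 20
    n_la: int = 20
    f_neutral: float = 0.05
    f_selected: float = 0.5
    ha_diversity_factor: float = 0.3
    gene_length_bp: int = 2000
    missing_rate: float = 0.0
    annotation_model: AnnotationModel = field(default_factory=AnnotationModel)

    def __post_init__(self):
        if not 0 <= self.frac_selected <= 1:
            raise ValueError("frac_selected must be in [0,1]")
        if self.frac_selected > 0 and not self.f_selected > self.f_neutral:
            raise ValueError("f_selected must exceed f_neutral")
        for name in ("f_neutral", "f_selected"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if not 0 < self.ha_diversity_factor <= 1:
            raise ValueError("ha_diversity_factor must be in (0,1]")
        for name in ("n_genes", "n_ha", "n_la", "gene_length_bp"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.snps_per_gene_mean <= 0:
            raise ValueError("snps_per_gene_mean must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "annotation_model" in raw:
            raw["annotation_model"] = AnnotationModel(**raw["annotation_model"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _bn_frequency(rng: np.random.Generator, p: float, f: float) -> float:
    return float(rng.beta(p * (1 - f) / f, (1 - p) * (1 - f) / f))


def _push_toward_fixation(p: float, factor: float) -> float:
    # exponent 1/factor > 1 shrinks the distance to the nearer boundary;
    # factor = 1 is the identity
    if p > 0.5:
        return 1.0 - (1.0 - p) ** (1.0 / factor)
    return p ** (1.0 / factor)


def simulate_two_pop_dataset(
    config: SimulationConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Simulate a VCF + BED + population table + truth table into out_dir.

    One contig per gene; the gene occupies the 0-based interval
    [100, 100 + gene_length_bp) of its contig and carries
    max(1, Poisson(snps_per_gene_mean)) SNPs at distinct positions.
    Returns the paths keyed by kind (vcf/bed/pop_table/truth).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    samples = [f"HA_{i + 1:03d}" for i in range(config.n_ha)] + [
        f"LA_{i + 1:03d}" for i in range(config.n_la)
    ]
    n_selected = round(config.n_genes * config.frac_selected)
    selected = set(rng.choice(config.n_genes, size=n_selected, replace=False).tolist())

    records: list[VariantRecord] = []
    bed_rows: list[str] = []
    truth_rows: list[str] = []
    contig_lengths: dict[str, int] = {}
    start = 100

    for g in range(config.n_genes):
        gene_id = f"gene_{g + 1:05d}"
        contig = f"scaffold_{g + 1:05d}"
        contig_lengths[contig] = config.gene_length_bp + 2 * start
        is_selected = g in selected
        f = config.f_selected if is_selected else config.f_neutral
        k = max(1, int(rng.poisson(config.snps_per_gene_mean)))
        k = min(k, config.gene_length_bp)
        positions = np.sort(
            rng.choice(config.gene_length_bp, size=k, replace=False)
        ) + start + 1  # 1-based, inside [start, start+L)
        bed_rows.append(
            f"{contig}\t{start}\t{start + config.gene_length_bp}\t{gene_id}"
        )
        p_anc_list, p_ha_list, p_la_list = [], [], []
        for pos in positions:
            p = float(rng.uniform(0.05, 0.95))
            p_ha = _bn_frequency(rng, p, f)
            p_la = _bn_frequency(rng, p, f)
            if is_selected:
                p_ha = _push_toward_fixation(p_ha, config.ha_diversity_factor)
            g_ha = rng.binomial(2, p_ha, size=config.n_ha)
            g_la = rng.binomial(2, p_la, size=config.n_la)
            geno = np.concatenate([g_ha, g_la]).astype(np.int8)
            if config.missing_rate > 0:
                mask = rng.random(geno.size) < config.missing_rate
                geno[mask] = -1
            ref, alt = rng.choice(4, size=2, replace=False)
            ann = config.annotation_model.draw(rng)
            records.append(
                VariantRecord(
                    contig=contig, pos=int(pos),
                    ref=str(_BASES[ref]), alt=str(_BASES[alt]),
                    dp=ann["DP"], qd=ann["QD"], mq=ann["MQ"], sor=ann["SOR"],
                    genotypes=geno,
                )
            )
            p_anc_list.append(p)
            p_ha_list.append(p_ha)
            p_la_list.append(p_la)
        truth_rows.append(
            "\t".join([
                gene_id,
                "selected" if is_selected else "neutral",
                str(k),
                f"{np.mean(p_anc_list):.6f}",
                f"{np.mean(p_ha_list):.6f}",
                f"{np.mean(p_la_list):.6f}",
            ])
        )

    paths = {
        "vcf": out_dir / "simulated.vcf",
        "bed": out_dir / "genes.bed",
        "pop_table": out_dir / "populations.tsv",
        "truth": out_dir / "truth.tsv",
    }
    write_vcf(records, samples, paths["vcf"], contig_lengths)
    paths["bed"].write_text("\n".join(bed_rows) + "\n")
    paths["pop_table"].write_text(
        "".join(f"{s}\t{'HA' if s.startswith('HA') else 'LA'}\n" for s in samples)
    )
    paths["truth"].write_text(
        "gene_id\tstatus\tn_snps\tmean_p_ancestral\tmean_p_ha\tmean_p_la\n"
        + "\n".join(truth_rows) + "\n"
    )
    logger.info(
        "simulated %d genes (%d selected), %d SNPs, %d samples",
        config.n_genes, n_selected, len(records), len(samples),
    )
    return paths


def simulate_neutral_alignment(
    n_seqs: int, length: int, theta_per_site: float, seed: int,
    out_fasta: str | Path | None = None,
) -> AlignmentMatrix:
    """Neutral alignment: S ~ Poisson(theta * L * a1(n)) segregating sites.

    Derived-allele counts i in {1..n-1} are drawn with probability
    proportional to 1/i (the standard neutral site-frequency spectrum);
    carriers are chosen uniformly.  All other columns are monomorphic.
    If the Poisson draw exceeds the alignment length, S is capped at
    ``length`` with a logged warning.
    """
    if n_seqs < 2:
        raise ValueError(f"need n_seqs >= 2, got {n_seqs}")
    if length < 1:
        raise ValueError(f"need length >= 1, got {length}")
    if theta_per_site < 0:
        raise ValueError("theta_per_site must be >= 0")
    rng = np.random.default_rng(seed)
    a1 = harmonic_constants(n_seqs).a1
    s = int(rng.poisson(theta_per_site * length * a1))
    if s > length:
        logger.warning("S=%d exceeds alignment length %d; capping", s, length)
        s = length

    matrix = _BASES[rng.integers(4, size=length)]
    aln = np.tile(matrix, (n_seqs, 1))
    if s > 0:
        cols = rng.choice(length, size=s, replace=False)
        freqs = 1.0 / np.arange(1, n_seqs)
        probs = freqs / freqs.sum()
        for col in cols:
            i = int(rng.choice(np.arange(1, n_seqs), p=probs))
            carriers = rng.choice(n_seqs, size=i, replace=False)
            anc = aln[0, col]
            derived = rng.choice([b for b in _BASES if b != anc])
            aln[carriers, col] = derived
    result = AlignmentMatrix(
        [f"seq_{i + 1:04d}" for i in range(n_seqs)],
        ["".join(row) for row in aln],
    )
    if out_fasta is not None:
        result.to_fasta(out_fasta)
    return result
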