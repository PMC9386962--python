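"""Sequence-diversity estimators: S, Watterson's theta, pi and Tajima's D.

Alignment-based statistics operate on an :class:`AlignmentMatrix` after
*complete deletion*: any column containing a gap ``-`` or an ambiguous
base (anything outside A/C/G/T) is removed before all statistics, and
``L_effective`` reflects the retained column count.  Windowed Tajima's D
operates on genotype records for a single population, treating diploid
genotypes as allele counts (heterozygote phase is irrelevant).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID = np.frombuffer(b"ACGT", dtype="S1")


class AlignmentMatrix:
    """A rectangular nucleotide alignment: n sequences over L columns.

    Parameters
    ----------
    ids
        One identifier per sequence.
    sequences
        Equal-length strings over ``{A,C,G,T,-,N}`` (case-insensitive).

    Raises
    ------
    ValueError
        If rows have unequal lengths (ragged alignment) or ids and
        sequences disagree in number.
    """

    def __init__(self, ids: Sequence[str], sequences: Sequence[str]):
        if len(ids) != len(sequences):
            raise ValueError("ids and sequences must have the same length")
        lengths = {len(s) for s in sequences}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        self.ids = list(ids)
        self.matrix = np.array(
            [np.frombuffer(s.upper().encode(), dtype="S1") for s in sequences]
        )
        if self.matrix.size == 0:
            self.matrix = self.matrix.reshape(len(ids), 0)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "AlignmentMatrix":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls([r.id for r in records], [str(r.seq) for r in records])

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for ident, row in zip(self.ids, self.matrix):
                fh.write(f">{ident}\n{row.tobytes().decode()}\n")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def retained(self) -> np.ndarray:
        """Columns surviving complete deletion (all bases in A/C/G/T)."""
        return np.isin(self.matrix, _VALID).all(axis=0)

    @property
    def l_effective(self) -> int:
        return int(self.retained().sum())


@dataclass(frozen=True)
class DiversityConstants:
    """Tajima (1989) normalising constants for sample size n."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def harmonic_constants(n: int) -> DiversityConstants:
    """Tajima's D constants a1, a2, b1, b2, c1, c2, e1, e2 for n sequences.

    a1 = sum_{i<n} 1/i and a2 = sum_{i<n} 1/i^2 are the harmonic sums;
    the remaining fields follow the standard closed forms.

    Raises
    ------
    ValueError
        If ``n < 2``.
    """
    if n < 2:
        raise ValueError(f"need at least 2 sequences, got n={n}")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return DiversityConstants(n=n, a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def count_segregating_sites(aln: AlignmentMatrix) -> int:
    """Number of retained columns carrying >= 2 distinct bases.

    Columns with 3+ alleles count once.  Columns removed by complete
    deletion never count.
    """
    if aln.n < 1:
        raise ValueError("empty alignment")
    sub = aln.matrix[:, aln.retained()]
    if sub.shape[1] == 0:
        return 0
    return int(np.sum((sub != sub[0]).any(axis=0)))


def _pairwise_totals(aln: AlignmentMatrix) -> tuple[int, int]:
    """(total pairwise differences over all pairs, number of pairs)."""
    sub = aln.matrix[:, aln.retained()]
    n = aln.n
    n_pairs = n * (n - 1) // 2
    total = 0
    for col in range(sub.shape[1]):
        _, counts = np.unique(sub[:, col], return_counts=True)
        concordant = int(np.sum(counts * (counts - 1) // 2))
        total += n_pairs - concordant
    return total, n_pairs


def nucleotide_diversity(aln: AlignmentMatrix) -> tuple[float, float]:
    """Mean pairwise difference count k_bar and per-site diversity pi.

    k_bar averages the per-pair difference counts over all C(n,2)
    sequence pairs on retained columns; ``pi = k_bar / L_effective``.
    The column-wise allele-count computation is exactly equivalent to
    enumerating every pair (integer arithmetic before division).
    """
    if aln.n < 2:
        raise ValueError(f"need at least 2 sequences, got n={aln.n}")
    total, n_pairs = _pairwise_totals(aln)
    k_bar = total / n_pairs
    l_eff = aln.l_effective
    if l_eff == 0:
        raise ValueError("no columns retained after complete deletion")
    return k_bar, k_bar / l_eff


def watterson_theta(s: int, n: int, length: int) -> float:
    """Watterson's estimator theta_W = S / (a1(n) * L), per site."""
    if length < 1:
        raise ValueError(f"alignment length must be >= 1, got {length}")
    return s / (harmonic_constants(n).a1 * length)


def tajimas_d_from_counts(s: int, k_bar: float, n: int) -> float:
    """Tajima's D from segregating sites, mean pairwise differences and n.

    Returns NaN (missing, never zero) when ``s == 0``: with no variation
    the statistic is undefined and zero would be a meaningful value.
    """
    if s == 0:
        logger.info("Tajima's D undefined: no segregating sites (reported missing)")
        return math.nan
    const = harmonic_constants(n)
    var = const.e1 * s + const.e2 * s * (s - 1)
    return (k_bar - s / const.a1) / math.sqrt(var)


def tajimas_d(aln: AlignmentMatrix) -> float:
    """Tajima's D on an alignment; NaN when no site segregates."""
    s = count_segregating_sites(aln)
    if s == 0:
        logger.info("Tajima's D undefined for alignment with S=0 (reported missing)")
        return math.nan
    k_bar, _ = nucleotide_diversity(aln)
    return tajimas_d_from_counts(s, k_bar, aln.n)


def alignment_stats(aln: AlignmentMatrix) -> dict:
    """All alignment statistics in one pass: S, k_bar, theta_W, pi, D."""
    s = count_segregating_sites(aln)
    k_bar, pi = nucleotide_diversity(aln)
    return {
        "n": aln.n,
        "L_effective": aln.l_effective,
        "S": s,
        "k_bar": k_bar,
        "theta_w_per_site": watterson_theta(s, aln.n, aln.l_effective),
        "pi_per_site": pi,
        "tajimas_d": tajimas_d_from_counts(s, k_bar, aln.n) if s else math.nan,
    }


def windowed_tajimas_d(
    records: Sequence,
    pops,
    population: str,
    window_bp: int = 30_000,
    step_bp: int | None = None,
    contig_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Tajima's D in windows along each contig for one population.

    Within each window, ``S`` counts sites segregating within the
    population, and the pairwise-difference sum adds
    ``2 j (n_chr - j) / (n_chr (n_chr - 1))`` per site with ``j`` the
    within-population alternate-allele count over called genotypes and
    ``n_chr`` twice the called individuals.  D uses n = n_chr (the
    per-window modal chromosome count).  Windows are non-overlapping by
    default (``step_bp = window_bp``); every window up to the contig end
    (from ``contig_lengths`` if given, else the last variant position)
    is reported, with NaN for windows where ``S = 0``.

    Raises
    ------
    ValueError
        If positions are not sorted within a contig, or the population
        has fewer than 2 individuals.
    """
    if step_bp is None:
        step_bp = window_bp
    idx = pops.population_indices(population)
    if len(idx) < 2:
        raise ValueError(f"population {population!r} needs >= 2 individuals")

    by_contig: dict[str, list] = {}
    for rec in records:
        by_contig.setdefault(rec.contig, []).append(rec)
    for contig, recs in by_contig.items():
        pos = [r.pos for r in recs]
        if any(b < a for a, b in zip(pos, pos[1:])):
            raise ValueError(f"variant positions unsorted on contig {contig!r}")

    contigs = list(by_contig)
    if contig_lengths:
        for c in contig_lengths:
            if c not in by_contig:
                contigs.append(c)

    rows = []
    for contig in contigs:
        recs = by_contig.get(contig, [])
        end = (contig_lengths or {}).get(contig) or (recs[-1].pos if recs else 0)
        n_windows = max(1, math.ceil(end / step_bp)) if end else 0
        for w in range(n_windows):
            lo = w * step_bp + 1          # 1-based inclusive
            hi = lo + window_bp - 1
            s = 0
            k_sum = 0.0
            n_chr_seen: list[int] = []
            for rec in recs:
                if not (lo <= rec.pos <= hi):
                    continue
                g = rec.genotypes[idx]
                called = g[g >= 0]
                n_chr = 2 * len(called)
                if n_chr < 2:
                    continue
                j = int(called.sum())
                n_chr_seen.append(n_chr)
                if 0 < j < n_chr:
                    s += 1
                    k_sum += 2.0 * j * (n_chr - j) / (n_chr * (n_chr - 1))
            if s > 0:
                n_for_d = max(set(n_chr_seen), key=n_chr_seen.count)
                d = tajimas_d_from_counts(s, k_sum, n_for_d)
            else:
                d = math.nan
            rows.append(
                {"contig": contig, "start": lo, "end": hi, "population": population,
                 "S": s, "k_bar": k_sum, "tajimas_d": d}
            )
    return pd.DataFrame(
        rows, columns=["contig", "start", "end", "population", "S", "k_bar", "tajimas_d"]
    )
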