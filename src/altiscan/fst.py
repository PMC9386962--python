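"""Per-site Weir & Cockerham (1984) F_ST and within-population diversity.

The F_ST estimator is the two-population variance-components form used
by VCFtools: among-population (a), among-individual-within-population
(b) and within-individual (c) components, with
``fst = a / (a + b + c)``.  Negative estimates are reported as computed
(clamping would bias downstream per-gene means upward); globally
monomorphic sites have all components zero and a missing fst.

Per-site, per-population nucleotide diversity is the unbiased
heterozygosity ``2 j (n_chr - j) / (n_chr (n_chr - 1))`` over called
chromosomes — exactly the mean pairwise difference among the 2N
haplotypes implied by the genotypes.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .variants import PopulationAssignment, VariantRecord, minor_allele_count


@dataclass(frozen=True)
class SiteFst:
    """Weir-Cockerham variance components and intermediates at one site (r=2)."""

    a: float
    b: float
    c: float
    fst: float          # NaN iff a + b + c == 0 (monomorphic overall)
    n_i: tuple[int, int]
    p_i: tuple[float, float]    # reference-allele frequencies
    h_i: tuple[float, float]    # observed heterozygosity
    n_bar: float
    n_c: float
    p_bar: float
    s2: float
    h_bar: float


def wc_fst_site(
    geno_counts_ha: tuple[int, int, int], geno_counts_la: tuple[int, int, int]
) -> SiteFst:
    """Weir-Cockerham components from (hom_ref, het, hom_alt) genotype counts.

    Both populations need at least one called individual.  Observed
    heterozygosity comes from the genotype counts themselves
    (het / n_i), as the individual-level estimator requires.
    """
    r = 2
    counts = (geno_counts_ha, geno_counts_la)
    n_i = tuple(sum(cts) for cts in counts)
    if min(n_i) < 1:
        raise ValueError("each population needs >= 1 called individual")
    p_i = tuple((2 * cts[0] + cts[1]) / (2 * n) for cts, n in zip(counts, n_i))
    h_i = tuple(cts[1] / n for cts, n in zip(counts, n_i))

    n_tot = sum(n_i)
    n_bar = n_tot / r
    n_c = (n_tot - sum(n * n for n in n_i) / n_tot) / (r - 1)
    p_bar = sum(n * p for n, p in zip(n_i, p_i)) / (r * n_bar)
    s2 = sum(n * (p - p_bar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * n_bar)
    h_bar = sum(n * h for n, h in zip(n_i, h_i)) / (r * n_bar)

    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar * (2 * n_bar - 1) / (4 * n_bar)
    )
    c = h_bar / 2
    denom = a + b + c
    fst = a / denom if denom != 0 else math.nan
    if denom == 0:
        a = b = c = 0.0
    return SiteFst(a=a, b=b, c=c, fst=fst, n_i=n_i, p_i=p_i, h_i=h_i,
                   n_bar=n_bar, n_c=n_c, p_bar=p_bar, s2=s2, h_bar=h_bar)


def site_pi(j: int, n_chr: int) -> float:
    """Per-site nucleotide diversity 2j(n_chr-j)/(n_chr(n_chr-1)).

    ``j`` is the within-population alternate-allele count, ``n_chr`` the
    called chromosomes.  Returns NaN when fewer than two chromosomes
    are called.
    """
    if n_chr < 2:
        return math.nan
    if not 0 <= j <= n_chr:
        raise ValueError(f"allele count {j} outside [0, {n_chr}]")
    return 2.0 * j * (n_chr - j) / (n_chr * (n_chr - 1))


def _pop_counts(rec: VariantRecord, idx: np.ndarray) -> tuple[int, int, int]:
    g = rec.genotypes[idx]
    called = g[g >= 0]
    return (int((called == 0).sum()), int((called == 1).sum()), int((called == 2).sum()))


def site_table(
    records: Sequence[VariantRecord],
    pops: PopulationAssignment,
    ha: str = "HA",
    la: str = "LA",
) -> pd.DataFrame:
    """Per-site F_ST and per-population pi for every record, in genomic order.

    Columns: contig, pos, fst (possibly negative or NaN), pi_ha, pi_la, mac.
    """
    idx_ha = pops.population_indices(ha)
    idx_la = pops.population_indices(la)
    rows = []
    for rec in records:
        c_ha = _pop_counts(rec, idx_ha)
        c_la = _pop_counts(rec, idx_la)
        if sum(c_ha) == 0 or sum(c_la) == 0:
            continue
        site = wc_fst_site(c_ha, c_la)
        j_ha = c_ha[1] + 2 * c_ha[2]
        j_la = c_la[1] + 2 * c_la[2]
        rows.append({
            "contig": rec.contig,
            "pos": rec.pos,
            "fst": site.fst,
            "pi_ha": site_pi(j_ha, 2 * sum(c_ha)),
            "pi_la": site_pi(j_la, 2 * sum(c_la)),
            "mac": minor_allele_count(rec),
        })
    return pd.DataFrame(rows, columns=["contig", "pos", "fst", "pi_ha", "pi_la", "mac"])
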