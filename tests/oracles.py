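"""Independent brute-force oracles, written before and separately from the
package implementations they check.  Each deliberately uses the most direct
formulation available (pair enumeration, exhaustive scans, general-r
formulas) rather than the package's code paths.
"""
from __future__ import annotations

import math
from itertools import combinations


def harmonic_a1_a2(n: int) -> tuple[float, float]:
    """Direct-summation harmonic sums."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    return a1, a2


def brute_segregating_sites(seqs: list[str]) -> int:
    """Column scan over gap/N-free columns, counting polymorphic ones."""
    s = 0
    for col in zip(*seqs):
        if any(b not in "ACGT" for b in col):
            continue
        if len(set(col)) >= 2:
            s += 1
    return s


def brute_pairwise_diversity(seqs: list[str]) -> tuple[float, float]:
    """(k_bar, pi_per_site) by enumerating every sequence pair."""
    keep = [i for i, col in enumerate(zip(*seqs)) if all(b in "ACGT" for b in col)]
    total = 0
    pairs = list(combinations(seqs, 2))
    for a, b in pairs:
        total += sum(a[i] != b[i] for i in keep)
    k_bar = total / len(pairs)
    return k_bar, k_bar / len(keep)


def brute_site_pi(j: int, n_chr: int) -> float:
    """Pairwise comparison over the n_chr haplotypes at one biallelic site."""
    haps = [1] * j + [0] * (n_chr - j)
    diffs = sum(a != b for a, b in combinations(haps, 2))
    return diffs / math.comb(n_chr, 2)


def brute_tajimas_d(seqs: list[str]) -> float:
    """Tajima's D from the direct-summation constants and pair enumeration."""
    n = len(seqs)
    a1, a2 = harmonic_a1_a2(n)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    s = brute_segregating_sites(seqs)
    k_bar, _ = brute_pairwise_diversity(seqs)
    return (k_bar - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


def wc_fst_general(pop_counts: list[tuple[int, int, int]]) -> tuple[float, float, float, float]:
    """Weir & Cockerham (1984) theta-hat components for r populations.

    Generic-r transcription of the published variance components (a, b, c)
    from (hom_ref, het, hom_alt) genotype counts; returns (a, b, c, fst).
    Written as the independent cross-check for the package's two-population
    specialisation.
    """
    r = len(pop_counts)
    ns = [sum(c) for c in pop_counts]
    ps = [(2 * c[0] + c[1]) / (2 * n) for c, n in zip(pop_counts, ns)]
    hs = [c[1] / n for c, n in zip(pop_counts, ns)]
    nbar = sum(ns) / r
    nc = (sum(ns) - sum(n * n for n in ns) / sum(ns)) / (r - 1)
    pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    denom = a + b + c
    return a, b, c, (a / denom if denom != 0 else math.nan)


def brute_scan(genes: list[dict], quantile: float = 0.9, half_factor: float = 0.5,
               min_snps: int = 5) -> tuple[set, list[int]]:
    """Sort-cut-filter enumeration of the gene outlier scan.

    ``genes`` rows need gene_id, n_snps, mean_fst, mean_pi_ha, mean_pi_la.
    Returns (candidate gene_id set, per-stage survivor counts).
    """
    def ratio(g):
        if g["mean_pi_la"] == 0:
            return None
        if g["mean_pi_ha"] == 0:
            return math.inf
        return -math.log10(g["mean_pi_ha"] / g["mean_pi_la"])

    def top(metric):
        vals = [(m, g["gene_id"]) for g in genes
                if (m := metric(g)) is not None and not (isinstance(m, float) and math.isnan(m))]
        if not vals:
            return set()
        k = math.ceil((1 - quantile) * len(vals))
        thr = sorted((v for v, _ in vals), reverse=True)[k - 1]
        return {gid for v, gid in vals if v >= thr}

    top_fst = top(lambda g: g["mean_fst"])
    top_ratio = top(ratio)
    stage1 = {g["gene_id"] for g in genes} & top_fst & top_ratio
    stage2 = {g["gene_id"] for g in genes
              if g["gene_id"] in stage1
              and g["mean_pi_ha"] <= half_factor * g["mean_pi_la"]}
    stage3 = {g["gene_id"] for g in genes
              if g["gene_id"] in stage2 and g["n_snps"] >= min_snps}
    return stage3, [len(stage1), len(stage2), len(stage3)]


def brute_interval_assignment(sites: list[tuple[str, int]],
                              intervals: list[tuple[str, int, int, str]]) -> set:
    """All (site index, gene_id) memberships by direct comparison."""
    hits = set()
    for i, (contig, pos) in enumerate(sites):
        for c, start, end, gid in intervals:
            if c == contig and start <= pos - 1 < end:
                hits.add((i, gid))
    return hits
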