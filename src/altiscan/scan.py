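"""Gene-level outlier scan: dual top-decile, half-diversity and min-SNP filters.

Per gene the scan computes the mean per-site F_ST (negatives included,
missing excluded), the mean per-site pi in each population, and the
diversity ratio ``R = -log10(mean_pi_ha / mean_pi_la)``.  A gene is a
candidate when (1) it sits in the top decile of both mean F_ST and R,
(2) its HA diversity is at most half its LA diversity, and (3) it
carries at least ``min_snps`` retained SNPs.  Filters apply in that
order; the min-SNP filter comes last so the dual-decile survivor count
is comparable before and after it.

Ratio sentinels: ``mean_pi_la == 0`` makes R undefined (the gene is
ineligible for the ratio decile); ``mean_pi_ha == 0`` with positive LA
diversity gives R = +inf, ranked above every finite value — zero HA
diversity is the strongest possible signal.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

GENE_SUMMARY_COLUMNS = [
    "gene_id", "n_snps", "mean_fst", "mean_pi_ha", "mean_pi_la", "ratio",
    "in_top_decile_fst", "in_top_decile_ratio", "passes_half_pi",
    "passes_min_snps", "candidate",
]


@dataclass(frozen=True)
class ScanConfig:
    """Scan parameters: decile cut, half-diversity factor, minimum SNP count."""

    quantile: float = 0.90
    half_factor: float = 0.5
    min_snps: int = 5

    def __post_init__(self):
        if not 0 < self.quantile < 1:
            raise ValueError(f"quantile must be in (0,1), got {self.quantile}")
        if not 0 < self.half_factor <= 1:
            raise ValueError(f"half_factor must be in (0,1], got {self.half_factor}")
        if self.min_snps < 1:
            raise ValueError(f"min_snps must be >= 1, got {self.min_snps}")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a 4-column BED (contig, start, end, gene_id; 0-based half-open)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"malformed BED line {lineno}: need 4 columns, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"malformed BED line {lineno}: non-integer coordinates") from exc
            if start < 0 or end <= start:
                raise ValueError(f"malformed BED line {lineno}: bad interval [{start}, {end})")
            rows.append({"contig": parts[0], "start": start, "end": end,
                         "gene_id": parts[3]})
    return pd.DataFrame(rows, columns=["contig", "start", "end", "gene_id"])


def assign_sites_to_genes(
    site_table: pd.DataFrame, gene_intervals: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Map 1-based sites into 0-based half-open gene intervals.

    A site at position p lands in every interval [start, end) with
    start <= p-1 < end on the same contig; overlapping genes each
    receive the site.  Returns the assigned table (site rows duplicated
    per gene, with a ``gene_id`` column) and the count of sites that
    fell in no interval.
    """
    trees: dict[str, IntervalTree] = {}
    for row in gene_intervals.itertuples():
        trees.setdefault(row.contig, IntervalTree()).addi(row.start, row.end, row.gene_id)
    rows = []
    n_unassigned = 0
    for row in site_table.itertuples(index=False):
        hits = trees.get(row.contig, IntervalTree())[row.pos - 1]
        if not hits:
            n_unassigned += 1
            continue
        for hit in sorted(hits, key=lambda iv: iv.data):
            d = row._asdict()
            d["gene_id"] = hit.data
            rows.append(d)
    cols = list(site_table.columns) + ["gene_id"]
    return pd.DataFrame(rows, columns=cols), n_unassigned


def _ratio(pi_ha: float, pi_la: float) -> float:
    if pi_la == 0:
        return math.nan          # undefined: ineligible for the ratio decile
    if pi_ha == 0:
        return math.inf          # strongest possible signal
    return -math.log10(pi_ha / pi_la)


def summarise_genes(assigned: pd.DataFrame) -> pd.DataFrame:
    """Per-gene aggregates from the assigned site table.

    mean_fst averages non-missing per-site fst (negative values kept);
    mean_pi averages over *all* assigned sites, including sites
    monomorphic within one population (pi = 0) — excluding them would
    inflate that population's apparent diversity.
    """
    rows = []
    for gene_id, grp in assigned.groupby("gene_id", sort=True):
        fst = grp["fst"].dropna()
        mean_pi_ha = float(grp["pi_ha"].mean())
        mean_pi_la = float(grp["pi_la"].mean())
        rows.append({
            "gene_id": gene_id,
            "n_snps": int(len(grp)),
            "mean_fst": float(fst.mean()) if len(fst) else math.nan,
            "mean_pi_ha": mean_pi_ha,
            "mean_pi_la": mean_pi_la,
            "ratio": _ratio(mean_pi_ha, mean_pi_la),
        })
    df = pd.DataFrame(rows, columns=GENE_SUMMARY_COLUMNS[:6])
    for col in GENE_SUMMARY_COLUMNS[6:]:
        df[col] = False
    return df


def _top_flags(values: pd.Series, quantile: float) -> pd.Series:
    """True for the top (1-quantile) fraction, k = ceil((1-q)*N) by rank.

    The threshold is the k-th largest eligible value; every eligible
    value >= threshold is flagged (ties at the threshold all included;
    +inf ranks highest).  NaN values are ineligible and never flagged.
    """
    eligible = values.notna().to_numpy()
    n = int(eligible.sum())
    flags = np.zeros(len(values), dtype=bool)
    if n == 0:
        logger.warning("no eligible genes for decile flagging")
        return pd.Series(flags, index=values.index)
    k = math.ceil((1 - quantile) * n)
    if n < math.ceil(1 / (1 - quantile)):
        logger.warning("degenerate decile: only %d eligible genes", n)
    v = values.to_numpy(dtype=float)
    threshold = np.sort(v[eligible])[::-1][k - 1]
    flags[eligible] = v[eligible] >= threshold
    return pd.Series(flags, index=values.index)


def decile_flags(summaries: pd.DataFrame, config: ScanConfig = ScanConfig()) -> pd.DataFrame:
    """Set in_top_decile_fst / in_top_decile_ratio on a gene-summary table."""
    out = summaries.copy()
    out["in_top_decile_fst"] = _top_flags(out["mean_fst"], config.quantile)
    out["in_top_decile_ratio"] = _top_flags(out["ratio"], config.quantile)
    return out


def apply_scan_filters(
    summaries: pd.DataFrame, config: ScanConfig = ScanConfig()
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Apply dual-decile, half-pi and min-SNP filters.

    Returns (flagged summary table, candidate table, stage ledger).

    Stage order: (1) both decile flags; (2) mean_pi_ha <= half_factor *
    mean_pi_la, boundary passing; (3) n_snps >= min_snps, a gene with
    exactly min_snps SNPs passing.  The ledger lists genes entering and
    surviving each stage.  Candidates are sorted by mean_fst descending,
    then gene_id.
    """
    out = summaries.copy()
    out["passes_half_pi"] = out["mean_pi_ha"] <= config.half_factor * out["mean_pi_la"]
    out["passes_min_snps"] = out["n_snps"] >= config.min_snps

    stage1 = out["in_top_decile_fst"] & out["in_top_decile_ratio"]
    stage2 = stage1 & out["passes_half_pi"]
    stage3 = stage2 & out["passes_min_snps"]
    out["candidate"] = stage3

    n0 = len(out)
    ledger = pd.DataFrame(
        [
            {"stage": "dual_decile", "entering": n0, "surviving": int(stage1.sum())},
            {"stage": "half_pi", "entering": int(stage1.sum()), "surviving": int(stage2.sum())},
            {"stage": "min_snps", "entering": int(stage2.sum()), "surviving": int(stage3.sum())},
        ],
        columns=["stage", "entering", "surviving"],
    )
    candidates = (
        out[out["candidate"]]
        .sort_values(["mean_fst", "gene_id"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return out, candidates, ledger


@dataclass
class ScanResult:
    gene_summary: pd.DataFrame
    candidates: pd.DataFrame
    ledger: pd.DataFrame
    n_sites_unassigned: int


def run_selection_scan(
    vcf_path, bed_path, pop_table_path,
    config: ScanConfig = ScanConfig(),
    thresholds=None,
    mac_min: int = 8,
    ha: str = "HA",
    la: str = "LA",
) -> ScanResult:
    """End-to-end scan: read -> hard/MAC filter -> F_ST & pi -> aggregate -> filters."""
    from .fst import site_table as _site_table
    from .variants import HardFilterThresholds, filter_variants, read_variants

    thresholds = thresholds or HardFilterThresholds()
    records, pops = read_variants(vcf_path, pop_table_path)
    kept, filter_ledger = filter_variants(records, pops, thresholds, mac_min)
    logger.info("filtering: %d of %d records retained", len(kept), len(records))
    sites = _site_table(kept, pops, ha=ha, la=la)
    genes = read_bed(bed_path)
    assigned, n_unassigned = assign_sites_to_genes(sites, genes)
    if n_unassigned:
        logger.info("%d sites fell outside all gene intervals", n_unassigned)
    summaries = decile_flags(summarise_genes(assigned), config)
    summaries, candidates, stage_ledger = apply_scan_filters(summaries, config)
    return ScanResult(
        gene_summary=summaries,
        candidates=candidates,
        ledger=stage_ledger,
        n_sites_unassigned=n_unassigned,
    )
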