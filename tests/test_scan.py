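"""Gene-level outlier scan: interval assignment, deciles, filters, end to end."""
import math

import numpy as np
import pandas as pd
import pytest

from altiscan import (
    ScanConfig,
    apply_scan_filters,
    assign_sites_to_genes,
    decile_flags,
    read_bed,
    run_selection_scan,
    summarise_genes,
)

from oracles import brute_interval_assignment, brute_scan


def _summary(rows):
    df = pd.DataFrame(rows)
    for col in ("in_top_decile_fst", "in_top_decile_ratio", "passes_half_pi",
                "passes_min_snps", "candidate"):
        df[col] = False
    return df


def random_summary_table(rng, n_genes):
    """Random gene summaries with deliberate ties and zero-pi sentinels."""
    rows = []
    for g in range(n_genes):
        pi_ha = float(rng.choice([0.0, rng.uniform(0.001, 0.02)], p=[0.1, 0.9]))
        pi_la = float(rng.choice([0.0, rng.uniform(0.001, 0.02)], p=[0.1, 0.9]))
        fst = float(rng.choice([rng.uniform(-0.05, 1.0), round(rng.uniform(0, 1), 1)]))
        rows.append({
            "gene_id": f"g{g:03d}",
            "n_snps": int(rng.integers(1, 12)),
            "mean_fst": fst,
            "mean_pi_ha": pi_ha,
            "mean_pi_la": pi_la,
        })
    return rows


class TestAssignSitesToGenes:
    BED = pd.DataFrame(
        [{"contig": "c1", "start": 100, "end": 200, "gene_id": "gA"},
         {"contig": "c1", "start": 150, "end": 300, "gene_id": "gB"},
         {"contig": "c2", "start": 0, "end": 50, "gene_id": "gC"}],
    )

    def _sites(self, positions, contig="c1"):
        return pd.DataFrame(
            [{"contig": contig, "pos": p, "fst": 0.1, "pi_ha": 0.01,
              "pi_la": 0.01, "mac": 10} for p in positions]
        )

    def test_coordinate_convention(self):
        # BED is 0-based half-open, sites 1-based: pos=101 is the first
        # base of [100, 200); pos=100 is outside it
        assigned, dropped = assign_sites_to_genes(self._sites([101, 100]), self.BED)
        assert set(assigned.gene_id) == {"gA"}
        assert list(assigned.pos) == [101]
        assert dropped == 1

    def test_overlapping_genes_both_receive_site(self):
        assigned, _ = assign_sites_to_genes(self._sites([175]), self.BED)
        assert sorted(assigned.gene_id) == ["gA", "gB"]

    def test_matches_brute_force_membership(self):
        rng = np.random.default_rng(31)
        intervals = []
        for i in range(30):
            start = int(rng.integers(0, 1000))
            intervals.append((f"c{rng.integers(1, 4)}", start,
                              start + int(rng.integers(10, 200)), f"g{i}"))
        bed = pd.DataFrame(intervals, columns=["contig", "start", "end", "gene_id"])
        sites = [(f"c{rng.integers(1, 4)}", int(rng.integers(1, 1200))) for _ in range(200)]
        site_df = pd.DataFrame(
            [{"contig": c, "pos": p, "fst": 0.0, "pi_ha": 0.0, "pi_la": 0.0, "mac": 8}
             for c, p in sites]
        )
        assigned, dropped = assign_sites_to_genes(site_df, bed)
        expected = brute_interval_assignment(sites, intervals)
        got = set()
        for row in assigned.itertuples():
            got.add((sites.index((row.contig, row.pos)), row.gene_id))
        # a site value may repeat; compare membership pairs by (contig,pos,gene)
        exp_pairs = {(sites[i][0], sites[i][1], g) for i, g in expected}
        got_pairs = {(row.contig, row.pos, row.gene_id) for row in assigned.itertuples()}
        assert got_pairs == exp_pairs
        assert dropped == sum(
            1 for i, s in enumerate(sites) if not any(i == j for j, _ in expected)
        )

    def test_malformed_bed_reports_line_number(self, tmp_path):
        bad = tmp_path / "bad.bed"
        bad.write_text("c1\t0\t100\tgA\nc1\t200\n")
        with pytest.raises(ValueError, match="line 2"):
            read_bed(bad)


class TestSummariseGenes:
    def _assigned(self, rows):
        return pd.DataFrame(rows)

    def test_zero_ha_diversity_gives_infinite_ratio(self):
        df = summarise_genes(self._assigned(
            [{"contig": "c1", "pos": 1, "fst": 1.0, "pi_ha": 0.0, "pi_la": 0.5,
              "mac": 8, "gene_id": "g1"}]
        ))
        assert df.mean_fst.iloc[0] == 1.0
        assert math.isinf(df.ratio.iloc[0]) and df.ratio.iloc[0] > 0

    def test_tenfold_diversity_drop_is_ratio_one(self):
        df = summarise_genes(self._assigned(
            [{"contig": "c1", "pos": p, "fst": 0.2, "pi_ha": 0.001, "pi_la": 0.010,
              "mac": 8, "gene_id": "g1"} for p in (1, 2)]
        ))
        assert df.ratio.iloc[0] == pytest.approx(1.0)

    def test_mild_drop_ratio_and_half_pi_disagree(self):
        # pi_HA/pi_LA = 0.8: R ~ 0.0969 but the half-diversity rule fails
        df = summarise_genes(self._assigned(
            [{"contig": "c1", "pos": 1, "fst": 0.2, "pi_ha": 0.004, "pi_la": 0.005,
              "mac": 8, "gene_id": "g1"}]
        ))
        df, _, _ = apply_scan_filters(decile_flags(df))
        assert df.ratio.iloc[0] == pytest.approx(0.09691, abs=1e-4)
        assert not df.passes_half_pi.iloc[0]

    def test_zero_la_diversity_ineligible(self):
        df = summarise_genes(self._assigned(
            [{"contig": "c1", "pos": 1, "fst": 0.2, "pi_ha": 0.01, "pi_la": 0.0,
              "mac": 8, "gene_id": "g1"}]
        ))
        assert math.isnan(df.ratio.iloc[0])

    def test_all_missing_fst_excluded_from_ranking(self):
        rows = [{"contig": "c1", "pos": 1, "fst": math.nan, "pi_ha": 0.01,
                 "pi_la": 0.01, "mac": 8, "gene_id": "g0"}]
        rows += [{"contig": "c1", "pos": 2 + i, "fst": 0.1 * i, "pi_ha": 0.01,
                  "pi_la": 0.01, "mac": 8, "gene_id": f"g{i + 1}"} for i in range(10)]
        df = decile_flags(summarise_genes(pd.DataFrame(rows)))
        assert math.isnan(df.loc[df.gene_id == "g0", "mean_fst"].iloc[0])
        assert not df.loc[df.gene_id == "g0", "in_top_decile_fst"].iloc[0]


class TestDecileFlags:
    def test_twenty_distinct_values_flag_exactly_two(self):
        rows = [{"gene_id": f"g{i:02d}", "n_snps": 6, "mean_fst": 0.01 * i,
                 "mean_pi_ha": 0.001, "mean_pi_la": 0.01} for i in range(20)]
        df = decile_flags(summarise_genes_like(rows))
        assert df.in_top_decile_fst.sum() == 2
        assert set(df[df.in_top_decile_fst].gene_id) == {"g18", "g19"}

    def test_ties_at_threshold_all_included(self):
        fst = [0.01 * i for i in range(17)] + [0.9, 0.9, 1.0]
        rows = [{"gene_id": f"g{i:02d}", "n_snps": 6, "mean_fst": v,
                 "mean_pi_ha": 0.001, "mean_pi_la": 0.01} for i, v in enumerate(fst)]
        df = decile_flags(summarise_genes_like(rows))
        assert df.in_top_decile_fst.sum() == 3

    def test_infinite_ratio_ranks_highest(self):
        rows = [{"gene_id": f"g{i:02d}", "n_snps": 6, "mean_fst": 0.1,
                 "mean_pi_ha": 0.01, "mean_pi_la": 0.01} for i in range(19)]
        rows.append({"gene_id": "g19", "n_snps": 6, "mean_fst": 0.1,
                     "mean_pi_ha": 0.0, "mean_pi_la": 0.01})
        df = decile_flags(summarise_genes_like(rows))
        assert df.loc[df.gene_id == "g19", "in_top_decile_ratio"].iloc[0]


def summarise_genes_like(rows):
    """Build a summary table with ratios computed as summarise_genes does."""
    df = _summary(rows)
    from altiscan.scan import _ratio
    df["ratio"] = [_ratio(r["mean_pi_ha"], r["mean_pi_la"]) for r in rows]
    return df


class TestApplyScanFilters:
    def _flagged(self, rows, config=ScanConfig()):
        return decile_flags(summarise_genes_like(rows), config)

    def test_min_snp_boundary(self):
        # one clear outlier gene; 4 SNPs is excluded, exactly 5 passes
        for n_snps, expected in ((4, 0), (5, 1)):
            rows = [{"gene_id": f"g{i:02d}", "n_snps": 8, "mean_fst": 0.01 * i,
                     "mean_pi_ha": 0.009, "mean_pi_la": 0.01} for i in range(19)]
            rows.append({"gene_id": "g19", "n_snps": n_snps, "mean_fst": 0.9,
                         "mean_pi_ha": 0.001, "mean_pi_la": 0.01})
            _, candidates, _ = apply_scan_filters(self._flagged(rows))
            assert len(candidates) == expected

    def test_half_pi_boundary_passes(self):
        rows = [{"gene_id": f"g{i:02d}", "n_snps": 8, "mean_fst": 0.01 * i,
                 "mean_pi_ha": 0.009, "mean_pi_la": 0.01} for i in range(19)]
        rows.append({"gene_id": "g19", "n_snps": 8, "mean_fst": 0.9,
                     "mean_pi_ha": 0.005, "mean_pi_la": 0.01})  # exactly half
        _, candidates, _ = apply_scan_filters(self._flagged(rows))
        assert list(candidates.gene_id) == ["g19"]

    def test_constructed_single_candidate_and_stage_counts(self):
        rows = [{"gene_id": f"g{i:02d}", "n_snps": 8, "mean_fst": 0.005 * i,
                 "mean_pi_ha": 0.0099, "mean_pi_la": 0.01} for i in range(19)]
        rows.append({"gene_id": "g19", "n_snps": 20, "mean_fst": 0.95,
                     "mean_pi_ha": 0.004, "mean_pi_la": 0.01})
        summary, candidates, ledger = apply_scan_filters(self._flagged(rows))
        expected_cands, expected_stages = brute_scan(rows)
        assert set(candidates.gene_id) == expected_cands == {"g19"}
        assert list(ledger.surviving) == expected_stages

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            rows = random_summary_table(rng, int(rng.integers(5, 51)))
            _, candidates, ledger = apply_scan_filters(self._flagged(rows))
            expected_cands, expected_stages = brute_scan(rows)
            assert set(candidates.gene_id) == expected_cands
            assert list(ledger.surviving) == expected_stages

    def test_survivor_monotonicity(self):
        rng = np.random.default_rng(41)
        rows = random_summary_table(rng, 40)
        summary, candidates, ledger = apply_scan_filters(self._flagged(rows))
        assert list(ledger.surviving) == sorted(ledger.surviving, reverse=True)
        dual = set(summary[summary.in_top_decile_fst & summary.in_top_decile_ratio].gene_id)
        assert set(candidates.gene_id) <= dual <= set(summary.gene_id)

    def test_candidates_imply_all_flags(self):
        rng = np.random.default_rng(43)
        rows = random_summary_table(rng, 40)
        summary, _, _ = apply_scan_filters(self._flagged(rows))
        cand = summary[summary.candidate]
        assert bool(
            (cand.in_top_decile_fst & cand.in_top_decile_ratio
             & cand.passes_half_pi & cand.passes_min_snps).all()
        )

    def test_half_pi_consistent_with_ratio_threshold(self):
        # for positive means, pi_HA <= pi_LA/2 is the same event as R >= log10(2)
        rng = np.random.default_rng(47)
        rows = [r for r in random_summary_table(rng, 60)
                if r["mean_pi_ha"] > 0 and r["mean_pi_la"] > 0]
        summary, _, _ = apply_scan_filters(self._flagged(rows))
        expected = summary.ratio >= math.log10(2)
        assert (summary.passes_half_pi == expected).all()

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(53)
        rows = [r for r in random_summary_table(rng, 30)
                if r["mean_pi_ha"] > 0 and r["mean_pi_la"] > 0]
        swapped = [dict(r, mean_pi_ha=r["mean_pi_la"], mean_pi_la=r["mean_pi_ha"])
                   for r in rows]
        r1 = summarise_genes_like(rows).ratio.to_numpy(dtype=float)
        r2 = summarise_genes_like(swapped).ratio.to_numpy(dtype=float)
        np.testing.assert_allclose(r1, -r2, atol=1e-12)


class TestRunSelectionScan:
    def test_deterministic_and_bounded_null(self, small_dataset):
        _, paths = small_dataset
        res1 = run_selection_scan(paths["vcf"], paths["bed"], paths["pop_table"])
        res2 = run_selection_scan(paths["vcf"], paths["bed"], paths["pop_table"])
        pd.testing.assert_frame_equal(res1.gene_summary, res2.gene_summary)
        pd.testing.assert_frame_equal(res1.candidates, res2.candidates)

    def test_null_simulation_candidate_bound(self, tmp_path):
        from altiscan import SimulationConfig, simulate_two_pop_dataset
        cfg = SimulationConfig(seed=19, n_genes=150, frac_selected=0.0)
        paths = simulate_two_pop_dataset(cfg, tmp_path)
        res = run_selection_scan(paths["vcf"], paths["bed"], paths["pop_table"])
        # each decile filter keeps ~10%, so their intersection (and every
        # later stage) cannot exceed 10% of genes
        assert len(res.candidates) <= 0.10 * cfg.n_genes
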