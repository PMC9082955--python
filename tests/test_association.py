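"""Contingency construction, prefilter, Fisher test, BH, and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enhasso import (
    bh_adjust,
    build_contingency,
    effective_size,
    enhancers_per_gene,
    fisher_exact,
    odds_ratio,
    prefilter,
    run_association,
    summarize_counts,
)

from helpers import simulate_and_run
from oracles import bh_stepup, fisher_two_sided_exact


class TestBuildContingency:
    def test_direct_count_excluding_none(self):
        pres = [True, True, False, True]
        shifts = ["inclusive", "inclusive", "exclusive", "none"]
        assert build_contingency(pres, shifts) == (2, 0, 0, 1)

    def test_all_none_gives_empty_table(self):
        assert build_contingency([True, False], ["none", "none"]) == (0, 0, 0, 0)


class TestPrefilter:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((20, 2, 3, 25), True),   # OR ~ 83, effect 40
            ((5, 5, 5, 5), False),    # OR = 1
            ((6, 0, 0, 5), True),     # OR = +inf, effect 11
            ((0, 6, 5, 0), True),     # OR = 0, effect 11
            ((0, 0, 0, 21), False),   # OR undefined: both cross-products zero
            ((12, 2, 3, 13), True),   # OR = 26, effect 20
        ],
    )
    def test_rule(self, cells, expected):
        assert prefilter(*cells) is expected

    def test_strictness_at_boundaries(self):
        # effective size exactly 10 fails; OR exactly 2 fails
        assert effective_size(8, 2, 3, 7) == 10
        assert not prefilter(8, 2, 3, 7)
        assert odds_ratio(4, 2, 2, 2) == 2.0
        assert not prefilter(4, 2, 2, 2)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(*(st.integers(0, 30) for _ in range(4)))
    def test_invariant_under_simultaneous_row_and_column_swap(self, a, b, c, d):
        # relabeling present<->absent together with inclusive<->exclusive
        # maps (a,b,c,d) -> (d,c,b,a): OR and effective size are unchanged
        assert prefilter(a, b, c, d) == prefilter(d, c, b, a)


class TestFisherExact:
    def test_enumeration_example(self):
        assert fisher_exact(3, 1, 1, 3) == pytest.approx(34 / 70, abs=1e-12)

    def test_all_zero_table(self):
        assert fisher_exact(0, 0, 0, 0) == 1.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact(-1, 0, 0, 0)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(*(st.integers(0, 12) for _ in range(4)))
    def test_matches_enumeration_oracle_small_margins(self, a, b, c, d):
        assert fisher_exact(a, b, c, d) == pytest.approx(
            fisher_two_sided_exact(a, b, c, d), abs=1e-10
        )


class TestBhAdjust:
    def test_step_up_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_is_unchanged(self):
        assert bh_adjust([0.3]).tolist() == [0.3]

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_monotone_in_sorted_p_order_and_never_below_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-12)  # up to (p*m)/m rounding
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_exactly_matches_definitional_stepup(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(1, 500))
            p = rng.beta(0.5, 3.0, size=n)
            assert np.array_equal(bh_adjust(p), bh_stepup(p))

    def test_cross_check_against_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(size=300)
        q = bh_adjust(p)
        q_sm = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, q_sm, atol=1e-12)


class TestRunAssociation:
    def test_empty_pairing_table_empty_result(self):
        result, truth, pairings = simulate_and_run(
            2, config_overrides=dict(n_tissues=4, n_latent_enhancers=5, n_planted=0,
                                     n_events_per_type={"SE": 3}, chrom_length=500_000)
        )
        empty = run_association(
            result.presence, result.psi_table, pairings.iloc[0:0]
        )
        assert empty.empty

    def test_unknown_pairing_skipped_and_counted(self):
        # presence_prob high enough that every latent locus is called somewhere,
        # so the only unresolvable pairing is the one added below
        result, truth, pairings = simulate_and_run(
            2, config_overrides=dict(n_tissues=8, n_latent_enhancers=5, n_planted=0,
                                     presence_prob=0.9, n_events_per_type={"SE": 3},
                                     chrom_length=500_000)
        )
        bad = pd.concat(
            [pairings, pd.DataFrame([{"gene_id": "nope", "refined_id": "chr9_99"}])],
            ignore_index=True,
        )
        records = run_association(result.presence, result.psi_table, bad)
        assert records.attrs["n_skipped_pairings"] == 1

    def test_planted_pair_concentrates_in_concordant_cells(self):
        # near-noiseless limit: junction depth 10^4
        result, truth, _ = simulate_and_run(
            6,
            config_overrides=dict(
                n_tissues=12, n_latent_enhancers=10, n_planted=5, read_depth=10_000,
                boundary_jitter_sd=0.0, n_events_per_type={"SE": 10, "RI": 10},
                n_decoy_pairs=20, chrom_length=800_000,
            ),
        )
        rec = result.records.set_index(["refined_id", "event_id"])
        for lid, eid, _direction in truth.planted_pairs:
            if (lid, eid) in rec.index:
                row = rec.loc[(lid, eid)]
                assert row["a"] + row["d"] > row["b"] + row["c"]

    def test_significance_requires_prefilter_and_q(self):
        result, truth, _ = simulate_and_run(1)
        r = result.records
        assert (r.loc[r["significant"], "prefilter_pass"]).all()
        assert (r.loc[r["significant"], "q_value"] < 0.05).all()

    def test_tested_scope_restricts_q_to_prefiltered(self):
        result, truth, pairings = simulate_and_run(1)
        r = run_association(result.presence, result.psi_table, pairings, bh_scope="tested")
        assert r.loc[~r["prefilter_pass"], "q_value"].isna().all()
        assert r.loc[r["prefilter_pass"], "q_value"].notna().all()

    def test_deterministic_ordering_and_content(self):
        r1, truth, pairings = simulate_and_run(8)
        r2, _, _ = simulate_and_run(8)
        pd.testing.assert_frame_equal(r1.records, r2.records)
        key = list(zip(r1.records["refined_id"], r1.records["event_id"]))
        assert key == sorted(key)


class TestSummaries:
    def test_multi_type_gene_counts_once_per_type_and_once_in_all(self):
        records = pd.DataFrame(
            {
                "refined_id": ["chr1_1", "chr1_2"],
                "event_id": ["SE_1", "RI_1"],
                "gene_id": ["g1", "g1"],
                "as_type": ["SE", "RI"],
                "prefilter_pass": [True, True],
                "significant": [True, True],
            }
        )
        s = summarize_counts(records).set_index("as_type")
        assert s.loc["SE", "n_significant_genes"] == 1
        assert s.loc["RI", "n_significant_genes"] == 1
        assert s.loc["All", "n_significant_genes"] == 1
        assert s.loc["All", "n_significant_enhancers"] == 2

    def test_no_significant_records_all_zeros(self):
        result, truth, _ = simulate_and_run(
            2, config_overrides=dict(n_tissues=4, n_latent_enhancers=5, n_planted=0,
                                     n_events_per_type={"SE": 3}, chrom_length=500_000)
        )
        r = result.records.copy()
        r["significant"] = False
        s = summarize_counts(r)
        assert (s["n_significant_genes"] == 0).all()

    def test_all_gene_count_matches_truth_recovery(self):
        result, truth, _ = simulate_and_run(1)
        sig = result.records[result.records["significant"]]
        planted = {(l, e) for l, e, _ in truth.planted_pairs}
        recovered_genes = {
            g for (l, e), g in zip(
                zip(sig["refined_id"], sig["event_id"]), sig["gene_id"]
            ) if (l, e) in planted
        }
        s = summarize_counts(result.records).set_index("as_type")
        assert s.loc["All", "n_significant_genes"] >= len(recovered_genes)

    def test_degree_summary_bounds(self):
        result, truth, pairings = simulate_and_run(1)
        deg = enhancers_per_gene(result.records, pairings)
        assert 0 <= deg["mean_significant_enhancers_per_gene"] <= deg["mean_paired_enhancers_per_gene"]
        assert 0 <= deg["mean_significant_genes_per_enhancer"] <= deg["mean_paired_genes_per_enhancer"]
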