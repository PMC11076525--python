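"""Enrichment statistics: frozen arithmetic examples, oracle equivalence,
exact symmetries, filters and hit calling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicescreen.counting import BinCountTable
from splicescreen.stats import (
    ZNormStats,
    analyze_screen,
    call_hits,
    combine_replicates,
    enrichment_score,
    quantifiable,
    replicate_stats,
    replicate_z,
    robust_z,
)

from _oracle import (
    oracle_bh,
    oracle_combine,
    oracle_hits,
    oracle_replicate,
)
from conftest import make_random_counts


class TestQuantifiable:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((5, 5, 20.0, 1.0), True),    # boundary inclusive
            ((4, 1000, 19.0, 5000.0), False),  # count filter is a hard conjunct
            ((0, 0, 0.0, 0.0), False),
            ((5, 5, 19.9, 19.9), False),  # RPM must reach 20 somewhere
            ((1000, 5, 0.0, 20.0), True),
        ],
    )
    def test_thresholds(self, args, expected):
        assert quantifiable(*args) is expected


class TestEnrichmentScore:
    def test_per_guide_hand_value(self):
        e = enrichment_score(30, 10, 10**6, 10**6, mode="per_guide")
        r, r0 = 0.75, 0.5
        s = math.sqrt(r * (1 - r) / 40)
        assert e == pytest.approx((r - r0) / s, abs=1e-12)
        assert e == pytest.approx(3.6514837, abs=1e-6)

    def test_per_guide_null_is_zero(self):
        # counts exactly proportional to totals -> r == r0
        assert enrichment_score(30, 10, 3 * 10**6, 10**6) == pytest.approx(0.0, abs=1e-12)

    def test_as_printed_hand_value(self):
        e = enrichment_score(30, 0, 1000, 1000, mode="as_printed")
        r = 30 / 2000
        s = math.sqrt(r * (1 - r) / 2000)
        assert e == pytest.approx((r - 0.5) / s, abs=1e-9)
        assert e == pytest.approx(-178.44, abs=0.01)

    def test_degenerate_proportion_is_missing(self):
        assert math.isnan(enrichment_score(0, 0, 100, 100))
        assert math.isnan(enrichment_score(10, 0, 100, 100))  # r == 1 in per_guide

    @given(st.integers(0, 500), st.integers(0, 500), st.integers(1, 500))
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_bin_count(self, n_bin, n_ref, delta):
        """For fixed totals and reference count, e is non-decreasing in n_bin."""
        N_bin = N_ref = 10**6
        e1 = enrichment_score(n_bin, n_ref, N_bin, N_ref)
        e2 = enrichment_score(n_bin + delta, n_ref, N_bin, N_ref)
        if not (math.isnan(e1) or math.isnan(e2)):
            assert e2 >= e1 - 1e-12


class TestRobustZ:
    def test_hand_values(self):
        z, stats_ = robust_z([1, 2, 3, 4, 100])
        assert stats_.m == 3 and stats_.sigma == pytest.approx(1 / 0.6745)
        assert z[-1] == pytest.approx(65.4265, abs=1e-4)

    def test_shift_equivariance(self):
        e = np.array([0.3, -1.2, 4.5, 2.2, -0.7])
        z1, _ = robust_z(e)
        z2, _ = robust_z(e + 7.0)
        np.testing.assert_allclose(z1, z2, atol=1e-12)

    def test_antisymmetry_about_median(self):
        e = np.array([-3.0, -1.0, 0.0, 1.0, 3.0])
        z, _ = robust_z(e)
        np.testing.assert_allclose(z, -z[::-1], atol=1e-12)

    def test_nan_propagates_without_entering_pool(self):
        z, stats_ = robust_z([1.0, np.nan, 2.0, 3.0, 4.0, 100.0])
        assert math.isnan(z[1]) and stats_.n_used == 5

    def test_zero_mad_aborts(self):
        with pytest.raises(ValueError, match="MAD"):
            robust_z([5.0, 5.0, 5.0, 5.0])


class TestReplicateZ:
    def test_stouffer_two_bins(self):
        assert replicate_z(2.0, -2.0, 1, 1) == pytest.approx(4 / math.sqrt(2), abs=1e-12)

    def test_single_bin_passthrough(self):
        assert replicate_z(2.0, math.nan, 1, 0) == pytest.approx(2.0)

    def test_no_quantifiable_bins_is_missing(self):
        assert math.isnan(replicate_z(math.nan, math.nan, 0, 0))


class TestCombine:
    @staticmethod
    def _frame(z_top, z_bottom, reporter, rep_id, ids=("g",)):
        df = pd.DataFrame(
            {"z_top": z_top, "w_top": 1, "z_bottom": z_bottom, "w_bottom": 1},
            index=pd.Index(ids, name="guide_id"),
        )
        df.attrs["reporter"] = reporter
        df.attrs["replicate_id"] = rep_id
        return df

    def test_eight_bin_hand_value(self):
        reps = [
            self._frame(3.0, -3.0, "DUAL_IN", "IN1"),
            self._frame(3.0, -3.0, "DUAL_IN", "IN2"),
            self._frame(-3.0, 3.0, "DUAL_EX", "EX1"),
            self._frame(-3.0, 3.0, "DUAL_EX", "EX2"),
        ]
        out = combine_replicates(reps)
        assert out.loc["g", "W"] == 8
        assert out.loc["g", "Z"] == pytest.approx(24 / math.sqrt(8), abs=1e-12)

    def test_single_quantifiable_bin(self):
        df = self._frame(2.0, 0.0, "DUAL_IN", "IN1")
        df["w_bottom"] = 0
        out = combine_replicates([df])
        assert out.loc["g", "W"] == 1 and out.loc["g", "Z"] == pytest.approx(2.0)

    def test_all_zero(self):
        reps = [self._frame(0.0, 0.0, "DUAL_IN", "IN1"),
                self._frame(0.0, 0.0, "DUAL_EX", "EX1")]
        out = combine_replicates(reps)
        assert out.loc["g", "Z"] == 0.0 and out.loc["g", "W"] == 4


class TestCallHits:
    def test_p_values(self):
        df = pd.DataFrame({"Z": [0.0, 1.959964], "W": [8, 8]},
                          index=pd.Index(["a", "b"], name="guide_id"))
        out = call_hits(df, fdr_threshold=0.01)
        assert out.loc["a", "p"] == pytest.approx(1.0)
        assert out.loc["b", "p"] == pytest.approx(0.05, abs=1e-6)

    def test_bh_matches_brute_force(self):
        p = [0.001, 0.02, 0.03, 0.5]
        z = [-abs(x) for x in (3.29, 2.33, 2.17, 0.67)]  # signs irrelevant for BH
        from scipy.stats import norm

        zs = norm.isf(np.array(p) / 2)
        df = pd.DataFrame({"Z": zs, "W": [8] * 4},
                          index=pd.Index(list("abcd"), name="guide_id"))
        out = call_hits(df, fdr_threshold=0.05)
        np.testing.assert_allclose(out["fdr"], oracle_bh(p), atol=1e-9)
        np.testing.assert_allclose(out["fdr"], [0.004, 0.04, 0.04, 0.5], atol=1e-9)

    def test_w_filter_excludes_from_fdr(self):
        df = pd.DataFrame({"Z": [5.0, 5.0, 0.1], "W": [8, 3, 8]},
                          index=pd.Index(list("abc"), name="guide_id"))
        out = call_hits(df)
        assert math.isnan(out.loc["b", "p"]) and out.loc["b", "hit_class"] == "none"
        # BH ran over exactly 2 guides: smallest fdr = p_min * 2 / 1
        assert out.loc["a", "fdr"] == pytest.approx(out.loc["a", "p"] * 2, abs=1e-15)

    def test_empty_filtered_set_warns(self):
        df = pd.DataFrame({"Z": [1.0], "W": [2]}, index=pd.Index(["a"], name="guide_id"))
        with pytest.warns(UserWarning, match="W >= 4"):
            out = call_hits(df)
        assert (out["hit_class"] == "none").all()

    def test_hit_classes_follow_sign(self):
        df = pd.DataFrame({"Z": [8.0, -8.0, 0.1], "W": [8, 8, 8]},
                          index=pd.Index(list("abc"), name="guide_id"))
        out = call_hits(df, fdr_threshold=0.01)
        assert list(out["hit_class"]) == ["activator", "inhibitor", "none"]


# ---------------------------------------------------------------------------
# oracle equivalence and exact symmetries on full random tables


def _four_replicates(seed0=100):
    tables = []
    for i, (rid, rep) in enumerate(
        [("IN1", "DUAL_IN"), ("IN2", "DUAL_IN"), ("EX1", "DUAL_EX"), ("EX2", "DUAL_EX")]
    ):
        tables.append(make_random_counts(seed=seed0 + i, replicate_id=rid, reporter=rep))
    return tables


@pytest.mark.parametrize("mode", ["per_guide", "as_printed"])
def test_full_chain_matches_oracle(mode):
    """e, z, z_rep, Z, p, fdr reproduced by the straight-line oracle to 1e-9."""
    tables = _four_replicates()
    per_rep = [replicate_stats(t, mode=mode) for t in tables]
    oracle_reps = []
    for t in tables:
        counts = {
            g: (int(t.counts.at[g, "n_u"]), int(t.counts.at[g, "n_t"]),
                int(t.counts.at[g, "n_b"]))
            for g in t.counts.index
        }
        totals = (t.totals["unsorted"], t.totals["top"], t.totals["bottom"])
        oracle_reps.append((oracle_replicate(counts, totals, mode=mode), t.reporter))

    for df, (orc, _) in zip(per_rep, oracle_reps):
        for g in df.index:
            for col in ("e_top", "z_top", "e_bottom", "z_bottom", "z_rep"):
                got, want = df.at[g, col], orc[g][col]
                if want is None:
                    assert math.isnan(got), (g, col)
                else:
                    assert got == pytest.approx(want, abs=1e-9), (g, col)
            assert df.at[g, "w_top"] == orc[g]["w_top"]
            assert df.at[g, "w_bottom"] == orc[g]["w_bottom"]

    combined = combine_replicates(per_rep)
    oc = oracle_combine(oracle_reps)
    for g in combined.index:
        assert combined.at[g, "W"] == oc[g]["W"]
        want = oc[g]["Z"]
        if want is None:
            assert math.isnan(combined.at[g, "Z"])
        else:
            assert combined.at[g, "Z"] == pytest.approx(want, abs=1e-9)

    hits = call_hits(combined, fdr_threshold=0.01)
    oh = oracle_hits(oc, fdr_threshold=0.01)
    for g in hits.index:
        if g in oh:
            assert hits.at[g, "p"] == pytest.approx(oh[g]["p"], abs=1e-9)
            assert hits.at[g, "fdr"] == pytest.approx(oh[g]["fdr"], abs=1e-9)
            assert hits.at[g, "hit_class"] == oh[g]["hit_class"]
        else:
            assert math.isnan(hits.at[g, "p"])


def _swap_bins(table: BinCountTable) -> BinCountTable:
    df = table.counts.rename(columns={"n_t": "n_b", "n_b": "n_t"})[["n_u", "n_t", "n_b"]]
    return BinCountTable(
        table.replicate_id, table.reporter, df,
        {"unsorted": table.totals["unsorted"], "top": table.totals["bottom"],
         "bottom": table.totals["top"]},
        {"unsorted": table.unassigned["unsorted"], "top": table.unassigned["bottom"],
         "bottom": table.unassigned["top"]},
    )


def test_swapping_bins_negates_z_exactly():
    tables = _four_replicates(seed0=200)
    z1 = combine_replicates([replicate_stats(t) for t in tables])
    z2 = combine_replicates([replicate_stats(_swap_bins(t)) for t in tables])
    assert (z1["W"] == z2["W"]).all()
    both = np.isfinite(z1["Z"]) & np.isfinite(z2["Z"])
    assert both.equals(np.isfinite(z1["Z"])) and bool(both.any())
    np.testing.assert_array_equal(z1.loc[both, "Z"].to_numpy(), -z2.loc[both, "Z"].to_numpy())


def test_reporter_flip_with_bin_swap_is_invariant():
    tables = _four_replicates(seed0=300)
    z1 = combine_replicates([replicate_stats(t) for t in tables])
    flipped = []
    for t in tables:
        s = _swap_bins(t)
        s.reporter = "DUAL_EX" if t.reporter == "DUAL_IN" else "DUAL_IN"
        flipped.append(s)
    z2 = combine_replicates([replicate_stats(t) for t in flipped])
    both = np.isfinite(z1["Z"])
    np.testing.assert_array_equal(z1.loc[both, "Z"].to_numpy(), z2.loc[both, "Z"].to_numpy())
    assert (z1["W"] == z2["W"]).all()


def test_analyze_screen_attaches_replicate_columns():
    tables = _four_replicates(seed0=400)
    res = analyze_screen(tables)
    assert {"Z", "W", "p", "fdr", "hit_class"} <= set(res.columns)
    for rid in ("IN1", "IN2", "EX1", "EX2"):
        assert f"z_rep_{rid}" in res.columns
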