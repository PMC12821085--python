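from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capcogs import cogs
from capcogs.finemap import Signal
from capcogs.genome_model import GenomicInterval, MHC_GRCH38, Promoter


def _consensus(rows):
    return pd.DataFrame(
        rows, columns=["bait_id", "oe_frag", "score", "trans"]
    ).assign(n_obs=1.0, raw_reads=10, distance=1e4, provenance="fragment")


def _abcc(rows):
    return pd.DataFrame(rows, columns=["gene_id", "abc_score", "fragment_ids"])


class TestBuildGeneFeatures:
    def test_proximal_window_is_tss_fragment_plus_minus_five(self, uniform_fragmap):
        prom = [Promoter("G1", "chr1", 2050, 20, baited=False)]
        feats = cogs.build_gene_features(
            "G1", prom, uniform_fragmap, _consensus([]), _abcc([]), {}
        )
        assert feats.fragments["promoter_proximal"] == frozenset(range(15, 26))
        # unbaited promoters contribute no PIRs
        assert feats.fragments["pchic_pir"] == frozenset()

    def test_chicago_threshold_is_inclusive_at_five(self, uniform_fragmap):
        prom = [Promoter("G1", "chr1", 2050, 20, baited=True)]
        consensus = _consensus(
            [(20, 40, 4.9, False), (20, 41, 5.0, False), (20, 60, 9.0, True)]
        )
        feats = cogs.build_gene_features(
            "G1", prom, uniform_fragmap, consensus, _abcc([]), {}
        )
        assert feats.fragments["pchic_pir"] == frozenset({41})

    def test_abcc_threshold_and_coding(self, uniform_fragmap):
        prom = [Promoter("G1", "chr1", 2050, 20, baited=True)]
        pairs = _abcc(
            [("G1", 0.04, (33,)), ("G1", 0.039, (34,)), ("G2", 0.5, (35,))]
        )
        coding = {"G1": {("chr1", 123)}}
        feats = cogs.build_gene_features(
            "G1", prom, uniform_fragmap, _consensus([]), pairs, coding
        )
        assert feats.fragments["abcc_enhancer"] == frozenset({33})
        assert feats.coding_positions == frozenset({("chr1", 123)})

    def test_union_over_alternative_promoters_matches_enumeration(
        self, uniform_fragmap
    ):
        proms = [
            Promoter("G1", "chr1", 1050, 10, baited=True),
            Promoter("G1", "chr1", 3050, 30, baited=True),
        ]
        consensus = _consensus([(10, 44, 6.0, False), (30, 45, 7.0, False)])
        feats = cogs.build_gene_features(
            "G1", proms, uniform_fragmap, consensus, _abcc([]), {}
        )
        expect_prox = set(range(5, 16)) | set(range(25, 36))
        assert feats.fragments["promoter_proximal"] == frozenset(expect_prox)
        assert feats.fragments["pchic_pir"] == frozenset({44, 45})

    def test_gene_without_tss_rejected(self, uniform_fragmap):
        with pytest.raises(ValueError, match="promoter"):
            cogs.build_gene_features(
                "G9", [], uniform_fragmap, _consensus([]), _abcc([]), {}
            )


class TestScoreSignalForGene:
    def _features(self):
        return cogs.GeneFeatureSet(
            "G1",
            coding_positions=frozenset({("chr1", 710)}),
            fragments={
                "promoter_proximal": frozenset({1, 2, 3}),
                "pchic_pir": frozenset({7}),
                "abcc_enhancer": frozenset(),
            },
        )

    def test_sums_pips_inside_features(self, uniform_fragmap):
        sig = Signal("B0", "cs1", {"a": 0.5, "b": 0.3, "c": 0.1})
        positions = {
            "a": ("chr1", 750),   # fragment 7 = PIR
            "b": ("chr1", 710),   # coding position
            "c": ("chr1", 4500),  # outside
        }
        s = cogs.score_signal_for_gene(
            self._features(), sig, positions, uniform_fragmap
        )
        assert s == pytest.approx(0.8)

    def test_variant_in_two_features_counts_once(self, uniform_fragmap):
        # position 710 is both a coding SNP and inside PIR fragment 7
        feats = cogs.GeneFeatureSet(
            "G1",
            coding_positions=frozenset({("chr1", 710)}),
            fragments={"pchic_pir": frozenset({7})},
        )
        sig = Signal("B0", "cs1", {"a": 0.4})
        s = cogs.score_signal_for_gene(
            feats, sig, {"a": ("chr1", 710)}, uniform_fragmap
        )
        assert s == 0.4

    def test_empty_overlap_scores_zero(self, uniform_fragmap):
        sig = Signal("B0", "cs1", {"a": 0.9})
        s = cogs.score_signal_for_gene(
            self._features(), sig, {"a": ("chr2", 100)}, uniform_fragmap
        )
        assert s == 0.0

    def test_unknown_position_drop_vs_error(self, uniform_fragmap):
        sig = Signal("B0", "cs1", {"zzz": 0.9})
        with pytest.warns(UserWarning, match="unknown position"):
            s = cogs.score_signal_for_gene(
                self._features(), sig, {}, uniform_fragmap
            )
        assert s == 0.0
        with pytest.raises(KeyError):
            cogs.score_signal_for_gene(
                self._features(), sig, {}, uniform_fragmap, on_missing="error"
            )


class TestMulticogsScore:
    def test_printed_example(self):
        assert cogs.multicogs_score([0.6, 0.5]) == 0.8

    def test_empty_and_identity(self):
        assert cogs.multicogs_score([]) == 0.0
        assert cogs.multicogs_score([0.37]) == pytest.approx(0.37)

    def test_matches_inclusion_exclusion_on_all_small_subsets(self):
        rng = np.random.default_rng(12)
        pool = rng.uniform(0, 1, size=6)
        for k in range(len(pool) + 1):
            for subset in combinations(pool, k):
                # brute-force inclusion-exclusion under independence
                expect = 0.0
                for j in range(1, len(subset) + 1):
                    for combo in combinations(subset, j):
                        expect += (-1) ** (j + 1) * np.prod(combo)
                assert cogs.multicogs_score(list(subset)) == pytest.approx(
                    expect, abs=1e-12
                )

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            cogs.multicogs_score([1.2])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        scores=st.lists(st.floats(min_value=0, max_value=1), max_size=8),
        extra=st.floats(min_value=0, max_value=1),
    )
    def test_bounds_monotonicity_and_zero_neutrality(self, scores, extra):
        s = cogs.multicogs_score(scores)
        assert max(scores, default=0.0) - 1e-12 <= s <= min(
            1.0, sum(scores)
        ) + 1e-12
        assert cogs.multicogs_score(scores + [0.0]) == pytest.approx(s)
        assert cogs.multicogs_score(scores + [extra]) >= s - 1e-12
        assert cogs.multicogs_score(scores[::-1]) == pytest.approx(s)


class TestStandardCogs:
    def test_one_block_passthrough(self, uniform_fragmap):
        feats = cogs.GeneFeatureSet(
            "G1", frozenset(), {"pchic_pir": frozenset({7})}
        )
        sig = Signal("B0", "single", {"a": 0.95})
        s = cogs.standard_cogs_score(
            feats, [sig], {"a": ("chr1", 750)}, uniform_fragmap
        )
        assert s == pytest.approx(0.95)

    def test_duplicate_block_rejected(self, uniform_fragmap):
        feats = cogs.GeneFeatureSet("G1", frozenset(), {})
        sigs = [Signal("B0", "cs1", {}), Signal("B0", "cs2", {})]
        with pytest.raises(ValueError, match="one signal per block"):
            cogs.standard_cogs_score(feats, sigs, {}, uniform_fragmap)

    def test_equivalent_to_multicogs_with_one_credset_per_block(
        self, uniform_fragmap
    ):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n_frag_feats = rng.integers(1, 6)
            feats = cogs.GeneFeatureSet(
                "G1", frozenset(),
                {"pchic_pir": frozenset(
                    int(f) for f in rng.choice(50, n_frag_feats, replace=False)
                )},
            )
            signals, positions = [], {}
            for b in range(int(rng.integers(1, 5))):
                pips = {}
                for v in range(int(rng.integers(1, 6))):
                    name = f"b{b}v{v}"
                    pips[name] = float(rng.uniform(0, 0.2))
                    positions[name] = ("chr1", int(rng.integers(0, 5000)))
                signals.append(Signal(f"B{b}", "cs1", pips))
            std = cogs.standard_cogs_score(
                feats, signals, positions, uniform_fragmap
            )
            multi = cogs.multicogs_score(
                [
                    cogs.score_signal_for_gene(
                        feats, s, positions, uniform_fragmap
                    )
                    for s in signals
                ]
            )
            assert std == multi


class TestDecomposeByCategory:
    def test_all_mass_in_coding(self, uniform_fragmap):
        feats = cogs.GeneFeatureSet(
            "G1",
            coding_positions=frozenset({("chr1", 100)}),
            fragments={"pchic_pir": frozenset({40})},
        )
        sig = Signal("B0", "cs1", {"a": 0.7})
        out = cogs.decompose_by_category(
            feats, [sig], {"a": ("chr1", 100)}, uniform_fragmap
        )
        assert out["coding"] == pytest.approx(0.7)
        assert out["promoter_proximal"] == 0.0
        assert out["abcc_enhancer"] == 0.0
        # position 100 also not in fragment 40
        assert out["pchic_pir"] == 0.0

    def test_full_score_bounds_categories_with_disjoint_variants(
        self, uniform_fragmap
    ):
        feats = cogs.GeneFeatureSet(
            "G1",
            coding_positions=frozenset({("chr1", 4105)}),
            fragments={
                "promoter_proximal": frozenset({10}),
                "pchic_pir": frozenset({20}),
                "abcc_enhancer": frozenset({30}),
            },
        )
        positions = {
            "c": ("chr1", 4105), "p": ("chr1", 1050),
            "i": ("chr1", 2050), "e": ("chr1", 3050),
        }
        sigs = [
            Signal("B0", "cs1", {"c": 0.2, "p": 0.3}),
            Signal("B1", "cs1", {"i": 0.25, "e": 0.15}),
        ]
        cats = cogs.decompose_by_category(feats, sigs, positions, uniform_fragmap)
        full = cogs.multicogs_score(
            [
                cogs.score_signal_for_gene(feats, s, positions, uniform_fragmap)
                for s in sigs
            ]
        )
        # full signal combines per-signal sums 0.5 and 0.4
        assert full == pytest.approx(1 - 0.5 * 0.6)
        assert full >= max(cats.values()) - 1e-12
        assert cats["coding"] == pytest.approx(0.2)
        assert cats["pchic_pir"] == pytest.approx(0.25)


class TestExcludeRegion:
    def test_variant_inside_mhc_removed(self):
        sigs = [Signal("B0", "cs1", {"in": 0.5, "out": 0.3})]
        positions = {"in": ("6", 30_000_000), "out": ("6", 40_000_000)}
        out = cogs.exclude_region(sigs, positions)
        assert out[0].pip == {"out": 0.3}

    def test_boundary_follows_half_open_zero_based(self):
        # MHC stored 0-based half-open [28510119, 33480577)
        sigs = [Signal("B0", "cs1", {"a": 0.5, "b": 0.3, "c": 0.1})]
        positions = {
            "a": ("6", 28_510_118),  # last base before the MHC
            "b": ("6", 28_510_119),  # first MHC base
            "c": ("6", 33_480_577),  # first base after the MHC
        }
        out = cogs.exclude_region(sigs, positions)
        assert set(out[0].pip) == {"a", "c"}

    def test_empty_region_list_is_identity(self):
        sigs = [Signal("B0", "cs1", {"a": 0.5})]
        assert cogs.exclude_region(sigs, {"a": ("6", 1)}, regions=()) == sigs

    def test_signal_left_empty_is_dropped(self):
        sigs = [Signal("B0", "cs1", {"a": 0.5})]
        out = cogs.exclude_region(sigs, {"a": (MHC_GRCH38.chrom, 30_000_000)})
        assert out == []


class TestPrioritise:
    def _scores(self, values):
        return pd.DataFrame(
            {"gene_id": [f"G{i}" for i in range(len(values))],
             "multicogs": values}
        )

    def test_strict_threshold(self):
        out = cogs.prioritise(self._scores([0.51, 0.5, 0.49]))
        flagged = out[out["prioritised"]]
        assert list(flagged["gene_id"]) == ["G0"]

    def test_inclusive_option(self):
        out = cogs.prioritise(self._scores([0.51, 0.5, 0.49]), strict=False)
        assert out["prioritised"].sum() == 2

    def test_empty_input(self):
        out = cogs.prioritise(self._scores([]))
        assert out.empty and "prioritised" in out.columns

    def test_ranking_matches_sort_oracle(self):
        rng = np.random.default_rng(8)
        vals = list(np.round(rng.uniform(0, 1, 40), 2))  # force some ties
        out = cogs.prioritise(self._scores(vals))
        expect = sorted(
            zip(vals, [f"G{i}" for i in range(len(vals))]),
            key=lambda t: (-t[0], t[1]),
        )
        assert list(out["gene_id"]) == [g for _, g in expect]
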