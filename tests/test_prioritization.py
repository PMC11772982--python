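"""Top-variant selection, nearest-TSS assignment and enrichment."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from sulcalvar.prioritization import (
    assign_nearest_tss,
    assign_targets,
    hypergeometric_enrichment,
    interval_overlap,
    nearest_tss_bulk,
    read_gmt,
    read_tss_bed,
    recurrent_targets,
    top_variant_per_participant,
    write_gmt,
    TargetAssignment,
)


def tss_frame(positions, genes=None, chrom="chrS"):
    genes = genes or [f"g{i}" for i in range(len(positions))]
    return pd.DataFrame({
        "chrom": chrom, "tss_pos": positions, "gene": genes,
        "strand": "+"}).sort_values("tss_pos", ignore_index=True)


class TestTopVariant:
    def test_argmax(self):
        scores = pd.Series({"v1": 0.2, "v2": 0.9})
        pmap = pd.Series({"v1": "p1", "v2": "p1"})
        top = top_variant_per_participant(scores, pmap)
        assert top.loc["p1", "variant_id"] == "v2"

    def test_tie_breaks_lexicographically(self):
        scores = pd.Series({"vB": 1.0, "vA": 1.0, "vC": 1.0})
        pmap = pd.Series("p1", index=scores.index)
        top = top_variant_per_participant(scores, pmap)
        assert top.loc["p1", "variant_id"] == "vA"

    def test_one_selection_per_participant(self, rng):
        n_participants = 200
        ids = [f"v{i}" for i in range(1000)]
        scores = pd.Series(rng.standard_normal(1000), index=ids)
        pmap = pd.Series([f"p{i % n_participants}" for i in range(1000)],
                         index=ids)
        top = top_variant_per_participant(scores, pmap)
        assert len(top) == n_participants

    def test_min_direction(self):
        scores = pd.Series({"v1": 0.2, "v2": -0.9})
        pmap = pd.Series("p1", index=scores.index)
        top = top_variant_per_participant(scores, pmap, direction="min")
        assert top.loc["p1", "variant_id"] == "v2"


class TestNearestTSS:
    def test_forced_by_distance(self):
        gene, dist = assign_nearest_tss("chrS", 10_000,
                                        tss_frame([5_000, 14_000]))
        assert gene == "g1" and dist == -4_000

    def test_beyond_max_distance(self):
        gene, dist = assign_nearest_tss("chrS", 10_000,
                                        tss_frame([35_000]))
        assert gene is None and dist is None

    def test_missing_chromosome(self):
        gene, _ = assign_nearest_tss("chr9", 100, tss_frame([50]))
        assert gene is None

    def test_brute_force_oracle(self, rng):
        tss = tss_frame(sorted(rng.choice(
            np.arange(1, 2_000_000), size=120, replace=False)))
        positions = tss["tss_pos"].to_numpy()
        genes = tss["gene"].to_numpy()
        variants = rng.integers(1, 2_000_000, size=1000)
        bulk = nearest_tss_bulk(
            pd.DataFrame({"chrom": "chrS", "pos": variants}), tss)
        for k, pos in enumerate(variants):
            dist = np.abs(positions - pos)
            best = dist.min()
            expected = None
            if best <= 20_000:
                expected = min(genes[dist == best])
            gene, _ = assign_nearest_tss("chrS", int(pos), tss)
            assert gene == expected
            assert bulk.iloc[k] == expected

    def test_bed6_strand_aware_tss(self, tmp_path):
        path = tmp_path / "tss.bed"
        path.write_text(
            "chrS\t99\t200\tgplus\t0\t+\n"
            "chrS\t300\t400\tgminus\t0\t-\n")
        tss = read_tss_bed(path)
        assert tss.set_index("gene").loc["gplus", "tss_pos"] == 100
        assert tss.set_index("gene").loc["gminus", "tss_pos"] == 400

    def test_duplicate_gene_ids_rejected(self, tmp_path):
        path = tmp_path / "tss.bed"
        path.write_text("chrS\t1\t2\tg\t0\t+\nchrS\t5\t6\tg\t0\t+\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_tss_bed(path)


class TestRecurrentTargets:
    def asg(self, pairs):
        return [TargetAssignment(v, "p", 0.0, g, 0) for v, g in pairs]

    def test_min_count_two(self):
        out = recurrent_targets(
            self.asg([("v1", "g1"), ("v2", "g1"), ("v3", "g2")]), 2)
        assert out.to_dict("records") == [{"gene": "g1", "n_variants": 2}]

    def test_min_count_one_returns_all(self):
        out = recurrent_targets(
            self.asg([("v1", "g1"), ("v2", "g2")]), 1)
        assert set(out["gene"]) == {"g1", "g2"}

    def test_higher_tier_threshold(self):
        pairs = [(f"v{i}", "g1") for i in range(3)] + [("v9", "g2"),
                                                       ("v10", "g2")]
        out = recurrent_targets(self.asg(pairs), 3)
        assert out.to_dict("records") == [{"gene": "g1", "n_variants": 3}]


class TestEnrichment:
    def test_exact_small_case(self):
        # N=20, K=5, n=5, k=4: p = (C(5,4)C(15,1)+C(5,5))/C(20,5)
        background = [f"g{i}" for i in range(20)]
        study = background[:4] + ["g19"]
        sets = {"s": background[:5]}
        out = hypergeometric_enrichment(study, background, sets)
        assert out.loc[0, "p"] == pytest.approx(76 / 15504, abs=1e-12)

    def test_zero_overlap_p_one(self):
        background = [f"g{i}" for i in range(10)]
        out = hypergeometric_enrichment(background[:3], background,
                                        {"s": background[5:]})
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_study_equals_background(self):
        background = [f"g{i}" for i in range(12)]
        out = hypergeometric_enrichment(background, background,
                                        {"s": background[:4]})
        assert out.loc[0, "k"] == out.loc[0, "K"]
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_exact_rational_enumeration_oracle(self, rng):
        for _ in range(15):
            n_total = int(rng.integers(8, 26))
            big_k = int(rng.integers(1, n_total + 1))
            n_study = int(rng.integers(1, n_total + 1))
            background = [f"g{i}" for i in range(n_total)]
            study = list(rng.choice(background, size=n_study,
                                    replace=False))
            members = list(rng.choice(background, size=big_k,
                                      replace=False))
            out = hypergeometric_enrichment(study, background,
                                            {"s": members})
            k = len(set(study) & set(members))
            exact = sum(
                Fraction(comb(big_k, i) * comb(n_total - big_k,
                                               n_study - i),
                         comb(n_total, n_study))
                for i in range(k, min(n_study, big_k) + 1))
            assert out.loc[0, "p"] == pytest.approx(float(exact),
                                                    abs=1e-12)

    def test_empty_study_warns_empty_result(self):
        out = hypergeometric_enrichment([], ["g1"], {"s": ["g1"]})
        assert out.empty

    def test_gmt_round_trip(self, tmp_path):
        sets = {"a": ["g1", "g2"], "b": ["g3"]}
        path = tmp_path / "sets.gmt"
        write_gmt(sets, path)
        assert read_gmt(path) == sets


class TestIntervalOverlap:
    def test_boundary_arithmetic(self):
        regions = pd.DataFrame({"chrom": ["chrS"], "start": [99],
                                "end": [100]})
        variants = pd.DataFrame({"chrom": ["chrS"], "pos": [100]})
        flags, frac = interval_overlap(variants, regions)
        assert flags.iloc[0] and frac == 1.0

    def test_left_edge_excluded(self):
        regions = pd.DataFrame({"chrom": ["chrS"], "start": [100],
                                "end": [200]})
        variants = pd.DataFrame({"chrom": ["chrS"], "pos": [100]})
        flags, _ = interval_overlap(variants, regions)
        assert not flags.iloc[0]

    def test_fraction_reporting(self):
        # 58 of 89 variants inside regions -> 65%
        pos = list(range(1, 59)) + list(range(1_000_000, 1_000_031))
        variants = pd.DataFrame({"chrom": "chrS", "pos": pos})
        regions = pd.DataFrame({"chrom": ["chrS"], "start": [0],
                                "end": [58]})
        flags, frac = interval_overlap(variants, regions)
        assert flags.sum() == 58
        assert frac == pytest.approx(58 / 89)
        assert round(frac, 3) == 0.652


def test_assign_targets_respects_max_distance(rng):
    top = pd.DataFrame(
        {"variant_id": ["chrS:10000:A:G", "chrS:500000:A:G"],
         "score": [1.0, 2.0]}, index=["p1", "p2"])
    tss = tss_frame([14_000, 900_000])
    out = assign_targets(top, tss)
    assert out[0].gene == "g0" and out[0].distance == -4_000
    assert out[1].gene is None
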