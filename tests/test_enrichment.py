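"""Pooling, EF computation, quartiles, and subgroup summaries."""

from collections import Counter

import numpy as np
import pytest

from caaxscreen.enrichment import (ConditionCounts, assign_quartiles,
                                   compute_ef, pool_replicates,
                                   read_ef_table, subgroup_mean_ef,
                                   write_ef_table)
from caaxscreen.extraction import ReplicateCounts
from caaxscreen.motifs import enumerate_cxxx

from conftest import make_ef_table


def _rep(counts, condition="25C", rep_id="r"):
    return ReplicateCounts(replicate_id=rep_id, condition=condition,
                           counts=Counter(counts),
                           n_reads_total=sum(counts.values()))


def _condition(counts, condition):
    return ConditionCounts(condition=condition, counts=Counter(counts),
                           total=sum(counts.values()))


class TestPooling:
    def test_two_replicates(self):
        pooled = pool_replicates([_rep({"CASQ": 3}),
                                  _rep({"CASQ": 5, "CVIA": 2})])
        assert pooled.counts == Counter({"CASQ": 8, "CVIA": 2})
        assert pooled.total == 10

    def test_single_replicate_identity(self):
        pooled = pool_replicates([_rep({"CASQ": 3, "CKQQ": 1})])
        assert pooled.counts == Counter({"CASQ": 3, "CKQQ": 1})

    def test_mixed_conditions_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            pool_replicates([_rep({"CASQ": 1}, "25C"),
                             _rep({"CASQ": 1}, "37C")])

    def test_eight_replicates_against_bruteforce(self):
        rng = np.random.default_rng(42)
        motifs = enumerate_cxxx()[:50]
        reps = []
        for i in range(8):
            counts = {m: int(rng.integers(0, 100)) for m in motifs}
            reps.append(_rep(counts, rep_id=f"r{i}"))
        pooled = pool_replicates(reps)
        for m in motifs:
            expected = sum(r.counts[m] for r in reps)
            assert pooled.counts[m] == expected


class TestComputeEF:
    def test_absent_at_25_raw_count(self):
        """A motif absent at the permissive temperature stays finite:
        EF = (5+1)/(0+1) = 6 on the raw-count scale."""
        base = {m: 10 for m in enumerate_cxxx()}
        c25 = dict(base)
        c37 = dict(base)
        c25["CVFF"] = 0
        c37["CVFF"] = 5
        table = compute_ef(_condition(c25, "25C"), _condition(c37, "37C"),
                           scale="raw_count")
        assert table.ef["CVFF"] == pytest.approx(6.0)

    def test_identical_conditions_all_unity(self):
        counts = {m: (i % 7) + 1 for i, m in enumerate(enumerate_cxxx())}
        for scale in ("cpm", "raw_count", "fraction"):
            table = compute_ef(_condition(counts, "25C"),
                               _condition(counts, "37C"), scale=scale)
            assert np.allclose(table.df["ef"], 1.0)

    def test_dropout_motifs_finite_and_enriched(self):
        """Motifs with zero permissive counts but selective counts have
        EF > 1, and motifs absent everywhere get EF exactly 1."""
        dropouts = ["CFFM", "CIFF", "CILF", "CIYM", "CNWC", "CTFA",
                    "CVFF", "CVLW", "CWIA"]
        c25 = {m: 50 for m in enumerate_cxxx()}
        c37 = {m: 50 for m in enumerate_cxxx()}
        for m in dropouts:
            c25[m] = 0
            c37[m] = 40
        c25["CAAA"] = c37["CAAA"] = 0  # absent from both conditions
        table = compute_ef(_condition(c25, "25C"), _condition(c37, "37C"))
        efs = table.ef
        for m in dropouts:
            assert np.isfinite(efs[m]) and efs[m] > 1
        assert efs["CAAA"] == pytest.approx(1.0)

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(3)
        counts = {m: int(rng.integers(1, 50)) for m in enumerate_cxxx()}
        table = compute_ef(_condition(counts, "25C"),
                          _condition(counts, "37C"))
        assert table.df["freq25"].sum() == pytest.approx(1.0, abs=1e-12)
        assert table.df["freq37"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_cpm_scale_invariance(self):
        """Multiplying all counts in both conditions by a constant leaves
        cpm-scale EFs unchanged."""
        rng = np.random.default_rng(9)
        counts = {m: int(rng.integers(1, 200)) for m in enumerate_cxxx()}
        t1 = compute_ef(_condition(counts, "25C"), _condition(counts, "37C"))
        scaled = {m: 13 * c for m, c in counts.items()}
        t2 = compute_ef(_condition(scaled, "25C"), _condition(scaled, "37C"))
        np.testing.assert_allclose(t1.df["ef"], t2.df["ef"], rtol=1e-12)

    def test_zero_total_rejected(self):
        good = _condition({m: 1 for m in enumerate_cxxx()[:10]}, "25C")
        empty = _condition({}, "37C")
        with pytest.raises(ValueError, match="zero total"):
            compute_ef(good, empty)

    def test_table_io_roundtrip(self, tmp_path):
        counts = {m: 5 for m in enumerate_cxxx()}
        table = compute_ef(_condition(counts, "25C"),
                           _condition(counts, "37C"))
        path = tmp_path / "ef.tsv"
        write_ef_table(table, path)
        back = read_ef_table(path)
        np.testing.assert_allclose(back.df["ef"], table.df["ef"])
        assert back.metadata["scale"] == "cpm"


class TestQuartiles:
    def test_equal_blocks_and_extremes(self, random_ef_table):
        quart = assign_quartiles(random_ef_table)
        assert sorted(quart.value_counts()) == [2000] * 4
        top = random_ef_table.df.loc[random_ef_table.df["ef"].idxmax(),
                                     "motif"]
        assert quart[top] == 4

    def test_matches_rank_oracle(self, random_ef_table):
        df = random_ef_table.df
        ranked = df.sort_values(["ef", "motif"]).reset_index(drop=True)
        oracle = {}
        for i, motif in enumerate(ranked["motif"]):
            oracle[motif] = 1 + (i * 4) // len(ranked)
        quart = assign_quartiles(random_ef_table)
        assert quart.to_dict() == oracle


class TestSubgroupMeanEF:
    def test_canonical_caal_group_size(self, random_ef_table):
        n, mean, sd = subgroup_mean_ef(random_ef_table, a1_set="ILV",
                                       a2_set="ILV", x_set="LFMI")
        assert n == 36  # 3 x 3 x 4 motifs
        assert np.isfinite(mean) and np.isfinite(sd)

    def test_cxxl_group_size(self, random_ef_table):
        n, _, _ = subgroup_mean_ef(random_ef_table, x_set="LFMI")
        assert n == 1600

    def test_full_alphabet_grand_mean(self, random_ef_table):
        n, mean, sd = subgroup_mean_ef(random_ef_table)
        ef = random_ef_table.df["ef"].to_numpy()
        assert n == 8000
        assert mean == pytest.approx(ef.mean())
        assert sd == pytest.approx(ef.std(ddof=0))

    def test_subgroup_matches_bruteforce(self, random_ef_table):
        efs = random_ef_table.ef
        want = [efs[m] for m in efs.index
                if m[1] in "ILV" and m[2] in "ILV" and m[3] in "LFMI"]
        _, mean, _ = subgroup_mean_ef(random_ef_table, "ILV", "ILV", "LFMI")
        assert mean == pytest.approx(np.mean(want))

    def test_empty_intersection_flagged(self):
        table = make_ef_table(np.ones(8000))
        sub = table.df[table.df["motif"].str[1] != "P"].reset_index(drop=True)
        table.df = sub
        n, mean, _ = subgroup_mean_ef(table, a1_set="P")
        assert n == 0 and np.isnan(mean)
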