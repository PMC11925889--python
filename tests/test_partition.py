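import numpy as np
import pandas as pd
import pytest

import microkeystone as mk
from microkeystone.containers import RelAbundanceTable, ValidationError
from microkeystone.partition import ABUNDANCE_CLASSES, classify_min_max, tmm_factors


class TestRelativeAbundance:
    def test_simple_column(self):
        table = mk.CountTable(pd.DataFrame(
            {"s1": [2, 2, 4], "s2": [1, 1, 2]}, index=["a", "b", "c"]
        ))
        rel = mk.to_relative_abundance(table)
        assert rel.data["s1"].tolist() == [0.25, 0.25, 0.5]

    def test_single_feature_is_all_ones(self):
        table = mk.CountTable(pd.DataFrame({"s1": [5], "s2": [9]}, index=["a"]))
        rel = mk.to_relative_abundance(table)
        assert (rel.values == 1.0).all()

    def test_columns_sum_to_one(self, community):
        rel = mk.to_relative_abundance(community[0])
        np.testing.assert_allclose(rel.values.sum(axis=0), 1.0, atol=1e-9)

    def test_zero_sample_rejected(self):
        df = pd.DataFrame({"s1": [1, 2], "s2": [0, 0]}, index=["a", "b"])
        with pytest.raises(ValidationError, match="s2"):
            mk.to_relative_abundance(mk.CountTable(df))


class TestPrevalenceFilter:
    def test_matches_brute_force(self, community):
        table, meta, _ = community
        rel = mk.to_relative_abundance(table)
        filt = mk.prevalence_filter(rel, meta)
        # independent recount of the two rules
        expected = []
        for fid in rel.feature_ids:
            row = rel.data.loc[fid]
            prev_ok = False
            for g in meta.group_names:
                vals = [row[s] for s in meta.samples_in(g)]
                if sum(v > 0 for v in vals) / len(vals) >= 0.20:
                    prev_ok = True
            if prev_ok and row.sum() > 0.025:
                expected.append(fid)
        assert filt.feature_ids == expected

    def test_retains_sparse_but_grouped_feature(self):
        # present in 3/10 samples of one group, total relabund 0.05
        n = 20
        data = np.full((2, n), 0.0)
        data[0] = 1.0  # filler feature
        data[1, :3] = [0.02, 0.02, 0.01]
        data[0] -= data[1]
        rel = RelAbundanceTable(pd.DataFrame(
            data, index=["filler", "target"], columns=[f"s{i}" for i in range(n)]
        ))
        meta = mk.SampleMetadata(pd.Series(
            ["g1"] * 10 + ["g2"] * 10, index=rel.sample_ids
        ))
        filt = mk.prevalence_filter(rel, meta)
        assert "target" in filt.feature_ids

    def test_absent_feature_removed(self, community):
        table, meta, _ = community
        rel = mk.to_relative_abundance(table)
        ghost = rel.data.copy()
        ghost.loc["GHOST"] = 0.0
        rel2 = RelAbundanceTable.from_subset(ghost)
        filt = mk.prevalence_filter(rel2, meta)
        assert "GHOST" not in filt.feature_ids

    def test_idempotent(self, community):
        table, meta, _ = community
        rel = mk.to_relative_abundance(table)
        once = mk.prevalence_filter(rel, meta)
        twice = mk.prevalence_filter(once, meta)
        assert once.feature_ids == twice.feature_ids

    def test_threshold_range_checked(self, community):
        table, meta, _ = community
        rel = mk.to_relative_abundance(table)
        with pytest.raises(ValidationError):
            mk.prevalence_filter(rel, meta, min_group_prevalence=1.5)


def _tmm_oracle(counts: np.ndarray, m_trim=0.30, a_trim=0.05) -> np.ndarray:
    """Slow, loop-based TMM from the published definition (independent of the
    vectorised implementation)."""
    lib = counts.sum(axis=0).astype(float)
    uq = np.array([np.quantile(counts[:, k], 0.75) / lib[k] for k in range(counts.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = []
    for k in range(counts.shape[1]):
        rows = [
            (np.log2((counts[i, k] / lib[k]) / (counts[i, ref] / lib[ref])),
             0.5 * np.log2((counts[i, k] / lib[k]) * (counts[i, ref] / lib[ref])),
             (lib[k] - counts[i, k]) / (lib[k] * counts[i, k])
             + (lib[ref] - counts[i, ref]) / (lib[ref] * counts[i, ref]))
            for i in range(counts.shape[0])
            if counts[i, k] > 0 and counts[i, ref] > 0
        ]
        if not rows or max(abs(m) for m, _, _ in rows) < 1e-6:
            factors.append(1.0)
            continue
        n = len(rows)
        m_sorted = sorted(r[0] for r in rows)
        a_sorted = sorted(r[1] for r in rows)
        lo_m, hi_m = int(np.floor(n * m_trim)), n - int(np.floor(n * m_trim))
        lo_a, hi_a = int(np.floor(n * a_trim)), n - int(np.floor(n * a_trim))
        m_keep = set(m_sorted[lo_m:hi_m])
        a_keep = set(a_sorted[lo_a:hi_a])
        kept = [r for r in rows if r[0] in m_keep and r[1] in a_keep]
        num = sum(m / v for m, _, v in kept)
        den = sum(1 / v for _, _, v in kept)
        factors.append(2.0 ** (num / den))
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))


class TestTmm:
    def test_identical_libraries(self):
        df = pd.DataFrame({"s1": [10, 20, 30], "s2": [10, 20, 30]}, index=list("abc"))
        res = tmm_factors(mk.CountTable(df))
        np.testing.assert_allclose(res.factors.to_numpy(), [1.0, 1.0])

    def test_scaled_library_gives_unit_factors(self):
        a = np.array([10, 20, 30, 5, 100])
        df = pd.DataFrame({"s1": a, "s2": 2 * a}, index=list("abcde"))
        res = tmm_factors(mk.CountTable(df))
        np.testing.assert_allclose(res.factors.to_numpy(), [1.0, 1.0])

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 500, size=(200, 5))
        counts[:40, 2] *= 6  # spiked sample
        table = mk.CountTable(pd.DataFrame(
            counts, index=[f"f{i}" for i in range(200)],
            columns=[f"s{j}" for j in range(5)],
        ))
        res = tmm_factors(table)
        np.testing.assert_allclose(
            res.factors.to_numpy(), _tmm_oracle(counts), atol=1e-6
        )

    def test_geometric_mean_one_and_scale_invariance(self, community):
        table = community[0]
        res = tmm_factors(table)
        assert abs(np.log(res.factors).mean()) < 1e-9
        doubled = mk.CountTable(table.data * 2)
        res2 = tmm_factors(doubled)
        np.testing.assert_allclose(
            res.factors.to_numpy(), res2.factors.to_numpy(), rtol=1e-9
        )


class TestAbundanceClasses:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([0.0005, 0.0005, 0.0005], "RT"),
            ([0.0005, 0.005, 0.02], "CRAT"),
            ([0.002, 0.005, 0.009], "MT"),
            ([0.02, 0.03, 0.05], "AT"),
            ([0.0005, 0.002, 0.005], "CRT"),
            ([0.002, 0.005, 0.02], "CAT"),
        ],
    )
    def test_wording_fixtures(self, values, expected):
        rest = [1 - v for v in values]
        data = pd.DataFrame(
            np.vstack([values, rest]),
            index=["target", "rest"],
            columns=["s1", "s2", "s3"],
        )
        rel = RelAbundanceTable(data)
        res = mk.classify_abundance(rel)
        assert res.classes["target"] == expected

    def test_grid_partition_is_exclusive_and_total(self):
        grid = np.arange(0.0001, 0.0502, 0.0007)
        for m in grid:
            for M in grid:
                if m > M:
                    continue
                predicates = {
                    "RT": M <= 0.001,
                    "AT": m >= 0.01,
                    "MT": m > 0.001 and M < 0.01,
                    "CRT": m <= 0.001 < M < 0.01,
                    "CAT": 0.001 < m < 0.01 <= M,
                    "CRAT": m <= 0.001 and M >= 0.01,
                }
                holding = [c for c, ok in predicates.items() if ok]
                assert len(holding) == 1, (m, M, holding)
                assert classify_min_max(m, M, 0.001, 0.01) == holding[0]

    def test_boundaries_are_closed_as_worded(self):
        # "<= 0.1%" and ">= 1%" are closed bounds
        assert classify_min_max(0.001, 0.001, 0.001, 0.01) == "RT"
        assert classify_min_max(0.01, 0.02, 0.001, 0.01) == "AT"
        assert classify_min_max(0.001, 0.01, 0.001, 0.01) == "CRAT"

    def test_invariant_to_sample_and_feature_order(self, community):
        rel = mk.to_relative_abundance(community[0])
        res = mk.classify_abundance(rel)
        shuffled = RelAbundanceTable(
            rel.data.iloc[::-1, ::-1]
        )
        res2 = mk.classify_abundance(shuffled)
        assert res.classes.sort_index().equals(res2.classes.sort_index())

    def test_every_feature_classified_once(self, community):
        rel = mk.to_relative_abundance(community[0])
        res = mk.classify_abundance(rel)
        assert len(res.classes) == len(rel.feature_ids)
        assert res.classes.isin(ABUNDANCE_CLASSES).all()
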