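"""PI_HAT relatedness, unrelated-set selection, ROH and F_ROH."""

import numpy as np
import pandas as pd
import pytest

import popgenkit as pk
from popgenkit.panel import MISSING
from popgenkit.relatedness import KinshipMatrix

from conftest import make_panel


@pytest.fixture(scope="module")
def family_panel():
    """Panel with planted parent-offspring pair and full sibs."""
    model = pk.DemographicModel(
        demes=[pk.Deme("A", 150)],
        generations=4,
        # several chromosomes keep realized sib sharing close to its 0.5 mean
        chromosomes=[pk.Chromosome(str(c), 100.0, 900) for c in range(1, 7)],
    )
    panel, _ = pk.simulate_panel(model, 14, seed=31)
    planted, truth = pk.plant_fixtures(
        panel,
        [
            {"kind": "parent_offspring", "parent": "A_0", "other_parent": "A_1",
             "child": "A_2"},
            {"kind": "full_sibs", "parent1": "A_3", "parent2": "A_4",
             "child1": "A_5", "child2": "A_6"},
        ],
        seed=32,
    )
    return planted, truth


class TestPairwisePiHat:
    def test_parent_offspring_near_half(self, family_panel):
        panel, _ = family_panel
        kin = pk.pairwise_pi_hat(panel, warn_unpruned=False)
        assert 0.4 <= kin.pi_hat("A_0", "A_2") <= 0.6

    def test_full_sibs_near_half(self, family_panel):
        panel, _ = family_panel
        kin = pk.pairwise_pi_hat(panel, warn_unpruned=False)
        assert 0.35 <= kin.pi_hat("A_5", "A_6") <= 0.65

    def test_self_pair_is_one(self, family_panel):
        panel, _ = family_panel
        kin = pk.pairwise_pi_hat(panel, warn_unpruned=False)
        assert kin.pi_hat("A_7", "A_7") == 1.0

    def test_independent_demes_near_zero(self):
        model = pk.DemographicModel(
            demes=[pk.Deme("X", 200, bn_f=0.05), pk.Deme("Y", 200, bn_f=0.05)],
            generations=2,
            chromosomes=[pk.Chromosome("1", 100.0, 2000)],
        )
        panel, _ = pk.simulate_panel(model, 8, seed=33)
        kin = pk.pairwise_pi_hat(panel, warn_unpruned=False)
        t = kin.table
        cross = t[
            t["id1"].str.startswith("X") != t["id2"].str.startswith("X")
        ]
        assert cross["pi_hat"].mean() < 0.05

    def test_too_few_snps_rejected(self):
        g = np.random.default_rng(0).integers(0, 3, (4, 30)).astype(np.int8)
        with pytest.raises(ValueError, match="50"):
            pk.pairwise_pi_hat(make_panel(g), warn_unpruned=False)


def kinship_from_pairs(ids, related_pairs):
    rows = []
    rel = {tuple(sorted(p)) for p in related_pairs}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            pi = 0.5 if tuple(sorted((a, b))) in rel else 0.0
            rows.append((*sorted((a, b)), 0.5, 0.0, 0.5 * (pi > 0), pi))
    return KinshipMatrix(
        list(ids),
        pd.DataFrame(
            rows, columns=["id1", "id2", "p_ibd0", "p_ibd1", "p_ibd2", "pi_hat"]
        ),
    )


class TestMaxUnrelatedSet:
    def test_triangle_keeps_one(self):
        kin = kinship_from_pairs(
            ["a", "b", "c"], [("a", "b"), ("b", "c"), ("a", "c")]
        )
        subset, mode = pk.max_unrelated_set(kin)
        assert len(subset) == 1 and mode == "exact"

    def test_chain_keeps_endpoints(self):
        # exhaustive check over all 8 subsets says {a, c} is the unique max
        kin = kinship_from_pairs(["a", "b", "c"], [("a", "b"), ("b", "c")])
        subset, _ = pk.max_unrelated_set(kin)
        assert subset == ["a", "c"]

    def test_no_related_pairs_keeps_all(self):
        kin = kinship_from_pairs(["a", "b", "c", "d"], [])
        subset, _ = pk.max_unrelated_set(kin)
        assert subset == ["a", "b", "c", "d"]

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(34)
        ids = [f"s{i}" for i in range(9)]
        for _ in range(10):
            pairs = [
                (ids[i], ids[j])
                for i in range(9)
                for j in range(i + 1, 9)
                if rng.random() < 0.3
            ]
            kin = kinship_from_pairs(ids, pairs)
            subset, _ = pk.max_unrelated_set(kin)
            # brute force over all 2^9 subsets
            best = 0
            rel = {tuple(sorted(p)) for p in pairs}
            for mask in range(2**9):
                chosen = [ids[k] for k in range(9) if mask >> k & 1]
                ok = all(
                    tuple(sorted((a, b))) not in rel
                    for i, a in enumerate(chosen)
                    for b in chosen[i + 1 :]
                )
                if ok:
                    best = max(best, len(chosen))
            assert len(subset) == best

    def test_removes_all_first_degree_pairs(self, family_panel):
        panel, _ = family_panel
        kin = pk.pairwise_pi_hat(panel, warn_unpruned=False)
        subset, _ = pk.max_unrelated_set(kin, threshold=0.375)
        for r in kin.table.itertuples(index=False):
            if r.pi_hat > 0.375:
                assert not (r.id1 in subset and r.id2 in subset)


def roh_test_panel(n_snps=3000, spacing_bp=3_000, seed=40):
    """Evenly spaced SNPs (no >100 kb gaps); all-heterozygous background so
    planted homozygous runs have unambiguous boundaries."""
    rng = np.random.default_rng(seed)
    h0 = rng.integers(0, 2, (2, n_snps)).astype(np.int8)
    hap = np.empty((4, n_snps), dtype=np.int8)
    hap[0::2] = h0
    hap[1::2] = 1 - h0
    geno = hap[0::2] + hap[1::2]
    pos = np.arange(n_snps, dtype=np.int64) * spacing_bp + 1
    cm = pos / 1e6
    return make_panel(geno, hap, cm=cm, pos=pos, populations=["P", "P"])


class TestCallRoh:
    def test_planted_600kb_run_recovered(self):
        panel = roh_test_panel()
        # 600 kb = 0.6 cM at this map (3 kb SNP spacing, ~200 SNPs)
        planted, truth = pk.plant_fixtures(
            panel,
            [{"kind": "roh", "sample": "s0", "chrom": "1",
              "start_cm": 2.0, "end_cm": 2.6}],
            seed=41,
        )
        rohs = pk.call_roh(planted)
        mine = rohs.for_sample("s0")
        assert len(mine) == 1
        row, tr = mine.iloc[0], truth.roh.iloc[0]
        # boundary within one SNP spacing
        assert abs(row.start_bp - tr.start_bp) <= 3_000
        assert abs(row.end_bp - tr.end_bp) <= 3_000

    def test_planted_400kb_run_rejected(self):
        panel = roh_test_panel(seed=42)
        planted, _ = pk.plant_fixtures(
            panel,
            [{"kind": "roh", "sample": "s0", "chrom": "1",
              "start_cm": 2.0, "end_cm": 2.4}],
            seed=43,
        )
        rohs = pk.call_roh(planted)
        assert len(rohs.for_sample("s0")) == 0

    def test_two_hets_in_window_break_run(self):
        panel = roh_test_panel(seed=44)
        planted, _ = pk.plant_fixtures(
            panel,
            [{"kind": "roh", "sample": "s0", "chrom": "1",
              "start_cm": 2.0, "end_cm": 5.0}],
            seed=45,
        )
        g = planted.genotypes.copy()
        hap = planted.haplotypes.copy()
        mid = np.flatnonzero(
            (planted.snp_table["cm"] >= 3.495) & (planted.snp_table["cm"] <= 3.505)
        )
        sl = [mid[0], mid[0] + 1]  # two adjacent hets
        for k in sl:
            g[0, k] = 1
            hap[0, k], hap[1, k] = 0, 1
        broken = pk.GenotypePanel(g, planted.snp_table, planted.sample_table, hap)
        rohs = pk.call_roh(broken)
        mine = rohs.for_sample("s0")
        # the single 3 Mb run is split around the het pair
        assert len(mine) == 2
        assert mine["end_bp"].min() < 3.5e6 < mine["start_bp"].max()


class TestFroh:
    @staticmethod
    def table(rows):
        return pk.ROHSet(
            pd.DataFrame(
                rows,
                columns=["sample", "chrom", "start_bp", "end_bp", "n_snps", "length_bp"],
            )
        )

    def _panel(self):
        return roh_test_panel(seed=46)

    def test_no_roh_zero(self):
        ftab = pk.froh(self.table([]), 1_000_000, self._panel())
        assert (ftab.per_sample["froh"] == 0).all()

    def test_simple_arithmetic(self):
        rohs = self.table([("s0", "1", 1, 30_000_000, 100, 30_000_000)])
        ftab = pk.froh(rohs, 3_000_000_000, self._panel())
        assert ftab.per_sample.set_index("id").loc["s0", "froh"] == pytest.approx(0.01)

    def test_full_span_is_one(self):
        rohs = self.table([("s0", "1", 1, 10_000, 10, 10_000)])
        ftab = pk.froh(rohs, 10_000, self._panel())
        assert ftab.per_sample.set_index("id").loc["s0", "froh"] == 1.0

    def test_roh_exceeding_span_rejected(self):
        rohs = self.table([("s0", "1", 1, 2_000_000, 10, 2_000_000)])
        with pytest.raises(ValueError):
            pk.froh(rohs, 1_000_000, self._panel())


class TestFrohGeography:
    @staticmethod
    def froh_table(values):
        per_pop = pd.DataFrame(
            {
                "population": [f"p{i}" for i in range(len(values))],
                "mean_froh": values,
                "n": 5,
            }
        )
        per_sample = pd.DataFrame(columns=["id", "population", "froh"])
        return pk.FrohTable(per_sample, per_pop)

    def test_monotone_increase_gives_perfect_spearman(self):
        ftab = self.froh_table([0.01, 0.02, 0.04, 0.08, 0.1])
        coords = pd.DataFrame(
            {"population": [f"p{i}" for i in range(5)],
             "lat": 0.0, "lon": [-70, -65, -60, -55, -50]}
        )
        res = pk.froh_geography(ftab, coords)
        assert res.spearman_r == pytest.approx(1.0)

    def test_wilcoxon_between_regions(self):
        vals = [0.01, 0.012, 0.011, 0.09, 0.095, 0.1]
        ftab = self.froh_table(vals)
        coords = pd.DataFrame(
            {"population": [f"p{i}" for i in range(6)],
             "lat": 0.0, "lon": np.arange(6.0)}
        )
        regions = pd.Series(
            {f"p{i}": ("west" if i < 3 else "east") for i in range(6)}
        )
        res = pk.froh_geography(ftab, coords, region_labels=regions)
        assert res.wilcoxon_p < 0.15  # exact p floor for 3v3 is 0.1

    def test_constant_froh_rejected(self):
        ftab = self.froh_table([0.05, 0.05, 0.05])
        coords = pd.DataFrame(
            {"population": ["p0", "p1", "p2"], "lat": 0.0, "lon": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ValueError):
            pk.froh_geography(ftab, coords)
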