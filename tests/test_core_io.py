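"""Panel data model, format round-trips, QC filtering and LD pruning."""

import numpy as np
import pandas as pd
import pytest

import popgenkit as pk
from popgenkit.panel import MISSING, PanelError
from popgenkit.qc import hwe_exact_midp

from conftest import make_panel


class TestGeneticMap:
    def setup_method(self):
        self.gmap = pk.GeneticMap({"1": [(0, 0.0), (1_000_000, 1.0)]})

    def test_linear_interpolation(self):
        assert pk.interpolate_cm(self.gmap, "1", 500_000) == pytest.approx(0.5)

    def test_query_at_anchor(self):
        assert pk.interpolate_cm(self.gmap, "1", 1_000_000) == pytest.approx(1.0)

    def test_constant_extrapolation_past_last_anchor(self):
        assert pk.interpolate_cm(self.gmap, "1", 2_000_000) == pytest.approx(1.0)

    def test_unknown_chromosome(self):
        with pytest.raises(KeyError):
            pk.interpolate_cm(self.gmap, "7", 100)

    def test_decreasing_anchors_rejected(self):
        with pytest.raises(PanelError):
            pk.GeneticMap({"1": [(100, 1.0), (50, 2.0)]})


class TestPanelInvariants:
    def test_bad_genotype_value_rejected(self):
        with pytest.raises(PanelError):
            make_panel(np.array([[0, 3]], dtype=np.int8))

    def test_haplotype_sum_mismatch_rejected(self):
        hap = np.array([[1, 1], [1, 1]], dtype=np.int8)
        with pytest.raises(PanelError):
            make_panel(np.array([[1, 2]]), haplotypes=hap)

    def test_phased_vcf_pair_sums(self, tmp_path, two_deme_panel):
        panel, _ = two_deme_panel
        sub = panel.take_samples([0, 1, 2]).take_snps(np.arange(5))
        path = str(tmp_path / "t.vcf")
        pk.write_panel(sub, path, "vcf")
        back = pk.read_panel(path, "vcf")
        assert back.phased
        sums = back.haplotypes[0::2] + back.haplotypes[1::2]
        assert np.array_equal(sums, back.genotypes)


@pytest.mark.parametrize("fmt", ["vcf", "plink_text", "eigenstrat_text"])
def test_round_trip_lossless(fmt, tmp_path, two_deme_panel):
    panel, _ = two_deme_panel
    sub = panel.take_samples([0, 1, 2]).take_snps(np.arange(50))
    # inject missingness to exercise the sentinel in every dialect
    g = sub.genotypes.copy()
    g[0, 3] = MISSING
    sub = pk.GenotypePanel(g, sub.snp_table, sub.sample_table, None)
    path = str(tmp_path / ("t" if fmt != "vcf" else "t.vcf"))
    pk.write_panel(sub, path, fmt)
    back = pk.read_panel(path, fmt)
    assert np.array_equal(back.genotypes, sub.genotypes)
    assert list(back.sample_ids) == list(sub.sample_ids)
    assert np.array_equal(
        back.snp_table["pos"].to_numpy(), sub.snp_table["pos"].to_numpy()
    )


def test_vcf_shape_from_handwritten_file(tmp_path):
    text = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc\n"
        + "".join(
            f"1\t{1000 * (k + 1)}\tv{k}\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1\t0|0\n"
            for k in range(5)
        )
    )
    path = tmp_path / "hand.vcf"
    path.write_text(text)
    panel = pk.read_panel(str(path), "vcf")
    assert panel.genotypes.shape == (3, 5)
    assert panel.phased
    assert np.array_equal(panel.genotypes[:, 0], [1, 2, 0])


def test_metadata_attach(tmp_path, two_deme_panel):
    panel, _ = two_deme_panel
    meta = pd.DataFrame(
        {"id": panel.sample_ids, "lat": -10.0, "lon": -60.0, "region": "west"}
    )
    mpath = tmp_path / "meta.tsv"
    meta.to_csv(mpath, sep="\t", index=False)
    joined = pk.attach_metadata(panel, pk.read_metadata(str(mpath)))
    assert "region" in joined.sample_table


class TestHweExactMidp:
    @staticmethod
    def brute_force_midp(n_het, n_ref, n_alt):
        """Enumerate the conditional het distribution directly."""
        from math import comb, factorial

        n = n_het + n_ref + n_alt
        rare = 2 * min(n_ref, n_alt) + n_het
        common = 2 * n - rare
        probs = {}
        for h in range(rare % 2, rare + 1, 2):
            r_hom = (rare - h) // 2
            c_hom = n - r_hom - h
            if c_hom < 0:
                continue
            probs[h] = (
                factorial(n)
                / (factorial(r_hom) * factorial(c_hom) * factorial(h))
                * 2**h
            )
        z = sum(probs.values())
        p_obs = probs[n_het] / z
        p = sum(v / z for v in probs.values() if v / z <= p_obs * (1 + 1e-12))
        return p - 0.5 * p_obs

    @pytest.mark.parametrize(
        "het,ref,alt", [(5, 10, 5), (0, 18, 2), (10, 5, 5), (3, 3, 3), (2, 16, 0)]
    )
    def test_matches_enumeration(self, het, ref, alt):
        assert hwe_exact_midp(het, ref, alt) == pytest.approx(
            self.brute_force_midp(het, ref, alt), rel=1e-9
        )

    def test_monomorphic_is_one(self):
        assert hwe_exact_midp(0, 20, 0) == 1.0


class TestQcFilter:
    def _panel_with_missing(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, (50, 40)).astype(np.int8)
        g[:3, 0] = MISSING  # snp 0: 6% missing
        return make_panel(g)

    def test_snp_above_missing_threshold_removed(self):
        out, report = pk.qc_filter(self._panel_with_missing(), snp_missing_max=0.05)
        assert report.snps_removed_missing == 1
        assert "snp0" not in set(out.snp_table["id"])

    def test_rare_snp_retained_but_counted(self):
        g = np.zeros((100, 10), dtype=np.int8)
        g[0, 0] = 1  # MAF 0.5% at snp 0
        g[:, 1:] = np.random.default_rng(2).integers(0, 3, (100, 9))
        out, report = pk.qc_filter(make_panel(g), maf_rare_threshold=0.01)
        assert out.n_snps == 10
        assert report.rare_allele_fraction == pytest.approx(0.1)

    def test_monomorphic_snp_survives_hwe(self):
        g = np.ones((30, 5), dtype=np.int8)
        g[:, 0] = 0  # monomorphic
        out, _ = pk.qc_filter(make_panel(g), hwe_p_min=1e-8)
        assert "snp0" in set(out.snp_table["id"])

    def test_idempotent(self):
        p1, _ = pk.qc_filter(self._panel_with_missing())
        p2, r2 = pk.qc_filter(p1)
        assert np.array_equal(p1.genotypes, p2.genotypes)
        assert r2.snps_removed_missing == 0

    def test_arm_trim(self):
        g = np.random.default_rng(3).integers(0, 3, (20, 40)).astype(np.int8)
        panel = make_panel(g)
        last = int(panel.snp_table["pos"].max())
        out, report = pk.qc_filter(
            panel, arm_trim_bp=100_000, arm_table={"1": [(1, last)]}
        )
        assert report.snps_removed_arm_trim > 0
        assert out.snp_table["pos"].min() >= 100_000

    def test_empty_after_filter_errors(self):
        g = np.full((4, 3), MISSING, dtype=np.int8)
        g[0] = 1
        with pytest.raises(PanelError):
            pk.qc_filter(make_panel(g), snp_missing_max=0.0)


class TestLdPrune:
    def test_duplicated_column_drops_one(self):
        rng = np.random.default_rng(4)
        g = rng.integers(0, 3, (200, 20)).astype(np.int8)
        g[:, 11] = g[:, 10]
        panel = make_panel(g, cm=np.arange(20) * 0.002)
        out = pk.ld_prune(panel)
        kept = set(out.snp_table["id"])
        assert ("snp10" in kept) != ("snp11" in kept) or len(kept) == 19
        assert out.n_snps == 19

    def test_independent_sites_mostly_retained(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.1, 0.9, 300)
        g = (rng.random((200, 300, 2)) < p[None, :, None]).sum(-1).astype(np.int8)
        panel = make_panel(g, cm=np.arange(300) * 0.005)
        out = pk.ld_prune(panel)
        assert out.n_snps >= 0.95 * 300

    def test_distant_duplicates_both_survive(self):
        rng = np.random.default_rng(6)
        g = rng.integers(0, 3, (100, 2)).astype(np.int8)
        g[:, 1] = g[:, 0]  # r^2 = 1 but 60 kb apart
        panel = make_panel(g, pos=np.array([1, 60_001]), cm=np.array([0.0, 0.06]))
        out = pk.ld_prune(panel, window_bp=50_000)
        assert out.n_snps == 2

    def test_no_residual_high_ld_within_window(self):
        rng = np.random.default_rng(7)
        base = rng.integers(0, 3, (150, 10)).astype(np.int8)
        g = np.repeat(base, 3, axis=1)  # triples of identical columns
        panel = make_panel(g, cm=np.arange(30) * 0.001)
        out = pk.ld_prune(panel)
        x = out.genotypes.astype(float)
        r2 = np.corrcoef(x.T) ** 2
        iu = np.triu_indices(out.n_snps, 1)
        assert np.nanmax(r2[iu]) <= 0.2 + 1e-9
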