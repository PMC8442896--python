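import numpy as np
import pandas as pd
import pytest

import sexlinkage as sl
from sexlinkage.differentiation_haplotype import (
    differentiation_regions,
    extract_sex_haplotypes,
    haplotype_nj_tree,
    species_proportion,
)
from sexlinkage.io_prep import SexlinkageError
from sexlinkage.wgs_sexscan import CXY, SiteClassTable, classify_sites

from conftest import balanced_newick, make_variant_table


def sct_single_species(positions, lg="LG01", cls=CXY):
    sites = pd.DataFrame({"lg": lg, "pos": positions})
    sites["row"] = np.arange(len(positions))
    classes = np.full((len(positions), 1), cls, dtype=np.int8)
    return SiteClassTable(sites, ["sp1"], classes)


def xy_call(lgs={"LG01"}):
    return sl.SpeciesCall("sp1", frozenset(lgs), "XY", frozenset({"A2"}))


class TestDifferentiationRegions:
    def test_uniform_density_gives_zero_proportion(self):
        # one SNP per 10-kb window everywhere: no window beats 2x the mean
        lgs = sl.default_lg_table(2, 100_000)
        positions = list(range(5_000, 100_001, 10_000))
        sct = sct_single_species(positions)
        regions = differentiation_regions(sct, xy_call(), lgs)
        # mean = 10 SNPs / 20 windows = 0.5; threshold 1.0; all counts are 1
        assert all(r.proportion_of_lg == 0.0 for r in regions) or all(
            r.cumulative_bp < 100_000 for r in regions
        )

    def test_single_heavy_window_qualifies(self):
        lgs = sl.default_lg_table(1, 10_000_000)  # 1000 windows
        positions = [50_001 + i for i in range(50)]  # 50 SNPs in one window
        sct = sct_single_species(positions)
        regions = differentiation_regions(sct, xy_call(), lgs)
        r = regions[0]
        # mean = 0.05/window, threshold 0.1: the heavy window qualifies alone
        assert r.cumulative_bp == 10_000
        assert (r.range_start, r.range_end) == (50_001, 60_000)
        assert r.proportion_of_lg == pytest.approx(0.001)

    def test_planted_region_proportion_recovered(self, panel10, lgs5):
        truth = sl.SimTruth(
            species={"sp01": sl.SpeciesTruth("LG01", "XY", (400_001, 1_000_000), 1.0)}
        )
        vt, _ = sl.simulate_wgs_cohort(panel10, lgs5, truth, 2000, seed=21)
        sct = classify_sites(vt, panel10)
        call = sl.SpeciesCall("sp01", frozenset({"LG01"}), "XY", frozenset({"A2"}))
        regions = differentiation_regions(sct, call, lgs5)
        prop = species_proportion(regions, lgs5)
        assert prop == pytest.approx(0.30, abs=0.05)

    def test_zero_mean_yields_no_windows(self):
        lgs = sl.default_lg_table(1, 100_000)
        sct = sct_single_species([5_000], cls=0)  # nosex only
        r = differentiation_regions(sct, xy_call(), lgs)[0]
        assert r.cumulative_bp == 0 and r.proportion_of_lg == 0.0

    def test_monotone_in_added_snps(self):
        """Adding sex-specific SNPs to a qualifying window keeps it qualified."""
        lgs = sl.default_lg_table(1, 1_000_000)
        base = [50_001 + i for i in range(30)]
        r1 = differentiation_regions(sct_single_species(base), xy_call(), lgs)[0]
        r2 = differentiation_regions(
            sct_single_species(base + [50_500, 50_600]), xy_call(), lgs
        )[0]
        assert r2.cumulative_bp >= r1.cumulative_bp


class TestAgeDifferentiationPgls:
    def test_exact_linear_recovery(self):
        tt = sl.timetree_from_string(balanced_newick(8, 10.0))
        labels = tt.tip_labels
        ages = {t: float(i + 1) for i, t in enumerate(labels)}
        props = {t: 0.05 * ages[t] for t in labels}
        fit = sl.age_differentiation_pgls(props, ages, tt)
        assert fit.coefficient == pytest.approx(0.05, abs=1e-6)

    def test_requires_three_species(self):
        tt = sl.timetree_from_string("(A:1,B:1,C:1);")
        with pytest.raises(SexlinkageError, match="3"):
            sl.age_differentiation_pgls({"A": 0.1, "B": 0.2}, {"A": 1, "B": 2}, tt)


class TestHaplotypes:
    def panel(self):
        rows = [
            ("sp1_m", "sp1", "T", "male"), ("sp1_f", "sp1", "T", "female"),
            ("sp2_m", "sp2", "T", "male"), ("sp2_f", "sp2", "T", "female"),
        ]
        return sl.SamplePanel(
            pd.DataFrame(rows, columns=["individual_id", "species_id", "tribe_id", "sex"])
        )

    def test_x_is_allele_shared_with_female(self):
        vt = make_variant_table(
            [("LG19", 100, "A", "G", [(0, 1), (0, 0), (0, 0), (0, 0)])],
            ["sp1_m", "sp1_f", "sp2_m", "sp2_f"],
        )
        hs = extract_sex_haplotypes(vt, self.panel(), ["sp1"])
        assert hs.sequences["sp1_m_X"] == "A"
        assert hs.sequences["sp1_m_Y"] == "G"

    def test_homozygous_male_site_uninformative(self):
        # site 200 is XY in focal sp2; focal sp1's male is homozygous there
        vt = make_variant_table(
            [
                ("LG19", 100, "A", "G", [(0, 1), (0, 0), (0, 0), (0, 0)]),
                ("LG19", 200, "C", "T", [(1, 1), (1, 1), (0, 1), (0, 0)]),
            ],
            ["sp1_m", "sp1_f", "sp2_m", "sp2_f"],
        )
        hs = extract_sex_haplotypes(vt, self.panel(), ["sp1", "sp2"])
        assert hs.sequences["sp1_m_X"][1] == "T"
        assert hs.sequences["sp1_m_Y"][1] == "T"

    def test_involution_swapping_male_allele_order(self):
        gts = [(1, 0), (0, 0), (0, 0), (0, 0)]  # male alleles given as G/A
        vt = make_variant_table(
            [("LG19", 100, "A", "G", [gts[0], gts[1], gts[2], gts[3]])],
            ["sp1_m", "sp1_f", "sp2_m", "sp2_f"],
        )
        hs = extract_sex_haplotypes(vt, self.panel(), ["sp1"])
        assert hs.sequences["sp1_m_X"] == "A" and hs.sequences["sp1_m_Y"] == "G"

    def test_high_missingness_site_excluded(self):
        recs = [
            ("LG19", 100, "A", "G", [(0, 1), (0, 0), (0, 0), (0, 0)]),
            ("LG19", 200, "A", "G", [(0, 1), (0, 0), None, (0, 0)]),  # 25% missing
        ]
        vt = make_variant_table(recs, ["sp1_m", "sp1_f", "sp2_m", "sp2_f"])
        hs = extract_sex_haplotypes(vt, self.panel(), ["sp1"], max_missing=0.10)
        assert hs.site_index["pos"].tolist() == [100]

    def test_focal_species_without_xy_sites_excluded(self):
        vt = make_variant_table(
            [("LG19", 100, "A", "G", [(0, 1), (0, 0), (0, 0), (0, 0)])],
            ["sp1_m", "sp1_f", "sp2_m", "sp2_f"],
        )
        with pytest.warns(UserWarning, match="no XY sites"):
            hs = extract_sex_haplotypes(vt, self.panel(), ["sp1", "sp2"])
        assert "sp2_m_h1" in hs.sequences  # sp2 demoted to unphased contributor


class TestNjTree:
    def test_additive_distances_recover_topology(self):
        # ((A,B),(C,D)) with distinct Hamming distances by construction
        seqs = {
            "A": "AAAAAAAAAA" + "AAAA",
            "B": "AAAAAAAAAA" + "GGAA",
            "C": "GGGGGAAAAA" + "AAGG",
            "D": "GGGGGAAAAA" + "GGGG",
        }
        import dendropy

        nwk = haplotype_nj_tree(seqs)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        d_ab = pdm.distance(taxa["A"], taxa["B"])
        d_ac = pdm.distance(taxa["A"], taxa["C"])
        assert d_ab == pytest.approx(2 / 14, abs=1e-9)
        assert d_ac > d_ab

    def test_identical_sequences_zero_branches(self):
        seqs = {"A": "AAAA", "B": "AAAA", "C": "AAAA"}
        nwk = haplotype_nj_tree(seqs)
        assert ":0" in nwk.replace(":0.0", ":0")

    def test_unequal_lengths_rejected(self):
        with pytest.raises(SexlinkageError, match="equal length"):
            haplotype_nj_tree({"A": "AA", "B": "AAA", "C": "AA"})

    def test_convergent_y_haplotypes_group_within_clades(self, lgs5):
        """Two tribes with independent XY systems on the same LG: Y haplotypes
        cluster with their own clade, not with the other tribe's Y."""
        rows = []
        for tribe, sps in (("T1", ["a1", "a2"]), ("T2", ["b1", "b2"])):
            for sp in sps:
                rows.append((f"{sp}_m", sp, tribe, "male"))
                rows.append((f"{sp}_f", sp, tribe, "female"))
        panel = sl.SamplePanel(
            pd.DataFrame(rows, columns=["individual_id", "species_id", "tribe_id", "sex"])
        )
        grouped = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n_sites = 400
            # clade-specific background divergence + independent Y alleles
            recs = []
            a0 = np.zeros((n_sites, 8), dtype=np.int8)
            a1 = np.zeros((n_sites, 8), dtype=np.int8)
            for i in range(n_sites):
                clade_allele = rng.integers(0, 2)
                for j in range(8):
                    in_t2 = j >= 4
                    base = clade_allele if in_t2 else 1 - clade_allele
                    a0[i, j] = a1[i, j] = base if rng.random() < 0.4 else 0
            # independent sex-specific sites per tribe: male het at disjoint sites
            t1_sites = rng.choice(n_sites, 60, replace=False)
            rest = np.setdiff1d(np.arange(n_sites), t1_sites)
            t2_sites = rng.choice(rest, 60, replace=False)
            for s in t1_sites:
                for j in (0, 2):  # a1_m, a2_m columns
                    a0[s, j] = 0
                    a1[s, j] = 1
                for j in (1, 3):
                    a0[s, j] = a1[s, j] = 0
            for s in t2_sites:
                for j in (4, 6):
                    a0[s, j] = 0
                    a1[s, j] = 1
                for j in (5, 7):
                    a0[s, j] = a1[s, j] = 0
            sites = pd.DataFrame(
                {"lg": "LG19", "pos": np.arange(1, n_sites + 1) * 100,
                 "ref": "A", "alt": "G", "is_indel": False, "indel_size": 0}
            )
            inds = ["a1_m", "a1_f", "a2_m", "a2_f", "b1_m", "b1_f", "b2_m", "b2_f"]
            vt = sl.VariantTable(
                sites, a0, a1,
                np.full(a0.shape, 99, np.int16), np.full(a0.shape, 20, np.int16),
                inds,
            )
            hs = extract_sex_haplotypes(vt, panel, ["a1", "a2", "b1", "b2"], seed=seed)
            import dendropy

            tree = dendropy.Tree.get(data=haplotype_nj_tree(hs.sequences),
                                     schema="newick")
            pdm = tree.phylogenetic_distance_matrix()
            taxa = {t.label: t for t in tree.taxon_namespace}

            def d(x, y):
                return pdm.path_edge_count(taxa[x], taxa[y])

            within = d("a1_m_Y", "a2_m_Y") + d("b1_m_Y", "b2_m_Y")
            across = d("a1_m_Y", "b1_m_Y") + d("a2_m_Y", "b2_m_Y")
            grouped += within < across
        assert grouped >= 18  # >=90% of seeds
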