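import numpy as np
import pandas as pd
import pytest
from scipy import stats

from leafqtl import linkage_map as lm
from leafqtl import qtl_scan as qs
from leafqtl import synthetic_data as synth


class TestGenotypeProbabilities:
    def test_mass_one_at_observed_markers(self, cross94, probs94):
        coded = {m: cross94.genotypes.f1_genotypes[m].to_numpy()
                 for m in cross94.genotypes.marker_names}
        for gid, gp in probs94.groups.items():
            for j, m in enumerate(gp.marker_names):
                k = int(np.argmin(np.abs(gp.positions_cM
                                         - gp.marker_positions[j])))
                expect = np.where(coded[m] == "H", 1.0, 0.0)
                assert np.allclose(gp.prob_h[:, k], expect)

    def test_midpoint_of_20cM_interval_both_flanks_A(self):
        # enumerate the two-interval recombination classes by hand:
        # r_half = 0.0906 each side -> P(A|A,A) = 0.990
        par = pd.DataFrame([["H", "H"], ["A", "A"]], index=["P1", "P2"],
                           columns=["a", "b"])
        f1 = pd.DataFrame([["A", "A"]] * 30,
                          index=[f"x{i}" for i in range(30)],
                          columns=["a", "b"])
        g = synth.MarkerGenotypes(parent_genotypes=par, f1_genotypes=f1)
        group = lm.LinkageGroup(parent_of_origin="P1", markers=["a", "b"],
                                adjacent_rf=[lm.distance_to_rf(20.0)],
                                positions_cM=[0.0, 20.0])
        gmap = lm.GeneticMap(groups=[group])
        probs = qs.genotype_probabilities(gmap, g, step_cM=2.0)
        gp = probs.groups["1.P1"]
        k = int(np.argmin(np.abs(gp.positions_cM - 10.0)))
        assert 1 - gp.prob_h[0, k] == pytest.approx(0.9901639988223626,
                                                    abs=1e-9)

    def test_all_missing_individual_gets_flat_half(self):
        par = pd.DataFrame([["H", "H"], ["A", "A"]], index=["P1", "P2"],
                           columns=["a", "b"])
        rows = ([["A", "A"]] * 15 + [["H", "H"]] * 14 + [["-", "-"]])
        f1 = pd.DataFrame(rows, index=[f"x{i}" for i in range(30)],
                          columns=["a", "b"])
        g = synth.MarkerGenotypes(parent_genotypes=par, f1_genotypes=f1)
        gmap = lm.build_maps(g)
        with pytest.warns(RuntimeWarning, match="untyped"):
            probs = qs.genotype_probabilities(gmap, g)
        for gp in probs.groups.values():
            assert np.all(gp.prob_h[-1] == 0.5)

    def test_probabilities_bounded(self, probs94):
        for gp in probs94.groups.values():
            assert gp.prob_h.min() >= 0.0 and gp.prob_h.max() <= 1.0

    def test_grid_step_and_marker_positions_included(self, probs94):
        for gp in probs94.groups.values():
            diffs = np.diff(gp.positions_cM)
            assert diffs.max() <= 2.0 + 1e-9
            assert set(np.round(gp.marker_positions, 6)) <= \
                set(np.round(gp.positions_cM, 6))


def _trait(cross, qtl, h2=0.4, seed=0):
    return synth.plant_qtl_effects(cross, [qtl], h2=h2, seed=seed)


class TestHkScan:
    def test_constant_trait_gives_zero_lod(self, probs94):
        scan = qs.hk_scan(probs94, np.ones(94))
        assert scan.max_lod == 0.0
        assert (scan.table["lod"] == 0.0).all()

    def test_marker_lod_equals_single_marker_regression(self, cross94,
                                                        probs94, rng):
        # algebraic identity at a fully observed marker:
        # LOD = -(n/2) log10(1 - R^2) of y on the 0/1 genotype
        y = rng.normal(size=94)
        scan = qs.hk_scan(probs94, y)
        for gid, gp in probs94.groups.items():
            for j in (0, len(gp.marker_names) - 1):
                x = gp.marker_coded[:, j]
                r = stats.pearsonr(x, y)[0]
                expect = -(94 / 2) * np.log10(1 - r**2)
                k = gp.marker_positions[j]
                got = scan.table[(scan.table.group == gid)
                                 & (np.isclose(scan.table.position_cM, k))
                                 ]["lod"].iloc[0]
                assert got == pytest.approx(expect, abs=1e-10)

    def test_lod_invariant_to_affine_trait_transform(self, cross94, probs94):
        q = synth.QTL("P1", 0, 30.0, 1.0)
        y = _trait(cross94, q)
        a = qs.hk_scan(probs94, y)
        b = qs.hk_scan(probs94, -3.2 * y + 7.0)
        assert np.allclose(a.table["lod"], b.table["lod"], atol=1e-10)

    def test_peak_on_true_group(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cross = synth.simulate_pseudo_testcross(n_f1=94, seed=300 + seed)
            gmap = lm.build_maps(cross.genotypes)
            probs = qs.genotype_probabilities(gmap, cross.genotypes)
            q = synth.QTL("P2", 0, 30.0, 1.0)
            y = _trait(cross, q, h2=0.2, seed=seed)  # effect ~1 SD of noise
            scan = qs.hk_scan(probs, y)
            peak = scan.table.loc[scan.table["lod"].idxmax()]
            marker = cross.nearest_marker(q)
            true_gid = [gid for gid, gp in probs.groups.items()
                        if marker in gp.marker_names]
            hits += peak["group"] in true_gid
        assert hits / n_seeds >= 0.9

    def test_peak_position_recovery(self):
        # planted QTL at a known cM: median |peak - truth| small
        errs = []
        for seed in range(15):
            cross = synth.simulate_pseudo_testcross(n_f1=94, seed=500 + seed)
            gmap = lm.build_maps(cross.genotypes)
            probs = qs.genotype_probabilities(gmap, cross.genotypes)
            q = synth.QTL("P1", 1, 30.0, 1.0)
            y = _trait(cross, q, h2=0.3, seed=seed)
            scan = qs.hk_scan(probs, y)
            marker = cross.nearest_marker(q)
            gid, gp = next((gid, gp) for gid, gp in probs.groups.items()
                           if marker in gp.marker_names)
            sub = scan.table[scan.table.group == gid]
            peak_pos = sub.loc[sub["lod"].idxmax(), "position_cM"]
            j = gp.marker_names.index(marker)
            errs.append(abs(peak_pos - gp.marker_positions[j]))
        assert np.median(errs) <= 10.0


class TestCimScan:
    def test_zero_cofactors_reduces_to_hk(self, cross94, probs94):
        y = _trait(cross94, synth.QTL("P1", 0, 20.0, 1.0))
        a = qs.hk_scan(probs94, y)
        b = qs.cim_scan(probs94, y, n_cofactors=0)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_cofactor_dropped_inside_window(self, cross94, probs94):
        y = _trait(cross94, synth.QTL("P2", 1, 30.0, 2.0), h2=0.8)
        scan = qs.cim_scan(probs94, y, window_cM=30.0, n_cofactors=3)
        assert scan.cofactors  # something was selected
        # at the cofactor's own position its LOD must reflect the cofactor
        # being excluded: the scan there cannot be degenerate (LOD > 0)
        cof = scan.cofactors[0]
        gid, gp = next((gid, gp) for gid, gp in probs94.groups.items()
                       if cof in gp.marker_names)
        pos = gp.marker_positions[gp.marker_names.index(cof)]
        lod = scan.table[(scan.table.group == gid)
                         & np.isclose(scan.table.position_cM, pos)]["lod"]
        assert lod.iloc[0] > 0

    def test_cim_sharpens_two_qtl_separation(self):
        # with two QTLs on different groups, conditioning on cofactors
        # reduces residual variance, so CIM peaks at the true QTLs should
        # usually be at least the plain HK peaks
        wins = 0
        n_seeds = 12
        for seed in range(n_seeds):
            cross = synth.simulate_pseudo_testcross(n_f1=94, seed=700 + seed)
            q1, q2 = synth.QTL("P1", 0, 30.0, 1.0), synth.QTL("P2", 2, 30.0, 1.0)
            y = synth.plant_qtl_effects(cross, [q1, q2], h2=0.5, seed=seed)
            gmap = lm.build_maps(cross.genotypes)
            probs = qs.genotype_probabilities(gmap, cross.genotypes)
            hk = qs.hk_scan(probs, y)
            cim = qs.cim_scan(probs, y)
            better = 0
            for q in (q1, q2):
                marker = cross.nearest_marker(q)
                gid = next(gid for gid, gp in probs.groups.items()
                           if marker in gp.marker_names)
                h = hk.table[hk.table.group == gid]["lod"].max()
                c = cim.table[cim.table.group == gid]["lod"].max()
                better += c >= h
            wins += better == 2
        assert wins / n_seeds >= 0.7


class TestPermutationThresholds:
    def test_same_seed_same_thresholds(self, probs94, rng):
        y = rng.normal(size=94)
        a = qs.permutation_thresholds(probs94, y, n=100, seed=42)
        b = qs.permutation_thresholds(probs94, y, n=100, seed=42)
        assert a.threshold_5 == b.threshold_5
        assert np.array_equal(a.null_max_lods, b.null_max_lods)

    def test_threshold_ordering(self, probs94, rng):
        y = rng.normal(size=94)
        t = qs.permutation_thresholds(probs94, y, n=120, seed=3)
        assert t.threshold_10 <= t.threshold_5

    def test_small_n_warns(self, probs94, rng):
        y = rng.normal(size=94)
        with pytest.warns(RuntimeWarning, match="permutations"):
            qs.permutation_thresholds(probs94, y, n=50, seed=1)

    def test_matrix_path_matches_scan_loop(self, probs94, rng):
        # the vectorised null distribution must equal re-running hk_scan on
        # each permuted trait one by one
        y = rng.normal(size=94)
        fast = qs.permutation_thresholds(probs94, y, n=100, seed=13)
        rng2 = np.random.default_rng(13)
        slow = np.array([qs.hk_scan(probs94, rng2.permutation(y)).max_lod
                         for _ in range(100)])
        assert np.allclose(fast.null_max_lods, slow, atol=1e-10)

    def test_thresholds_stable_under_doubling(self, probs94, rng):
        y = rng.normal(size=94)
        a = qs.permutation_thresholds(probs94, y, n=300, seed=9)
        b = qs.permutation_thresholds(probs94, y, n=600, seed=10)
        assert abs(a.threshold_5 - b.threshold_5) < 0.15


class TestSignificantQtls:
    @staticmethod
    def _thr(t5, t10):
        return qs.PermutationThresholds(
            n_permutations=100, null_max_lods=np.zeros(100), threshold_5=t5,
            threshold_10=t10, seed=0)

    def test_subthreshold_scan_is_empty(self, probs94, rng):
        scan = qs.hk_scan(probs94, rng.normal(size=94))
        out = qs.significant_qtls(scan, self._thr(99.0, 98.0))
        assert out.empty

    def test_single_peak_at_argmax(self, cross94, probs94):
        q = synth.QTL("P2", 0, 30.0, 2.0)
        y = _trait(cross94, q, h2=0.8)
        scan = qs.hk_scan(probs94, y)
        out = qs.significant_qtls(scan, self._thr(3.0, 2.5))
        marker = cross94.nearest_marker(q)
        gid = next(gid for gid, gp in probs94.groups.items()
                   if marker in gp.marker_names)
        top = out.loc[out["lod"].idxmax()]
        assert top["group"] == gid and top["level"] == "5%"
        assert top["lod"] == scan.table[scan.table.group == gid]["lod"].max()

    def test_marginal_label_between_thresholds(self, cross94, probs94):
        q = synth.QTL("P2", 0, 30.0, 2.0)
        y = _trait(cross94, q, h2=0.8)
        scan = qs.hk_scan(probs94, y)
        big = scan.max_lod
        out = qs.significant_qtls(scan, self._thr(big + 1, big - 0.5))
        assert (out["level"] == "10%").all()

    def test_two_planted_qtls_both_reported(self, cross94, probs94):
        q1, q2 = synth.QTL("P1", 0, 30.0, 1.0), synth.QTL("P2", 2, 30.0, 1.0)
        y = synth.plant_qtl_effects(cross94, [q1, q2], h2=0.7, seed=4)
        scan = qs.cim_scan(probs94, y)
        thr = qs.permutation_thresholds(probs94, y, n=200, seed=5,
                                        method="cim")
        out = qs.significant_qtls(scan, thr)
        found = set(out["group"])
        for q in (q1, q2):
            marker = cross94.nearest_marker(q)
            gid = next(gid for gid, gp in probs94.groups.items()
                       if marker in gp.marker_names)
            assert gid in found


class TestQtlClasses:
    def test_two_letter_class_from_marker_genotypes(self, cross94):
        m1, m2 = "P2g1m01", "P1g1m01"
        classes = qs.classify_by_qtl_markers(cross94.genotypes, m1, m2)
        g = cross94.genotypes.f1_genotypes
        for pid, cls in classes.items():
            assert cls == g.loc[pid, m1] + g.loc[pid, m2]
        assert set(classes) <= {"AH", "AA", "HH", "HA"}

    def test_counts_match_brute_force_tally(self, cross94):
        m1, m2 = "P2g2m03", "P1g3m05"
        classes = qs.classify_by_qtl_markers(cross94.genotypes, m1, m2)
        g = cross94.genotypes.f1_genotypes
        tally: dict[str, int] = {}
        for pid in g.index:
            a, b = g.loc[pid, m1], g.loc[pid, m2]
            if a != "-" and b != "-":
                tally[a + b] = tally.get(a + b, 0) + 1
        assert classes.value_counts().to_dict() == tally

    def test_missing_genotype_omitted(self):
        cross = synth.simulate_pseudo_testcross(n_f1=60, missing_rate=0.2,
                                                seed=8)
        g = cross.genotypes
        with pytest.warns(RuntimeWarning, match="omitted"):
            classes = qs.classify_by_qtl_markers(g, "P1g1m01", "P2g1m01")
        assert len(classes) < g.n_f1

    def test_unknown_marker_rejected(self, cross94):
        with pytest.raises(KeyError):
            qs.classify_by_qtl_markers(cross94.genotypes, "nope", "P1g1m01")


class TestAnova:
    def test_constant_trait_single_letter(self, cross94):
        classes = qs.classify_by_qtl_markers(cross94.genotypes, "P2g1m01",
                                             "P1g1m01")
        y = pd.Series(1.0, index=classes.index)
        out = qs.compare_groups_anova(classes, y)
        assert out["F"] == 0.0
        assert set(out["letters"].values()) == {"a"}

    def test_hand_anova_table(self):
        # two classes of three: {1,2,3} vs {7,8,9}.  Hand table: grand mean
        # 5, between-SS = 3*(2-5)^2 + 3*(8-5)^2 = 54 (df 1), within-SS =
        # 2 + 2 = 4 (df 4) -> F = 54 / (4/4) = 54
        classes = pd.Series(["AA"] * 3 + ["HH"] * 3,
                            index=[f"x{i}" for i in range(6)])
        y = pd.Series([1.0, 2, 3, 7, 8, 9], index=classes.index)
        out = qs.compare_groups_anova(classes, y)
        assert out["F"] == pytest.approx(54.0, abs=1e-10)

    def test_highest_mean_gets_letter_a(self):
        classes = pd.Series(["AA"] * 5 + ["HH"] * 5,
                            index=[f"x{i}" for i in range(10)])
        y = pd.Series([10.0, 11, 10, 11, 10, 1, 2, 1, 2, 1],
                      index=classes.index)
        out = qs.compare_groups_anova(classes, y)
        assert out["letters"]["AA"] == "a"
        assert out["letters"]["HH"] == "b"

    def test_small_class_dropped_with_warning(self):
        classes = pd.Series(["AA"] * 5 + ["HH"] * 5 + ["HA"],
                            index=[f"x{i}" for i in range(11)])
        y = pd.Series(np.arange(11, dtype=float), index=classes.index)
        with pytest.warns(RuntimeWarning, match="dropped"):
            out = qs.compare_groups_anova(classes, y)
        assert "HA" not in out["classes"]

    def test_depressed_class_gets_distinct_letter(self):
        # a strong one-class depression should separate at alpha=0.01
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cross = synth.simulate_pseudo_testcross(n_f1=94, seed=900 + seed)
            classes = qs.classify_by_qtl_markers(cross.genotypes, "P2g1m01",
                                                 "P1g1m01")
            rng = np.random.default_rng(seed)
            y = pd.Series(rng.normal(0, 1, len(classes)), index=classes.index)
            y[classes == "HA"] -= 2.0  # 2 SD depression
            out = qs.compare_groups_anova(classes, y)
            others = {out["letters"][c] for c in out["classes"] if c != "HA"}
            hits += all(set(out["letters"]["HA"]) & set(o) == set()
                        for o in others)
        assert hits / n_seeds >= 0.8
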