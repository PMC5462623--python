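import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from skullqtl.assoc import KinshipMatrix, lmm_scan
from skullqtl.finemap import (
    ConsensusHaplotype,
    CriticalInterval,
    HaplotypePanel,
    carrier_stats,
    consensus_haplotype,
    critical_interval,
    interval_length,
    select_cases,
    window_haplotype_assoc,
)


def make_panel(alleles, positions=None):
    alleles = np.asarray(alleles, dtype=np.int8)
    n2, m = alleles.shape
    assert n2 % 2 == 0
    pos = positions if positions is not None else np.arange(1, m + 1) * 1000
    gmap = pd.DataFrame(
        {"chrom": "chr1", "pos": pos, "id": [f"m{j}" for j in range(m)],
         "ref": "A", "alt": "G"}
    )
    return HaplotypePanel([f"s{i}" for i in range(n2 // 2)], alleles, gmap)


class TestWindowAssoc:
    def test_constant_phenotype_yields_missing_p(self, rng):
        panel = make_panel(rng.integers(0, 2, size=(20, 15)))
        out = window_haplotype_assoc(panel, np.zeros(10), window=10)
        assert out["p"].isna().all()

    def test_window_positions_are_first_marker_coordinates(self, rng):
        pos = np.arange(1, 16) * 250
        panel = make_panel(rng.integers(0, 2, size=(12, 15)), positions=pos)
        out = window_haplotype_assoc(panel, rng.normal(size=6), window=10)
        np.testing.assert_array_equal(out["pos"], pos[:6])

    def test_haplotype_signal_invisible_to_single_markers(self, rng):
        """An XOR-style haplotype effect: every marker dosage is constant,
        so single-marker tests see nothing, but the window ANOVA does."""
        n_per = 10
        h = {"h1": [1, 0], "h2": [0, 1], "h3": [1, 1], "h4": [0, 0]}
        copies = []
        pheno = []
        for _ in range(n_per):  # cases carry h1/h2, controls h3/h4
            copies += [h["h1"], h["h2"]]
            pheno.append(-1.0)
        for _ in range(n_per):
            copies += [h["h3"], h["h4"]]
            pheno.append(1.0)
        pheno = np.array(pheno) + rng.normal(0, 0.01, size=2 * n_per)
        alleles = np.array(copies, dtype=np.int8)
        panel = make_panel(alleles)
        out = window_haplotype_assoc(panel, pheno, window=2)
        assert out["p"][0] < 1e-10
        dos = panel.dosages()
        assert np.ptp(dos[:, 0]) == 0 and np.ptp(dos[:, 1]) == 0

    def test_rare_haplotypes_pooled(self, rng):
        # 3 copies of a private haplotype must land in the pooled class,
        # leaving a 2-class ANOVA rather than erroring on a singleton class
        alleles = np.zeros((40, 4), dtype=np.int8)
        alleles[:3] = [1, 1, 1, 1]
        alleles[20:] = [0, 1, 0, 1]
        panel = make_panel(alleles)
        y = rng.normal(size=20)
        out = window_haplotype_assoc(panel, y, window=4)
        assert np.isfinite(out["p"][0])

    def test_recovers_planted_window(self, small_study):
        truth = small_study.truth
        y = truth["causal_dosage"].astype(float)
        lo = max(0, truth["causal_indices"][0] - 30)
        hi = truth["causal_indices"][-1] + 30
        sub = HaplotypePanel(
            small_study.haplotypes.sample_ids,
            small_study.haplotypes.alleles[:, lo:hi],
            small_study.haplotypes.gmap.iloc[lo:hi].reset_index(drop=True),
        )
        out = window_haplotype_assoc(sub, y, window=10)
        best = out.loc[out["p"].idxmin()]
        run_lo, run_hi = truth["causal_indices"][0] - lo, truth["causal_indices"][-1] - lo
        assert best["start"] <= run_hi and best["start"] + 10 > run_lo


class TestSelectCases:
    def test_le_boundary_inclusive(self):
        mask = select_cases(np.array([-0.3, -0.2, -0.1]), -0.2, "le")
        np.testing.assert_array_equal(mask, [True, True, False])

    def test_lt_boundary_exclusive(self):
        mask = select_cases(np.array([-0.3, -0.2, -0.1]), -0.2, "lt")
        np.testing.assert_array_equal(mask, [True, False, False])

    def test_empty_case_set_rejected(self):
        with pytest.raises(ValueError):
            select_cases(np.array([0.5, 1.0]), -0.2)


class TestConsensus:
    def test_identical_copies(self):
        h = np.tile([1, 0, 1, 1, 0], (6, 1))
        cons = consensus_haplotype(h)
        np.testing.assert_array_equal(cons.alleles, [1, 0, 1, 1, 0])
        np.testing.assert_array_equal(cons.support, np.ones(5))

    def test_majority_with_support(self):
        h = np.array([[1, 0], [1, 1], [0, 1]])
        cons = consensus_haplotype(h)
        np.testing.assert_array_equal(cons.alleles, [1, 1])
        np.testing.assert_allclose(cons.support, [2 / 3, 2 / 3])

    def test_tie_broken_toward_most_negative_phenotype(self):
        h = np.array([[1, 1], [0, 0]])
        cons = consensus_haplotype(h, copy_phenotype=np.array([-0.5, -2.0]))
        np.testing.assert_array_equal(cons.alleles, [0, 0])

    def test_matches_brute_force_majority(self, rng):
        h = rng.integers(0, 2, size=(11, 30))  # odd count: no ties
        cons = consensus_haplotype(h)
        oracle = np.array(
            [np.bincount(h[:, j], minlength=2).argmax() for j in range(30)]
        )
        np.testing.assert_array_equal(cons.alleles, oracle)
        assert np.all(cons.support >= 0.5) and np.all(cons.support <= 1.0)


def panel_with_breakpoints(m=21, index=10):
    """Hand-constructed case copies: 3 recombine just left of marker 7,
    3 just right of marker 13, the rest match consensus fully."""
    copies = []
    for _ in range(3):
        c = np.ones(m, dtype=np.int8)
        c[:7] = 0  # run starts at 7 -> left breakpoint at gap 6
        copies.append(c)
    for _ in range(3):
        c = np.ones(m, dtype=np.int8)
        c[14:] = 0  # run ends at 13 -> right breakpoint at gap 13
        copies.append(c)
    for _ in range(4):
        copies.append(np.ones(m, dtype=np.int8))
    return np.array(copies)


class TestCriticalInterval:
    def gmap(self, m=21):
        return pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(1, m + 1) * 1000,
             "id": [f"m{j}" for j in range(m)], "ref": "A", "alt": "G"}
        )

    def cons(self, m=21):
        return ConsensusHaplotype(np.arange(m), np.ones(m, np.int8), np.ones(m))

    def test_hand_constructed_fixture(self):
        h = panel_with_breakpoints()
        iv = critical_interval(h, self.cons(), 10, self.gmap(), min_recomb=3)
        assert (iv.start_marker, iv.end_marker) == (7, 13)
        assert (iv.start_pos, iv.end_pos) == (8000, 14000)
        assert iv.left_breakpoints == 3 and iv.right_breakpoints == 3
        assert not iv.hit_edge and iv.excluded_copies == []

    def test_brute_force_gap_scan_oracle(self, rng):
        m = 25
        h = rng.integers(0, 2, size=(16, m)).astype(np.int8)
        cons_alleles = rng.integers(0, 2, size=m).astype(np.int8)
        index = 12
        h[:, index] = cons_alleles[index]  # everyone a carrier at the index
        cons = ConsensusHaplotype(np.arange(m), cons_alleles, np.ones(m))
        iv = critical_interval(h, cons, index, self.gmap(m), min_recomb=3)

        # oracle: for each copy find its run; count breakpoints per gap
        left, right = [], []
        for row in h == cons_alleles:
            lo = index
            while lo > 0 and row[lo - 1]:
                lo -= 1
            hi = index
            while hi < m - 1 and row[hi + 1]:
                hi += 1
            if lo > 0:
                left.append(lo - 1)
            if hi < m - 1:
                right.append(hi)
        start = 0
        for g in range(index - 1, -1, -1):
            if sum(1 for x in left if x >= g) >= 3:
                start = g + 1
                break
        end = m - 1
        for g in range(index, m - 1):
            if sum(1 for x in right if x <= g) >= 3:
                end = g
                break
        assert (iv.start_marker, iv.end_marker) == (start, end)

    def test_interval_always_contains_index(self, rng):
        for trial in range(20):
            m = 15
            h = rng.integers(0, 2, size=(10, m)).astype(np.int8)
            cons_alleles = rng.integers(0, 2, size=m).astype(np.int8)
            h[0] = cons_alleles  # at least one carrier
            cons = ConsensusHaplotype(np.arange(m), cons_alleles, np.ones(m))
            iv = critical_interval(h, cons, 7, self.gmap(m), min_recomb=2)
            assert iv.start_marker <= 7 <= iv.end_marker

    def test_full_matches_extend_to_edge_with_warning(self):
        h = np.ones((6, 21), dtype=np.int8)
        iv = critical_interval(h, self.cons(), 10, self.gmap(), min_recomb=3)
        assert iv.hit_edge
        assert (iv.start_marker, iv.end_marker) == (0, 20)

    def test_monotone_in_min_recomb(self):
        h = panel_with_breakpoints()
        iv1 = critical_interval(h, self.cons(), 10, self.gmap(), min_recomb=1)
        iv3 = critical_interval(h, self.cons(), 10, self.gmap(), min_recomb=3)
        assert iv3.start_marker <= iv1.start_marker
        assert iv3.end_marker >= iv1.end_marker

    def test_index_mismatch_copies_excluded(self):
        h = panel_with_breakpoints()
        h[0, 10] = 0  # non-carrier at the index
        iv = critical_interval(h, self.cons(), 10, self.gmap(), min_recomb=3)
        assert iv.excluded_copies == [0]

    def test_copy_order_permutation_invariance(self, rng):
        h = panel_with_breakpoints()
        iv0 = critical_interval(h, self.cons(), 10, self.gmap(), min_recomb=3)
        perm = rng.permutation(h.shape[0])
        iv1 = critical_interval(h[perm], self.cons(), 10, self.gmap(), min_recomb=3)
        assert (iv0.start_marker, iv0.end_marker) == (iv1.start_marker, iv1.end_marker)


class TestIntervalLength:
    def make(self, start, end):
        cons = ConsensusHaplotype(np.arange(2), np.ones(2, np.int8), np.ones(2))
        return CriticalInterval("chr1", start, end, 0, 1, 3, 3, cons)

    def test_study_interval_arithmetic(self):
        assert interval_length(self.make(55_850_299, 56_037_676)) == 187_377

    def test_zero_length(self):
        assert interval_length(self.make(100, 100)) == 0

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(1, 10**8), st.integers(0, 10**6), st.integers(-500, 500))
    def test_shift_invariance(self, start, span, shift):
        a = interval_length(self.make(start, start + span))
        b = interval_length(self.make(start + shift, start + span + shift))
        assert a == b == span


class TestCarrierStats:
    def build_panel(self, case_carrier_copies, case_total, ctrl_carrier_copies, ctrl_total):
        core = np.array([1, 1, 1], dtype=np.int8)
        copies = []
        for total, carriers in ((case_total, case_carrier_copies),
                                (ctrl_total, ctrl_carrier_copies)):
            for i in range(total):
                if i < carriers:
                    copies.append(core.copy())
                else:
                    c = core.copy()
                    c[i % 3] = 0
                    copies.append(c)
        alleles = np.array(copies)
        n = alleles.shape[0] // 2
        pheno = np.concatenate(
            [np.full(case_total // 2, -0.5), np.full(ctrl_total // 2, 0.5)]
        )
        return make_panel(alleles), pheno

    def test_study_scale_carrier_frequencies(self):
        panel, pheno = self.build_panel(63, 74, 28, 674)
        cons = ConsensusHaplotype(np.arange(3), np.ones(3, np.int8), np.ones(3))
        cs = carrier_stats(panel, cons, pheno, threshold=-0.2)
        assert cs.counts["case"] == (63, 74)
        assert cs.counts["control"] == (28, 674)
        assert cs.frequency_str("case") == "85.1"
        assert cs.frequency_str("control") == "4.2"
        assert cs.t_p < 1e-10  # carriers are strongly enriched among cases

    def test_no_carriers_skips_t_test(self):
        panel, pheno = self.build_panel(0, 4, 0, 4)
        cons = ConsensusHaplotype(np.arange(3), np.ones(3, np.int8), np.ones(3))
        cs = carrier_stats(panel, cons, pheno, threshold=-0.2)
        assert cs.frequencies_pct["case"] == 0.0
        assert np.isnan(cs.t_stat) and "skipped" in cs.note

    def test_carrier_requires_every_core_marker(self):
        alleles = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1], [1, 1, 1]], np.int8)
        panel = make_panel(alleles)
        cons = ConsensusHaplotype(np.arange(3), np.ones(3, np.int8), np.ones(3))
        cs = carrier_stats(panel, cons, np.array([-0.5, 0.5]), threshold=-0.2)
        assert cs.counts["case"] == (1, 2)
        assert cs.counts["control"] == (2, 2)


def test_window_beats_best_single_marker_on_partitioning_haplotype(rng):
    """A haplotype that perfectly partitions the phenotype scores lower p
    in the window test than any single constituent marker in the scan."""
    n_per = 12
    h_case, h_ctrl1, h_ctrl2 = [1, 0, 1], [0, 1, 1], [1, 1, 0]
    copies, pheno = [], []
    for _ in range(n_per):
        copies += [h_case, h_case]
        pheno.append(-1.0)
    for i in range(n_per):
        copies += [h_ctrl1, h_ctrl2] if i % 2 else [h_ctrl2, h_ctrl1]
        pheno.append(1.0)
    pheno = np.array(pheno) + rng.normal(0, 0.05, size=2 * n_per)
    panel = make_panel(np.array(copies, np.int8))
    win = window_haplotype_assoc(panel, pheno, window=3)
    from skullqtl.assoc import GenotypeMatrix

    g = GenotypeMatrix(panel.sample_ids, panel.dosages(), panel.gmap.copy())
    scan = lmm_scan(pheno, g, KinshipMatrix(np.eye(2 * n_per)))
    assert win["p"].min() < np.nanmin(scan.results["p"].to_numpy())
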