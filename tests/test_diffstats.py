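"""Weir–Cockerham F_ST, frequency-binned outlier flags, and PBS."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sweepdriver import diffstats
from sweepdriver.diffstats import (
    binned_fst_flags,
    branch_length,
    fst_scan,
    pbs,
    pbs_top_flags,
    wc_fst,
)

from conftest import make_matrix


def wc84_oracle(counts1, counts2):
    """Independent literal transcription of the 1984 two-population
    variance-component estimator from genotype counts (nAA, nAa, naa)."""
    r = 2
    n = [sum(counts1), sum(counts2)]
    p = [
        (2 * c[0] + c[1]) / (2 * sum(c)) for c in (counts1, counts2)
    ]  # freq of allele 'A'
    h = [c[1] / sum(c) for c in (counts1, counts2)]
    nbar = sum(n) / r
    nc = (r * nbar - sum(x * x for x in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def genotypes_from_counts(n_AA, n_Aa, n_aa):
    """Dosages of the derived allele 'a' given counts of A-homozygote,
    heterozygote and a-homozygote individuals."""
    return [0] * n_AA + [1] * n_Aa + [2] * n_aa


class TestWcFst:
    def test_fixed_difference_gives_one(self):
        rec = wc_fst([2, 2, 2, 2], [0, 0, 0, 0])
        assert rec.fst == pytest.approx(1.0)

    def test_identical_populations_give_nonpositive(self, rng):
        for _ in range(10):
            g = rng.integers(0, 3, size=8)
            if len(set(g.tolist())) == 1:
                continue
            rec = wc_fst(g, g)
            assert rec.fst <= 1e-12

    def test_matches_hand_evaluated_components(self):
        # genotype counts pop1 (AA:4, Aa:2, aa:4), pop2 (AA:8, Aa:2, aa:0)
        g1 = genotypes_from_counts(4, 2, 4)
        g2 = genotypes_from_counts(8, 2, 0)
        rec = wc_fst(g1, g2)
        a, b, c = wc84_oracle([4, 2, 4], [8, 2, 0])
        assert rec.a == pytest.approx(a, abs=1e-12)
        assert rec.b == pytest.approx(b, abs=1e-12)
        assert rec.c == pytest.approx(c, abs=1e-12)
        assert rec.fst == pytest.approx(a / (a + b + c), abs=1e-12)

    def test_symmetric_in_population_order(self, rng):
        for _ in range(20):
            g1 = rng.integers(0, 3, size=6)
            g2 = rng.integers(0, 3, size=9)
            r1 = wc_fst(g1, g2)
            r2 = wc_fst(g2, g1)
            if np.isfinite(r1.fst):
                assert r1.fst == pytest.approx(r2.fst, abs=1e-12)

    def test_too_few_individuals_rejected(self):
        with pytest.raises(ValueError):
            wc_fst([1], [0, 2])


class TestFstScan:
    def test_identical_matrices_nonpositive(self, rng):
        entries = rng.integers(0, 2, size=(20, 50)).astype(np.uint8)
        a = make_matrix(entries, population="A")
        b = make_matrix(entries.copy(), population="B")
        track = fst_scan(a, b)
        vals = track.data["raw"].dropna()
        assert (vals <= 1e-12).all()

    def test_elementwise_agreement_with_per_site_oracle(self, rng):
        ea = rng.integers(0, 2, size=(24, 200)).astype(np.uint8)
        eb = rng.integers(0, 2, size=(30, 200)).astype(np.uint8)
        a = make_matrix(ea, positions=np.arange(1, 201), population="A")
        b = make_matrix(eb, positions=np.arange(1, 201), population="B")
        track = fst_scan(a, b)
        for j in range(200):
            g1 = ea[0::2, j] + ea[1::2, j]
            g2 = eb[0::2, j] + eb[1::2, j]
            n_AA = int((g1 == 0).sum()), int((g2 == 0).sum())
            n_Aa = int((g1 == 1).sum()), int((g2 == 1).sum())
            n_aa = int((g1 == 2).sum()), int((g2 == 2).sum())
            oa, ob, oc = wc84_oracle(
                [n_AA[0], n_Aa[0], n_aa[0]], [n_AA[1], n_Aa[1], n_aa[1]]
            )
            got = track.data["raw"].iloc[j]
            if oa + ob + oc == 0:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(oa / (oa + ob + oc), abs=1e-9)

    def test_mismatched_site_lists_rejected(self, rng):
        a = make_matrix(rng.integers(0, 2, (10, 5)), positions=[1, 2, 3, 4, 5])
        b = make_matrix(rng.integers(0, 2, (10, 5)), positions=[1, 2, 3, 4, 6])
        with pytest.raises(ValueError):
            fst_scan(a, b)


class TestBinnedFstFlags:
    @staticmethod
    def _track(fst_vals, mafs):
        df = pd.DataFrame(
            {
                "chrom": "1",
                "pos": np.arange(1, len(fst_vals) + 1),
                "maf": mafs,
                "raw": fst_vals,
            }
        )
        from sweepdriver.haplostats import ScoreTrack

        return ScoreTrack("FST", df)

    def test_all_equal_bin_yields_no_flags(self):
        track = self._track([0.3] * 50, [0.25] * 50)
        flags, _ = binned_fst_flags(track, quantile=0.05)
        assert flags.sum() == 0

    def test_distinct_bin_flags_exact_top_fraction(self, rng):
        vals = rng.permutation(np.linspace(0.01, 0.99, 100))
        track = self._track(vals, [0.3] * 100)
        flags, table = binned_fst_flags(track, quantile=0.05)
        assert flags.sum() == 5
        # the flagged sites are exactly the 5 largest (sort-and-count oracle)
        assert set(np.flatnonzero(flags)) == set(np.argsort(vals)[-5:])

    def test_site_order_invariance(self, rng):
        vals = rng.uniform(0, 1, 200)
        mafs = rng.uniform(0, 0.5, 200)
        t1 = self._track(vals, mafs)
        perm = rng.permutation(200)
        t2 = self._track(vals[perm], mafs[perm])
        f1, _ = binned_fst_flags(t1)
        f2, _ = binned_fst_flags(t2)
        assert np.array_equal(f1[perm], f2)

    def test_sparse_bins_merged(self, rng):
        # 5 sites in one bin, 100 in another -> one merged group
        vals = np.concatenate([rng.uniform(0, 1, 5), rng.uniform(0, 1, 100)])
        mafs = np.concatenate([np.full(5, 0.02), np.full(100, 0.4)])
        _, table = binned_fst_flags(self._track(vals, mafs), min_per_bin=20)
        assert len(table) == 1
        assert table["n_sites"].iloc[0] == 105


class TestPbs:
    @staticmethod
    def _tracks(f_ts, f_to, f_so):
        from sweepdriver.haplostats import ScoreTrack

        def t(vals):
            return ScoreTrack(
                "FST",
                pd.DataFrame(
                    {"chrom": "1", "pos": np.arange(1, len(vals) + 1), "raw": vals}
                ),
            )

        return t(f_ts), t(f_to), t(f_so)

    def test_printed_equation_arithmetic(self):
        # T triplet (0.2, 0.3, 0.1) -> PBS = (0.2 + 0.3 - 0.1)/2 = 0.2
        f = lambda T: 1 - np.exp(-T)
        comp = pbs(*self._tracks([f(0.2)], [f(0.3)], [f(0.1)]), "t", "s", "o")
        assert comp.data["pbs"].iloc[0] == pytest.approx(0.2, abs=1e-12)

    def test_zero_fst_gives_zero_pbs(self):
        comp = pbs(*self._tracks([0.0], [0.0], [0.0]), "t", "s", "o")
        assert comp.data["pbs"].iloc[0] == 0.0

    def test_hand_evaluated_triplet(self):
        # F_ST (0.3, 0.3, 0.0): PBS = (2*(-ln 0.7) - 0)/2 = -ln(0.7)
        comp = pbs(*self._tracks([0.3], [0.3], [0.0]), "t", "s", "o")
        assert comp.data["pbs"].iloc[0] == pytest.approx(0.3566749, abs=1e-6)

    def test_undefined_fst_propagates(self):
        comp = pbs(*self._tracks([0.1, np.nan], [0.1, 0.1], [0.1, 0.1]), "t", "s", "o")
        assert np.isnan(comp.data["pbs"].iloc[1])
        assert np.isfinite(comp.data["pbs"].iloc[0])

    def test_negative_fst_clamped_to_zero_branch(self):
        assert branch_length(-0.3) == 0.0
        assert branch_length(0.5) == pytest.approx(-np.log(0.5))

    @given(
        st.tuples(
            st.floats(0, 0.99), st.floats(0, 0.99), st.floats(0, 0.99)
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_role_swap_identity(self, triple):
        """PBS(test) + PBS(sister) with roles swapped equals T_test,sister."""
        f_ts, f_to, f_so = triple
        c1 = pbs(*self._tracks([f_ts], [f_to], [f_so]), "t", "s", "o")
        c2 = pbs(*self._tracks([f_ts], [f_so], [f_to]), "s", "t", "o")
        total = c1.data["pbs"].iloc[0] + c2.data["pbs"].iloc[0]
        assert total == pytest.approx(branch_length(f_ts), abs=1e-9)

    @given(st.floats(0.01, 0.9), st.floats(0.01, 0.9), st.floats(0.01, 0.9))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_each_argument(self, f_ts, f_to, f_so):
        base = pbs(*self._tracks([f_ts], [f_to], [f_so]), "t", "s", "o")
        up_ts = pbs(*self._tracks([f_ts + 0.05], [f_to], [f_so]), "t", "s", "o")
        up_to = pbs(*self._tracks([f_ts], [f_to + 0.05], [f_so]), "t", "s", "o")
        up_so = pbs(*self._tracks([f_ts], [f_to], [f_so + 0.05]), "t", "s", "o")
        b = base.data["pbs"].iloc[0]
        assert up_ts.data["pbs"].iloc[0] > b
        assert up_to.data["pbs"].iloc[0] > b
        assert up_so.data["pbs"].iloc[0] < b


class TestPbsTopFlags:
    def test_distinct_values_flag_exact_count(self, rng):
        vals = rng.permutation(np.linspace(0, 1, 1000))
        flags, thr = pbs_top_flags(vals, quantile=0.05)
        assert flags.sum() == 50
        assert set(np.flatnonzero(flags)) == set(np.argsort(vals)[-50:])

    def test_constant_values_flag_nothing(self):
        flags, _ = pbs_top_flags(np.full(200, 0.5))
        assert flags.sum() == 0

    def test_few_values_warn_but_compute(self):
        with pytest.warns(UserWarning):
            flags, thr = pbs_top_flags(np.linspace(0, 1, 30), quantile=0.1)
        assert np.isfinite(thr)
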