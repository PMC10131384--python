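"""EHH/iHH/iHS/xpEHH against brute-force oracles, plus invariants."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sweepdriver import haplostats as hs
from sweepdriver.haplostats import (
    EHHCurve,
    MonomorphicCoreError,
    ehh,
    ihh,
    ihs_scan,
    standardize,
    xpehh_scan,
)

from conftest import make_matrix, random_matrix


def brute_ehh_curve(entries, positions, carriers, core):
    """O(n^2) oracle: at every extent j, the fraction of carrier pairs whose
    haplotypes agree at every site from the core through j."""
    n = len(carriers)
    pairs = list(itertools.combinations(range(n), 2))

    def at(j):
        lo, hi = min(core, j), max(core, j)
        same = sum(
            1
            for a, b in pairs
            if np.array_equal(
                entries[carriers[a], lo : hi + 1], entries[carriers[b], lo : hi + 1]
            )
        )
        return same / len(pairs)

    up = [(positions[j], at(j)) for j in range(core - 1, -1, -1)]
    down = [(positions[j], at(j)) for j in range(core + 1, entries.shape[1])]
    return up, down


class TestEhh:
    def test_identical_carriers_keep_ehh_one(self):
        entries = np.tile([1, 0, 1, 1, 0], (6, 1)).astype(np.uint8)
        entries = np.vstack([entries, 1 - entries[:2]])  # non-carriers differ
        m = make_matrix(entries)
        curve = ehh(m, 2, "derived", cutoff=0.0)
        assert all(e == 1.0 for _, e in curve.upstream)
        assert all(e == 1.0 for _, e in curve.downstream)

    def test_hand_counted_group_split(self):
        # six carriers split {3,2,1} one site downstream of the core:
        # EHH = (C(3,2)+C(2,2)) / C(6,2) = 4/15
        entries = np.zeros((6, 3), dtype=np.uint8)
        entries[:, 0] = 1  # core: all carry derived
        entries[:, 1] = [0, 0, 0, 1, 1, 1]
        entries[:, 2] = [0, 0, 0, 0, 0, 1]
        m = make_matrix(entries)
        curve = ehh(m, 0, "derived", cutoff=0.0)
        ehh_values = [e for _, e in curve.downstream]
        assert ehh_values[0] == 1.0  # core
        assert ehh_values[1] == pytest.approx((3 * 2 + 3 * 2) / 2 / 15)
        assert ehh_values[2] == pytest.approx((3 + 1) / 15)  # groups {3,2,1}

    def test_matches_pairwise_oracle_on_random_matrices(self, rng):
        for _ in range(10):
            m = random_matrix(rng, n_hap=16, n_sites=30)
            core = int(rng.integers(5, 25))
            for allele, code in (("derived", 1), ("ancestral", 0)):
                carriers = np.flatnonzero(m.entries[:, core] == code)
                if carriers.size < 2:
                    continue
                curve = ehh(m, core, allele, cutoff=0.0)
                up, down = brute_ehh_curve(m.entries, m.positions, carriers, core)
                assert [(p, pytest.approx(e)) for p, e in up] == [
                    (p, e) for p, e in curve.upstream[1:]
                ]
                assert [(p, pytest.approx(e)) for p, e in down] == [
                    (p, e) for p, e in curve.downstream[1:]
                ]

    def test_monomorphic_core_signalled(self):
        m = make_matrix(np.zeros((6, 5), dtype=np.uint8))
        with pytest.raises(MonomorphicCoreError, match="monomorphic core"):
            ehh(m, 2, "derived")

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_monotone_nonincreasing_in_unit_range(self, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, n_hap=12, n_sites=25)
        core = 12
        for allele in ("derived", "ancestral", "pooled"):
            try:
                curve = ehh(m, core, allele, cutoff=0.0)
            except MonomorphicCoreError:
                continue
            for arm in (curve.upstream, curve.downstream):
                values = [e for _, e in arm]
                assert all(0.0 <= e <= 1.0 for e in values)
                assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))

    def test_row_permutation_invariance(self, rng):
        m = random_matrix(rng, n_hap=14, n_sites=30)
        perm = rng.permutation(14)
        m2 = make_matrix(m.entries[perm], m.positions)
        c1 = ehh(m, 15, "derived", cutoff=0.0)
        c2 = ehh(m2, 15, "derived", cutoff=0.0)
        assert c1.downstream == c2.downstream
        assert c1.upstream == c2.upstream


class TestIhh:
    @staticmethod
    def _curve(up, down):
        return EHHCurve(0, "derived", up, down, "cutoff", "cutoff")

    def test_rectangle(self):
        up = [(1000.0, 1.0), (0.0, 1.0)]
        down = [(1000.0, 1.0), (2000.0, 1.0)]
        assert ihh(self._curve(up, down)) == pytest.approx(2000.0)

    def test_below_cutoff_endpoint_excluded(self):
        down = [(0.0, 1.0), (100.0, 0.5), (200.0, 0.04)]
        curve = self._curve([(0.0, 1.0)], down)
        # only trapezoid 0-100 contributes: (1+0.5)/2*100 = 75
        assert ihh(curve, cutoff=0.05) == pytest.approx(75.0)

    def test_distance_linearity(self):
        down = [(0.0, 1.0), (150.0, 0.6), (300.0, 0.2)]
        doubled = [(p * 2, e) for p, e in down]
        assert ihh(self._curve([(0.0, 1.0)], doubled)) == pytest.approx(
            2 * ihh(self._curve([(0.0, 1.0)], down))
        )


class TestIhsScan:
    def test_allele_label_swap_flips_sign(self, rng):
        m = random_matrix(rng, n_hap=20, n_sites=40, span=4000)
        flipped = make_matrix(1 - m.entries, m.positions)
        t1 = ihs_scan(m, cutoff=0.05, max_gap=None)
        t2 = ihs_scan(flipped, cutoff=0.05, max_gap=None)
        r1, r2 = t1.data["raw"].to_numpy(), t2.data["raw"].to_numpy()
        both = np.isfinite(r1) & np.isfinite(r2)
        assert both.any()
        assert np.allclose(r1[both], -r2[both])
        assert np.array_equal(np.isnan(r1), np.isnan(r2))

    def test_mirror_structure_gives_zero(self):
        # ancestral and derived carrier sets with identical haplotype
        # structure around the core -> iHH_A = iHH_D -> iHS = 0
        block = np.array(
            [[0, 0, 0], [0, 1, 0], [1, 0, 1], [1, 1, 1]], dtype=np.uint8
        )
        entries = np.zeros((8, 7), dtype=np.uint8)
        entries[:4, 3] = 0
        entries[4:, 3] = 1
        entries[:4, :3], entries[:4, 4:] = block[:, :3], block[:, :3]
        entries[4:, :3], entries[4:, 4:] = block[:, :3], block[:, :3]
        m = make_matrix(entries)
        track = ihs_scan(m, cutoff=0.01, max_gap=None)
        assert track.data["raw"].iloc[3] == pytest.approx(0.0, abs=1e-12)

    def test_skip_reasons_are_reported(self, rng):
        entries = rng.integers(0, 2, size=(12, 10)).astype(np.uint8)
        entries[:, 0] = 0  # monomorphic core
        m = make_matrix(entries, positions=np.arange(1, 11) * 10)
        track = ihs_scan(m, cutoff=1e-9, max_gap=None)
        # cutoff ~0 means EHH never drops below it -> every walk hits an edge
        reasons = set(track.data["reason"])
        assert "monomorphic" in reasons
        assert "edge" in reasons
        assert track.data["raw"].isna().all()

    def test_max_gap_suppresses_cores(self):
        entries = np.array(
            [[1, 0, 1], [1, 1, 0], [0, 0, 1], [0, 1, 0]] * 3, dtype=np.uint8
        )
        m = make_matrix(entries, positions=[100, 200, 900_000])
        track = ihs_scan(m, cutoff=0.05, max_gap=1000)
        assert (track.data["reason"] == "max_gap").any()


class TestXpehhScan:
    def test_identical_populations_score_zero(self, rng):
        m = random_matrix(rng, n_hap=20, n_sites=40, span=4000)
        other = make_matrix(m.entries.copy(), m.positions, population="B")
        track = xpehh_scan(m, other, max_gap=None)
        vals = track.data["raw"].dropna()
        assert len(vals) > 0
        assert np.allclose(vals, 0.0)

    def test_population_swap_antisymmetry(self, rng):
        a = random_matrix(rng, n_hap=16, n_sites=40, span=4000, population="A")
        b = random_matrix(rng, n_hap=20, n_sites=40, span=4000, population="B")
        b = make_matrix(b.entries, a.positions, population="B")
        t_ab = xpehh_scan(a, b, max_gap=None)
        t_ba = xpehh_scan(b, a, max_gap=None)
        r1, r2 = t_ab.data["raw"].to_numpy(), t_ba.data["raw"].to_numpy()
        assert np.array_equal(np.isnan(r1), np.isnan(r2))
        ok = np.isfinite(r1)
        assert np.allclose(r1[ok], -r2[ok])

    def test_pooled_maf_filter_reasons(self, rng):
        a = random_matrix(rng, n_hap=20, n_sites=30)
        entries_b = a.entries.copy()
        b = make_matrix(entries_b, a.positions, population="B")
        a.entries[:, 0] = 0
        b.entries[:, 0] = 0
        a.entries[0, 0] = 1  # pooled freq 1/40 < 0.05
        track = xpehh_scan(a, b, maf_min=0.05, max_gap=None)
        assert track.data["reason"].iloc[0] == "low-maf"


class TestStandardize:
    @staticmethod
    def _track(raw, freq=None):
        import pandas as pd

        n = len(raw)
        df = pd.DataFrame(
            {
                "chrom": "1",
                "pos": np.arange(1, n + 1),
                "derived_freq": freq if freq is not None else np.full(n, 0.5),
                "raw": raw,
                "standardized": np.nan,
                "reason": "ok",
            }
        )
        return hs.ScoreTrack("iHS", df)

    def test_population_moment_convention(self):
        out = standardize(self._track([-1.0, 1.0]), bin_variable="none", min_per_bin=1)
        assert list(out.data["standardized"]) == [-1.0, 1.0]

    def test_per_bin_moments_are_exact(self, rng):
        raw = rng.normal(size=2000) * 3 + 1
        freq = rng.uniform(0, 1, 2000)
        out = standardize(self._track(raw, freq), n_bins=20)
        df = out.data
        # recover the merged-bin grouping from the bin table
        for _, row in out.bin_table.iterrows():
            bins = [int(b) for b in row["bins"].split(",")]
            mask = np.isin(
                np.clip((freq * 20).astype(int), 0, 19), bins
            )
            vals = df.loc[mask, "standardized"]
            assert vals.mean() == pytest.approx(0.0, abs=1e-9)
            assert vals.std(ddof=0) == pytest.approx(1.0, abs=1e-6)

    def test_zero_variance_bin_undefined(self):
        out = standardize(self._track([2.0] * 30), bin_variable="none")
        assert out.data["standardized"].isna().all()

    def test_sparse_bins_merged_to_reach_floor(self, rng):
        raw = rng.normal(size=60)
        freq = rng.uniform(0, 1, 60)
        out = standardize(self._track(raw, freq), n_bins=100, min_per_bin=20)
        assert (out.bin_table["n"] >= 20).all()

    def test_undefined_raw_scores_stay_undefined(self, rng):
        raw = rng.normal(size=50)
        raw[::5] = np.nan
        out = standardize(self._track(raw), bin_variable="none")
        assert out.data["standardized"].isna()[::5].all()
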