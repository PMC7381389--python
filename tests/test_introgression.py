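"""ISC/VSC identity counting, the introgressive index, and fragment screening."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from introscan.io import GenomeWindow, SampleGrouping, windows_for_matrix
from introscan.introgression import (
    IdentityCounts,
    introgression_index,
    scan_receptors,
    site_identity_counts,
    windowed_identity_counts,
)
from introscan.simulate import SimulationConfig, TractSpec, simulate_genotypes

from conftest import M, make_matrix, random_matrix
from oracles import brute_identity_counts, brute_window_index


class TestSiteIdentityCounts:
    def test_twenty_matching_donors(self):
        # receptor genotype shared by exactly 20 of 30 genotyped donors
        group = [0] * 20 + [2] * 10 + [M] * 5
        counts = site_identity_counts(0, group)
        assert counts.isc == 20
        assert counts.vsc == 30

    def test_missing_receptor_contributes_nothing(self):
        assert site_identity_counts(M, [0, 1, 2, M]) == IdentityCounts(0, 0)

    def test_het_matches_only_het(self):
        counts = site_identity_counts(1, [1, 1, 0])
        assert (counts.isc, counts.vsc) == (2, 3)
        # hom receptor does not match het carriers of the same allele
        assert site_identity_counts(2, [1, 1, 2]).isc == 1

    def test_invariant_enforced(self):
        with pytest.raises(ValueError):
            IdentityCounts(isc=3, vsc=2)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(rc=st.sampled_from([0, 1, 2, M]),
           group=st.lists(st.sampled_from([0, 1, 2, M]), max_size=40))
    def test_matches_brute_force_and_bounds(self, rc, group):
        c = site_identity_counts(rc, group)
        assert (c.isc, c.vsc) == brute_identity_counts(rc, group)
        assert 0 <= c.isc <= c.vsc <= len(group)


class TestWindowedIdentityCounts:
    def test_additivity_over_sites(self):
        # site counts (3,5) and (2,5) -> window (5,10); receptor is column s5
        calls = [
            [0, 0, 0, 2, 2, 0],  # donors s0..s4: three 0s -> isc 3, vsc 5
            [0, 0, 2, 2, 2, 0],  # two 0s -> isc 2, vsc 5
        ]
        m = make_matrix(calls)
        w = GenomeWindow("A01", 0, 100)
        c = windowed_identity_counts(m, "s5", [f"s{i}" for i in range(5)], w)
        assert (c.isc, c.vsc) == (5, 10)

    def test_receptor_all_missing_in_window(self):
        m = make_matrix([[0, 1, M], [2, 2, M]])
        c = windowed_identity_counts(m, "s2", ["s0", "s1"],
                                     GenomeWindow("A01", 0, 10))
        assert (c.isc, c.vsc) == (0, 0)

    def test_window_sum_equals_site_loop(self, rng):
        m = random_matrix(rng, 50, 11, missing_rate=0.2)
        w = GenomeWindow("A01", 0, int(m.pos.max()))
        group = m.samples[:10]
        c = windowed_identity_counts(m, "s10", group, w)
        gi = [m.samples.index(s) for s in group]
        isc = vsc = 0
        for i in range(m.n_sites):
            si, sv = brute_identity_counts(
                int(m.calls[i, 10]), [int(m.calls[i, j]) for j in gi])
            isc += si
            vsc += sv
        assert (c.isc, c.vsc) == (isc, vsc)


class TestIntrogressionIndex:
    def test_receptor_identical_to_all_donors_only(self):
        # receptor matches every donor call, no acceptor call
        calls = [
            [0, 0, 2, 2, 0],  # donors s0,s1; acceptors s2,s3; receptor s4
            [2, 2, 0, 0, 2],
        ]
        m = make_matrix(calls)
        w = GenomeWindow("A01", 0, 10)
        idx = introgression_index(m, "s4", ["s0", "s1"], ["s2", "s3"], w)
        assert idx == pytest.approx(1.0)

    def test_identical_donor_and_acceptor_groups_give_zero(self, rng):
        base = rng.integers(0, 3, size=(30, 4)).astype(np.int8)
        calls = np.concatenate([base, base, rng.integers(0, 3, (30, 1), dtype=np.int8)], axis=1)
        m = make_matrix(calls)
        w = GenomeWindow("A01", 0, 100)
        idx = introgression_index(m, "s8", m.samples[:4], m.samples[4:8], w,
                                  exclude_receptor_from_acceptor=False)
        assert idx == pytest.approx(0.0, abs=0)

    def test_hand_worked_two_site_window(self):
        # donor calls {s1:[0,0,2], s2:[0,2,M]}, acceptor {s1:[2,2], s2:[0,0]},
        # receptor [0,0]: donor ratio (2+1)/(3+2)=0.6, acceptor (0+2)/4=0.5
        calls = [
            [0, 0, 2, 2, 2, 0],
            [0, 2, M, 0, 0, 0],
        ]
        m = make_matrix(calls)
        w = GenomeWindow("A01", 0, 10)
        idx = introgression_index(m, "s5", ["s0", "s1", "s2"], ["s3", "s4"], w)
        assert idx == pytest.approx(0.1)
        assert idx == pytest.approx(
            brute_window_index(m, "s5", ["s0", "s1", "s2"], ["s3", "s4"], w))

    def test_undefined_when_vsc_zero_not_zero(self):
        m = make_matrix([[0, M, 1]])
        w = GenomeWindow("A01", 0, 10)
        idx = introgression_index(m, "s2", ["s0"], ["s1"], w)
        assert math.isnan(idx)

    def test_receptor_removed_from_acceptor_group(self):
        # receptor inside acceptor group: self-match must not count
        calls = [[0, 2, 2, 0]]  # donor s0; acceptors s1,s2,s3; receptor s3
        m = make_matrix(calls)
        w = GenomeWindow("A01", 0, 10)
        idx = introgression_index(m, "s3", ["s0"], ["s1", "s2", "s3"], w)
        assert idx == pytest.approx(1.0 - 0.0)
        idx_keep = introgression_index(m, "s3", ["s0"], ["s1", "s2", "s3"], w,
                                       exclude_receptor_from_acceptor=False)
        assert idx_keep == pytest.approx(1.0 - 1 / 3)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_bounds_antisymmetry_and_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_d = int(rng.integers(1, 6))
        n_a = int(rng.integers(1, 6))
        m = random_matrix(rng, int(rng.integers(1, 60)), n_d + n_a + 1,
                          missing_rate=0.3)
        donors = m.samples[:n_d]
        acceptors = m.samples[n_d:n_d + n_a]
        receptor = m.samples[-1]
        w = GenomeWindow("A01", 0, int(m.pos.max()))
        idx = introgression_index(m, receptor, donors, acceptors, w)
        swapped = introgression_index(m, receptor, acceptors, donors, w)
        oracle = brute_window_index(m, receptor, donors, acceptors, w)
        if math.isnan(idx):
            assert math.isnan(oracle) and math.isnan(swapped)
        else:
            assert -1.0 <= idx <= 1.0
            assert idx == pytest.approx(oracle)
            assert swapped == pytest.approx(-idx)

    def test_adding_receptor_clone_to_donors_never_decreases_ratio(self, rng):
        m = random_matrix(rng, 40, 8, missing_rate=0.2)
        donors = m.samples[:3]
        receptor = m.samples[7]
        ri = m.samples.index(receptor)
        w = GenomeWindow("A01", 0, int(m.pos.max()))
        c0 = windowed_identity_counts(m, receptor, donors, w)
        # append a clone of the receptor as a new donor
        calls = np.concatenate([m.calls, m.calls[:, [ri]]], axis=1)
        m2 = make_matrix(calls, positions=list(m.pos),
                         samples=m.samples + ["clone"])
        c1 = windowed_identity_counts(m2, receptor, donors + ["clone"], w)
        r0 = c0.isc / c0.vsc if c0.vsc else 0.0
        r1 = c1.isc / c1.vsc if c1.vsc else 0.0
        assert r1 >= r0 - 1e-12


def _grouping_for(m, n_d, n_a):
    assignments = {}
    for s in m.samples[:n_d]:
        assignments[s] = "donor"
    for s in m.samples[n_d:n_d + n_a]:
        assignments[s] = "background"
    for s in m.samples[n_d + n_a:]:
        assignments[s] = "receptor"
    return SampleGrouping(assignments, donor_labels=("donor",),
                          acceptor_label="background",
                          receptor_labels=("receptor",))


class TestScanReceptors:
    def test_synthetic_tract_recovered(self):
        tract = TractSpec("R001", "A06", 10_000_000, 13_000_000)
        cfg = SimulationConfig(n_donor=30, n_acceptor=60, n_receptor_carrier=1,
                               chrom_length=30_000_000, snp_density=100,
                               differentiation=0.5, missing_rate=0.05,
                               tracts=[tract], seed=7)
        m, g, _ = simulate_genotypes(cfg)
        profiles = scan_receptors(m, g, threshold=0.15)
        assert len(profiles) == 1
        frags = profiles[0].fragments
        assert any(f.start < tract.end and tract.start < f.end for f in frags)
        # nothing called far from the tract
        for f in frags:
            assert f.start >= tract.start - 1_000_000
            assert f.end <= tract.end + 1_000_000

    def test_threshold_above_one_yields_no_fragments(self, rng):
        m = random_matrix(rng, 80, 12, missing_rate=0.1)
        g = _grouping_for(m, 5, 5)
        profiles = scan_receptors(m, g, threshold=1.1)
        assert all(not p.fragments for p in profiles)

    def test_two_donor_labels_give_two_profiles_per_receptor(self, rng):
        m = random_matrix(rng, 40, 10, missing_rate=0.1)
        assignments = {s: "blue" for s in m.samples[:3]}
        assignments.update({s: "purple" for s in m.samples[3:6]})
        assignments.update({s: "background" for s in m.samples[6:8]})
        assignments.update({s: "receptor" for s in m.samples[8:]})
        g = SampleGrouping(assignments, donor_labels=("blue", "purple"),
                           acceptor_label="background",
                           receptor_labels=("receptor",))
        profiles = scan_receptors(m, g)
        assert len(profiles) == 4
        keys = [(p.receptor, p.donor) for p in profiles]
        assert keys == sorted(keys)

    def test_empty_receptor_set_errors(self, rng):
        m = random_matrix(rng, 10, 6, missing_rate=0)
        g = _grouping_for(m, 3, 3)  # no receptor samples left
        with pytest.raises(ValueError, match="receptor"):
            scan_receptors(m, g)

    def test_windowed_scan_matches_brute_force_track(self, rng):
        m = random_matrix(rng, 200, 15, missing_rate=0.2, max_pos=4000)
        g = _grouping_for(m, 6, 6)
        windows = windows_for_matrix(m, 1000)
        profiles = scan_receptors(m, g, windows=windows)
        donors = g.samples_in("donor")
        acceptors = g.samples_in("background")
        for p in profiles:
            for ws in p.window_stats:
                expect = brute_window_index(m, p.receptor, donors, acceptors,
                                            ws.window)
                assert ws.value == pytest.approx(expect, nan_ok=True)
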