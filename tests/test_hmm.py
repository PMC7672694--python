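"""Windowed state space, emissions and Viterbi decoding."""

from __future__ import annotations

import math

import numpy as np
import pytest

import hicorient as hc
from hicorient.hmm import (
    HMMConfig,
    StateSpace,
    build_state_space,
    compute_emissions,
    exhaustive_decode,
    refine,
    viterbi,
)
from hicorient.likelihood import LOG_HALF, joint_log_probability

from conftest import reverse_instance, small_instance


def _scaffold(lengths, orientations=None):
    n = len(lengths)
    orients = "+" * n if orientations is None else orientations
    layout = hc.make_layout(
        {"s": [(f"c{i}", lengths[i], orients[i]) for i in range(n)]}
    )
    return layout.scaffolds[0]


class TestStateSpace:
    def test_fixed_k3_n5_window_and_partition(self):
        """k=3, n=5: three windows; the seven |i-j|<3 pairs are partitioned
        as first-window pairs plus two pairs per later window."""
        scaf = _scaffold([10_000] * 5)
        space = build_state_space(scaf, HMMConfig(K=1e9, mode="fixed", k=3))
        assert space.windows == [(0, 2), (1, 3), (2, 4)]
        assert space.observations[0] == [(0, 1), (0, 2), (1, 2)]
        assert space.observations[1] == [(1, 3), (2, 3)]
        assert space.observations[2] == [(2, 4), (3, 4)]
        assert sum(len(o) for o in space.observations) == 7

    def test_adaptive_collapse_with_long_contigs(self):
        """All contigs at least K long: only adjacent pairs are informative
        and every window has arity 2."""
        scaf = _scaffold([50_000] * 6)
        space = build_state_space(scaf, HMMConfig(K=40_000, mode="adaptive"))
        assert all(b - a + 1 == 2 for a, b in space.windows)
        assert space.k0 == 2
        assert all(obs == [(b - 1, b)] for (a, b), obs in
                   list(zip(space.windows, space.observations))[1:])

    def test_adaptive_windows_grow_over_short_contigs(self):
        scaf = _scaffold([100_000, 5_000, 5_000, 5_000, 100_000])
        space = build_state_space(scaf, HMMConfig(K=20_000, mode="adaptive"))
        arity = {b: b - a + 1 for a, b in space.windows}
        assert arity[4] > 2  # window ending at the long right contig spans the run

    @pytest.mark.parametrize("seed", range(5))
    def test_partition_oracle_random_lengths(self, seed):
        """Brute-force scan: every pair with intervening length < K is
        assigned to exactly one observation, pairs at >= K to none."""
        rng = np.random.default_rng(seed)
        lengths = rng.integers(2_000, 80_000, size=int(rng.integers(2, 30)))
        K = float(rng.integers(10_000, 150_000))
        scaf = _scaffold(list(map(int, lengths)))
        space = build_state_space(scaf, HMMConfig(K=K, mode="adaptive", k_max=16))
        seen = [pair for obs in space.observations for pair in obs]
        assert len(seen) == len(set(seen))
        prefix = np.concatenate([[0], np.cumsum(lengths)])
        expected = {
            (i, j)
            for i in range(len(lengths))
            for j in range(i + 1, len(lengths))
            if prefix[j] - prefix[i + 1] < K
        }
        assert set(seen) | set(space.dropped_pairs) == expected

    def test_k_max_caps_window_arity(self):
        scaf = _scaffold([1_000] * 30)
        space = build_state_space(scaf, HMMConfig(K=1e8, mode="adaptive", k_max=4))
        assert max(space.arities) == 4
        assert space.dropped_pairs  # far pairs could not be scored

    def test_single_contig(self):
        scaf = _scaffold([10_000])
        space = build_state_space(scaf, HMMConfig(K=1e4))
        assert space.windows == [(0, 0)] and space.observations == [[]]

    def test_state_count_scales_as_two_to_k(self):
        scaf = _scaffold([10_000] * 12)
        for k in (2, 3, 5):
            space = build_state_space(scaf, HMMConfig(K=1e9, mode="fixed", k=k))
            store = hc.ContactStore(inter={}, intra={})
            dist = hc.power_law_distribution(1.0, 50_000)
            em = compute_emissions(space, store, dist, scaf)
            assert all(t.shape[0] == 2**k for t in em)


class TestEmissions:
    def test_no_contacts_all_zero(self, power_dist):
        scaf = _scaffold([10_000] * 5)
        space = build_state_space(scaf, HMMConfig(K=50_000, mode="fixed", k=3))
        em = compute_emissions(space, hc.ContactStore(inter={}, intra={}),
                               power_dist, scaf)
        assert all(np.all(t == 0.0) for t in em)

    def test_single_pair_broadcasts_its_four_values(self, power_dist):
        """One contact set in a k=3 window: the emission table is that
        pair's 2x2 log-likelihood broadcast over the bystander contig."""
        scaf = _scaffold([10_000] * 3)
        contacts = np.array([[9_000, 500], [8_000, 1_500]])
        store = hc.ContactStore(inter={(0, 0, 1): contacts}, intra={})
        space = build_state_space(scaf, HMMConfig(K=1e9, mode="fixed", k=3))
        em = compute_emissions(space, store, power_dist, scaf)[0]
        pl = hc.pair_log_likelihood(
            contacts, hc.PairGeometry(10_000, 10_000, 0), power_dist
        )
        states = np.arange(8)
        expect = pl.log_like[states & 1, (states >> 1) & 1]
        assert em == pytest.approx(expect)

    def test_terms_match_joint_probability(self, power_dist):
        """Summing the emissions of the true orientations' restriction
        reproduces the joint log-probability term by term."""
        inst = small_instance(3)
        layout = inst.scrambled_layout
        scaf = layout.scaffolds[0]
        cfg = HMMConfig(K=power_dist.K, mode="adaptive", k_max=16)
        space = build_state_space(scaf, cfg)
        assert not space.dropped_pairs
        em = compute_emissions(space, inst.store, power_dist, scaf)
        theta = scaf.orientations
        total = scaf.n * LOG_HALF
        for (a, b), table in zip(space.windows, em):
            s = 0
            for q in range(b - a + 1):
                s |= int(theta[a + q]) << q
            total += table[s]
        joint = joint_log_probability(layout, inst.store, power_dist, theta)
        assert total == pytest.approx(joint, abs=1e-9)


class TestViterbi:
    def test_three_window_sketch_decodes_overlapping_maxima(self):
        """Engineered emissions whose per-window maxima are (+,-,-),
        (-,-,+) and (-,+,-) decode to the consistent path (+,-,-,+,-)."""
        scaf = _scaffold([10_000] * 5)
        space = build_state_space(scaf, HMMConfig(K=1e9, mode="fixed", k=3))
        targets = [0b110, 0b011, 0b101]  # bit q = window contig q, 1 = '-'
        emissions = []
        for t in targets:
            table = np.full(8, -10.0)
            table[t] = 0.0
            emissions.append(table)
        ov = viterbi(space, emissions, HMMConfig(K=1e9, mode="fixed", k=3),
                     np.zeros(5, dtype=np.uint8))
        assert list(ov.orientations) == [0, 1, 1, 0, 1]

    def test_all_zero_emissions_return_input(self):
        scaf = _scaffold([10_000] * 6, "+-+-+-")
        cfg = HMMConfig(K=1e9, mode="fixed", k=3)
        space = build_state_space(scaf, cfg)
        em = [np.zeros(2**m) for m in space.arities]
        ov = viterbi(space, em, cfg, scaf.orientations)
        assert np.array_equal(ov.orientations, scaf.orientations)
        assert not ov.flip_mask.any()

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_argmax(self, seed, power_dist):
        """Viterbi equals brute-force argmax over all 2^n orientation
        vectors under the identical tie policy."""
        inst = small_instance(seed)
        layout = inst.scrambled_layout
        scaf = layout.scaffolds[0]
        cfg = HMMConfig(K=power_dist.K, mode="adaptive", k_max=16)
        space = build_state_space(scaf, cfg)
        em = compute_emissions(space, inst.store, power_dist, scaf)
        ov = viterbi(space, em, cfg, scaf.orientations)
        brute = exhaustive_decode(layout, inst.store, power_dist)
        assert np.array_equal(ov.orientations, brute)

    def test_decode_invariant_to_constant_emission_shift(self, power_dist):
        inst = small_instance(2)
        scaf = inst.scrambled_layout.scaffolds[0]
        cfg = HMMConfig(K=power_dist.K, mode="adaptive")
        space = build_state_space(scaf, cfg)
        em = compute_emissions(space, inst.store, power_dist, scaf)
        ov1 = viterbi(space, em, cfg, scaf.orientations)
        shifted = [t + 137.5 for t in em]
        ov2 = viterbi(space, shifted, cfg, scaf.orientations)
        assert np.array_equal(ov1.orientations, ov2.orientations)

    def test_decode_invariant_to_include_Z(self, fitted_dist):
        """Z is identical across orientation cases, so including it cannot
        change any decision."""
        inst = small_instance(4)
        scaf = inst.scrambled_layout.scaffolds[0]
        cfg = HMMConfig(K=fitted_dist.K, mode="adaptive")
        space = build_state_space(scaf, cfg)
        em_no = compute_emissions(space, inst.store, fitted_dist, scaf)
        em_yes = compute_emissions(space, inst.store, fitted_dist, scaf,
                                   include_Z=True)
        ov_no = viterbi(space, em_no, cfg, scaf.orientations)
        ov_yes = viterbi(space, em_yes, cfg, scaf.orientations)
        assert np.array_equal(ov_no.orientations, ov_yes.orientations)

    def test_global_reversal_decodes_to_flipped_reverse(self, power_dist):
        inst = small_instance(6)
        layout = inst.scrambled_layout
        fwd = exhaustive_decode(layout, inst.store, power_dist)
        rlayout, rstore = reverse_instance(layout, inst.store)
        scaf = rlayout.scaffolds[0]
        cfg = HMMConfig(K=power_dist.K, mode="adaptive", k_max=16)
        space = build_state_space(scaf, cfg)
        em = compute_emissions(space, rstore, power_dist, scaf)
        rov = viterbi(space, em, cfg, scaf.orientations)
        assert np.array_equal(rov.orientations, (1 - fwd[::-1]).astype(np.uint8))


class TestRefine:
    def test_unscrambled_instance_needs_no_flips(self, power_dist):
        """Contacts simulated under the input orientations: refine leaves
        the layout unchanged."""
        inst = small_instance(1, flip_rate=0.0, n_contacts=8_000)
        new_layout, vectors, report = refine(
            inst.scrambled_layout, inst.store, power_dist,
            HMMConfig(K=power_dist.K),
        )
        assert not report["flipped"].any()
        assert new_layout.layout_equal(inst.truth_layout)

    def test_scrambled_instance_is_corrected(self, power_dist):
        inst = small_instance(5, flip_rate=0.4, n_contacts=8_000)
        new_layout, _, report = refine(
            inst.scrambled_layout, inst.store, power_dist,
            HMMConfig(K=power_dist.K),
        )
        assert np.array_equal(
            new_layout.all_orientations(), inst.truth_layout.all_orientations()
        )
        assert report["flipped"].sum() == inst.flip_mask.sum()

    def test_single_contig_scaffold_unchanged(self, power_dist):
        layout = hc.make_layout({"s": [("c1", 10_000, "-")]})
        store = hc.ContactStore(inter={}, intra={})
        new_layout, vectors, report = refine(layout, store, power_dist)
        assert new_layout.layout_equal(layout)
        assert report.iloc[0]["no_contacts"]
        assert report.iloc[0]["confidence"] == 0.5

    def test_contact_free_contig_keeps_input_orientation(self, power_dist):
        """A contig with no in-range contacts is left alone and flagged."""
        inst = small_instance(7, n_contacts=3_000)
        si = 0
        scaf = inst.scrambled_layout.scaffolds[si]
        # strip every contact touching the middle contig
        mid = scaf.n // 2
        inter = {
            k: v for k, v in inst.store.inter.items() if mid not in (k[1], k[2])
        }
        store = hc.ContactStore(inter=inter, intra=dict(inst.store.intra))
        _, vectors, report = refine(
            inst.scrambled_layout, store, power_dist, HMMConfig(K=power_dist.K)
        )
        row = report.iloc[mid]
        assert row["n_contacts"] == 0 and row["no_contacts"]
        assert row["output_orientation"] == row["input_orientation"]

    def test_multi_scaffold_independence(self, power_dist):
        """Two scaffolds refine to the same result as each alone."""
        a = small_instance(8, n_contacts=4_000)
        b = small_instance(9, n_contacts=4_000)
        sa = a.scrambled_layout.scaffolds[0]
        sb = b.scrambled_layout.scaffolds[0]
        merged = hc.ScaffoldLayout([
            hc.Scaffold("A", sa.contigs, sa.orientations.copy()),
            hc.Scaffold(
                "B",
                [hc.Contig("B_" + c.name, c.length, c.index) for c in sb.contigs],
                sb.orientations.copy(),
            ),
        ])
        inter = dict(a.store.inter)
        inter.update({(1, i, j): arr for (_, i, j), arr in b.store.inter.items()})
        store = hc.ContactStore(inter=inter, intra={})
        new_layout, _, _ = refine(merged, store, power_dist)
        ra, _, _ = refine(a.scrambled_layout, a.store, power_dist)
        rb, _, _ = refine(b.scrambled_layout, b.store, power_dist)
        got = new_layout.all_orientations()
        expect = np.concatenate(
            [ra.all_orientations(), rb.all_orientations()]
        )
        assert np.array_equal(got, expect)

    def test_wider_windows_do_not_hurt_recovery(self, power_dist):
        """Mean recovery with k=3 is at least that of k=2 minus a small
        seed-noise allowance (longer-range contacts add information)."""
        rec = {2: [], 3: []}
        for seed in range(6):
            inst = small_instance(
                seed + 100, genome=900_000, median=30_000, contig_min=8_000,
                n_contacts=1_500, max_contigs=40,
            )
            truth = inst.truth_layout.all_orientations()
            for k in (2, 3):
                new_layout, _, _ = refine(
                    inst.scrambled_layout, inst.store, power_dist,
                    HMMConfig(K=power_dist.K, mode="fixed", k=k),
                )
                rec[k].append(
                    float((new_layout.all_orientations() == truth).mean())
                )
        assert np.mean(rec[3]) >= np.mean(rec[2]) - 0.02
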