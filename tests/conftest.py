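"""Shared fixtures and oracle helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hicorient as hc

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_layout(rng: np.random.Generator, n_scaffolds: int = 2,
                  max_contigs: int = 8) -> hc.ScaffoldLayout:
    """A random multi-scaffold layout with heterogeneous lengths."""
    spec = {}
    cid = 0
    for s in range(n_scaffolds):
        n = int(rng.integers(1, max_contigs + 1))
        entries = []
        for _ in range(n):
            cid += 1
            entries.append(
                (f"ctg{cid:04d}", int(rng.integers(1_000, 200_000)),
                 "+-"[int(rng.integers(0, 2))])
            )
        spec[f"scaf{s + 1}"] = entries
    return hc.make_layout(spec)


def reverse_instance(layout: hc.ScaffoldLayout, store: hc.ContactStore):
    """Reverse every scaffold's contig order, flip all orientations and
    remap the contacts accordingly (x/y swap, indices mirrored)."""
    scaffolds = []
    for scaf in layout.scaffolds:
        contigs = [
            hc.Contig(c.name, c.length, scaf.n - c.index + 1)
            for c in reversed(scaf.contigs)
        ]
        orients = (1 - scaf.orientations[::-1]).astype(np.uint8)
        scaffolds.append(hc.Scaffold(scaf.name, contigs, orients))
    new_layout = hc.ScaffoldLayout(scaffolds, gap_length=layout.gap_length)
    inter = {}
    for (si, i, j), arr in store.inter.items():
        n = layout.scaffolds[si].n
        ni, nj = n - 1 - j, n - 1 - i
        inter[(si, ni, nj)] = arr[:, ::-1].copy()
    new_store = hc.ContactStore(inter=inter, intra=dict(store.intra))
    return new_layout, new_store


def small_instance(seed: int, genome: int = 600_000, median: float = 70_000,
                   contig_min: int = 25_000, n_contacts: int = 3_000,
                   flip_rate: float = 0.4, d_cap: float = 300_000,
                   max_contigs: int = 10) -> hc.SimulatedInstance:
    """A simulated instance small enough for exhaustive 2^n decoding.

    Seeds are scanned deterministically until the contig count fits the cap.
    """
    s = seed
    while True:
        inst = hc.simulate_instance(
            hc.SimulationConfig(
                genome_length=genome, contig_median=median,
                contig_min=contig_min, n_contacts=n_contacts,
                flip_rate=flip_rate, d_cap=d_cap, seed=s,
            )
        )
        if inst.truth_layout.n_contigs <= max_contigs:
            return inst
        s += 10_000


@pytest.fixture(scope="session")
def power_dist() -> hc.ContactDistribution:
    """Analytic power-law decay curve used as a known-truth score."""
    return hc.power_law_distribution(c2=1.0, K=100_000, d_min=1_000)


@pytest.fixture(scope="session")
def fitted_dist() -> hc.ContactDistribution:
    """A curve fitted from simulated intra-contig distances."""
    rng = np.random.default_rng(42)
    d = 1_000.0 * (1_000_000.0 / 1_000.0) ** rng.random(50_000)  # c2 = 1
    K = hc.select_K(d)
    return hc.estimate_distribution(d, K)
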