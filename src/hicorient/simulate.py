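"""Ground-truthed synthetic scaffolding instances.

The simulator emulates the data regime this method targets: a chromosome
tiled by short-read-scale contigs of heterogeneous (log-normal) length,
shallow Hi-C coverage whose contact separation distances follow a
truncated power-law decay d^(-c2), and an input layout in which a
controllable fraction of contigs has been flipped.  Contacts are generated
in genome space and then mapped through the truth orientations into each
contig's native frame, so at high contact density the truth orientation
vector is exactly the maximum-likelihood target.

It does not emulate read-level artifacts (FASTQ, restriction-site
placement) or three-dimensional structure (TADs, loops, GC/mappability
bias): contact placement depends on separation distance only.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import integrate

from .core import ContactStore, Contig, Scaffold, ScaffoldLayout, orientation_char

SCAFFOLD_NAME = "sim_scaffold"


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions for one synthetic instance.

    Defaults mirror the short-read + shallow-Hi-C regime the method was
    designed for: a 10 Mb chromosome, log-normal contig lengths with median
    50 kb (N50 in the tens of kb), decay exponent 1.0 truncated to
    [1 kb, 1 Mb], 1e5 contacts and 30% of input orientations flipped.
    ``intra_fraction`` optionally forces the fraction of same-contig pairs
    by class-quota resampling of the same genome-space process; by default
    the split is whatever the geometry produces.
    """

    genome_length: int = 10_000_000
    contig_median: float = 50_000.0
    contig_sigma: float = 0.6
    contig_min: int = 5_000
    c2_true: float = 1.0
    d_min: float = 1_000.0
    d_cap: float = 1_000_000.0
    n_contacts: int = 100_000
    intra_fraction: float | None = None
    flip_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < self.contig_min:
            raise ValueError("genome shorter than the minimum contig length")
        if not 0.0 <= self.flip_rate <= 1.0:
            raise ValueError("flip_rate must be in [0, 1]")
        if self.n_contacts < 0:
            raise ValueError("n_contacts must be >= 0")
        if self.d_min <= 0 or self.d_cap <= self.d_min:
            raise ValueError("need 0 < d_min < d_cap")
        if self.d_cap >= self.genome_length:
            raise ValueError("d_cap must be smaller than the genome length")


@dataclasses.dataclass
class SimulatedInstance:
    """Everything a test or benchmark needs about one synthetic scaffold."""

    truth_layout: ScaffoldLayout
    store: ContactStore
    scrambled_layout: ScaffoldLayout
    truth_table: pd.DataFrame
    flip_mask: np.ndarray
    pair_records: list[tuple[str, int, str, int]]
    config: SimulationConfig


def _draw_contig_lengths(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Partition [0, genome_length) into contigs by the log-normal law.

    The last contig is truncated to fit; if that leaves it below the
    minimum length it is merged into its predecessor, so lengths always sum
    exactly to the genome length.
    """
    lengths: list[int] = []
    total = 0
    mu = math.log(cfg.contig_median)
    while total < cfg.genome_length:
        ln = max(cfg.contig_min, int(round(rng.lognormal(mu, cfg.contig_sigma))))
        if total + ln >= cfg.genome_length:
            ln = cfg.genome_length - total
            if ln < cfg.contig_min and lengths:
                lengths[-1] += ln
            else:
                lengths.append(ln)
            total = cfg.genome_length
        else:
            lengths.append(ln)
            total += ln
    return np.array(lengths, dtype=np.int64)


def _sample_truncated_power_law(
    cfg: SimulationConfig, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Inverse-CDF sampling of separation distances with density
    proportional to d^(-c2) on [d_min, d_cap]."""
    u = rng.random(size)
    if abs(cfg.c2_true - 1.0) < 1e-12:
        return cfg.d_min * (cfg.d_cap / cfg.d_min) ** u
    e = 1.0 - cfg.c2_true
    return (cfg.d_min**e + u * (cfg.d_cap**e - cfg.d_min**e)) ** (1.0 / e)


def simulate_instance(config: SimulationConfig | None = None) -> SimulatedInstance:
    """Generate one ground-truthed instance, fully reproducible from the seed."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)

    lengths = _draw_contig_lengths(cfg, rng)
    n = lengths.size
    starts = np.concatenate([[0], np.cumsum(lengths)])[:-1]
    names = [f"ctg{i + 1:05d}" for i in range(n)]
    truth_theta = rng.integers(0, 2, size=n).astype(np.uint8)

    def draw_batch(size: int):
        d = _sample_truncated_power_law(cfg, size, rng)
        left = rng.random(size) * (cfg.genome_length - d)
        p1 = np.floor(left).astype(np.int64)
        p2 = np.floor(left + d).astype(np.int64)
        p2 = np.minimum(p2, cfg.genome_length - 1)
        c1 = np.searchsorted(starts, p1, side="right") - 1
        c2 = np.searchsorted(starts, p2, side="right") - 1
        return p1, p2, c1, c2

    intra_records: list[tuple[int, int, int]] = []  # contig, off1, off2 (native)
    inter_records: list[tuple[int, int, int, int]] = []  # ci, cj, x, y

    def to_native(contig: int, genome_pos: int) -> int:
        off = genome_pos - starts[contig]
        if truth_theta[contig]:
            off = lengths[contig] - 1 - off
        return int(off)

    def accept(p1, p2, c1, c2, quota_intra, quota_inter):
        for a, b, ca, cb in zip(p1, p2, c1, c2):
            if ca == cb:
                if quota_intra is not None and len(intra_records) >= quota_intra:
                    continue
                intra_records.append((ca, to_native(ca, a), to_native(ca, b)))
            else:
                if quota_inter is not None and len(inter_records) >= quota_inter:
                    continue
                i, j = (ca, cb) if ca < cb else (cb, ca)
                x = to_native(i, a if ca < cb else b)
                y = to_native(j, b if ca < cb else a)
                inter_records.append((i, j, x, y))

    if cfg.n_contacts > 0:
        if cfg.intra_fraction is None:
            accept(*draw_batch(cfg.n_contacts), None, None)
        else:
            quota_intra = int(round(cfg.intra_fraction * cfg.n_contacts))
            quota_inter = cfg.n_contacts - quota_intra
            while len(intra_records) < quota_intra or len(inter_records) < quota_inter:
                accept(*draw_batch(cfg.n_contacts), quota_intra, quota_inter)

    flip_mask = rng.random(n) < cfg.flip_rate
    scrambled_theta = (truth_theta ^ flip_mask.astype(np.uint8)).astype(np.uint8)

    contigs = [Contig(names[i], int(lengths[i]), i + 1) for i in range(n)]
    truth_layout = ScaffoldLayout(
        [Scaffold(SCAFFOLD_NAME, contigs, truth_theta.copy())]
    )
    scrambled_layout = ScaffoldLayout(
        [Scaffold(SCAFFOLD_NAME, list(contigs), scrambled_theta)]
    )

    inter: dict[tuple[int, int, int], list[tuple[int, int]]] = {}
    for i, j, x, y in inter_records:
        inter.setdefault((0, i, j), []).append((x, y))
    intra: dict[str, list[int]] = {}
    for c, o1, o2 in intra_records:
        intra.setdefault(names[c], []).append(abs(o1 - o2))
    store = ContactStore(
        inter={k: np.array(v, dtype=np.int64) for k, v in inter.items()},
        intra={k: np.array(v, dtype=np.int64) for k, v in intra.items()},
        filters_applied={"source": "simulated", "seed": cfg.seed},
    )

    truth_table = pd.DataFrame(
        {
            "contig": names,
            "rank": np.arange(1, n + 1),
            "orientation": [orientation_char(t) for t in truth_theta],
        }
    )
    pair_records = [
        (names[c], o1, names[c], o2) for c, o1, o2 in intra_records
    ] + [(names[i], x, names[j], y) for i, j, x, y in inter_records]

    return SimulatedInstance(
        truth_layout=truth_layout,
        store=store,
        scrambled_layout=scrambled_layout,
        truth_table=truth_table,
        flip_mask=flip_mask,
        pair_records=pair_records,
        config=cfg,
    )


def expected_pair_counts(
    truth_layout: ScaffoldLayout, config: SimulationConfig
) -> dict[tuple[int, int], float]:
    """Analytic expected |R_ij| per contig pair under the sampling process.

    For a pair at intervening distance D the number of genome positions
    producing a contact at total separation u is the same 1-D overlap
    kernel used by the likelihood normalization integral, so
    E|R_ij| = n_contacts * \\int f(u) * overlap(u) / (G - u) du with f the
    truncated power-law density.  Pairs with no overlap of the support
    (gap beyond d_cap) get expectation 0.
    """
    cfg = config
    scaf = truth_layout.scaffolds[0]
    lengths = scaf.lengths
    prefix = np.concatenate([[0], np.cumsum(lengths)])
    G = float(cfg.genome_length)

    if abs(cfg.c2_true - 1.0) < 1e-12:
        norm = math.log(cfg.d_cap / cfg.d_min)
    else:
        e = 1.0 - cfg.c2_true
        norm = (cfg.d_cap**e - cfg.d_min**e) / e

    out: dict[tuple[int, int], float] = {}
    for i in range(scaf.n):
        for j in range(i + 1, scaf.n):
            D = float(prefix[j] - prefix[i + 1])
            Li, Lj = float(lengths[i]), float(lengths[j])
            lo = max(cfg.d_min, D)
            hi = min(cfg.d_cap, D + Li + Lj)
            if hi <= lo:
                out[(i, j)] = 0.0
                continue

            def integrand(u: float) -> float:
                ov = min(u - D, Li, Lj, Li + Lj + D - u)
                if ov <= 0:
                    return 0.0
                return u ** (-cfg.c2_true) / norm * ov / (G - u)

            pts = sorted(
                p for p in (D + min(Li, Lj), D + max(Li, Lj)) if lo < p < hi
            )
            val, _ = integrate.quad(integrand, lo, hi, points=pts or None, limit=200)
            out[(i, j)] = cfg.n_contacts * val
    return out


def write_instance(
    instance: SimulatedInstance,
    outdir,
    fasta: bool = False,
) -> dict[str, str]:
    """Write the scrambled layout (AGP), contacts (pairs4 dialect), truth
    table (TSV) and optionally a random contig FASTA to a directory."""
    from pathlib import Path

    from . import formats_io
    from .diagnostics import write_truth_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "layout": str(outdir / "scrambled_layout.agp"),
        "contacts": str(outdir / "contacts.pairs"),
        "truth": str(outdir / "truth.tsv"),
    }
    formats_io.write_layout(instance.scrambled_layout, None, paths["layout"], "agp")
    with open(paths["contacts"], "w") as fh:
        fh.write("# name1 pos1 name2 pos2 (0-based native offsets)\n")
        for n1, p1, n2, p2 in instance.pair_records:
            fh.write(f"{n1}\t{p1}\t{n2}\t{p2}\n")
    write_truth_table(instance.truth_table, paths["truth"])
    if fasta:
        rng = np.random.default_rng(instance.config.seed + 1)
        paths["fasta"] = str(outdir / "contigs.fasta")
        with open(paths["fasta"], "w") as fh:
            for _, _, contig, _ in instance.truth_layout.iter_contigs():
                seq = "".join(rng.choice(list("ACGT"), size=contig.length))
                fh.write(f">{contig.name}\n")
                for s in range(0, len(seq), 80):
                    fh.write(seq[s : s + 80] + "\n")
    return paths
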