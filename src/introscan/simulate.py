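"""Synthetic genotype panels with known introgression truth.

Two diverged gene pools — a landrace-like donor pool and a cultivar
background — are generated under the Balding–Nichols construction: each
site's ancestral alt-allele frequency p is drawn uniformly (default on
[0.05, 0.95]) and each pool's frequency from a Beta distribution with mean p
and variance F·p·(1-p) (shapes p(1-F)/F and (1-p)(1-F)/F), so the expected
differentiation between the pools equals the target F.  Individual diploid
genotypes are Hardy–Weinberg binomial draws from the pool frequency; carrier
receptors draw from the donor frequency inside their implanted tracts and
from the background frequency elsewhere.  Sites are independent (no LD)
unless block-copy mode is enabled.  Missing calls are inserted uniformly at
random.  Everything is reproducible from a single seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import (
    MISSING,
    GenomeWindow,
    GenotypeMatrix,
    SampleGrouping,
    write_bed,
    write_group_table,
    write_vcf,
)
from .introgression import IntrogressionFragment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TractSpec:
    """An introgressed interval to implant: 0-based half-open, one carrier."""

    receptor: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid tract [{self.start}, {self.end})")


#: Ground-truth introgressed interval, as recovered-against truth.
TractTruth = TractSpec


@dataclass
class SimulationConfig:
    """Parameters of the two-pool introgression scenario.

    Defaults are the package's standard scenario: strongly diverged pools
    (F = 0.5), 50 donors, 300 background accessions, 10 receptor carriers
    each with one 3 Mb tract on a 30 Mb chromosome at 100 SNPs/Mb, and 5%
    missing calls — the regime in which a 1 Mb-window identity scan at
    threshold 0.15 should recover tracts essentially perfectly.
    """

    n_donor: int = 50
    n_acceptor: int = 300
    n_receptor_carrier: int = 10
    n_receptor_background: int = 0
    chrom_length: int = 30_000_000
    chrom_name: str = "A06"
    snp_density: float = 100.0  # SNPs per Mb
    differentiation: float = 0.5  # target Fst between pools
    anc_freq_range: tuple[float, float] = (0.05, 0.95)
    tracts: list[TractSpec] | None = None  # None -> one random 3 Mb tract/carrier
    tract_length: int = 3_000_000
    align_tracts_to: int = 1_000_000  # tract starts snap to this grid
    missing_rate: float = 0.05
    het_inflation: float = 0.0  # extra het probability inside tracts
    block_copy: bool = False  # reuse the carrier draw across a window (LD mimic)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.differentiation < 1.0:
            raise ValueError("differentiation F must be in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        lo, hi = self.anc_freq_range
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("anc_freq_range must satisfy 0 < lo < hi < 1")
        for n in (self.n_donor, self.n_acceptor):
            if n < 1:
                raise ValueError("pool sizes must be >= 1")
        if self.tracts:
            for t in self.tracts:
                if t.chrom == self.chrom_name and t.end > self.chrom_length:
                    raise ValueError(f"tract {t} exceeds chromosome bounds")


def standard_scenario(seed: int = 0) -> SimulationConfig:
    """The canonical recovery scenario (see :class:`SimulationConfig`)."""
    return SimulationConfig(seed=seed)


# -- frequency draws ---------------------------------------------------------------


def draw_pool_frequencies(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (positions, p_donor, p_background).

    Positions are 1-based, strictly increasing, with expected density
    ``snp_density`` per Mb.  Each pool frequency is an independent
    Balding–Nichols Beta draw around the shared ancestral frequency.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_sites = int(round(config.snp_density * config.chrom_length / 1e6))
    if n_sites > config.chrom_length:
        raise ValueError("snp_density too high for chromosome length")
    positions = np.sort(
        rng.choice(config.chrom_length, size=n_sites, replace=False)
    ) + 1  # 1-based

    lo, hi = config.anc_freq_range
    p_anc = rng.uniform(lo, hi, size=n_sites)
    F = config.differentiation
    shape_a = p_anc * (1.0 - F) / F
    shape_b = (1.0 - p_anc) * (1.0 - F) / F
    p_donor = rng.beta(shape_a, shape_b)
    p_background = rng.beta(shape_a, shape_b)
    return positions, p_donor, p_background


# -- genotype simulation -----------------------------------------------------------


def _default_tracts(config: SimulationConfig, rng: np.random.Generator,
                    carriers: Sequence[str]) -> list[TractSpec]:
    """One tract per carrier, start snapped to the window grid."""
    grid = config.align_tracts_to
    tract_len = min(config.tract_length, config.chrom_length)
    n_slots = (config.chrom_length - tract_len) // grid + 1
    starts = rng.integers(0, n_slots, size=len(carriers)) * grid
    return [
        TractSpec(c, config.chrom_name, int(s), int(s) + tract_len)
        for c, s in zip(carriers, starts)
    ]


def simulate_genotypes(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, SampleGrouping, list[TractTruth]]:
    """Draw the full panel: donors, background, receptors, tract truth.

    Returns the genotype matrix, a grouping with roles pre-declared
    (donors = ``donor``, acceptor = ``background``, receptors =
    ``receptor``), and the list of implanted tracts.
    """
    rng = np.random.default_rng(config.seed)
    positions, p_d, p_b = draw_pool_frequencies(config, rng)
    n_sites = len(positions)

    donors = [f"D{i + 1:03d}" for i in range(config.n_donor)]
    acceptors = [f"B{i + 1:03d}" for i in range(config.n_acceptor)]
    carriers = [f"R{i + 1:03d}" for i in range(config.n_receptor_carrier)]
    rec_bg = [f"N{i + 1:03d}" for i in range(config.n_receptor_background)]
    samples = donors + acceptors + carriers + rec_bg

    tracts = config.tracts
    if tracts is None:
        tracts = _default_tracts(config, rng, carriers)
    receptor_names = set(carriers) | set(rec_bg)
    for t in tracts:
        if t.receptor not in receptor_names:
            raise ValueError(f"tract references unknown receptor {t.receptor!r}")

    calls = np.empty((n_sites, len(samples)), dtype=np.int8)
    col = 0
    for _ in donors:
        calls[:, col] = rng.binomial(2, p_d)
        col += 1
    for _ in acceptors:
        calls[:, col] = rng.binomial(2, p_b)
        col += 1

    tract_sites: dict[str, np.ndarray] = {}
    for name in carriers + rec_bg:
        in_tract = np.zeros(n_sites, dtype=bool)
        for t in tracts:
            if t.receptor == name and t.chrom == config.chrom_name:
                in_tract |= (positions - 1 >= t.start) & (positions - 1 < t.end)
        tract_sites[name] = in_tract
        p_mix = np.where(in_tract, p_d, p_b)
        if config.block_copy:
            gt = _block_copy_draw(rng, p_mix, positions, config.align_tracts_to)
        else:
            gt = rng.binomial(2, p_mix)
        if config.het_inflation > 0:
            flip = in_tract & (rng.random(n_sites) < config.het_inflation)
            gt = np.where(flip, 1, gt)
        calls[:, col] = gt
        col += 1

    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls[mask] = MISSING

    matrix = GenotypeMatrix(
        chrom=[config.chrom_name] * n_sites,
        pos=positions,
        ref=["A"] * n_sites,
        alt=["G"] * n_sites,
        samples=samples,
        calls=calls,
    )
    assignments = {s: "donor" for s in donors}
    assignments.update({s: "background" for s in acceptors})
    assignments.update({s: "receptor" for s in carriers + rec_bg})
    grouping = SampleGrouping(
        assignments,
        donor_labels=("donor",),
        acceptor_label="background",
        receptor_labels=("receptor",),
    )
    logger.info("simulate_genotypes: %d sites x %d samples, %d tracts, F=%g",
                n_sites, len(samples), len(tracts), config.differentiation)
    return matrix, grouping, list(tracts)


def _block_copy_draw(rng, p_mix, positions, block):
    """Draw one genotype per block and copy it across the block's sites."""
    block_of = (positions - 1) // block
    gt = np.empty(len(positions), dtype=np.int8)
    for b in np.unique(block_of):
        sel = block_of == b
        first = np.nonzero(sel)[0][0]
        gt[sel] = rng.binomial(2, p_mix[first])
    return gt


def write_simulation(
    config: SimulationConfig, out_prefix: str | Path
) -> tuple[Path, Path, Path]:
    """Run the simulator and write <prefix>.vcf, <prefix>.groups.tsv,
    <prefix>.truth.bed; returns the three paths."""
    matrix, grouping, truths = simulate_genotypes(config)
    vcf = Path(f"{out_prefix}.vcf")
    groups = Path(f"{out_prefix}.groups.tsv")
    bed = Path(f"{out_prefix}.truth.bed")
    write_vcf(matrix, vcf)
    write_group_table(grouping, groups)

    @dataclass(frozen=True)
    class _Row:
        chrom: str
        start: int
        end: int
        name: str
        score: float = 0.0

    write_bed([_Row(t.chrom, t.start, t.end, t.receptor) for t in truths], bed)
    return vcf, groups, bed


# -- recovery evaluation -----------------------------------------------------------


@dataclass(frozen=True)
class RecoveryMetrics:
    """Window-level confusion summary of a scan against the implanted truth.

    ``recall`` is NaN (flagged undefined) when there are no truth windows;
    ``boundary_error`` is the mean absolute offset, in window units, between
    the edges of each truth tract and its best-overlapping detected
    fragment (tracts with no overlapping fragment are excluded — they are
    already charged to recall).
    """

    precision: float
    recall: float
    boundary_error: float
    tp: int
    fp: int
    fn: int


def evaluate_recovery(
    truths: Sequence[TractTruth],
    fragments: Sequence[IntrogressionFragment],
    windows: Sequence[GenomeWindow],
) -> RecoveryMetrics:
    """Score detected fragments against truth tracts at window resolution.

    A truth window for a receptor is any window overlapping one of that
    receptor's truth tracts; a detected window is any window overlapped by
    one of its fragments (donor labels pooled).  Confusion counts are summed
    over all receptors appearing in either set.
    """
    windows = sorted(windows, key=lambda w: (w.chrom, w.start))
    width = max((w.span for w in windows), default=1)

    def overlapping(chrom: str, start: int, end: int) -> set[int]:
        return {i for i, w in enumerate(windows) if w.overlaps(chrom, start, end)}

    truth_by_rec: dict[str, set[int]] = {}
    for t in truths:
        truth_by_rec.setdefault(t.receptor, set()).update(
            overlapping(t.chrom, t.start, t.end))
    det_by_rec: dict[str, set[int]] = {}
    for f in fragments:
        det_by_rec.setdefault(f.receptor, set()).update(
            overlapping(f.chrom, f.start, f.end))

    tp = fp = fn = 0
    for rec in set(truth_by_rec) | set(det_by_rec):
        t_win = truth_by_rec.get(rec, set())
        d_win = det_by_rec.get(rec, set())
        tp += len(t_win & d_win)
        fp += len(d_win - t_win)
        fn += len(t_win - d_win)

    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    recall = tp / (tp + fn) if (tp + fn) else float("nan")

    edge_errors: list[float] = []
    for t in truths:
        best = None
        best_ov = 0
        for f in fragments:
            if f.receptor != t.receptor or f.chrom != t.chrom:
                continue
            ov = min(f.end, t.end) - max(f.start, t.start)
            if ov > best_ov:
                best, best_ov = f, ov
        if best is not None:
            err = (abs(best.start - t.start) + abs(best.end - t.end)) / 2.0
            edge_errors.append(err / width)
    boundary_error = float(np.mean(edge_errors)) if edge_errors else float("nan")
    return RecoveryMetrics(precision, recall, boundary_error, tp, fp, fn)
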