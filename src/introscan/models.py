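"""Model-style front door: scan objects whose ``fit()`` returns results.

`FstScan` and `IntrogressionScan` wrap the functional layer the way a
statistical model wraps its estimator: construct from data (a
:class:`~introscan.io.GenotypeMatrix` plus grouping, or straight from
files), call :meth:`fit`, and read estimates, diagnostics and a
``summary()`` table off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import introgression as _intro
from . import popgen as _popgen
from .io import (
    GenomeWindow,
    GenotypeMatrix,
    SampleGrouping,
    read_group_table,
    read_vcf,
    windows_for_matrix,
)


def _stats_frame(stats: Sequence[_popgen.WindowStat]) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": [ws.window.chrom for ws in stats],
        "start": [ws.window.start for ws in stats],
        "end": [ws.window.end for ws in stats],
        "value": [ws.value for ws in stats],
        "n_sites": [ws.n_sites for ws in stats],
    })


class FstScan:
    """Windowed two-population Fst genome scan.

    Parameters
    ----------
    genotypes : GenotypeMatrix
    group1_samples, group2_samples : sequences of sample ids
    window_size : window width in bp (default 1 Mb, tiled from 0)

    ``fit(quantile=0.99)`` computes per-window Weir–Cockerham Fst (weighted
    ratio of sums), the genome-wide weighted estimate, and calls divergent
    regions above the empirical quantile threshold.
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        group1_samples: Sequence[str],
        group2_samples: Sequence[str],
        window_size: int = 1_000_000,
        windows: Sequence[GenomeWindow] | None = None,
    ) -> None:
        if not group1_samples or not group2_samples:
            raise ValueError("both groups must be non-empty")
        overlap = set(group1_samples) & set(group2_samples)
        if overlap:
            raise ValueError(f"groups overlap: {sorted(overlap)[:3]}")
        self.genotypes = genotypes
        self.group1_samples = list(group1_samples)
        self.group2_samples = list(group2_samples)
        self.window_size = window_size
        self.windows = (list(windows) if windows is not None
                        else windows_for_matrix(genotypes, window_size))

    @classmethod
    def from_files(
        cls,
        vcf_path: str | Path,
        groups_path: str | Path,
        group1: str,
        group2: str,
        window_size: int = 1_000_000,
    ) -> "FstScan":
        matrix = read_vcf(vcf_path)
        grouping = read_group_table(groups_path)
        grouping.validate_against(matrix)
        return cls(matrix, grouping.samples_in(group1),
                   grouping.samples_in(group2), window_size)

    def fit(self, quantile: float = 0.99,
            threshold: float | None = None) -> "FstScanResults":
        window_stats = _popgen.windowed_fst(
            self.genotypes, self.group1_samples, self.group2_samples, self.windows)
        regions, realized = _popgen.call_divergent_regions(
            window_stats, quantile=quantile, threshold=threshold)
        gw = _popgen.genomewide_fst(
            self.genotypes, self.group1_samples, self.group2_samples)
        return FstScanResults(self, window_stats, gw, quantile, realized, regions)


@dataclass
class FstScanResults:
    model: FstScan
    window_stats: list[_popgen.WindowStat]
    genomewide_fst: float
    quantile: float
    threshold: float
    divergent_regions: list[_popgen.DivergentRegion]

    def to_frame(self) -> pd.DataFrame:
        return _stats_frame(self.window_stats).rename(columns={"value": "fst"})

    def regions_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": [r.chrom for r in self.divergent_regions],
            "start": [r.start for r in self.divergent_regions],
            "end": [r.end for r in self.divergent_regions],
            "mean_fst": [r.mean_stat for r in self.divergent_regions],
            "n_windows": [r.n_windows for r in self.divergent_regions],
        })

    def summary(self) -> str:
        vals = np.array([ws.value for ws in self.window_stats])
        defined = vals[~np.isnan(vals)]
        lines = [
            "Windowed Fst scan (Weir & Cockerham theta, ratio of sums)",
            "=" * 58,
            f"groups:             {len(self.model.group1_samples)} vs "
            f"{len(self.model.group2_samples)} samples",
            f"window size:        {self.model.window_size:,} bp",
            f"windows (defined):  {len(self.window_stats)} ({len(defined)})",
            f"genome-wide Fst:    {self.genomewide_fst:.4f}",
            f"quantile threshold: {self.threshold:.4f} "
            f"(top {100 * (1 - self.quantile):g}%)",
            f"divergent regions:  {len(self.divergent_regions)}",
        ]
        for r in self.divergent_regions:
            lines.append(
                f"  {r.chrom}:{r.start:,}-{r.end:,}  mean Fst {r.mean_stat:.3f}"
                f"  ({r.n_windows} windows)")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Genome-track plot of windowed Fst with the threshold line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        df = self.to_frame()
        offset = 0
        for chrom, sub in df.groupby("chrom", sort=False):
            mid = (sub["start"] + sub["end"]) / 2 + offset
            ax.plot(mid, sub["fst"], ".-", ms=3, label=chrom)
            offset += sub["end"].max()
        ax.axhline(self.threshold, color="red", lw=0.8, ls="--")
        ax.set_xlabel("genome position (bp, concatenated)")
        ax.set_ylabel("windowed Fst")
        return ax


class IntrogressionScan:
    """Per-accession genotype-identity introgression scan.

    Scans each receptor against each donor lineage and the acceptor
    background with the windowed introgressive index
    ISC_D/VSC_D - ISC_A/VSC_A, screening fragments where the index exceeds
    ``threshold`` (default 0.15).
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        grouping: SampleGrouping,
        window_size: int = 1_000_000,
        threshold: float = 0.15,
        exclude_receptor_from_acceptor: bool = True,
        merge_gap: int = 0,
    ) -> None:
        self.genotypes = genotypes
        self.grouping = grouping
        self.window_size = window_size
        self.threshold = threshold
        self.exclude_receptor_from_acceptor = exclude_receptor_from_acceptor
        self.merge_gap = merge_gap

    @classmethod
    def from_files(
        cls,
        vcf_path: str | Path,
        groups_path: str | Path,
        donors: Sequence[str],
        acceptor: str,
        receptors: Sequence[str],
        **kwargs,
    ) -> "IntrogressionScan":
        matrix = read_vcf(vcf_path)
        grouping = read_group_table(groups_path).with_roles(
            donors, acceptor, receptors)
        grouping.validate_against(matrix)
        return cls(matrix, grouping, **kwargs)

    def fit(self) -> "IntrogressionScanResults":
        profiles = _intro.scan_receptors(
            self.genotypes, self.grouping,
            window_size=self.window_size, threshold=self.threshold,
            exclude_receptor_from_acceptor=self.exclude_receptor_from_acceptor,
            merge_gap=self.merge_gap,
        )
        return IntrogressionScanResults(self, profiles)


@dataclass
class IntrogressionScanResults:
    model: IntrogressionScan
    profiles: list[_intro.IntrogressionProfile]

    @property
    def fragments(self) -> list[_intro.IntrogressionFragment]:
        return [f for p in self.profiles for f in p.fragments]

    def to_frame(self) -> pd.DataFrame:
        """Long-format window table: one row per (receptor, donor, window)."""
        rows = []
        for p in self.profiles:
            for i, ws in enumerate(p.window_stats):
                rows.append((
                    p.receptor, p.donor, ws.window.chrom,
                    ws.window.start, ws.window.end,
                    int(p.isc_donor[i]), int(p.vsc_donor[i]),
                    int(p.isc_acceptor[i]), int(p.vsc_acceptor[i]),
                    ws.value,
                ))
        return pd.DataFrame(rows, columns=[
            "receptor", "donor", "chrom", "start", "end",
            "isc_D", "vsc_D", "isc_A", "vsc_A", "index",
        ])

    def fragments_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "receptor": [f.receptor for f in self.fragments],
            "donor": [f.donor for f in self.fragments],
            "chrom": [f.chrom for f in self.fragments],
            "start": [f.start for f in self.fragments],
            "end": [f.end for f in self.fragments],
            "mean_index": [f.mean_index for f in self.fragments],
            "n_windows": [f.n_windows for f in self.fragments],
        })

    def summary(self) -> str:
        n_rec = len({p.receptor for p in self.profiles})
        donors = sorted({p.donor for p in self.profiles})
        lines = [
            "Introgression scan (windowed ISC/VSC identity index)",
            "=" * 54,
            f"receptors:        {n_rec}",
            f"donor groups:     {', '.join(donors)}",
            f"window size:      {self.model.window_size:,} bp",
            f"screen threshold: index > {self.model.threshold:g}",
            f"fragments:        {len(self.fragments)}",
        ]
        by_rec: dict[str, int] = {}
        for f in self.fragments:
            by_rec[f.receptor] = by_rec.get(f.receptor, 0) + 1
        for rec in sorted(by_rec):
            lines.append(f"  {rec}: {by_rec[rec]} fragment(s)")
        return "\n".join(lines)

    def plot_track(self, receptor: str, ax=None):
        """Index track for one receptor, one line per donor group."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 2.5))
        for p in self.profiles:
            if p.receptor != receptor:
                continue
            mid = [(ws.window.start + ws.window.end) / 2 for ws in p.window_stats]
            ax.plot(mid, [ws.value for ws in p.window_stats], ".-", ms=3,
                    label=p.donor)
        ax.axhline(self.model.threshold, color="red", lw=0.8, ls="--")
        ax.set_ylabel("introgressive index")
        ax.set_xlabel("position (bp)")
        ax.set_title(receptor)
        ax.legend(fontsize=7)
        return ax
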