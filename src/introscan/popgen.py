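"""Nucleotide diversity, two-population windowed Fst, and divergent-region calling.

Fst uses the Weir & Cockerham (1984) theta estimator for two populations of
diploids, built from per-group sample sizes, alt-allele frequencies and
observed heterozygote frequencies.  Windowed values are the weighted
ratio-of-sums sum(a) / sum(a + b + c) over contributing sites; negative window
values are reported as computed (clamping to zero happens only in BED score
output).  Divergent regions are windows above an empirical quantile of the
windowed values, merged when contiguous on one chromosome.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import MISSING, GenomeWindow, GenotypeMatrix, assign_windows

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowStat:
    """One window's value of a genome-scan statistic.

    ``value`` is NaN when no site contributed (``n_sites == 0``) or every
    contributing denominator was zero.
    """

    window: GenomeWindow
    value: float
    n_sites: int

    @property
    def defined(self) -> bool:
        return not np.isnan(self.value)


@dataclass(frozen=True)
class DivergentRegion:
    """A maximal run of contiguous above-threshold windows."""

    chrom: str
    start: int
    end: int
    mean_stat: float
    n_windows: int

    @property
    def score(self) -> float:
        return self.mean_stat


def group_allele_counts(
    matrix: GenotypeMatrix, sample_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (n_alleles, alt_count, het_count) over a set of sample columns.

    ``n_alleles`` counts non-missing allele observations (2 per called
    diploid), so it is even (or zero).
    """
    calls = matrix.calls[:, sample_idx]
    nonmiss = calls != MISSING
    n_alleles = 2 * nonmiss.sum(axis=1)
    alt_count = np.where(nonmiss, calls, 0).sum(axis=1)
    het_count = (calls == 1).sum(axis=1)
    return n_alleles, alt_count, het_count


# -- nucleotide diversity ----------------------------------------------------------


def site_pi(n_alleles, alt_count):
    """Per-site nucleotide diversity 2j(n-j) / (n(n-1)).

    ``n_alleles`` (n) is the number of sampled alleles and ``alt_count`` (j)
    the number of alternate alleles; the value is the expected pairwise
    difference at the site, 0 for monomorphic sites, NaN where n < 2.
    Accepts scalars or arrays.
    """
    n = np.asarray(n_alleles, dtype=float)
    j = np.asarray(alt_count, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * j * (n - j) / (n * (n - 1.0))
    pi = np.where(n < 2, np.nan, pi)
    return float(pi) if pi.ndim == 0 else pi


def mean_pi(
    matrix: GenotypeMatrix,
    group_samples: Sequence[str],
    windows: Sequence[GenomeWindow] | None = None,
    per_bp: bool = False,
) -> float | list[WindowStat]:
    """Average nucleotide diversity for a group of samples.

    With ``windows=None`` returns a scalar; otherwise one :class:`WindowStat`
    per window.  Two normalizations are exposed:

    * per-variant (default): mean of site pi over sites where pi is defined.
      This is the only normalization recoverable from a SNP-only matrix.
    * ``per_bp=True``: sum of site pi divided by the window span (or, for the
      scalar, by the summed chromosome extent), the convention used for
      genome-wide diversity when the accessible length is taken as the
      window size.
    """
    if not group_samples:
        raise ValueError("empty group")
    idx = matrix.sample_indices(group_samples)
    n, j, _ = group_allele_counts(matrix, idx)
    pi = site_pi(n, j)

    if windows is None:
        defined = ~np.isnan(pi)
        if per_bp:
            span = sum(int(matrix.pos[matrix.chrom == c].max())
                       for c in matrix.chromosomes())
            return float(np.nansum(pi) / span) if span else np.nan
        return float(pi[defined].mean()) if defined.any() else np.nan

    win_of_site = assign_windows(matrix, windows)
    out: list[WindowStat] = []
    for wi, w in enumerate(windows):
        mask = (win_of_site == wi) & ~np.isnan(pi)
        k = int(mask.sum())
        if k == 0:
            out.append(WindowStat(w, np.nan, 0))
        elif per_bp:
            out.append(WindowStat(w, float(pi[mask].sum() / w.span), k))
        else:
            out.append(WindowStat(w, float(pi[mask].mean()), k))
    return out


# -- Weir & Cockerham Fst ----------------------------------------------------------


def wc_fst_components(n1, p1, h1, n2, p2, h2):
    """Weir & Cockerham (1984) variance components for two diploid samples.

    Parameters are per-group: ``n`` individuals with non-missing calls,
    ``p`` alt-allele frequency, ``h`` observed heterozygote proportion.
    Returns ``(a, d)`` with ``a`` the among-population component and
    ``d = a + b + c`` the total; the site estimate is ``a / d`` when
    ``d != 0``.  Sites where either group has no data, or both have a single
    individual, get ``(0, 0)`` and drop out of ratio-of-sums estimates.
    Accepts scalars or aligned arrays.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)

    valid = (n1 >= 1) & (n2 >= 1) & (n1 + n2 > 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / 2.0
        nc = n1 + n2 - (n1**2 + n2**2) / (n1 + n2)
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar  # r - 1 = 1
        hbar = (n1 * h1 + n2 * h2) / (n1 + n2)

        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 / 2.0 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 / 2.0 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0

    a = np.where(valid, a, 0.0)
    d = np.where(valid, a + b + c, 0.0)
    if a.ndim == 0:
        return float(a), float(d)
    return a, d


def wc_fst_site(
    matrix: GenotypeMatrix,
    g1_samples: Sequence[str],
    g2_samples: Sequence[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site WC84 components (a, d) between two sample groups."""
    i1 = matrix.sample_indices(g1_samples)
    i2 = matrix.sample_indices(g2_samples)
    out = []
    for idx in (i1, i2):
        n_alleles, alt, het = group_allele_counts(matrix, idx)
        n = n_alleles / 2.0
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / np.maximum(n_alleles, 1), 0.0)
            h = np.where(n > 0, het / np.maximum(n, 1), 0.0)
        out.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = out
    return wc_fst_components(n1, p1, h1, n2, p2, h2)


def windowed_fst(
    matrix: GenotypeMatrix,
    g1_samples: Sequence[str],
    g2_samples: Sequence[str],
    windows: Sequence[GenomeWindow],
) -> list[WindowStat]:
    """Weighted windowed Fst: ratio of summed WC84 components per window.

    Undefined (NaN) when a window's summed denominator is zero; ``n_sites``
    counts sites with a nonzero denominator.
    """
    a, d = wc_fst_site(matrix, g1_samples, g2_samples)
    win_of_site = assign_windows(matrix, windows)
    out: list[WindowStat] = []
    for wi, w in enumerate(windows):
        mask = win_of_site == wi
        denom = d[mask].sum()
        n_contrib = int((d[mask] != 0).sum())
        value = float(a[mask].sum() / denom) if denom != 0 else np.nan
        out.append(WindowStat(w, value, n_contrib))
    return out


def genomewide_fst(
    matrix: GenotypeMatrix,
    g1_samples: Sequence[str],
    g2_samples: Sequence[str],
) -> float:
    """Genome-wide weighted WC84 Fst: sum(a) / sum(a + b + c) over all sites."""
    a, d = wc_fst_site(matrix, g1_samples, g2_samples)
    denom = d.sum()
    return float(a.sum() / denom) if denom != 0 else np.nan


# -- divergent-region calling ------------------------------------------------------


def call_divergent_regions(
    window_stats: Sequence[WindowStat],
    quantile: float = 0.99,
    threshold: float | None = None,
) -> tuple[list[DivergentRegion], float]:
    """Call regions above the empirical top quantile of windowed values.

    The threshold is the order-statistic quantile (linear interpolation) of
    the defined window values pooled over everything passed in — pass the
    windows of several pairwise comparisons together to threshold them
    jointly, or one comparison to threshold it alone.  Windows with
    ``value > threshold`` (strict) are marked and adjacent marked windows on
    one chromosome merge into regions.  An explicit ``threshold`` overrides
    the quantile.

    Returns ``(regions, realized_threshold)``.
    """
    values = np.array([ws.value for ws in window_stats])
    defined = ~np.isnan(values)
    if not defined.any():
        raise ValueError("no defined window values")
    if defined.sum() < 100:
        warnings.warn(
            f"only {int(defined.sum())} defined windows; the empirical "
            f"quantile threshold will be coarse",
            stacklevel=2,
        )
    if threshold is None:
        threshold = float(np.quantile(values[defined], quantile))
    logger.info("call_divergent_regions: threshold %.4f (quantile %.3g)",
                threshold, quantile)

    marked = [ws for ws in window_stats if ws.defined and ws.value > threshold]
    marked.sort(key=lambda ws: (ws.window.chrom, ws.window.start))

    regions: list[DivergentRegion] = []
    run: list[WindowStat] = []

    def flush() -> None:
        if run:
            regions.append(DivergentRegion(
                chrom=run[0].window.chrom,
                start=run[0].window.start,
                end=run[-1].window.end,
                mean_stat=float(np.mean([ws.value for ws in run])),
                n_windows=len(run),
            ))

    for ws in marked:
        if run and (ws.window.chrom != run[-1].window.chrom
                    or ws.window.start != run[-1].window.end):
            flush()
            run = []
        run.append(ws)
    flush()
    return regions, threshold
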