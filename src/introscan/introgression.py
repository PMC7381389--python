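"""Genotype-identity introgression scan (ISC/VSC introgressive index).

For a receptor accession scanned against a donor gene pool and the cultivar
acceptor background, each site contributes an identical sample count (ISC:
group members whose genotype call exactly equals the receptor's) and a valid
sample count (VSC: group members with a known genotype).  Counts are summed
over 1 Mb windows and combined into the introgressive index

    index = ISC_D / VSC_D  -  ISC_A / VSC_A

which lies in [-1, 1]; windows where the index exceeds a screening threshold
(default 0.15, strict) form introgression fragments.  Identity is exact call
equality on {hom-ref, het, hom-alt}: a heterozygous receptor matches only
heterozygous group calls.  Sites where the receptor call is missing
contribute to neither ISC nor VSC for either group, so the two ratios are
always computed over the same site support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import (
    MISSING,
    GenomeWindow,
    GenotypeMatrix,
    SampleGrouping,
    assign_windows,
    windows_for_matrix,
)
from .popgen import WindowStat

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IdentityCounts:
    """ISC/VSC pair at site or window scope; invariant 0 <= isc <= vsc."""

    isc: int
    vsc: int

    def __post_init__(self) -> None:
        if not 0 <= self.isc <= self.vsc:
            raise ValueError(f"require 0 <= isc <= vsc, got ({self.isc}, {self.vsc})")

    @property
    def ratio(self) -> float:
        """ISC / VSC; NaN when no valid group calls."""
        return self.isc / self.vsc if self.vsc else float("nan")


@dataclass(frozen=True)
class IntrogressionFragment:
    """A maximal run of contiguous above-threshold windows for one
    (receptor, donor) pair."""

    receptor: str
    donor: str
    chrom: str
    start: int
    end: int
    mean_index: float
    n_windows: int

    @property
    def name(self) -> str:
        return f"{self.receptor}|{self.donor}"

    @property
    def score(self) -> float:
        return self.mean_index


@dataclass
class IntrogressionProfile:
    """One receptor's windowed index track against one donor group."""

    receptor: str
    donor: str
    window_stats: list[WindowStat]
    fragments: list[IntrogressionFragment]
    # per-window raw counts, aligned with window_stats
    isc_donor: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    vsc_donor: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    isc_acceptor: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    vsc_acceptor: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


# -- site- and window-level counts -------------------------------------------------


def site_identity_counts(receptor_call: int, group_calls) -> IdentityCounts:
    """ISC/VSC for one receptor call against a group's call vector at a site.

    A missing receptor call yields (0, 0): the site contributes nothing.
    Otherwise VSC counts the non-missing group calls and ISC the group calls
    exactly equal to the receptor's.
    """
    group_calls = np.asarray(group_calls)
    if receptor_call == MISSING:
        return IdentityCounts(0, 0)
    valid = group_calls != MISSING
    return IdentityCounts(
        isc=int((group_calls[valid] == receptor_call).sum()),
        vsc=int(valid.sum()),
    )


def _site_counts_matrix(
    receptor_col: np.ndarray, group_calls: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-site (isc, vsc) arrays for one receptor column.

    Sites with a missing receptor call get (0, 0).
    """
    valid_site = receptor_col != MISSING
    group_known = group_calls != MISSING
    vsc = np.where(valid_site, group_known.sum(axis=1), 0)
    isc = np.where(
        valid_site,
        (group_known & (group_calls == receptor_col[:, None])).sum(axis=1),
        0,
    )
    return isc.astype(np.int64), vsc.astype(np.int64)


def windowed_identity_counts(
    matrix: GenotypeMatrix,
    receptor: str,
    group_samples: Sequence[str],
    window: GenomeWindow,
) -> IdentityCounts:
    """Window ISC/VSC: sums of the site counts over sites in the window."""
    if not group_samples:
        raise ValueError("empty group")
    rcol = matrix.calls[:, matrix.sample_indices([receptor])[0]]
    gcalls = matrix.calls[:, matrix.sample_indices(group_samples)]
    isc, vsc = _site_counts_matrix(rcol, gcalls)
    in_win = matrix.sites_in_window(window)
    return IdentityCounts(int(isc[in_win].sum()), int(vsc[in_win].sum()))


def introgression_index(
    matrix: GenotypeMatrix,
    receptor: str,
    donor_samples: Sequence[str],
    acceptor_samples: Sequence[str],
    window: GenomeWindow,
    exclude_receptor_from_acceptor: bool = True,
) -> float:
    """Windowed introgressive index ISC_D/VSC_D - ISC_A/VSC_A for one window.

    NaN (undefined, never 0) when either group's window VSC is zero.  When
    the receptor belongs to the acceptor group it is removed from it by
    default, since matching a sample against itself inflates the acceptor
    ratio.
    """
    if not donor_samples or not acceptor_samples:
        raise ValueError("donor and acceptor groups must be non-empty")
    if exclude_receptor_from_acceptor:
        acceptor_samples = [s for s in acceptor_samples if s != receptor]
        if not acceptor_samples:
            raise ValueError("acceptor group is empty after removing the receptor")
    d = windowed_identity_counts(matrix, receptor, donor_samples, window)
    a = windowed_identity_counts(matrix, receptor, acceptor_samples, window)
    if d.vsc == 0 or a.vsc == 0:
        return float("nan")
    return d.ratio - a.ratio


# -- full scan ---------------------------------------------------------------------


def _screen_fragments(
    receptor: str,
    donor: str,
    stats: Sequence[WindowStat],
    threshold: float,
    merge_gap: int = 0,
) -> list[IntrogressionFragment]:
    """Maximal runs of contiguous windows with index > threshold (strict).

    ``merge_gap`` > 0 bridges runs separated by at most that many
    *undefined* windows; defined sub-threshold windows always break a run.
    """
    frags: list[IntrogressionFragment] = []
    run: list[WindowStat] = []
    gap = 0

    def flush() -> None:
        if run:
            frags.append(IntrogressionFragment(
                receptor=receptor, donor=donor,
                chrom=run[0].window.chrom,
                start=run[0].window.start,
                end=run[-1].window.end,
                mean_index=float(np.mean([ws.value for ws in run])),
                n_windows=len(run),
            ))

    prev_chrom: str | None = None
    for ws in stats:
        new_chrom = ws.window.chrom != prev_chrom
        prev_chrom = ws.window.chrom
        if new_chrom:
            flush()
            run, gap = [], 0
        if ws.defined and ws.value > threshold:
            run.append(ws)
            gap = 0
        elif not ws.defined and run and gap < merge_gap:
            gap += 1  # provisional bridge; closed only if a hit follows
        else:
            flush()
            run, gap = [], 0
    flush()
    return frags


def scan_receptors(
    matrix: GenotypeMatrix,
    grouping: SampleGrouping,
    windows: Sequence[GenomeWindow] | None = None,
    window_size: int = 1_000_000,
    threshold: float = 0.15,
    exclude_receptor_from_acceptor: bool = True,
    merge_gap: int = 0,
) -> list[IntrogressionProfile]:
    """Scan every receptor against every donor group.

    Donor lineages are scanned separately: the result holds one profile per
    (receptor, donor label) pair, ordered deterministically by
    (receptor, donor), each with its windowed index track and the screened
    fragments (index > ``threshold``, contiguous windows merged per
    chromosome).
    """
    if not grouping.donor_labels or grouping.acceptor_label is None:
        raise ValueError("grouping must declare donor label(s) and an acceptor label")
    receptors = grouping.receptors
    if not receptors:
        raise ValueError("receptor set is empty")
    grouping.validate_against(matrix)
    for lab in grouping.donor_labels:
        if not grouping.samples_in(lab):
            raise ValueError(f"donor group {lab!r} is empty")
    acceptor_all = grouping.samples_in(grouping.acceptor_label)
    if not acceptor_all:
        raise ValueError(f"acceptor group {grouping.acceptor_label!r} is empty")

    if windows is None:
        windows = windows_for_matrix(matrix, window_size)
    windows = sorted(windows, key=lambda w: (w.chrom, w.start))
    win_of_site = assign_windows(matrix, windows)
    n_win = len(windows)
    in_any = win_of_site >= 0
    safe_idx = np.where(in_any, win_of_site, 0)

    def window_sums(per_site: np.ndarray) -> np.ndarray:
        return np.bincount(
            safe_idx, weights=np.where(in_any, per_site, 0), minlength=n_win
        ).astype(np.int64)

    donor_cols = {
        lab: matrix.sample_indices(grouping.samples_in(lab))
        for lab in grouping.donor_labels
    }

    profiles: list[IntrogressionProfile] = []
    for receptor in sorted(receptors):
        rcol = matrix.calls[:, matrix.sample_indices([receptor])[0]]
        acceptor = acceptor_all
        if exclude_receptor_from_acceptor and receptor in acceptor:
            acceptor = [s for s in acceptor if s != receptor]
            if not acceptor:
                raise ValueError("acceptor group empty after removing the receptor")
        acc_calls = matrix.calls[:, matrix.sample_indices(acceptor)]
        isc_a_site, vsc_a_site = _site_counts_matrix(rcol, acc_calls)
        isc_a, vsc_a = window_sums(isc_a_site), window_sums(vsc_a_site)

        for donor_label in sorted(grouping.donor_labels):
            don_calls = matrix.calls[:, donor_cols[donor_label]]
            isc_d_site, vsc_d_site = _site_counts_matrix(rcol, don_calls)
            isc_d, vsc_d = window_sums(isc_d_site), window_sums(vsc_d_site)

            with np.errstate(invalid="ignore", divide="ignore"):
                index = isc_d / vsc_d - isc_a / vsc_a
            index[(vsc_d == 0) | (vsc_a == 0)] = np.nan
            n_sites = np.bincount(
                safe_idx,
                weights=np.where(in_any & (rcol != MISSING), 1, 0),
                minlength=n_win,
            ).astype(int)
            stats = [WindowStat(w, float(index[i]), int(n_sites[i]))
                     for i, w in enumerate(windows)]
            frags = _screen_fragments(receptor, donor_label, stats,
                                      threshold, merge_gap)
            profiles.append(IntrogressionProfile(
                receptor=receptor, donor=donor_label,
                window_stats=stats, fragments=frags,
                isc_donor=isc_d, vsc_donor=vsc_d,
                isc_acceptor=isc_a, vsc_acceptor=vsc_a,
            ))
    logger.info(
        "scan_receptors: %d profiles (%d receptors x %d donor groups), "
        "%d fragments at index > %g",
        len(profiles), len(receptors), len(grouping.donor_labels),
        sum(len(p.fragments) for p in profiles), threshold,
    )
    return profiles
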