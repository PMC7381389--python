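"""Per-site SNP quality filters: minor-allele frequency, missingness, heterozygosity.

The analysis-ready SNP set keeps sites with ``maf > maf_min``,
``missing_rate < missing_max`` and ``het_rate < het_max`` — all strict
inequalities, matching the usual "MAF >0.05, Missing <0.1, het <0.3"
screening notation.  Heterozygosity is the per-site proportion of
heterozygous calls among non-missing calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterThresholds:
    """Strict thresholds for the three per-site filters.

    A site passes when ``maf > maf_min`` and ``missing_rate < missing_max``
    and ``het_rate < het_max``; boundary values are dropped.
    """

    maf_min: float = 0.05
    missing_max: float = 0.1
    het_max: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        for name in ("missing_max", "het_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


#: Preset used for tree-building-grade SNP sets.
STRICT = FilterThresholds(0.05, 0.1, 0.3)
#: Preset tolerating more missingness (structure-analysis grade).
RELAXED = FilterThresholds(0.05, 0.2, 0.3)


class SiteStats(NamedTuple):
    maf: np.ndarray | float
    missing_rate: np.ndarray | float
    het_rate: np.ndarray | float


def site_stats(matrix: GenotypeMatrix, site_index: int | None = None) -> SiteStats:
    """Per-site (maf, missing_rate, het_rate).

    * maf: minor-allele frequency over non-missing alleles, with alt-allele
      count = het + 2 x hom-alt.
    * missing_rate: missing calls / total samples.
    * het_rate: het calls / non-missing calls.

    All-missing sites get ``maf = nan`` and ``het_rate = nan`` (undefined)
    with ``missing_rate = 1``; NaNs never pass the strict filter comparisons.

    Returns arrays over all sites, or scalars when ``site_index`` is given.
    """
    calls = matrix.calls if site_index is None else matrix.calls[[site_index]]
    n_samples = calls.shape[1]
    is_missing = calls == MISSING
    n_nonmiss = (~is_missing).sum(axis=1)
    missing_rate = is_missing.sum(axis=1) / n_samples

    with np.errstate(invalid="ignore", divide="ignore"):
        alt = np.where(is_missing, 0, calls).sum(axis=1)
        p = alt / (2.0 * n_nonmiss)
        maf = np.minimum(p, 1.0 - p)
        het_rate = (calls == 1).sum(axis=1) / n_nonmiss
    maf[n_nonmiss == 0] = np.nan
    het_rate[n_nonmiss == 0] = np.nan

    if site_index is not None:
        return SiteStats(float(maf[0]), float(missing_rate[0]), float(het_rate[0]))
    return SiteStats(maf, missing_rate, het_rate)


def filter_sites(
    matrix: GenotypeMatrix, thresholds: FilterThresholds = STRICT
) -> GenotypeMatrix:
    """Return a new matrix keeping only sites that pass all three filters.

    Site order is preserved (output sites are a subsequence of input sites);
    the retained/total count is logged.  An empty result is a warning, not
    an error.
    """
    maf, missing_rate, het_rate = site_stats(matrix)
    with np.errstate(invalid="ignore"):
        keep = (
            (maf > thresholds.maf_min)
            & (missing_rate < thresholds.missing_max)
            & (het_rate < thresholds.het_max)
        )
    keep &= ~np.isnan(maf) & ~np.isnan(het_rate)
    out = matrix.take_sites(np.nonzero(keep)[0])
    logger.info(
        "filter_sites: retained %d / %d sites (maf>%g, missing<%g, het<%g)",
        out.n_sites, matrix.n_sites,
        thresholds.maf_min, thresholds.missing_max, thresholds.het_max,
    )
    if out.n_sites == 0:
        logger.warning("filter_sites: no sites passed the filters")
    return out
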