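"""Genotype data model and file I/O.

The pipeline's central container is :class:`GenotypeMatrix`, a sites x samples
array of unphased diploid genotype codes (0 = hom-ref, 1 = het, 2 = hom-alt,
``MISSING`` = -1) with per-site chromosome/position metadata.  VCF positions
are 1-based as in the format standard; all windowing and BED output use
0-based half-open intervals, so a window ``w`` covers sites with
``pos - 1`` in ``[w.start, w.end)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Sentinel genotype code for a missing diploid call.
MISSING: int = -1

_SNP_ALLELES = frozenset("ACGT")


@dataclass(frozen=True)
class VariantSite:
    """A single biallelic SNP site.

    ``pos`` is 1-based, as printed in VCF.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")


@dataclass(frozen=True)
class GenomeWindow:
    """0-based half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid window [{self.start}, {self.end})")

    @property
    def span(self) -> int:
        return self.end - self.start

    def contains_pos(self, pos: int) -> bool:
        """Membership test for a 1-based site position."""
        return self.start <= pos - 1 < self.end

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


class GenotypeMatrix:
    """Diploid genotype calls for an ordered set of SNP sites and samples.

    Parameters
    ----------
    chrom, pos, ref, alt :
        Per-site arrays; positions are 1-based and must be strictly
        increasing within each chromosome.
    samples :
        Ordered sample identifiers.
    calls :
        ``(n_sites, n_samples)`` integer array with entries in
        ``{0, 1, 2, MISSING}``.
    ids :
        Optional per-site labels (VCF ID column).
    """

    def __init__(
        self,
        chrom: Sequence[str],
        pos: Sequence[int],
        ref: Sequence[str],
        alt: Sequence[str],
        samples: Sequence[str],
        calls: np.ndarray,
        ids: Sequence[str | None] | None = None,
    ) -> None:
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = np.asarray(ref, dtype=object)
        self.alt = np.asarray(alt, dtype=object)
        self.samples = list(samples)
        self.calls = np.asarray(calls, dtype=np.int8)
        if ids is None:
            self.ids = np.asarray([None] * len(self.pos), dtype=object)
        else:
            self.ids = np.asarray(ids, dtype=object)
        self._validate()

    # -- construction / validation -------------------------------------------------

    def _validate(self) -> None:
        n_sites = len(self.pos)
        for name, arr in (("chrom", self.chrom), ("ref", self.ref),
                          ("alt", self.alt), ("ids", self.ids)):
            if len(arr) != n_sites:
                raise ValueError(f"{name} length {len(arr)} != n_sites {n_sites}")
        if self.calls.shape != (n_sites, len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{n_sites} sites x {len(self.samples)} samples"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls contain codes outside {0, 1, 2, MISSING}")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")
        # strictly increasing positions within each chromosome
        for c in self.chromosomes():
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"positions on {c} are not strictly increasing")

    @classmethod
    def from_sites(
        cls,
        sites: Iterable[VariantSite],
        samples: Sequence[str],
        calls: np.ndarray,
    ) -> "GenotypeMatrix":
        sites = list(sites)
        return cls(
            chrom=[s.chrom for s in sites],
            pos=[s.pos for s in sites],
            ref=[s.ref_allele for s in sites],
            alt=[s.alt_allele for s in sites],
            samples=samples,
            calls=calls,
            ids=[s.id for s in sites],
        )

    # -- basic accessors -----------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def chromosomes(self) -> list[str]:
        """Chromosome names in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def site(self, i: int) -> VariantSite:
        return VariantSite(self.chrom[i], int(self.pos[i]),
                           self.ref[i], self.alt[i], self.ids[i])

    @property
    def sites(self) -> list[VariantSite]:
        return [self.site(i) for i in range(self.n_sites)]

    def sample_indices(self, names: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.asarray([lookup[n] for n in names], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in matrix") from None

    # -- subsetting ----------------------------------------------------------------

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the given site indices (order preserved)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            self.chrom[index], self.pos[index], self.ref[index], self.alt[index],
            self.samples, self.calls[index], self.ids[index],
        )

    def take_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_indices(names)
        return GenotypeMatrix(self.chrom, self.pos, self.ref, self.alt,
                              list(names), self.calls[:, idx], self.ids)

    def sites_in_window(self, window: GenomeWindow) -> np.ndarray:
        """Indices of sites falling in a window (0-based half-open vs pos-1)."""
        return np.nonzero(
            (self.chrom == window.chrom)
            & (self.pos - 1 >= window.start)
            & (self.pos - 1 < window.end)
        )[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return (f"<GenotypeMatrix {self.n_sites} sites x {self.n_samples} samples, "
                f"chromosomes {self.chromosomes()}>")


@dataclass
class SampleGrouping:
    """Assignment of samples to group labels plus role declarations.

    Roles: ``donor_labels`` are the donor gene pools scanned separately
    (e.g. the deep-blue and purple landrace lineages), ``acceptor_label`` is
    the single cultivar-background group, and ``receptor_labels`` mark the
    accessions to be scanned for donor-derived fragments.  Donor and acceptor
    label sets must be disjoint.
    """

    assignments: dict[str, str]
    donor_labels: tuple[str, ...] = ()
    acceptor_label: str | None = None
    receptor_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.acceptor_label is not None and self.acceptor_label in self.donor_labels:
            raise ValueError("donor and acceptor labels must be disjoint")

    @property
    def labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for lab in self.assignments.values():
            seen.setdefault(lab, None)
        return list(seen)

    def samples_in(self, label: str) -> list[str]:
        return [s for s, lab in self.assignments.items() if lab == label]

    @property
    def receptors(self) -> list[str]:
        return [s for s, lab in self.assignments.items()
                if lab in self.receptor_labels]

    def with_roles(
        self,
        donors: Sequence[str],
        acceptor: str,
        receptors: Sequence[str],
    ) -> "SampleGrouping":
        known = set(self.labels)
        for lab in [*donors, acceptor, *receptors]:
            if lab not in known:
                raise ValueError(f"group label {lab!r} not present in table")
        return replace(self, donor_labels=tuple(donors), acceptor_label=acceptor,
                       receptor_labels=tuple(receptors))

    def validate_against(self, matrix: GenotypeMatrix) -> None:
        present = set(matrix.samples)
        missing = [s for s in self.assignments if s not in present]
        if missing:
            raise ValueError(
                f"{len(missing)} grouped sample(s) absent from matrix, "
                f"e.g. {missing[:3]}"
            )


# -- VCF ---------------------------------------------------------------------------


def _parse_region(region: str) -> tuple[str, int | None, int | None]:
    """Parse ``chrom`` or ``chrom:start-end`` (1-based inclusive, as samtools)."""
    if ":" not in region:
        return region, None, None
    chrom, _, span = region.partition(":")
    start_s, _, end_s = span.partition("-")
    return chrom, int(start_s.replace(",", "")), int(end_s.replace(",", ""))


def read_vcf(path: str | Path, region_filter: str | None = None) -> GenotypeMatrix:
    """Load a diploid VCF 4.x into a :class:`GenotypeMatrix`.

    Only the GT field is interpreted; phased and unphased calls are treated
    identically.  Multi-allelic and non-SNP records are skipped (count
    logged).  ``./.``, ``.`` and half-missing calls such as ``./0`` map to
    :data:`MISSING`.

    Parameters
    ----------
    region_filter :
        Optional ``chrom`` or ``chrom:start-end`` restriction (1-based
        inclusive); applied while streaming, no index required.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no sample columns")

    want_chrom = want_start = want_end = None
    if region_filter is not None:
        want_chrom, want_start, want_end = _parse_region(region_filter)

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    ids: list[str | None] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        if want_chrom is not None:
            if rec.CHROM != want_chrom:
                continue
            if want_start is not None and not (want_start <= rec.POS <= want_end):
                continue
        if (
            len(rec.ALT) != 1
            or rec.REF not in _SNP_ALLELES
            or rec.ALT[0] not in _SNP_ALLELES
        ):
            n_skipped += 1
            continue
        gts = rec.genotype.array()  # (n_samples, ploidy + 1); last col = phasing
        alleles = gts[:, :-1]
        row = alleles.sum(axis=1).astype(np.int8)
        row[(alleles < 0).any(axis=1)] = MISSING  # half-missing -> MISSING
        rows.append(row)
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        ids.append(rec.ID)
    vcf.close()

    if n_skipped:
        logger.info("read_vcf: skipped %d multi-allelic/non-SNP record(s)", n_skipped)
    calls = (np.vstack(rows) if rows
             else np.empty((0, len(samples)), dtype=np.int8))
    matrix = GenotypeMatrix(chroms, poss, refs, alts, samples, calls, ids)
    matrix.n_skipped = n_skipped  # type: ignore[attr-defined]
    return matrix


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT-only genotype columns.

    Round-trips exactly through :func:`read_vcf` at the call level.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in matrix.chromosomes():
            max_pos = int(matrix.pos[matrix.chrom == c].max())
            fh.write(f"##contig=<ID={c},length={max_pos + 1}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        for i in range(matrix.n_sites):
            gts = "\t".join(_GT_STRINGS[int(g)] for g in matrix.calls[i])
            site_id = matrix.ids[i] or "."
            fh.write(
                f"{matrix.chrom[i]}\t{matrix.pos[i]}\t{site_id}\t"
                f"{matrix.ref[i]}\t{matrix.alt[i]}\t.\t.\t.\tGT\t{gts}\n"
            )


# -- group table -------------------------------------------------------------------


def read_group_table(path: str | Path) -> SampleGrouping:
    """Read a two-column (sample, label) delimited table.

    A header row is tolerated if its first field is ``sample`` (any case).
    Duplicate sample rows are an error; membership in a genotype matrix is
    checked later via :meth:`SampleGrouping.validate_against`.
    """
    assignments: dict[str, str] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            sample, label = fields[0], fields[1]
            if lineno == 1 and sample.lower() == "sample":
                continue
            if sample in assignments:
                raise ValueError(f"{path}:{lineno}: duplicate sample {sample!r}")
            assignments[sample] = label
    if not assignments:
        raise ValueError(f"{path}: no samples")
    return SampleGrouping(assignments)


def write_group_table(grouping: SampleGrouping, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample\tgroup\n")
        for sample, label in grouping.assignments.items():
            fh.write(f"{sample}\t{label}\n")


# -- BED ---------------------------------------------------------------------------


def write_bed(regions: Iterable, path: str | Path) -> None:
    """Serialize regions as BED6 (0-based half-open), sorted by (chrom, start).

    Each region must expose ``chrom``, ``start``, ``end`` and a ``score``
    attribute (or ``mean_stat`` / ``mean_index``); an optional ``name``
    attribute fills column 4.  Negative scores are clamped to 0 in BED
    output only.
    """
    rows = []
    for r in regions:
        score = getattr(r, "score", None)
        if score is None:
            score = getattr(r, "mean_stat", None)
        if score is None:
            score = getattr(r, "mean_index", 0.0)
        name = getattr(r, "name", None) or "."
        rows.append((r.chrom, int(r.start), int(r.end), name, max(float(score), 0.0)))
    rows.sort(key=lambda t: (t[0], t[1], t[2]))
    with Path(path).open("w") as fh:
        for chrom, start, end, name, score in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score:.6g}\t.\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str, float]]:
    """Read back BED rows as (chrom, start, end, name, score) tuples."""
    out = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 else "."
            score = float(f[4]) if len(f) > 4 else 0.0
            out.append((f[0], int(f[1]), int(f[2]), name, score))
    return out


# -- windows -----------------------------------------------------------------------


def tile_windows(chrom_lengths: dict[str, int], width: int = 1_000_000) -> list[GenomeWindow]:
    """Non-overlapping windows of ``width`` bp anchored at 0 per chromosome.

    The final window is truncated at the chromosome length.
    """
    windows: list[GenomeWindow] = []
    for chrom, length in chrom_lengths.items():
        start = 0
        while start < length:
            windows.append(GenomeWindow(chrom, start, min(start + width, length)))
            start += width
    return windows


def windows_for_matrix(matrix: GenotypeMatrix, width: int = 1_000_000) -> list[GenomeWindow]:
    """Tile every chromosome in the matrix out to its last site."""
    lengths = {c: int(matrix.pos[matrix.chrom == c].max())
               for c in matrix.chromosomes()}
    return tile_windows(lengths, width)


def assign_windows(
    matrix: GenotypeMatrix, windows: Sequence[GenomeWindow]
) -> np.ndarray:
    """Map each site to the index of the window containing it (-1 if none)."""
    out = np.full(matrix.n_sites, -1, dtype=np.intp)
    for wi, w in enumerate(windows):
        out[matrix.sites_in_window(w)] = wi
    return out
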