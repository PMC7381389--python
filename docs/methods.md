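# Methods

## Data model and coordinates

Genotypes are unphased diploid calls coded 0 (hom-ref), 1 (het), 2
(hom-alt) or missing; phase is discarded on VCF import because every
statistic in the package compares genotype calls, not haplotypes.
Half-missing calls (`./0`) are treated as missing — the conservative
reading, since a single observed allele cannot be assigned a genotype
class. VCF positions are 1-based; all windows and BED output are 0-based
half-open, so window `[s, e)` covers sites with `pos − 1 ∈ [s, e)`.
Multi-allelic and non-SNP records are skipped on import with a logged
count. Windows are non-overlapping, anchored at 0, default width 1 Mb; the
final partial window of a chromosome is retained.

## Site filters

A site passes when `maf > maf_min`, `missing_rate < missing_max` and
`het_rate < het_max`, all strict, defaults 0.05 / 0.1 / 0.3 (a relaxed
preset with `missing_max = 0.2` is provided). The minor-allele frequency is
computed over non-missing alleles (alt count = het + 2·hom-alt); the
heterozygosity denominator is the non-missing call count, not the sample
count — missingness is filtered separately, and using all samples would
penalize the same site twice. The heterozygosity screen is per-site
(proportion of het calls at the site), the usual interpretation for
outcrossing-contamination and paralog screens on inbred crop panels; a
per-sample reading is conceivable but is not implemented.

## Nucleotide diversity

Per site, π = 2j(n−j)/(n(n−1)) with n non-missing alleles and j alternates
— the unbiased expected-pairwise-difference estimator; undefined (and
excluded from averages) when n < 2. Two normalizations are exposed:
per-variant (mean over sites with defined π; the default, and the only one
recoverable from a SNP-only matrix) and per-bp (sum of site π divided by
the window span). Genome-wide per-bp values depend on the accessible
sequence length, which a filtered SNP matrix does not carry; published
per-bp diversity values can therefore only be matched when that denominator
is known.

## Windowed Fst and divergent regions

Between two groups the package computes Weir & Cockerham's (1984) θ for
diploids from per-group sample sizes, allele frequencies and observed
heterozygote frequencies. Sites where either group has no data, or the two
groups together contain a single individual, contribute nothing; windows
combine sites as the weighted ratio of sums Σa / Σ(a+b+c), the standard
low-bias combination for multi-locus θ. Negative values (sampling noise
around 0) are reported as computed; they are clamped to 0 only in BED score
output, preserving estimator properties for analysis.

Divergent regions are called against the empirical order-statistic quantile
(linear interpolation) of the defined window values pooled across whatever
scan(s) are passed in one call — pooling several pairwise comparisons gives
a single joint threshold; thresholding one comparison alone is the other
supported mode. Windows strictly above threshold are merged when adjacent
on a chromosome. With fewer than 100 defined windows the caller warns that
the quantile is coarse. Note that a k-window tract among N windows can only
be returned in full when the quantile leaves all k values above the cutoff
(top-1% of 100 windows is one window); callers scanning for multi-window
regions should pick the quantile accordingly.

## Introgressive index

For receptor r, group G and window w:

* site ISC = number of members of G whose call equals r's call at the site
  (exact equality on {0,1,2}: a het receptor matches only het calls);
* site VSC = number of members of G with a non-missing call;
* window ISC/VSC = sums of the site counts over w's sites;
* index(w) = ISC_D/VSC_D − ISC_A/VSC_A for donor D and acceptor A.

Sites where the receptor's own call is missing contribute to neither count
for either group, keeping the two ratios comparable over identical site
support; consequently 0 ≤ ISC/VSC ≤ 1 per group and the index is bounded in
[−1, 1] and antisymmetric under swapping D and A. A window where either
VSC is zero is undefined (NaN), never zero. When the receptor is itself a
member of the acceptor group it is removed from that group for its own scan
(self-matching would inflate the acceptor ratio by exactly one guaranteed
match per site); this exclusion and the choice of acceptor label are both
configurable. Donor lineage membership is an input (the group table), not
inferred: ancestry estimation is outside the package's scope.

Fragments are maximal runs of contiguous windows with index strictly
greater than the screening threshold (default 0.15). By default a defined
sub-threshold window or an undefined window breaks a run; `merge_gap = k`
allows bridging up to k consecutive *undefined* windows inside a run.
Multiple donor lineages are scanned separately, one profile per
(receptor, donor) pair.

## Synthetic data generator

The generator emulates the structure the scan assumes: a donor pool and a
cultivar background diverged to a target F, receptor accessions drawn from
the background except inside implanted donor tracts, uniform missingness,
and Hardy–Weinberg heterozygosity. Per site, an ancestral frequency p is
drawn uniformly on [0.05, 0.95] and each pool's frequency from
Beta(p(1−F)/F, (1−p)(1−F)/F) — the Balding–Nichols construction, whose
between-pool Weir–Cockerham θ expectation equals F (verified empirically to
±0.03 in the tests). Genotypes are Binomial(2, p_pool) draws; sites are
independent (no linkage disequilibrium) by default, with an optional
block-copy mode that reuses one draw per window to mimic tract-scale LD,
and an optional het-inflation knob to emulate the excess heterozygosity
real introgressed regions show. Everything derives from one seed and is
byte-reproducible.

The standard scenario — the repository's canonical recovery benchmark — is
F = 0.5, 50 donors, 300 background accessions, 10 carriers each with one
3 Mb tract, 100 SNPs/Mb on a 30 Mb chromosome, 5% missing calls, screening
threshold 0.15. Tract starts are drawn on the 1 Mb window grid so that
window-level recovery metrics are exact rather than diluted by partially
covered edge windows. Problem sizes throughout the test suite (thousands of
sites, hundreds of samples, tens of seeds) were chosen as the smallest
panels at which the statistics are well-resolved.

What passing these tests shows — and does not show: the simulator has no
LD beyond the implanted tracts, no selection, no allele-frequency spectrum
realism beyond the uniform-ancestral Balding–Nichols draw, and no
RAD-specific locus dropout; recovery at F = 0.5 demonstrates correctness of
the scan machinery under the assumed model, not detection power on real
panels with weaker donor divergence, admixed backgrounds or correlated
missingness.

## Recovery scoring

`evaluate_recovery` works at window resolution: a truth window for a
receptor is any window overlapping one of its truth tracts, a detected
window any window overlapped by one of its fragments (donor lineages
pooled); precision and recall come from the pooled confusion counts over
receptors. Boundary error is the mean, over truth tracts with at least one
overlapping same-receptor fragment, of the average absolute start/end
offset to the best-overlapping fragment, in window units; unmatched tracts
are excluded there because they are already charged to recall. With no
truth tracts, recall is NaN (flagged undefined) rather than raising.

## Numerical choices and degenerate inputs

* All-missing sites: MAF and heterozygosity are NaN (flagged undefined) and
  never pass the strict filters; missing rate is 1.
* Monomorphic sites: π = 0; WC84 components (0, 0), excluded from ratios.
* Empty windows: every windowed statistic is NaN with `n_sites = 0`.
* Ties at a filter or screening threshold are dropped (strict comparison).
* Quantile definition: `numpy.quantile` linear interpolation.
* Window membership uses integer arithmetic on `pos − 1`; no floating
  point is involved in coordinates.

## Known limitations

* Genotype identity is symbol-level; an allele-sharing variant (het
  counting as a half-match to either homozygote) is a plausible alternative
  for highly heterozygous material and is deliberately not implemented to
  keep the statistic's bounds and antisymmetry exact.
* No haplotype statistics, no local-ancestry HMM smoothing, no multi-
  population Fst, no bootstrap confidence intervals.
* The VCF writer emits a minimal GT-only VCF 4.2; BCF and indexed random
  access are out of scope.
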