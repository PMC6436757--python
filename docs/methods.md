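# Methods

## Model and detection principle

A recessive embryonic lethal removes its homozygotes before birth. Among
genotyped (live) animals the haplotype that carries it therefore shows
fewer homozygotes than either of two expectations:

- **Frequency expectation.** With `C` heterozygous carriers among `N`
  genotyped animals and haplotype frequency `f = (C + 2·O_hom)/(2N)`, the
  Hardy–Weinberg expected homozygote count is `N·f²` (equal to `C²/4N`
  when no homozygote carriers exist). Observed homozygote carriers — the
  signature of incomplete LD between the chip haplotype and the causal
  allele — contribute two alleles each before squaring, but the canonical
  report uses the heterozygous-carrier count alone, which is how the
  package reproduces the published expected counts for haplotypes that do
  have a few homozygotes.
- **Trio expectation.** Each genotyped offspring of two heterozygous
  carrier parents is homozygous with Mendelian probability 1/4, so
  `E_trio = 0.25 × n_CxC`. An extended mode substitutes the population
  haplotype frequency for a parent of unknown status; by default only
  fully-genotyped carrier×carrier trios contribute, which reproduces the
  published trio expectations exactly.

The deficit test is the one-sided lower-tail exact binomial
`P(X ≤ O | n, p)` with `(n, p) = (N, f²)`, and `(n_CxC, 1/4)` for trios.
The significance threshold is `p < 5×10⁻³` per tested haplotype, raw; the
number of tests and a Bonferroni-adjusted verdict are reported as an
advisory column only. Published per-haplotype p-values from the original
analyses are not used as ground truth anywhere: their exact
parameterization is not reconstructible from the printed counts, so the
test is defined explicitly as above.

## Scan mechanics

Windows of 0.5, 1, 2 and 5 Mb slide at half-window steps (a geometric
ladder covering the span lengths at which such haplotypes have been
reported). Haplotype identity is the exact allele vector over the
window's markers; an animal missing any call in a window is excluded
from that window. Haplotypes at frequency ≥ 0.5% are tested.

Significant windows are merged into one candidate when their spans
intersect and their carrier sets overlap by ≥ 80% **of the smaller set**
(containment rather than strict Jaccard): windows that extend one marker
past the shared segment split the carriers by their flanking allele, so
the same lethal produces *nested* carrier sets, which containment
recognises and Jaccard does not.

Each merged candidate is then **consensus-extended**: starting from the
smallest-p window, flanking markers are adopted while the carriers' modal
allele is shared by ≥ 90% of carrier haploids *and* the sharing exceeds
that allele's population frequency by ≥ 4 standard errors. On the lethal
haplotype carriers are identical by descent, so sharing is ~100%; past
its boundary their alleles are ordinary population draws and extension
stops. Haploids that merely matched the short seed window by chance are
shed along the way. The refined candidate therefore reports the full
shared segment and its true carriers, which is what downstream
co-segregation filtering needs. Refinement can be disabled
(`WindowSpec(refine=False)`).

Fine mapping divides a candidate span into consecutive 1 Mb
sub-haplotypes and excludes any sub-haplotype observed homozygous in a
carrier (it cannot harbour the lethal); the maximal remaining contiguous
interval is returned, or a flagged empty interval if recombinants exclude
everything.

## Marker and animal QC

Animals with call rate < 0.7 are removed first, then markers with
MAF < 0.01, call rate < 0.85, or Hardy–Weinberg exact-test p < 1×10⁻⁵.
The HWE exact test is the standard conditional enumeration over
heterozygote counts given allele counts (two-sided: all outcomes at most
as probable as the observed one). The default HWE threshold is
deliberately liberal; a strict re-scan mode (α = 1×10⁻³⁰) retains even
markers in near-complete LD with a lethal, whose genuine homozygote
deficit would otherwise remove them, and is provided as a sensitivity
check.

## Candidate causal variants

A variant passes for a candidate haplotype when it (1) lies within 5 Mb
of the haplotype boundaries, (2) has at most one homozygous-alternate
animal, (3) is heterozygous in carriers and absent from non-carriers with
at most one discordant animal in total (one false genotype assignment
tolerated), and (4) has dosage r² to the haplotype dosage of at least the
threshold — 0.8 by default with 0.7 supported, since both appear in
practice. Survivors rank loss-of-function classes (splice acceptor/donor,
frameshift, stop gained/lost, start lost) first, then deleterious
missense, then the rest, and by r² within a class. An empty result is a
valid outcome. r² is the squared Pearson correlation of 0/1/2 dosages
over complete pairs — the convention of standard association toolkits —
and is undefined (NaN, with a warning) for constant vectors.

## Wright–Fisher simulation

Viability selection updates the focal-allele frequency as
`p* = (p²w_AA + p(1−p)w_Aa) / (p²w_AA + 2p(1−p)w_Aa + (1−p)²w_aa)`;
for the lethal parameterization (0, 1, 1) this is `p* = p/(1+p)`, whose
boundary limit at p = 1 (one-half) is returned rather than an error
because the singularity is removable. Each generation draws
`Binomial(2N_e, p*)/2N_e` with `2N_e = 300` haploid copies by default
(effective size 150). Under lethality the allele can never fix; drift and
selection balance near 10% frequency.

De-novo arithmetic: mutations per individual = round(genome size × per-bp
rate) (4,915.82 Mb × 1.2×10⁻⁸ = 59) and per generation = replacements ×
per-individual (1,025 × 59 = 60,475). A new mutation enters at the census
frequency 1/4100 ≈ 0.024% — the census denominator as printed — while
sampling uses 2N_e = 300; the two knobs are independent in `DriftConfig`
because they describe different things (copy number at entry versus drift
intensity). With these settings 1–3% of de-novo lethals still segregate
after 10 generations, and fewer after 25. "Segregating" means
0 < p < 1 strictly.

`equilibrium_segregating` injects Poisson(2 × census × U) independent
lethal loci per generation, each evolving under the same update, and
reports the time-averaged number above a detection frequency plus their
mean frequency after burn-in. It is a simulation-based estimate of
mutation–selection–drift balance for the whole class of lethals, exposed
for qualitative comparison only — no closed-form target exists for it.

## Fertility impact and heterosis

Per haplotype: `reduction = (TNB_CxNC − TNB_CxC)/TNB_CxNC`;
`affected = (carrier frequency)²` under random mating;
`%death = affected × reduction`; `population reduction = mean TNB ×
%death`; totals are sums over haplotypes. CxNC pooling ignores which
parent carries. The CxC/CxNC comparison uses Welch's unequal-variance
t-test. Litter validation tests genotyped CxC progeny against 1:2:1 with
a Pearson chi-square (df 2, no continuity correction — this reproduces
the published single-litter p = 0.076 from counts (3, 10, 0) exactly)
plus a lower-tail exact binomial on the homozygote count at p = 1/4.
Heterosis attribution divides the total population TNB reduction by the
purebred–crossbred TNB difference, clipped to [0, 1] with a warning.

One source-table quirk: the affected-litters percentage printed for the
4.7%-carrier haplotype (0.212) is inconsistent with its rounded carrier
frequency (0.047² = 0.221); it was evidently computed from an unrounded
frequency. The table-reproduction path therefore accepts an explicit
affected-litters fraction and feeds the printed value for that row;
every other cell is computed from the printed carrier frequencies and
means, and all reproduced cells agree with the printed table to ±0.002.

The carrier-frequency time series counts carriers among live genotyped
animals per half-year bin from 2012-01-01; the pedigree carries no cull
dates, so "alive" means born on or before the bin end and within a
configurable lifespan (default 3 years) of the bin start.

## Synthetic populations

The generator emulates a breeding nucleus of 50 boars and 2,000 sows with
~50K-chip marker density (one marker per ~40–50 kb), founder MAF uniform
on [0.1, 0.5] (an ascertained SNP chip carries mostly common variants),
recombination at 1 cM/Mb, and ~50% replacement per generation with
uniform selection among surviving piglets. Founder haploid alleles are
drawn independently per marker; phase is known by construction (parental
origin is tracked through meiosis), standing in for statistical phasing,
with a `scramble_phase` option for robustness tests.

A lethal allele is planted on a 2 Mb founder haplotype centred on the
lethal position: every pre-existing copy of the host vector receives the
lethal on one haploid and further animals are drawn at random until the
target carrier frequency is met, so the window haplotype is in complete
LD with the lethal and no founder is homozygous.

Litters: ovulation is Poisson (mean 22 ova, within the physiological
range for commercial sows); zygote genotypes are Mendelian; homozygous
lethal zygotes die pre-implantation; survivors are truncated at the
uterine capacity (unlimited by default; 16 in the compensation regime)
and thinned so that non-carrier × non-carrier litters average the target
litter size (14.18, a typical maternal-line mean). With unlimited
capacity CxC litters converge to exactly 75% of that mean; with finite
capacity supernumerary ova partially replace dead homozygotes and the
observed reduction falls below 25%, reproducing the compensation
mechanism that makes real reductions (15–22%) smaller than Mendelian.
Background stillbirth (7% of TNB) and mummification (1%) are independent
of lethal status — only their non-association matters. Litter sizes are
Poisson before truncation: the simplest count model, as only means are
specified anywhere.

The variant panel emits the causal variant (complete LD, high-impact
class, zero homozygotes) plus background variants whose haploid-level
generation hits target dosage-r² values: with the host haplotype at
frequency `q` and a target `t`, the variant covers all host haploids plus
background haploids at rate `β = (p_v − q)/(1 − q)` with
`p_v = q/(q + t(1−q))`.

**What the generator does not emulate:** background linkage
disequilibrium between markers (founder alleles are independent, so real
chip haplotype-block structure is absent), ascertainment bias beyond the
MAF range, selection on breeding values, X-linked inheritance, genotyping
error, and imputation artefacts. Passing tests therefore demonstrate
that the statistics and pipeline logic are correct under the stated
population model, not that real-data discoveries are reproduced — the
original study's specific haplotypes and genes require the proprietary
genotype data and are represented here only through their printed summary
statistics, which the impact and expectation arithmetic reproduces.

## Problem sizes and numerical choices

The end-to-end recovery scenario uses 5,000 founders on one 20 Mb
chromosome with 500 markers and a 13% carrier target — large enough that
the expected homozygote count (~21) makes the deficit unambiguous, small
enough to run routinely. Drift checks use 10,000–20,000 replicates.
Binomial tail probabilities come from scipy's regularized incomplete
beta; the HWE exact test uses the standard mode-anchored recurrence with
a `1 + 1e-12` relative guard when comparing outcome probabilities.
Degenerate inputs are explicit: monomorphic markers give HWE p = 1,
empty windows are skipped with a warning, constant dosage vectors give
NaN r², populations that produce no offspring raise an extinction error,
and an all-excluded fine-mapping interval returns None with a warning.

## Known limitations

- The trio estimator's extended mode (population frequency for
  ungenotyped parents) is an extrapolation beyond the fully-genotyped
  default; only the default is validated against published values.
- Consensus extension assumes a single shared segment per carrier set;
  two distinct lethals on overlapping haplotypes would be merged if their
  carrier sets overlapped by ≥ 80%.
- The de-novo persistence fraction depends on both the entry frequency
  and the drift sample size; the package's parameterization (census entry,
  effective-size sampling) reproduces the reported 1–3% band but other
  combinations are possible.
- `equilibrium_segregating` treats loci as independent (no linkage,
  no interference between lethals).
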