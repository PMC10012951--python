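# Methods

## Scope

`droncqc` implements the computational side of droplet single-nucleus
RNA-seq preprocessing and QC for DroNc-seq-style chemistry, together with
a synthetic droplet-encapsulation generator that supplies ground-truthed
inputs. Alignment and annotation are out of scope: the package consumes
either raw FASTQ (for structural filtering only) or a *tagged-read*
table — one row per read with barcode, UMI, gene, genome of origin and
genomic region — that a user would derive from an aligned, annotated BAM
upstream, and that the generator produces directly.

## Synthetic encapsulation model

The generator emulates a barnyard run of the droplet device:

- **Loading.** Each of `n_droplets` droplets receives a Poisson(λ) number
  of nuclei with λ = −ln(1 − occupancy), the dilution that puts nuclei in
  exactly the target fraction of droplets. Each nucleus' species is an
  independent draw from `species_proportions`.
- **Bead barcodes.** One 12 nt barcode per droplet, unique across
  droplets (bead-barcode collisions are not modelled). Barcodes are drawn
  uniformly from the 4¹² space, so a pair of beads lands within Hamming
  distance 4 of each other with probability ≈ 2.8×10⁻³ — rare, and
  handled by the repair tie rule when it happens.
- **Molecules.** Per nucleus, the molecule count is log-normal with
  natural-scale location `molecules_per_nucleus_mean` and log-scale
  `molecules_per_nucleus_sigma`, rounded up to ≥ 1. No per-nucleus
  molecule-count distribution is established for this chemistry; the
  log-normal is a modelling choice (right-skewed, strictly positive) and
  its parameters are configuration, not fact. Each molecule draws a gene
  uniformly from its species' panel and an 8 nt UMI uniformly at random;
  UMI collisions are allowed, as in reality, and the quantifier must
  tolerate them.
- **Reads.** Each molecule is sequenced max(1, Poisson(`reads_per_molecule_mean`))
  times. Read 1 is barcode + UMI + a uniform A/C/G anchor + poly-T
  padding to 26 nt; i.i.d. per-base substitutions at `barcode_error_rate`
  are applied to the barcode segment only. Read 2 carries the gene
  identifier as a synthetic pre-aligned payload. Each read draws a region
  label (exonic / intronic / intergenic / mitochondrial) from a
  categorical distribution.

Default study conditions (all configurable): 2×10⁵ droplets, occupancy
0.05, 1:1 species mix, 1500 genes per species, molecule location 400 with
sigma 0.3 (a modest per-nucleus complexity typical of droplet snRNA-seq
nuclei, comfortably above the 200-gene filter for almost all singlets),
reads-per-molecule mean 1.2 (light duplication), barcode error rate 0.005
per base (≈ 5.8% of reads carry ≥ 1 barcode error), region probabilities
(0.34, 0.37, 0.28, 0.01) — an intron-rich, mitochondria-poor profile
characteristic of nuclei. The analysis drivers under `analysis/` use
4×10⁴ droplets so each script finishes in seconds; the parameter-recovery
test runs the full 2×10⁵.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: ambient/background RNA, bead-quality and
bead-collision effects, sequence-level cDNA errors or mismapping in read
2, UMI substitution errors, gene-expression programs (genes are uniform
within a species), batch or cell-cycle structure. Tests against the
generator validate the bookkeeping and the estimators under the stated
model, not robustness to these artefacts.

## Read-1 structural validation

Read 1 positions (1-based): 1–12 barcode, 13–20 UMI, 21 anchor, 22–26
observable poly-T. A read is valid iff it is ≥ 26 nt, barcode and UMI
contain no N, the anchor is A, C or G (the "V" base), and ≥ 4 of the 5
poly-T-window bases are T. The poly-T rule has no established length
contract; ≥ 4-of-5 tolerates one sequencing error in the observable
window and is configurable. N anywhere in barcode or UMI invalidates the
read, because downstream Hamming repair assumes an unambiguous 12-mer.
Reject reasons are assigned in a fixed priority order (too-short,
ambiguous base, bad anchor, bad poly-T), so parsing is total and
deterministic. Whether discarded reads were logged per reason in the
original processing is unknown; the per-reason tally here is this
package's own reporting choice.

## Whitelisting and H2 repair

Candidates are barcodes with ≥ 150 genes detected (a gene is detected at
≥ `min_reads_per_gene` reads, default 1), ranked descending by genes
detected (`by_genes`) or total reads (`by_reads`), ties broken by the
other key then lexicographically, and truncated to `n_expected` (default:
droplets × occupancy, the expected nucleus count). Candidates are
computed **before** repair, matching the order of operations in the
protocol's description; a post-repair recomputation is configurable.

Repair maps every observed barcode to the **unique nearest** whitelist
entry at Hamming distance ≤ `max_distance` (default 2; 0 and 1 give the
stricter variants). Two or more entries tying at the minimal qualifying
distance leave the barcode unassigned — the tie rule is not specified
anywhere authoritative, and discarding avoids fabricating molecules; ties
are counted and reported. Distances are computed exactly for all
(raw, entry) pairs using a packed 2-bit-per-base representation (XOR +
popcount), chunked to bound memory; the result is identical to a
brute-force scan, which the tests verify on random instances including
ties.

## Quantification and filters

Molecules are distinct (assigned barcode, gene, UMI) triples; raw read
support is kept alongside. UMI collapse is exact sequence identity — no
UMI error correction, none being described for this chemistry — so two
molecules sharing a UMI within one (barcode, gene) pair under-count by
one, by design. Unassignable reads are dropped. Gene rows are retained
even when all-zero so matrices from different preparations align by gene
set; matrix columns are whitelist entries in rank order, including
read-free entries.

The per-barcode filter counts a gene as expressed when its **read**
support reaches `min_reads_per_gene` (default 1) and removes barcodes
below `min_genes_per_barcode` (default 200). Read support is the default
because the figure-level cut-off is phrased in reads; a
transcript-support mode is provided since the surrounding text counts
transcripts — at the default threshold of 1 the two are identical.
Filtering is idempotent.

## Species classification and doublet correction

Per barcode, transcripts (UMIs; a reads mode exists for the same
ambiguity as above) aligned to each genome are totalled over the
union of the two matrices' barcode sets. The barcode is a species singlet
iff its majority fraction **strictly exceeds** 0.95 — exactly 95% is
mixed — else mixed; zero-total barcodes are excluded with a warning
count. The classification denominator is the barcodes surviving the
expression filters.

With mix proportions (p, q) and M mixed barcodes of N classified, the
corrected doublet rate is M/(2pq)/N, capped at 1 with a warning. The
published worked example (8 mixed of 391 = 204 + 179 + 8, reported as
4.09%) equals exactly 2 × 8/391, which is this formula at p = q = ½; the
general 1/(2pq) form is an inference from that arithmetic — the doubling
rule is nowhere stated as a formula — and is recorded here as such.
The independence assumption behind 2pq (species assigned independently
per nucleus) is the same one the generator implements, and simulation
verifies the correction is unbiased under it.

## Profiles

Region fractions are category tallies over all mapped reads; the four
categories are exclusive, so fractions sum to 1. Mean log expression is
the per-gene mean of ln(count + 1) over barcodes, zeros included; the log
base is a free choice (Pearson r is invariant to it) and natural log
fixes the reported scale. Concordance pairs two mean vectors on the
**union** of their gene sets with absent genes as 0 (consistent with
retaining all-zero rows; intersection pairing is a flag, since the
original pairing rule is unstated) and computes Pearson r with the exact
t-based two-sided p-value; p-values below 2.2×10⁻¹⁶ are reported as
"< 2.2e-16" in the R convention. `deviating_genes` — genes whose mean
log expression differs by at least a threshold, ranked by |difference| —
is a declared stand-in for the per-gene differential-expression test used
in the original analyses; it has no significance calibration and a
rank-based test is deliberately out of scope.

The empirical correlations of the original study (R = 0.72 / 0.63 / 0.59)
and its region-fraction percentages depend on non-public sequencing data
and are not reproduction targets; the concordance machinery is instead
validated on synthetic paired matrices, where r rises monotonically to 1
as the compartment effect vanishes.

## Determinism and numerical choices

One seed governs a pipeline run; stage generators derive from it as
`SeedSequence([seed, stage_index])` with fixed indices, so stages are
independently reproducible and a rerun is byte-identical (FASTQ bytes and
report JSON are both compared in tests). Reports serialize with sorted
keys; counts are exact integers, rates carried at full precision and
printed to 2 decimals. Degenerate inputs fail loudly: occupancy ≥ 1,
empty gene panels, zero classified barcodes, constant vectors in a
correlation, unequal FASTQ pair counts and length-mismatched barcodes all
raise, while structurally invalid reads are returned as data (with a
reject reason), never raised.

## Known limitations

- No ambient RNA or bead-collision model, so the generator cannot probe
  the false-mixed calls those artefacts cause in real barnyards.
- No UMI error correction; UMI-rich, deeply sequenced libraries would
  under-count slightly.
- No knee-point auto-detection of `n_expected`; the expected nucleus
  count must come from the loading arithmetic or the user.
- The mean-difference deviating-gene list is descriptive, not a test.
- The 1/(2pq) correction assumes independent species assignment per
  nucleus and breaks down for strongly clumped loading.
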