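# Methods

## Problem and scope

`anccap` analyses hybridisation-capture experiments in which baits are
designed from a computationally reconstructed *ancestral* mitogenome and
used to enrich mitochondrial DNA from degraded museum specimens of
descendant lineages. The questions the package answers are the ones such
an experiment raises: how much of the mitogenome is recovered at callable
depth, how strongly does local bait-to-target sequence divergence
suppress capture efficiency, are nuclear copies of mitochondrial DNA
(numts) leaking into the consensus, and how do the recovered haplotypes
cluster into matrilines.

The package operates either on real inputs (FASTA references, a plain
SAM dialect of mapped reads, tabular CDS annotations) or fully
self-contained on its own synthetic-data generator, which produces every
input with ground truth.

## Synthetic-data generator

The generator emulates the data-generating process of a
degraded-specimen capture study:

- **Ancestral genome.** An i.i.d. nucleotide sequence of length 16,500 bp
  (a typical mitogenome) with GC content 0.40, generated circular but
  linearised at position 0; fragments never span the origin, matching
  standard mitogenome file handling.
- **Divergence track.** The descendant differs from the ancestor by
  substitutions at piecewise-constant per-site rates. The default track
  has eleven equal segments with targets
  (0.12, 0.06, 0.00, 0.03, 0.06, 0.10, 0.13, 0.18, 0.23, 0.27, 0.14),
  chosen so the divergence spans 0–27% with a mean of exactly 12% — both
  genome-wide and over the 2–15 kb analysis region — the distribution
  observed between an ancestral bait sequence and a real capture target
  at the family-level divergence this emulates. Substitutions are
  recorded in an exhaustive per-site truth map. An optional indel mode
  exists solely to exercise window gap-flagging.
- **Fragments.** Lengths are lognormal with mean 70 bp and SD 25 bp,
  clipped below at 30 bp — typical historical-specimen fragmentation
  combined with the 30 bp minimum read length that mapping pipelines
  retain. Starts are uniform; strands are fair coin flips.
- **Deamination.** Position *k* from a read's 5′ end is C→T converted
  with probability `rate_5prime * decay^k` (defaults 0.3 and 0.5). This
  reproduces the terminal damage signature of degraded DNA; with these
  defaults the expected identity loss per 60 bp comparison is ~0.002,
  i.e. damage perturbs but does not dominate bait-fragment identity.
- **Capture retention.** A fragment with bait identity *x* is retained
  with probability `p_max / (1 + exp(-slope * (x - id_50)))`, defaults
  `p_max = 0.95`, `id_50 = 0.80`, `slope = 40`: retention is
  near-maximal below ~10% divergence and near zero above ~20%, the
  qualitative behaviour of array capture with divergent baits. Shotgun
  libraries retain every fragment.
- **PCR duplicates.** Each retained fragment yields
  `1 + Geometric(dup_rate)` copies (default rate 0.15), so `dup_rate=0`
  produces no duplicates.

All draws flow from explicit per-call seeds; identical inputs and seed
give byte-identical libraries.

### Which identity drives retention

Retention is evaluated at the fragment's identity to its **homologous
bait** — the tile maximally overlapping the fragment's origin, compared
in register. An earlier design scored each fragment by its *best*
identity over all baits, orientations and ungapped offsets (the metric
`baitdesign.best_bait_identity` exposes). That maximum is taken over
about six overlapping in-register tiles per fragment and systematically
selects the 60-of-70 positions with the fewest mismatches, inflating
fragment identity by roughly 0.03 at intermediate divergence. The
consequence is a generator whose apparent retention midpoint, expressed
in window-identity units, sits near 0.77 rather than the nominal
`id_50` — the model-recovery step then "fails" for a reason that has
nothing to do with the recovery. The homologous-bait identity is an
unbiased, symmetric-noise sample of local bait-to-target identity, and
it is also the biophysically sensible choice: at ≤ 27% divergence a
fragment can only form a productive duplex with the probe from its own
locus (the expected best identity against any unrelated 60-mer across
~8,200 baits is ≈ 0.47).

### What the generator does not emulate

Sequencing error beyond deamination, quality scores, paired-end
structure, origin-spanning fragments, mappability variation, reference
bias in alignment, and numt co-enrichment (numt-like reads are
constructed directly in tests instead). Passing tests therefore
demonstrate correctness of the analysis logic under a clean, known
generative model — not robustness to every artefact of real capture
data.

## Analysis pipeline

Stages run in fixed order: simulate → bait design → MAPQ filter →
duplicate removal → pileup/consensus → windows → divergence response and
model fit → haplotype network.

- **Bait tiling.** Baits of 60 nt tiled every 2 bp (the assay's tiling
  step). Probe length is configurable; 60 nt matches the analysis window
  used to relate divergence to capture. If `(L - bait_length)` is not
  divisible by the step, an extra bait is anchored at `L - bait_length`
  so the 3′ end is covered.
- **MAPQ filter.** Reads with mapping quality < 30 are removed; a read
  at exactly Q30 is kept (the threshold is exclusive on the low side).
- **Duplicate removal.** Reads sharing reference, start, end *and*
  strand collapse to one representative — the read with the most non-N
  bases, ties broken by input order. Keying on both fragment ends is
  stricter than start-only marking and appropriate for degraded DNA,
  where natural end heterogeneity makes joint-end collisions between
  distinct templates rare (their expected number follows a birthday
  computation from the fragment model and is verified in tests). A plus-
  and a minus-strand read with identical coordinates derive from
  different template strands and are not duplicates.
- **Consensus.** A base (or deletion) is called where depth ≥ 3 and a
  single allele holds ≥ 90% of the depth; otherwise N. The majority
  boundary is inclusive (a 9-of-10 column is called). N observations in
  reads contribute neither to tallies nor to the depth denominator —
  uninformative observations should not dilute the majority. Consensus
  deletions compete in the vote and are excised from the reported
  sequence but keep their slot in the depth vector. Because a second
  haplotype above 10% of reads forces N, co-enriched numts drop out of
  the consensus rather than being incorporated; a second guard
  translates CDS annotations under the vertebrate mitochondrial code
  (NCBI table 2, where AGA/AGG are stops) and reports internal stop
  codons. Recovery statistics (fraction of positions at ≥ 3×, mean
  depth) are computed after filtering and deduplication, mirroring the
  pipeline order.
- **Windows.** 60 bp windows advancing by 30 bp across the 2–15 kb
  region (the rRNAs and control region are excluded because indel
  variation there makes ungapped window identity meaningless; windows
  are clipped to lie entirely inside the region). Identity counts
  matches over columns where both rows are unambiguous bases; windows
  containing any gap or N are flagged and excluded from binned
  summaries. Divergence bins are 0.02 wide (configurable); bins with
  fewer than 5 windows are reported with a warning.
- **Divergence response and model fit.** Per bin, the table reports the
  share of windows and the share of total capture and shotgun depth;
  the capture/shotgun ratio of depth shares is the enrichment-efficiency
  readout. The logistic retention curve is refit to per-window
  capture/shotgun depth ratios by least squares (`scipy`
  `curve_fit`), with the amplitude absorbing the library-size ratio;
  uncertainty comes from a percentile bootstrap over windows (200
  resamples by default). Flat ratio profiles or windows spanning fewer
  than three divergence levels are rejected as degenerate rather than
  fit. The fitted midpoint is unbiased under the generator (see above);
  the fitted *slope* is attenuated (about 28 recovered for a generative
  40) because 60-site binomial identity noise convolves the curve —
  symmetric noise preserves the midpoint of an antisymmetric logistic
  but flattens its slope. Trendlines use an explicitly specified tricube
  local-linear smoother (span 0.5): nearest `ceil(span*n)` points,
  weights `(1-(d/h)^3)^3`, weighted straight-line fit per grid point.
  It reproduces collinear input exactly; equivalence with any particular
  loess implementation is not a contract (agreement with statsmodels
  lowess is cross-checked in tests).
- **Banded aligner.** Whole-molecule identity uses a global affine-gap
  aligner (match +1, mismatch −1, gap `−5 − 1·g`) restricted to a
  diagonal band of half-width 200 — mitogenomes are collinear. If the
  optimal path touches the band boundary or doubling the band improves
  the score, the band doubles with a warning, so results are
  band-unconstrained in practice. Identity counts matched columns over
  comparable columns, excluding terminal gap runs.
- **Haplotype network.** Consensus sequences are stripped of every
  column containing missing data, collapsed into haplotypes with
  multiplicities, and joined by a minimum spanning tree over pairwise
  difference counts (Kruskal; ties broken lexicographically by node
  ids, so the tree is deterministic). The matriline partition deletes
  the single largest edge: by the MST cut property this recovers any
  two clusters separated by more differences than occur within them.
  Median vectors and reticulations of full median-joining networks are
  deliberately omitted — the deepest-split readout does not need them.
- **Pool planning.** Volume fractions proportional to
  `1/(target_content × molarity)` make expected on-target molecules
  (`content × molarity × volume`) exactly equal across libraries — the
  simplest rule achieving equal post-capture representation. An
  optional per-library cap (off by default; 0.5 is a sensible value)
  prevents one very poor library dominating; equal representation then
  holds only among uncapped libraries.

## Problem sizes and defaults

The standard scenario used by the test suite and the acceptance script
is a 16.5 kb genome, 20,000 capture + 20,000 shotgun fragments for the
focal individual (mean deduplicated shotgun depth ≈ 85×) and eight
6,000-fragment capture samples in two matrilines (1% between-matriline,
0.1% within-matriline divergence). End-to-end pipeline tests use
smaller libraries (hundreds to a few thousand fragments); statistical
checks state their own sizes (e.g. 50,000 fragments for the shotgun
neutrality chi-square).

## Known limitations

- The aligner is a desk-scale tool, not a production aligner; its
  identity denominator excludes internal gap columns, so indel-rich
  comparisons report substitution identity rather than alignment-length
  identity.
- The consensus makes haploid calls only; heteroplasmy and IUPAC
  ambiguity codes are out of scope.
- Bootstrap intervals treat overlapping windows as independent, which
  slightly understates uncertainty; at the default window/step ratio
  the effect is small relative to the reported intervals.
- The pooling rule is declared, not inferred from any particular
  laboratory's weighting scheme.
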