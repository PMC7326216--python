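# anccap

Analysis toolkit for **ancestral mitogenome capture**: hybridisation
enrichment experiments whose baits are designed from a computationally
reconstructed ancestral mitochondrial genome, so that a single bait set
can pull down mitochondrial DNA from all descendant and sister lineages
— including degraded museum specimens of species with no close extant
relative.

The package is aimed at people analysing (or planning) such
experiments. It implements the downstream pipeline as a tested library
plus CLI:

- **Bait design** — tile probes across an ancestral reference at a
  fixed step (default 60 nt every 2 bp) and score fragments against the
  bait set.
- **Read processing** — a plain-text SAM dialect, mapping-quality
  filtering (`MAPQ < 30` removed), and PCR-duplicate removal keyed on
  **both** fragment-end coordinates and strand.
- **Consensus calling** — pileup consensus requiring depth ≥ 3 and a
  ≥ 90% majority; mixed columns become N, so co-enriched nuclear copies
  of mtDNA (numts) are masked instead of merged, with an internal
  stop-codon screen (vertebrate mitochondrial code) as a second guard.
- **Divergence-response analysis** — sliding-window (60/30 bp)
  bait-to-target identity and per-window capture vs. shotgun depth; the
  capture/shotgun depth-share ratio per divergence bin quantifies how
  enrichment efficiency decays with bait-target divergence, and a
  logistic retention model
  `p(x) = p_max / (1 + exp(-slope · (x - id_50)))`
  is refit to the windowed data with bootstrap intervals.
- **Haplotype networks** — pairwise differences, minimum-spanning
  network with collapsed haplotypes, and the deepest split (matriline
  partition).
- **Pool planning** — pre-capture volume fractions
  ∝ `1/(target_content × molarity)` that equalise expected on-target
  molecules across libraries.
- **Synthetic data** — a generator emulating the whole experiment
  (diverged target spanning 0–27% divergence with mean 12%, ≥ 30 bp
  fragments with 5′ C→T deamination, divergence-dependent capture
  retention, PCR duplicates) with full ground truth, driving the
  self-contained end-to-end pipeline.

See `docs/methods.md` for the models, defaults and design rationale.

## Worked example

Run the full study analog from one config (or pure defaults):

```bash
anccap run --seed 42 --out runs/demo
```

This simulates a 16.5 kb ancestral bait source and a descendant target,
tiles 8,221 baits, draws 20,000-fragment capture and shotgun libraries
plus eight capture samples in two matrilines, then filters, deduplicates,
calls consensus, and runs the window and network analyses. The report
(`runs/demo/report.json`, also printed) contains, for example:

```
"samples": [
  {"sample_id": "focal_capture",  "mode": "capture",
   "unique_mapped_reads": 15011, "portion_at_min_depth": 0.989, "mean_depth": 63.9},
  {"sample_id": "focal_shotgun",  "mode": "shotgun",
   "unique_mapped_reads": 19925, "portion_at_min_depth": 1.000, "mean_depth": 84.7},
  ...
],
"fit": {"id_50": 0.791, "slope": 26.3, "ci_id_50": [0.783, 0.799], ...},
"whole_molecule_identity": 0.883,
"mean_window_divergence": 0.114,
"partition": [["SIM-01A", ...], ["SIM-05B", ...]],
"split_length": 147
```

Reading: the shotgun library covers essentially the whole molecule
(~85× mean depth) while the capture library, although deeper than
shotgun in low-divergence regions, loses the most divergent windows —
its divergence-response table (`divergence_response.tsv`, plotted in
`divergence_response.png`) shows the capture/shotgun depth-share ratio
falling from ~1.3 in the 0–2% divergence bin to near 0 beyond 20%. The
refit retention midpoint (0.791, interval 0.783–0.799 for this seed)
estimates the generating `id_50 = 0.80`; the whole-molecule identity of
0.883 is the bait-to-target identity of a target averaging ~12%
divergence. The eight samples split into the two simulated matrilines,
separated by 147 differences.

Individual stages are exposed as subcommands
(`anccap design-baits | dedup | consensus | windows | response |
fit-model | network | pool-plan`), each reading and writing the plain
formats (FASTA, SAM dialect, BED, TSV).

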