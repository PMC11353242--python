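# cinmetrics

Chromosomal-instability (CIN) metrics on synthetic data. The package
implements four analysis chains plus the simulators that feed them:

- **Copy-number profiling** (`cinmetrics.cnprofile`): binned read counts →
  GC-bias correction (quadratic fit over copy-neutral-candidate bins) →
  median-of-ratios normalization (the *MedianRatio* reference) → recursive
  binary segmentation with permutation-calibrated split acceptance →
  integer copy-number calls.
- **Baseline-distance comparison** (`cinmetrics.baseline`): locus-matched
  subtraction of knock-down and control log2 ratios on the finest common
  tiling; each locus is classed *closer to* / *further from* the
  copy-neutral zero-baseline, or *unchanged* within 2 × the control
  profile's ratio dispersion (MAD-based by default, pluggable); summaries
  in Mbp and percent over changed loci, plus affected-chromosome lists.
- **Karyotype / count statistics** (`cinmetrics.stats`): chromosome-count
  summaries, two-sided variance-ratio F-test, Fisher-exact event-proportion
  comparison, two-channel spindle intensity ratio, Mann–Whitney U
  (exact for small tie-free samples).
- **Comet tracking** (`cinmetrics.tracking`): max-intensity projection,
  difference-of-Gaussians filtering, sub-pixel spot detection,
  frame-to-frame linear-assignment linking with a displacement cap (no gap
  closing), duration/spot filters, per-track and per-cell mean speeds in
  µm/min.
- **Simulators** (`cinmetrics.simulate`): paired control/knock-down genomes
  with known closer/further ground truth, GC-biased negative-binomial bin
  counts, missegregation-driven karyotype spreads, binomial event counts
  and comet movies with Gaussian PSFs — every stage is testable offline.

All interval data are 0-based half-open (BED convention), bp internally,
Mbp only in reports. Every simulator takes an explicit seed; noise or
dispersion 0 always means "return the expectation".

## CLI

```sh
# all-in-one demo: simulate -> profile -> compare (deterministic per seed)
cinmetrics run --seed 7 --out-dir out/

# individual stages
cinmetrics simulate cnv --seed 1 --out-dir sim/
cinmetrics profile --bins sim/control.bins.tsv --ploidy 2 --seed 1 --out ctrl.segs.tsv
cinmetrics profile --bins sim/knockdown.bins.tsv --ploidy 2 --seed 2 --out kd.segs.tsv
cinmetrics compare --control ctrl.segs.tsv --knockdown kd.segs.tsv \
    --control-bins sim/control.bins.tsv --out summary.json

cinmetrics simulate movie --frames 90 --speed 3.0 --seed 3 --out m.tif
cinmetrics track --movie m.tif --pixel-size 0.1 --interval 2 --out tracks.csv

cinmetrics simulate karyotype --base-count 107 --rate 0.02 --out karyo.tsv
cinmetrics stats karyotype --a karyo.tsv
cinmetrics stats events --events-a 24 --n-a 100 --events-b 10 --n-b 100
```

`cinmetrics run` accepts a YAML config mirroring the CLI flags; CLI options
override the file. Outputs carry a provenance header (tool, version,
parameter echo); reruns with identical seeds are byte-identical.

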