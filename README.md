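# delscreen

Screen deletion calls in DGV-style variant catalogues for GC-content and
mappability bias, then validate each suspicious call against paired-end
read-mapping (PEM) evidence from alignment files. Depth-of-coverage
valleys caused by extreme GC content or poor mappability look like
deletions; read pairs that span a real deletion are not fooled by those
biases. Calls without sufficient spanning-pair support are classified as
false positives.

## How it works

1. **profiles** — binned GC and mappability tracks (100 bp bins) are
   LOESS-smoothed; thresholds are picked from the value distributions
   (GC: 5% tail quantiles; mappability: quantile after dropping the
   exact-0/1 point masses, or a fixed value); runs of beyond-threshold
   bins longer than 500 bp whose raw mean confirms the violation become
   *suspicious regions*.
2. **dgv** — the supporting-variants table is parsed (1-based inclusive →
   0-based half-open), filtered (sequencing method, deletion/loss
   subtype, size strictly < 10 kbp, nonempty samples), duplicate loci are
   merged, and variants overlapping a suspicious region at base-level
   F-score > 0.9 are flagged.
3. **pem** — for each flagged variant, read pairs fully contained in the
   ROI (variant ± (1 kbp + half the variant length)) are extracted; pairs
   whose span matches the variant at F > 0.7 are selected; the variant is
   a **true positive** iff the average and sum of the selected pairs'
   qualities reach 30 and 90 (so one pair at 90, two at 45, or three at
   30 suffice), else a **false positive**.
4. **report** — results spreadsheet, four-panel per-variant figures
   (GC / mappability / DOC / PEM), per-chromosome/sample/study tallies,
   chromosome-length correlation, and a 3-component Gaussian mixture over
   log10(size).
5. **synthetic** — a truth-labelled simulator (tracks, sorted+indexed
   BAM, DGV-style table, manifest) so the whole pipeline is testable
   offline: homozygous deletions with excised fragments (spanning pairs),
   and bias artifacts with thinned but concordant coverage (no PEM
   support).

## CLI

```sh
# synthetic dataset
delscreen simulate --seed 1 --out-dir sim/

# suspicious regions from tracks (fixed mappability threshold here)
delscreen scan --gc sim/gc.bedgraph --map sim/mappability.bedgraph \
    --th3 0.92 --out suspicious.bed

# filter + dedup + flag variants overlapping suspicious regions
delscreen flag --dgv sim/variants.tsv --regions suspicious.bed \
    --f-threshold 0.9 --out flagged.tsv

# paired-end validation
delscreen validate --variants flagged.tsv --manifest sim/manifest.tsv \
    --f-cut 0.7 --avg-cut 30 --sum-cut 90 --out results.tsv

# summary statistics
delscreen report --results results.tsv --out-prefix summary

# or everything at once on a fresh synthetic dataset
delscreen run --seed 1 --out-dir run/
```

`simulate`/`run` accept `--config <yaml>` overriding any `SimConfig`
field (chromosome length, coverage, implant counts and sizes, ...).

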