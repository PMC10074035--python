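# peako

Rank transcription-factor motifs from paired wild-type (WT) / knockout (KO)
ChIP-seq experiments.

## The problem

ChIP-seq peak sets are contaminated by technical noise — antibody
cross-reactivity, library and alignment artifacts — that survives peak
calling. A knockout of the profiled factor provides a principled negative
control: read pileups shared between the WT and KO experiments are noise,
while WT-specific pileups represent genuine binding. Two standard ways of
exploiting that control are

* **Pipeline A — differential motif enrichment**: call WT and KO peaks
  separately and test each motif's *central* enrichment in WT peak windows
  against the KO windows (one-sided Fisher exact test on in-window best-site
  counts);
* **Pipeline B — differential peak calling**: call one differential peak set
  (WT against the KO as control) and test central enrichment positionally
  (binomial upper tail on in-window best-site counts).

Each arm has blind spots (A degrades when the KO peak set is small; B often
behaves like a WT-only analysis). `peako` combines them. From each arm's
enrichment results it extracts, per motif, the matched peak sets
A<sub>WT</sub> and A<sub>KO</sub> (Pipeline A positive and negative peaks
whose best site falls in the enriched central window) and B (Pipeline B
matched peaks), filters out motifs whose multiple-testing corrected p-value
exceeds 0.1 in either arm, and ranks the survivors by

```
r = | merge( intersect_wa( subtract_A(A_WT, A_KO), B ) ) | / |A_WT|
```

where `subtract_A` removes every A<sub>WT</sub> peak overlapping an
A<sub>KO</sub> peak by ≥ 1 bp (whole-interval removal), `intersect_wa`
keeps one copy of each surviving A<sub>WT</sub> peak per overlapping B peak,
and `merge` fuses overlapping/book-ended regions — guaranteeing
0 ≤ r ≤ 1. r is the proportion of high-quality A<sub>WT</sub> peaks found
in B but not in A<sub>KO</sub>.

All supporting statistics are built in: summit-centered extension of
narrowPeak regions to uniform 500 bp windows, two-strand PWM log-odds
scanning with one best site per sequence, centered-window binomial and
Fisher tests, and E-value correction (E = min(p, 1) × number of tests).
A seeded synthetic-experiment generator (random genome, planted target
motif, shared-noise loci, column-shuffled decoys) makes the whole method
testable without any external downloads.

## Worked example

Simulate a WT/KO experiment (80 signal peaks with a CRE-like 12-bp motif
planted near peak centers, 10 shared-noise loci, 20 KO-only peaks, 5
shuffled decoy motifs), then run both pipelines and the ranking:

```sh
peako simulate --outdir sim --genome-length 300000 --n-wt 80 --n-ko 20 \
    --n-shared-noise 10 --decoy-count 5 --center-sigma 10 --seed 7
peako peako --wt-peaks sim/wt_peaks.narrowPeak --ko-peaks sim/ko_peaks.narrowPeak \
    --diff-peaks sim/diff_peaks.narrowPeak --genome sim/genome.fa \
    --motif-db sim/motifs.meme --outdir out
```

prints

```
 rank        motif_id        r  numerator  denominator  filtered        reason   e_value_a    e_value_b
    1        TARGET.1 0.984848         65           66     False             .    0.000002 8.325701e-56
    2 TARGET.1_shuf01 1.000000          6            6      True insignificant  241.067696 4.081964e+01
    3 TARGET.1_shuf02 0.886364         78           88      True insignificant 1470.000000 4.060152e+02
    4 TARGET.1_shuf03 0.883721         76           86      True insignificant  215.297949 1.201912e+01
    5 TARGET.1_shuf04 0.903614         75           83      True insignificant  435.977890 3.886990e+00
    6 TARGET.1_shuf05 0.838710         52           62      True insignificant  986.885137 1.781259e+02
wrote out/peako.tsv (6 motifs)
```

The planted motif is the only one significant in both arms (corrected
p ≤ 0.1) and ranks first with r = 65/66: of the 66 WT peaks matched by the
differential arm, 65 survive KO subtraction and overlap a matched
differential-arm peak. The decoys are filtered as non-significant (their
E-values saturate toward the test count) and are listed afterwards in
alphanumeric order, where r carries no evidence. `out/` also contains both
arms' reports, per-motif matched-peak and numerator-region BED files, and a
JSON run manifest.

The same run is available from Python:

```python
from peako import SimulationConfig, generate_experiment, RunConfig, run_peako

exp = generate_experiment(SimulationConfig(seed=7), "sim")
records = run_peako(RunConfig(
    wt_peaks=exp.wt_peaks, ko_peaks=exp.ko_peaks, diff_peaks=exp.diff_peaks,
    genome=exp.genome, motif_db=exp.motif_db, outdir="out"))
print(records[0].motif_id, records[0].r)
```

## Scope

`peako` consumes called peaks (ENCODE narrowPeak / BED) — it does not trim,
align, or call peaks, and it does not perform de-novo motif discovery.
When no differentially called peak set is available, a locus-subtraction
approximation can be enabled explicitly (`--approximate-diff`) and is
labelled as such in logs and the run manifest.
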