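# embryoflow

Automated behavioural phenotyping of single embryos (zebrafish and similar
small aquatic life stages) from short video recordings.  Manual scoring of
embryo behaviour — counting tail flicks frame by frame — is the bottleneck of
high-throughput toxicological and pharmacological screens.  `embryoflow`
replaces it with an integrative motion measurement that captures *all* visible
movement (tail flicks, body shifts, heart beat, blood flow) and turns each
recording into a compact spectral fingerprint suitable for multivariate
statistics.

## The method

For a 30-s grayscale recording at 15 Hz of one embryo:

1. **Sparse optic flow.**  Shi-Tomasi corner features are detected and tracked
   between consecutive frames by pyramidal Lucas-Kanade refinement.  Each frame
   pair is reduced to four measures: summed clockwise and anticlockwise feature
   rotation about the feature centroid (*pos*, *neg*, radians), and the
   centre-of-mass displacement in polar form (*rho* in pixels, *theta* in
   radians).  A tail flick appears as a large transient peak in *pos* + *neg*.
2. **Spectral fingerprint.**  The first 448 frame pairs of each measure are
   Fourier-transformed; the 224 magnitude bins (bin *k* ↔ period 448/(15*k*) s,
   from 29.87 s down to 0.13 s) are summed into 18 fixed period bands, giving a
   72-feature fingerprint per recording, then transformed as log(x + 1).
3. **Multivariate comparison.**  Recordings are compared by Bray-Curtis
   dissimilarity, Σ|aᵢ − bᵢ| / Σ(aᵢ + bᵢ).  Differences between the five
   exposure periods of a pulse-exposure design (pre-exposure, two exposure
   halves, two recovery halves; 4 recording cycles each) are tested with
   ANOSIM, R = (r̄_between − r̄_within) / (n(n−1)/4), with a seeded permutation
   p-value, and visualised by non-metric MDS of the period-mean fingerprints
   (Kruskal stress-1).
4. **Cross-validation against counts.**  Tail flicks are counted as robust-z
   peaks of the activity trace and compared across periods with a
   repeated-measures ANOVA over embryos plus Bonferroni paired contrasts; a
   concordance report checks that the spectral and count-based routes call the
   same period pairs significant.

A fully seeded synthetic generator produces both parametric motion records and
rendered videos (textured embryo in a chorion ring, flicking tail, pulsing
heart spot) with ground truth, so every stage is testable without microscope
data.

## Worked example

```python
from embryoflow import (
    SyntheticConfig, generate_motion_record, canonicalize, fingerprint,
    log_transform, detect_tail_flicks,
)

cfg = SyntheticConfig(seed=42, flick_rate_per_30s=8.25)
record, truth = generate_motion_record(cfg)
canon = canonicalize(record)          # first 448 frame pairs
fp = log_transform(fingerprint(canon))
events = detect_tail_flicks(canon)

print(f"frame pairs:     {len(canon)}")
print(f"true flicks:     {truth.flick_count}")
print(f"detected flicks: {events.count} at frames {[int(f) for f in events.event_frames]}")
bands = fp.to_series().filter(like="pos_").sort_values(ascending=False).head(3)
print("largest clockwise-rotation features (log1p spectral mass):")
for name, value in bands.items():
    print(f"  {name:10s} {value:.2f}")
```

prints

```
frame pairs:     448
true flicks:     6
detected flicks: 6 at frames [117, 235, 256, 269, 345, 418]
largest clockwise-rotation features (log1p spectral mass):
  pos_band5  4.19
  pos_band12 4.12
  pos_band8  4.02
```

The generator scripted six flick bursts into the recording; the peak detector
recovers all six, and the flicks' broadband spectral mass spreads over the
mid-period bands of the clockwise-rotation measure.

## Command line

```bash
embryoflow simulate --seed 42 --out data/            # synthetic experiment
embryoflow extract --frames frames_dir/ --fps 15 --out motion.csv
embryoflow fingerprint --motion motion_dir/ --out fp.csv --log
embryoflow compare --fingerprints fp.csv --design data/design.csv \
    --permutations 9999 --seed 42 --out results.json
embryoflow flicks --motion-dir motion_dir/ --design data/design.csv \
    --out counts.csv --report flicks.json
embryoflow run --seed 42 --out report.json           # full synthetic pipeline
```

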