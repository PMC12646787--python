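# eggid

Quantify avian egg phenotypes from calibrated UV–visible photographs and
identify conspecific parasitic eggs.

Conspecific brood parasitism — a female laying an egg in the nest of another
female of the same species — is hard to detect in the field because the
foreign egg closely resembles the host's. When a female's eggs are more
similar to each other than to other females' eggs (within-clutch variation
below between-clutch variation), egg appearance carries an individual
signature that statistical methods can exploit. `eggid` implements a full
pipeline for this problem, developed around barn swallow (*Hirundo rustica*)
clutches but applicable to any species with calibrated egg photographs:

1. **Imaging** — from a calibrated multichannel egg image (R, G, B, UV,
   luminance reflectance in [0, 1], egg mask, px/mm scale): flat-field
   correction by Gaussian-blur division, spot segmentation by Phansalkar
   local thresholding (T = m(1 + p·e^(−qm) + k(s/R − 1))), spot/background
   colour means, a 10-bin luminance histogram, a granularity spectrum
   (band-pass pattern energy and skewness at 12 geometric scales × 4 egg
   regions), spot size/coverage/dispersion, and shape metrics (length,
   width, volume and surface of the solid of revolution, ellipse deviation,
   aspect ratio).
2. **Traits** — five per-group PCAs reduce the raw measurements to nine
   phenotypic traits (3 colour, 1 luminance, 2 pattern, 2 spot-pattern,
   1 shape); a random forest classifying female identity ranks the traits by
   out-of-bag mean decrease in accuracy, which doubles as multiplicative
   trait weights for distance-based methods.
3. **Identity statistics** — within/between-clutch variance metrics with a
   one-sample t-test, Beecher's information statistic H_S (bits of identity
   in the decorrelated phenotype, summed over significant components:
   Σ ½·log₂ F), and laying-order deviation profiles.
4. **Detection** — three detectors:
   * *MED*: the maximum over eggs of the mean pairwise weighted Euclidean
     distance within a clutch, thresholded to flag parasitized clutches;
   * *unsupervised*: in a known-parasitized clutch, the egg with the largest
     mean weighted distance is called parasitic;
   * *supervised*: a random forest classifies egg pairs as same/different
     female (features: |Δ| of the nine traits) and votes over repeated
     balanced trainings (265/265 pairs); validation is leave-one-clutch-out
     or, when the host's regular laying sequence is known, leave-one-egg-out.
     Vote ties are reported as ambiguous, never broken.
5. **Simulation** — hierarchical Gaussian clutch generator (female means ~
   N(0, σ_b²I₉), eggs ~ N(mean, σ_w²I₉)), exhaustive enumeration of
   (host clutch × foreign egg) combinations, per-participant assessment sets
   in two game layouts (pick the odd egg among six; pick between two
   candidates given four known host eggs), and a prolate spotted-egg
   renderer with ground-truth spot masks for imaging oracles.

## Worked example

Generate 54 synthetic five-egg clutches at the spreads observed in real
barn swallow clutches (within 0.58, between 0.82 on z-scored traits), report
the identity statistics, simulate one participant's 54 parasitized clutches
and identify the parasitic eggs in the two-candidate game:

```sh
eggid synth --out demo --seed 1
eggid identity-report --traits demo/traits.csv --out demo/identity.json
eggid simulate-parasitism --traits demo/traits.csv --out demo/layouts.csv \
    --n-participants 1 --seed 1
eggid identify --traits demo/traits.csv --layouts demo/layouts.csv \
    --method unsupervised --game 2 --out demo/calls.csv
eggid evaluate --calls demo/calls.csv --out demo/report.json
```

prints

```
within 0.55 (sd 0.07), between 0.86, t=-31.19 df=53, Hs=15.12 (control 0.31)
accuracy 98.1% (53/54, 0 ambiguous)
```

Reading: the recovered within-clutch metric (0.55) sits well below the
between-clutch metric (0.86) — the one-sample t-test is decisive at 53
degrees of freedom — so these synthetic eggs carry a strong individual
signature (H_S = 15.1 bits against a shuffled-label control of 0.31; real
eggs carry far less, since their traits are correlated and noisy). With that
signature, weighted-distance identification picks the right parasitic egg in
53 of 54 two-candidate clutches. Python equivalents of every stage are
exported from `eggid` (`synth_clutches`, `clutch_variance_stats`,
`beecher_hs`, `unsupervised_identify`, `supervised_identify`, ...).

For real photographs, start instead from `eggid extract-features
--metadata metadata.csv --out features.csv` (a sidecar CSV declaring
egg_id, clutch_id, scale_px_per_mm, blunt_end and the image path per egg)
followed by `eggid build-traits` and `eggid rank-traits`.

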