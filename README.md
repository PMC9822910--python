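# edcrowd

Image-based occupancy measurement and congestion analytics for hospital
emergency-department (ED) waiting areas.

Hospital managers need quantitative evidence of where and when their
departments are crowded, but collecting crowd data by hand is expensive.
`edcrowd` implements a complete measurement stack for doing this from
surveillance stills and routine visit records:

* **Crowd counting by density-map regression.** Head-point annotations are
  converted into Gaussian density maps (kernel 15 px, σ = 4 px) whose total
  pixel mass equals the head count, and a multi-fusion convolutional
  network (MFCNN) — an encoder–decoder with bottleneck residual blocks, a
  strip-wise fine-grained regressor and a global-average-pool regression
  head — is trained to predict those maps from raw frames. Counting
  accuracy is scored with the mean counting error
  `MCE = (1/R) Σ |C_gt − C_pred|` and
  `RMSE = sqrt((1/R) Σ (C_gt − C_pred)²)`.
* **A surveillance sampling design.** One one-minute video every half hour
  per area, frames extracted at 0.2 FPS (10 per video); 24-hour areas yield
  48 videos/day and 8:00–18:00 areas 21/day. Per-slot counts are averaged
  into chronological count tables with exact margins.
* **Unit congestion rates from proxemics.** A floor area `A` holds
  `N_theoretical = A / (π d²)` people at Hall's personal distance
  `d = 1.2 m`; the unit congestion rate is
  `R_c = N_actual / N_theoretical`. `R_c > 1` flags crowding, `R_c ≪ 1`
  flags wasted space.
* **Visit-time statistics.** From each record's earliest receipt,
  diagnosis, payment and dispensing timestamps, the diagnosis duration
  `T2` and post-diagnosis visit duration `T1` are derived, grouped by sex,
  age band, number of diagnoses and disease category, and compared with an
  automatically selected test (t-test for 2 groups; ANOVA when groups are
  Shapiro–Wilk-normal with Levene-homogeneous variances, otherwise
  Kruskal–Wallis; significance at P < 0.05).

Everything is exercised end-to-end on synthetic data: the `scenes` module
renders annotated waiting-room frames, half-hourly crowd profiles with
morning/evening peaks, and visit records with planted effects, so the whole
pipeline is testable on a laptop with no external data. The network runs on
a small NumPy reverse-mode autodiff engine included in the package.

## Worked example

The packaged one-week survey of a five-area tertiary ED (floor areas, mean
occupancies and the weekly census) reproduces the study's headline numbers:

```bash
$ edcrowd schedule
Registered: 21 videos/day
Pediatrics: 48 videos/day
Internal medicine and Surgery: 48 videos/day
Inspection: 21 videos/day
Pharmacy: 21 videos/day
5 areas x 7 days: 1113 videos, 11130 frames (offsets [0.0, 5.0, ..., 45.0] s)

$ edcrowd congestion-report
                               area_m2  seats  n_theoretical  mean_n_actual  mean_congestion_rate
area
Registered                      115.02     12          25.43          30.54                  1.20
Pediatrics                       67.14     30          14.84          40.75                  2.75
Internal medicine and Surgery    66.78     16          14.76          23.19                  1.57
Inspection                       44.73      1           9.89           7.84                  0.79
Pharmacy                        110.24     10          24.37           3.82                  0.16
```

Pediatrics waits at 2.75 times its personal-space capacity (the most
crowded area), while the pharmacy sits at 0.16 — strong evidence of both
congestion and space waste in the same department. A deterministic
end-to-end demonstration (scenes → density maps → short training → count
table → congestion report → visit statistics) runs with:

```bash
edcrowd full-demo --seed 1 --out demo/
```

In Python the same pieces compose directly:

```python
import edcrowd as ec

scene = ec.generate_scene(n_heads=25, height=96, width=128, seed=1)
dmap = ec.density_from_annotations(scene)     # mass == 25 exactly
cap = ec.theoretical_capacity(67.14)          # 14.84 people
rate = ec.congestion_rate(40.75, cap)         # 2.75
```

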