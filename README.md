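# chronospread

Diurnal activity archetypes and the spread of potentially disinformative
content on social media.

People post on social media in recognisable daily rhythms. When each
post also carries a source-reliability label, those rhythms can be
crossed with content quality: do "evening types" share more unreliable
content than "morning types"? Is unreliable content over-represented at
night, however "night" is defined? `chronospread` is a reusable pipeline
for exactly this kind of digital-chronobiology question. It is aimed at
computational social scientists and behavioural researchers who have (or
can emulate) a stream of timestamped, source-classified posts.

## The analysis

Given posts `P(t, i, f)` by user `i` of content type `f` in 15-minute
interval `t` (96 bins per day, local civil time):

* **Activity curves.** A user's diurnal activity is the share of their
  posts per bin, `a(t,i) = Σ_f |P(t,i,f)| / Σ_{s,f} |P(s,i,f)|`; curves
  are smoothed by a circular Gaussian rolling average (90-minute window,
  σ = 3 bins, wrapping at midnight).
* **Archetypes.** Users with fewer than 240 posts form an *infrequent*
  cluster; the rest are k-means-clustered (k = 3) on their smoothed
  curves and named *morning*, *intermediate* and *evening* from their
  peak times. Calinski–Harabasz, Davies–Bouldin, Silhouette,
  generalized Dunn and COP indices document the choice of k.
* **Harmonic smoothing.** Cluster curves are denoised by discrete
  Fourier transform, keeping the DC level plus the `m` largest-amplitude
  harmonics; `m ∈ [1, 4]` is chosen by an elbow rule voted over seven
  curve-distance metrics (partial curve mapping, area, discrete Fréchet,
  curve length, dynamic time warping, MAE, MSE).
* **Waking windows.** The 16 continuous hours of highest circular
  activity sum are a coarse proxy for a cluster's waking period; the
  complement is *prolonged wakefulness*. Curves can be re-indexed to
  hours-since-waking.
* **Content ratios.** Sources fall into nine categories of increasing
  Harm Score; categories scoring ≥ 7 (*Political*, *Fake and Hoax*,
  *Conspiracy and Junk Science*) are *potentially disinformative*. The
  per-user ratio `r^H(t,i)` divides disinformative posts by all
  classified posts (excluding the unclassifiable *Other*, which absorbs
  *Shadow*); cluster ratios are unweighted means over users with defined
  bins. Bins whose smoothed ratio exceeds its third quartile mark times
  of increased susceptibility.
* **Day vs night.** Three "day" definitions — fixed clock borders
  (annual sun times at the Italian centroid, 6:30–18:45), monthly
  geometric sunrise–sunset, and the inferred waking window — with a
  1-hour safety margin around each border. Ratio distributions are
  compared day vs night by one-tailed Mann–Whitney U tests (exact by
  enumeration for small samples), plus Spearman correlations, χ²
  contingency tests, Shapiro–Wilk, and Hartigan's dip test of
  unimodality (computed exactly; calibrated by a seeded bootstrap
  against the uniform null).
* **Lockdown.** Per-cluster percent changes in posts/day/user,
  disinformative posts/day/user and mean user disinformative ratio
  between a lockdown sub-interval and the rest of the span.

The original data this design mirrors is restricted, so the
`synthetic` module generates post streams with planted structure —
archetypes with wrapped-normal bimodal intensities, heavy-tailed post
counts, night-elevated disinformative probabilities, a lockdown rate
bump — making every downstream stage testable end to end.

## Worked example

```python
from chronospread import RunConfig, SyntheticConfig, run_pipeline

cfg = RunConfig(
    synthetic=SyntheticConfig(n_users=60, seed=1,
                              date_span=("2020-02-01", "2020-08-01")),
    run_validity=False, dip_draws=4000, dip_boots=200,
    outdir="results/demo")
res = run_pipeline(cfg)

names = res["model"].names
print("cluster sizes:", {names[c]: len(res["model"].members(c))
                         for c in sorted(names, key=str)})
print("clock-day borders:", res["borders"])
for cid, w in res["windows"].items():
    peak = res["peaks"][cid][0]
    print(f"{names[cid]:>12}: waking {w.onset:5.2f}-{w.end:5.2f} h, "
          f"top activity peak {peak[0]:.2f} h")
clock = res["daynight"].query("definition == 'clock'")
for _, row in clock.iterrows():
    print(f"{row.cluster:>12} clock-day vs night: U={row.U:7.1f} "
          f"p={row.p:.2e} less={row.less or '-'}")
```

prints:

```
cluster sizes: {'infrequent': 26, 'intermediate': 10, 'evening': 15, 'morning': 9}
clock-day borders: (6.5, 18.75)
  infrequent: waking 10.25- 2.25 h, top activity peak 17.75 h
intermediate: waking  8.25- 0.25 h, top activity peak 12.25 h
     evening: waking 10.50- 2.50 h, top activity peak 23.00 h
     morning: waking  6.50-22.50 h, top activity peak 9.25 h
  infrequent clock-day vs night: U=  468.0 p=7.21e-04 less=day
intermediate clock-day vs night: U=   25.0 p=7.24e-13 less=day
     evening clock-day vs night: U=  339.0 p=4.76e-06 less=day
     morning clock-day vs night: U=  701.0 p=7.09e-01 less=-
```

Reading this: the generator planted four archetypes and k-means
recovered them (peaks at 9:15, 12:15 and 23:00 for morning,
intermediate and evening types). The fixed clock-day borders computed
from solar geometry are 6:30 and 18:45. For three of four clusters the
day-time distribution of the potentially disinformative ratio is
significantly *smaller* than the night-time one (column `less=day`) —
the planted night elevation — while the morning cluster, which is
barely active at night, shows no significant difference in this run.
Artifacts (assignment tables, curves, test tables, a manifest with all
parameters and seeds) land in `results/demo/`.

The same run is available from a shell:

```sh
chronospread simulate --n-users 60 --seed 1 posts.csv
chronospread run --input posts.csv results/demo
chronospread daynight --definition clock --margin 1.0
```

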