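# bpengage

Engagement-trajectory clustering and follow-up effect estimation for
mHealth blood-pressure (BP) self-monitoring event logs.

## The problem

Hypertension self-management apps log, per patient, the days on which a
self-measured BP reading was uploaded and the dates on which a health-care
provider followed up (by phone or message). Two questions drive this
package:

1. **What longitudinal engagement patterns exist?** Patient engagement
   (PE) in week *w* is the number of distinct days with at least one BP
   record, an integer 0–7, over the first 4 weeks after registration.
   Patients are clustered on these length-4 series with **K-means under
   dynamic time warping (DTW)**, centroids updated by DTW barycenter
   averaging (DBA), and the number of clusters chosen by the **silhouette
   score** of the DTW distance matrix over k ∈ {3..7}. Four archetypes
   emerge: PELL (started low, dropped lower), PEHH (high, stayed high),
   PEHL (high, dropped), PELH (low, rose).
2. **What does a provider follow-up do?** For each follow-up event in
   week *i*, the effect samples are

   CPE = (1/N) Σ (PE<sub>i+1</sub> − PE<sub>i</sub>)  [days/week]  
   CSBP = (1/N) Σ (SBP<sub>i+1</sub> − SBP<sub>i</sub>)  [mmHg]

   where SBP<sub>i</sub> is the week-*i* mean systolic pressure and N the
   number of follow-ups in a stratum (cluster × follow-up type, or
   cluster × event week). Cluster differences are tested with chi-square
   tables, pairwise two-proportion z tests, two-way Type-III ANOVA and
   Bonferroni post-hocs.

Because the underlying clinical logs are not public, the package ships a
**synthetic cohort generator** that reproduces the published statistical
structure of the study cohort — archetype sizes 183/142/148/89, weekly
engagement means/SDs, demographic and first-week SBP margins, both
follow-up count margins (680 events), and injectable per-follow-up
effects — so every stage is testable end to end with a known ground
truth.

## Worked example

The numbered drivers under `analysis/` run the study pipeline on the
default synthetic cohort and write their tables under `results/`:

```bash
python analysis/01_simulate.py      # event log: 612 patients (562 passers + 50 failers)
python analysis/02_extract.py      # inclusion filters + weekly trajectories
python analysis/03_cluster.py      # DTW k-means, silhouette selection
python analysis/04_effects.py      # CPE / CSBP by cluster x type and x week
python analysis/05_characterize.py # chi-square, ANOVA, post-hocs
```

Output of the clustering step (seed 1 cohort, clustering seed 7):

```
silhouette by k: {3: 0.451, 4: 0.49, 5: 0.437, 6: 0.375, 7: 0.35}
-> best k = 4
  PEHH: n=152, centroid=[6.0, 6.9, 6.9, 5.9]
  PELL: n=189, centroid=[2.1, 0.3, 0.2, 0.9]
  PELH: n=86, centroid=[2.5, 1.9, 5.3, 4.6]
  PEHL: n=135, centroid=[5.8, 5.3, 2.5, 1.6]
```

The silhouette peaks at four clusters and the recovered cluster sizes and
centroid shapes track the planted archetypes (183/142/148/89; the
boundary patients that swap between overlapping archetypes are discussed
in `docs/methods.md`). The effect step then prints, for example,

```
headline: CPE(PELH, compliance) = +1.50 days/week (SD 1.77, N=48)
```

i.e. in the late-rising cluster a compliance follow-up is followed by
about 1.5 more recording days the next week — recovering the +1.31
days/week effect injected by the generator for that stratum to within
sampling noise.

The same pipeline runs as one command on any event-log directory in the
generator's CSV dialect (`demographics.csv`, `bp_records.csv`,
`followups.csv`):

```bash
bpengage all --seed 1 --out-dir results/run    # or --input <dir> for real logs
```

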