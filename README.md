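# crossnet

Cross-network resting-state functional-connectivity analysis for two-group
chronic-pain studies, centred on the striatum.

Chronic pain is increasingly understood as a property of communication
*between* intrinsic brain networks rather than activity within any single
region. `crossnet` implements that idea as a tested pipeline: it turns 4D
BOLD volumes into cleaned regional time series, computes within- and
cross-network functional-connectivity strength (FCS) over seven canonical
resting-state networks (motor, default-mode, salience, striatum, temporal,
hippocampus, dorsal-attention), condenses the striatum's coupling to the
rest of the brain into one scalar per subject — the **STM index** — and
relates that index to self-reported pain. A seed-based module computes
voxelwise periaqueductal-grey connectivity with Monte-Carlo cluster-extent
correction.

The statistical core, in standard notation:

- FC(i, j) = Pearson r between the BOLD series of regions i and j.
- Within-network FCS = mean FC over the n(n−1)/2 pairs of a network
  (15 pairs for the 6-region striatum).
- Cross-network FCS(A, B) = mean FC over all |A|·|B| pairs between
  networks A and B.
- STM index = mean of the six cross-network FCS values between the
  striatum and the other six networks.
- Pain model: `index = β₀ + β₁·PL + ε`, fitted by OLS (PL = 0–10
  visual-analog pain score); group contrasts use the two-sided Wilcoxon
  rank-sum test with Bonferroni correction over the 21 network pairs.
- Seed maps: m = artanh(r) per voxel, pooled-variance two-sample t, and an
  AlphaSim-style null-simulated minimum cluster extent at voxel p and
  cluster α.

A synthetic-cohort generator draws Gaussian time series with block
covariance (within-network, cross-network, and pain-linked striatal
decoupling in the patient group), so the entire chain is exercisable
end-to-end without any scanner data. The two study population tables
(10 patients with pain scores and indices, 13 healthy controls) ship with
the package.

## Worked example

Fit the index-on-pain model to the packaged patient table:

```python
from crossnet import StmPainModel, load_paper_fixtures

patients = [r for r in load_paper_fixtures() if r.group == "FBSS"]
print(StmPainModel.from_records(patients).fit().summary())
```

```
Striatum index ~ pain score (OLS)
================================================
n observations      9
excluded (missing)  ['FBSS_07']
beta0 (intercept)   +0.3051  SE 0.0444
beta1 (pain slope)  -0.0311  SE 0.0066
  95% CI            [-0.0468, -0.0155]
R-squared           0.7596
slope p (2-sided)   0.002201
```

One patient is dropped for a missing index (imaging artifacts); across the
nine remaining patients the striatum index falls by ≈ 0.031 per pain point,
explaining 76% of the index variance — lower striatal cross-network
coupling goes with worse pain.

Run the whole cohort analysis on a synthetic dataset:

```python
import pandas as pd
from crossnet import CohortSpec, CrossNetworkModel, generate_parcel_cohort

ts, recs = generate_parcel_cohort(CohortSpec(seed=7))
meta = pd.DataFrame(
    [{"subject_id": r.subject_id, "group": r.group, "vas_pain": r.vas_pain}
     for r in recs]
)
print(CrossNetworkModel(ts, meta).fit().summary())
```

```
Cross-network connectivity analysis
================================================
CN: n=12  index mean 0.2765  SD 0.0211
FBSS: n=10  index mean 0.0950  SD 0.0702
group comparisons: 21 network pairs, 6 Bonferroni-significant at alpha=0.05
  MTN-STM: p_adj = 0.001834
  DMN-STM: p_adj = 0.001834
  SAN-STM: p_adj = 0.001834
  STM-TEP: p_adj = 0.001834
  STM-HIP: p_adj = 0.001834
  STM-DAN: p_adj = 0.001834
```

Exactly the striatum-involving comparisons separate the groups — the
pattern the index is designed to summarise.

The same stages are available from the shell:

```bash
crossnet simulate --out sim/ --volumes
crossnet extract --bold sim/CN_01_bold.nii.gz --atlas sim/atlas.nii.gz \
    --labels sim/atlas_labels.tsv --out CN_01_ts.tsv
crossnet connectivity --ts sim/ --out fc/
crossnet group-stats --fc fc/ --meta sim/subjects.tsv --out report.json
crossnet seed-fc --bold sim/ --meta sim/subjects.tsv --seed "1,-29,-12" --out seed/
```

## Layout

- `src/crossnet/extraction.py` — volume dropping, despiking, detrending,
  ROI averaging, nuisance regression
- `src/crossnet/connectivity.py` — FC matrices, FCS, the STM index, Fisher z
- `src/crossnet/inference.py` — rank tests, Bonferroni, pain regression
- `src/crossnet/model.py` — `StmPainModel` / `CrossNetworkModel` fit surfaces
- `src/crossnet/seedfc.py` — seed ROI, z-maps, t-maps, cluster correction
- `src/crossnet/synthetic.py` — cohort and volume generators, packaged tables
- `src/crossnet/pipeline.py`, `src/crossnet/cli.py` — end-to-end driver + CLI
- `docs/methods.md` — model details, defaults, and design decisions
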