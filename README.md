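# alphaconn

Alpha-band (7–8 Hz) EEG functional-connectivity analysis for infant-sibling
cohort studies: debiased weighted phase lag index (dbWPLI) connectivity from
epoched EEG, Network-Based-Statistics (NBS) group comparison, global and
selected-connection connectivity summaries, and brain–behaviour correlation
analyses, together with a synthetic EEG/cohort generator carrying known
ground truth.

The package is aimed at developmental-EEG researchers who analyse phase-lag
connectivity in high-risk infant cohorts (groups such as LR, HR-TD, HR-Atyp,
HR-ASD) and relate it to dimensional trait scores (ADI-R, ADOS-2), and at
anyone who wants a tested, reproducible reference implementation of the
dbWPLI + NBS + rank-statistics pipeline.

## The statistics at the core

**dbWPLI.** With `X_j = F_a(j)·conj(F_b(j))` the Hann-tapered cross-spectrum
of channels *a, b* in epoch *j* at one frequency bin,

```
dbWPLI = Σ_{j≠k} Im(X_j)·Im(X_k) / Σ_{j≠k} |Im(X_j)|·|Im(X_k)|
```

— a pairwise-product (debiased) estimator of squared weighted phase-lag
connectivity: expectation ≈ 0 under independence, ≤ 1, insensitive to
zero-lag (volume-conducted) mixing because only imaginary cross-spectra
enter. Per-bin matrices are averaged over 7–8 Hz; *global* connectivity is
the mean below the matrix diagonal and *selected* connectivity the mean over
a fixed edge mask.

**NBS.** Edge-wise one-tailed Mann–Whitney Z matrices are thresholded
(default Z > 1.96) and the extent (edge count) of each connected component
is referred to the permutation null of the *maximum* component extent
(default 5000 label shuffles), controlling family-wise error over all edges.

**Cohort statistics.** Shapiro–Wilk/Levene dispatch between t and
Mann–Whitney tests; exact or tie-corrected asymptotic U p-values with
r = z/√N; Pearson chi-square without continuity correction; Spearman
correlations with single-maximum winsorising and Benjamini–Hochberg FDR for
non-a-priori families; RRB subtype scores summed from ADI-R item ever
scores.

## Worked example

Simulate a 33-infant cohort (20 "LR", 13 "HR-ASD") in which a 5-edge
subnetwork carries stronger 7.5-Hz phase-lagged coupling in the HR-ASD group
and an ADI-R-like trait score is a noisy monotone function of each subject's
planted coupling strength — then run the full analysis:

```python
import numpy as np
from alphaconn import *

edges = [(0, 1), (0, 2), (1, 2), (1, 3), (2, 3)]
pairs = tuple(CouplingPair(i, j, 7.5, np.pi / 2, 1.0) for i, j in edges)
cfg = CohortConfig(
    group_sizes={"LR": 20, "HR-ASD": 13},
    coupling_by_group={"LR": (0.15, 0.1), "HR-ASD": (0.55, 0.25)},
    traits={"adi_rrb": TraitModel(intercept=1.0, slope=8.0, noise_sd=1.0, integer=True)},
    template=SimConfig(n_channels=8, duration=64.0, fs=250.0,
                       coupling_pairs=pairs, snr=2.0),
    seed=0,
)
recordings, cohort, truth = simulate_cohort(cfg)
report = analyze_cohort(
    dict(zip(cohort["subject"], recordings)), cohort,
    edge_mask=EdgeMask.from_edges(edges, 8),
    comparisons=[("HR-ASD", "LR")],
    nbs_kwargs={"n_permutations": 2000},
    correlations=[{"name": "hrasd", "groups": ["HR-ASD"],
                   "measures": {"global": "dbwpli_global",
                                "selected": "dbwpli_selected"},
                   "scales": ["adi_rrb"]}],
    seed=1,
)
print(report.global_tests["HR-ASD_vs_LR"])
for c in report.nbs_results["HR-ASD_vs_LR"].significant:
    print("NBS component:", c.edges, "extent", c.extent, "p", round(c.p_value, 4))
print(report.correlations["hrasd"].to_string(index=False))
```

prints

```
TestResult(U = 246, z = 4.274, exact 2-tailed p = 1.769e-06, r = 0.74)
NBS component: [(0, 1), (0, 2), (1, 2), (1, 3), (1, 5), (1, 6), (2, 3)] extent 7 p 0.001
 measure   scale      rho        p  n
  global adi_rrb 0.461454 0.112450 13
selected adi_rrb 0.593700 0.032417 13
```

Each subject contributed 127 clean 1-s epochs (all above the >120 inclusion
rule). The Mann–Whitney test detects the planted group difference in global
connectivity (U = 246 for the 13 HR-ASD subjects vs 20 LR, r = 0.74); the
NBS component (p = 0.001 over 2000 permutations) contains all five planted
edges plus two spillover edges touching the coupled channels; and within the
HR-ASD group the selected-edge connectivity correlates with the simulated
trait score (rho = 0.59) more strongly than global connectivity does —
exactly the planted structure. Every number is deterministic under the
configured seeds.

The same pipeline runs from the shell over files
(`alphaconn simulate | preprocess | connectivity | nbs | stats | run`); see
`alphaconn --help`.

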