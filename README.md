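# updrs-abbrev

Discovery and validation of abbreviated MDS-UPDRS rating scales by
exhaustive subset search.

The Movement Disorder Society Unified Parkinson's Disease Rating Scale
(MDS-UPDRS) scores disease severity through 50 items — 65 individual
0–4 ratings across four parts — and takes around 30 minutes, which
limits its use in busy clinics and over telemedicine. This package
implements the computational route to a short form: enumerate **every**
k-item subset, score each by how much of the full-scale total its
unweighted rating sum explains, apply remote-assessment practicality
constraints, and validate the winner as an estimator of the total on an
independent cohort. It is aimed at clinical-scale methodologists and
anyone who wants to re-run or extend the search on their own
MDS-UPDRS exports (or on a different instrument, via a pluggable
definition file).

## The statistic at the core

For a subset S, let x = Σ_{i∈S} x_i be the unweighted sum of the
subset's ratings and y the 65-rating total (0–260). Each candidate is
scored by the explained variance score of the least-squares fit
ŷ = βx + α:

    EVS(S) = 1 − Var(y − ŷ)/Var(y) = Cov(x, y)² / (Var(x) · Var(y)),

the right-hand closed form following because EVS equals R² for
intercept-including least squares. Since Var(x) and Cov(x, y) are sums
of entries of the item-score covariance matrix, every subset is scored
in O(k²) from sufficient statistics computed once — which is what makes
the exhaustive searches (C(42,8) = 118,030,185 remote-pool candidates,
C(50,8) = 536,878,650 unconstrained) desk-sized jobs. Secondary metrics
(Pearson and Spearman correlation), bootstrap percentile intervals,
residual/unbiasedness analysis, Bland–Altman agreement and conditional
distributions support the validation of the winning subset.

Because the real training and validation datasets are access
restricted, the package ships a synthetic-cohort generator (latent
severity factor + part factors + ordinal discretisation) that
reproduces the structural features the search relies on; see
`docs/methods.md`.

## Worked example

Generate study-sized synthetic cohorts, search the remote pool
exhaustively, and validate the winner (a few minutes for the search):

```sh
python analysis/01_simulate_cohorts.py --seed 1
python analysis/02_search_subsets.py
python analysis/03_evaluate_transfer.py
```

which prints (abridged):

```
training cohort: n=7594, median total 43
validation cohort: n=377, median total 58
Mann-Whitney U = 1015256, p = 1.37e-21

evaluated 118,030,185 subsets
rank 1: 1.5,1.13,2.4,2.8,2.11,3.5,3.6,3.17  EVS = 0.894

conversion model: y = 3.60x + 6.48 (n = 7594)
  training           evs: +0.894 [+0.889, +0.899]
validation           evs: +0.918 [+0.900, +0.932]
  training mean_residual: -0.000 [-0.170, +0.166]
validation mean_residual: +1.478 [+0.717, +2.239]
```

Reading this: the two cohorts share an item model but the validation
cohort is more severe (higher median total; the Mann–Whitney U
comparison is reported with U oriented to the first cohort). The best
remote-administrable 8-item subset explains 89% of the total's variance
on this synthetic training cohort; the fitted conversion from the
8-item sum to the 50-item total is y = 3.60x + 6.48; its mean residual
on the training data is zero (the least-squares unbiasedness identity)
while the slight positive validation bias — about 1.5 points of 260 —
is the expected under-estimation on a more severe cohort (see the
conditional-bias discussion in `docs/methods.md`). Numbers describe the
synthetic cohorts, not real patients.

To score externally proposed subsets (for instance the published
remote-optimal 8 items) on any cohort:

```sh
python analysis/04_fixed_subsets.py
# remote_optimal (published): EVS=0.830 PCC=0.911 SRC=0.901
# any_item_optimal (published): EVS=0.844 PCC=0.919 SRC=0.909
```

The same stages are available as one CLI with checkpointable searches
and run manifests:

```sh
updrs-abbrev simulate --n 1000 --seed 42 --out train.csv,val.csv
updrs-abbrev search --input train.csv --k 8 --pool remote --out ranked.tsv
updrs-abbrev evaluate --train train.csv --validate val.csv \
    --subset "1.13,2.5,2.10,2.12,3.2,3.4,3.9,4.3" --out report/
updrs-abbrev full-pipeline --n 1000 --seed 42 --out run/
```

## Loading real exports

`load_assessments` reads wide CSV (one row per assessment, 0–4 integer
cells, empty/NA for missing) and a column map translating export codes
to the canonical rating fields; `docs/ppmi_column_map.example.yml`
shows the expected shape for a PPMI-style export. The completeness
filter keeps exactly the assessments with all 65 ratings present;
covariates (Hoehn & Yahr stage, age, gender) may be missing freely. The
instrument structure itself lives in
`src/updrs_abbrev/data/mds_updrs_items.tsv` (columns: `item_id`,
`name`, `part`, `rating_fields` comma-joined, `exclusion_reason` one of
`none`/`face_to_face`/`lower_limb`), so a different instrument is a
matter of a different TSV.

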