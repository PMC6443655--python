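# comorec

Comorbidity discovery from health-insurance claims data: an item-based
recommender over diagnosis-code co-occurrence, followed by a case-control
confirmation stage with survey-weighted logistic regression.

## The problem

Choosing which diseases to study alongside an index disease (here:
endometriosis, ICD-10 N80.x) is usually driven by clinical intuition or
prior literature.  Claims databases — such as Korea's HIRA national
inpatient sample, a weighted probabilistic sample of annual claims — record
millions of patient-years of diagnosis codes and make a data-driven
alternative possible: treat diseases as *items* and patients as *users*,
and let an item-similarity recommender propose candidate comorbidities,
which are then tested formally in a weighted case-control analysis.

`comorec` implements that two-stage pipeline for epidemiologists and
health-services researchers, together with a synthetic claims generator
with *plantable* pairwise disease associations, so that every stage can be
validated end-to-end without access to non-public claims data.

## The method

**Stage 1 — recommender.** Patients are split 80/20.  On the training
split, a binary incidence matrix over three-character ICD-10 categories
(N80 from N80.1, N30 from N30.0, …) is built, and the similarity between
two disease categories *a*, *b* is the Jaccard index of their patient sets

    J(a, b) = |P_a ∩ P_b| / |P_a ∪ P_b|.

The top-K (default 30) categories most similar to the query are extracted;
gynecologic categories (C51–C58, D06–D07, D25–D28, O00–O99, N70–N77,
N80–N98) are then excluded, since they co-occur with the index disease
through gynecologic examination rather than shared aetiology.  The model is
validated on the held-out split by a single-held-out-item protocol (mean
precision and recall at top-N).

**Stage 2 — confirmation.** Among women aged 15–45, cases are patient-years
with an N80.x code *and* a concurrent treatment code (gynecologic surgery
or hormonal prescription); controls carry no N80.x code; N80-coded women
without treatment are dropped.  Candidate diseases are flagged by
diagnosis-plus-test-code definitions (e.g. a cystitis code N30.x plus a
urine-test code).  Crude and adjusted odds ratios come from logistic
regression in which each record's sampling weight (7.692 inpatient, 100
outpatient) multiplies its Bernoulli log-likelihood:

    endometriosis ~ age band (per 5 years) + data year + low SES + disease flags

with Wald 95% intervals from a sampling-weight sandwich variance by
default.

## Worked example

Generate a synthetic population of 500,000 patient-years from the bundled
preset (seven candidate comorbidities planted at odds ratios 1.5–3 against
N80, plus gynecologic and background diseases), then run both stages:

```sh
comorec synth --n 500000 --seed 1 --out claims.csv
comorec recommend --claims claims.csv --query N80 --top-k 30 --seed 1 --out candidates.csv
comorec confirm --claims claims.csv --level category --out tables/
```

The recommend step prints

```
18 candidates after exclusion; held-out mean precision 0.039, mean recall 0.992 (9714 patients, n_rec=30)
```

and the top of `candidates.csv` ranks the planted comorbidities by their
Jaccard similarity to N80 (iron-deficiency anaemia D50, planted OR 3.0,
comes first):

```
category,similarity
D50,0.014421
N30,0.010348
D24,0.007989
N60,0.007524
```

`tables/odds_ratios_category.csv` holds the confirmation results, e.g.

```
term,unadjusted_or_ci,unadjusted_p,adjusted_or_ci,adjusted_p
benign_mammary_dysplasia,2.69 (1.54–4.67),0.0004784,2.69 (1.54–4.68),0.0004953
nontoxic_goitre,1.90 (1.21–2.98),0.005183,1.90 (1.21–2.98),0.005172
iron_deficiency_anaemia,3.60 (2.72–4.77),4.144e-19,3.58 (2.70–4.74),6.983e-19
```

— adjusted odds ratios near their planted values where flagged cases are
numerous (3.58 vs a planted 3.0 for anaemia), with the wide intervals that
rare flags (a few dozen flagged cases) necessarily produce.
`tables/characteristics.csv` is the matching group-characteristics table
(group sizes, weighted mean ages with a weighted t-test, count (percent)
rows with chi-square/Fisher p-values).

`comorec run-all --seed 1` executes every stage in sequence and writes all
artifacts plus a manifest sufficient to reproduce the run byte-identically.

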