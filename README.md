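# apohot

Discovery and triage of APOBEC-associated hotspot mutations in tumour
cohorts.

## The problem

APOBEC3 cytidine deaminases are a dominant mutagen in bladder cancer
(and in cervical, head-and-neck, breast and lung cancers).  They attack
cytosines in single-stranded DNA, preferring TpC dinucleotides, the
lagging-strand template of replication, and the loops of DNA hairpins.
Because hairpin-loop cytosines are hit again and again, APOBEC activity
alone can create *recurrent* mutations that carry no selective
advantage — passenger hotspots — which breaks the usual assumption
that recurrence implies driver status.

`apohot` implements, as a tested reusable pipeline, a strategy for (i)
finding hotspot mutations in a cohort of exome-sequenced tumours,
(ii) deciding which are APOBEC-associated, and (iii) classifying the
APOBEC-associated ones as drivers or passengers:

1. **Hotspot calling** — per-mutation recurrence counts; the head/tail
   threshold is the smallest integer *t* with
   `N(count > t) / N(count = t) > 1`.
2. **Motif and signature linkage** — candidates are hotspots whose
   pyrimidine-strand change is C>G/C>T in a TCN context (with
   YTCN/RTCN sub-typing).  Per-sample 96-channel catalogs are refit
   against a fixed signature reference by EM for the multinomial
   mixture; the APOBEC score of a sample is the summed exposure of the
   two APOBEC signatures (slots 2 + 13).  A candidate is
   APOBEC-associated when its carriers' APOBEC scores exceed those of
   tumours free of every candidate (one-sided Wilcoxon rank-sum,
   Benjamini–Hochberg).
3. **Structural context** — replication-strand asymmetry from RFD
   (Okazaki-fragment) tracks, and a nearest-neighbour minimum-free-
   energy DNA hairpin folder for 25-nt mutation-centred windows.  The
   normalised loop stability score is the min–max rescaled ΔG over
   in-loop panel sites (1 for sites not in a loop or with ΔG ≥ 0).
4. **Driver/passenger classification** — in the (loop score, expression
   rank) plane, an iterative similarity classifier assigns unknown
   mutations to the closer of the known-driver / known-passenger
   reference sets when a Welch t-test on the distance samples is
   significant; the permutation FDR enumerates all C(16,9) = 11,440
   relabelings of the seed points.  A two-step logistic (GLR)
   alternative, clonality tests (Fisher + logistic mixed model), a
   mutability-adjusted recurrence surrogate for selection intensity
   with exact 1-D two-cluster splitting, and a co-expression +
   knockdown-validated regulon activity analysis round out the toolkit.

Everything runs on synthetic cohorts generated by
`apohot.synthetic_data`, which plants recurrent APOBEC-motif sites in
hairpins of tunable stability and records a ground-truth manifest, so
every stage is testable without any external download.

## Worked example

```python
from apohot.pipeline import PipelineConfig, run_pipeline

results = run_pipeline(PipelineConfig(out_dir="demo", seed=1, run_regulon=False))
panel = results["panel"]
print("recurrence threshold:", panel.threshold)
print("hotspots called:", len(panel))
print("APOBEC-associated:",
      sum(bool(h.apobec_associated) for h in panel.hotspots))
print(results["predictions"]["label"].value_counts().to_string())
```

prints, for the default synthetic study (200 tumours, ~150 SNVs each,
28 planted APOBEC-motif recurrent sites and 2 non-APOBEC ones):

```
recurrence threshold: 2
hotspots called: 30
APOBEC-associated: 28
label
driver       7
passenger    5
```

All 28 planted APOBEC sites (and only those) are flagged as
APOBEC-associated, and the 12 hidden-role sites are classified —
7 drivers, 5 passengers, matching the planted truth.  The
`predictions.tsv` artifact carries, per mutation, the loop score (x1),
expression rank (x2), label, assignment iteration, mean
difference-of-distance, permutation p and BH FDR (the well-separated
predictions here reach the enumeration minimum, p = 1/11,440 ≈ 8.7e-5).

The same stages are exposed on the command line (`apohot ingest`,
`apohot hotspots`, `apohot signatures`, `apohot strand`, `apohot fold`,
`apohot rank`, `apohot run`, `apohot simulate`); see `apohot --help`.

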