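# acmgrules

Automated germline variant classification under the ACMG/AMP 2015
framework, for clinical bioinformaticians and variant curators who need
high-throughput, transparent, rule-level interpretation.

Given annotated variants (coordinates, consequences, population
frequencies, in-silico scores, ClinVar assertions), the engine applies
**19 automated evidence codes** — PVS1, PS1, PS3, PS4, PM1, PM2, PM4,
PM5, PP2, PP3, PP5, BA1, BS1, BS2, BP1, BP3, BP4, BP6, BP7 — and
combines them into the five-tier classification (pathogenic, likely
pathogenic, uncertain significance, likely benign, benign).  The nine
codes that require patient or family data (PS2, PM3, PM6, PP1, PP4, BS3,
BS4, BP2, BP5) enter through an external call file, which can also
override or disable any automated code.

## The model

Every evidence code is applied at an integer strength on one ladder:

    1 = supporting   2 = moderate   3 = strong   4 = very strong   5 = stand-alone

and strengths are assigned **dynamically**:

* **LOEUF-stratified frequency cutoffs** — genes fall into five
  constraint bins by their gnomAD LOEUF (loss-of-function
  observed/expected upper bound fraction); PM2, BS1, BA1 and BS2 read
  allele-frequency cutoffs from the variant's bin, so constrained genes
  get stricter thresholds.
* **ClinVar review-status weights** — assertions are weighted by review
  status (practice guidelines / expert panel → 5, multiple submitters →
  3, single submitter → 2, conflicting → 1, no assertion criteria → 0 =
  excluded); PS1/PM5/PP5/BP6 strengths follow these weights.
* **In-silico consensus** — PP3/BP4 map each tool score (REVEL, DANN,
  PhyloP, GERP, ABSplice) through a calibration ladder; agreement between
  tools upweights, a lone supporting-level tool is ignored, and a strong
  opposite signal disqualifies.

Combining follows the ACMG/AMP tables with two extensions: a
*pathogenic stand-alone* level (mirroring BA1) and an ordered two-pass
conflict check that routes variants with substantial evidence on both
polarities to Uncertain.  Every threshold lives in a flat, serialisable
configuration (`EngineConfig`); no cutoff is hard-coded in rule logic.

## Worked example

Generate a synthetic fixture suite (variants + reference bundle + expert
truth), classify it, and benchmark the output:

```bash
acmgrules simulate --seed 3 --n-per-scenario 2 --out fx
acmgrules classify --variants fx/variants.json --refs fx/bundle --out results.tsv
acmgrules validate --results results.tsv --truth fx/truth.tsv --out metrics.tsv
```

The classification TSV has one row per variant:

```
chrom  pos      ref  alt  gene    classification          codes               pathogenic_score  benign_score  conflict_stage
7      1000000  C    T    GPVS1   Uncertain significance  PVS1:very_strong    4                 0             none
```

— a stop-gained variant in a constrained gene (LOEUF 0.3) earns PVS1 at
very strong (score 4), which alone is not sufficient for a pathogenic
call.  `validate` prints per-bucket metrics; on engine-consistent
fixtures every bucket scores 100%:

```
P/LP: sensitivity=100.0 specificity=100.0 precision=100.0 f1=100.0
B/LB: sensitivity=100.0 specificity=100.0 precision=100.0 f1=100.0
VUS:  sensitivity=100.0 specificity=100.0 precision=100.0 f1=100.0
```

Manual curation folds in through the external call file
(`chrom pos ref alt code strength rationale`): strength 0 disables a
code, any other value adds or overrides it at that strength.

Reference bundles for real data are built from local tables — a
ClinVar-like variant table, domain intervals, RepeatMasker∩CCDS BED
files, a gene-constraint table, GWAS and literature tables — with
`acmgrules build-refs`.

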