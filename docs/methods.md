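# Methods

## The classification procedure

The engine is a pure function of (annotated variant, reference bundle,
configuration).  For each variant it runs 17 evaluator routines covering
19 automated ACMG/AMP evidence codes (PS1/PM5 and BA1/BS1 share a
routine each), folds in external calls, and combines the resulting
evidence set into one of the five tiers.  Evaluators never see each
other's output; all interaction happens in the combiner.

Assumptions inherited from the framework:

* one alternate allele per record (multi-allelic sites are split
  upstream);
* variant identity is exact string match on (chrom, pos, ref, alt) after
  stripping any `chr` prefix — indels are **not** left-aligned or
  normalised, so bundle and input must come from consistent
  normalisation (a documented limitation);
* variant records are 1-based (VCF convention), all interval inputs are
  0-based half-open (BED convention);
* coordinates are carried through untouched; the engine has no
  genome-build awareness.

## Evidence strengths and dynamic weighting

Strength is an integer 1–5 (supporting, moderate, strong, very strong,
stand-alone); 0 means not applied.  Up/down-weighting moves one step and
saturates (applied codes never drop below supporting, never exceed
stand-alone inside the in-silico consensus, which caps at very strong).

**ClinVar review weights** (configurable map): practice guidelines and
expert panel → 5; multiple submitters, no conflicts → 3; single
submitter → 2; conflicting interpretations → 1; no assertion criteria →
0 and excluded everywhere.  Unknown statuses map to 0.

**LOEUF bins.**  Five bins with upper bounds 0.35, 0.6, 1.0, 1.5, ∞
(inclusive edges; a gene with LOEUF exactly 1.5 is bin 3).  Genes absent
from the constraint table use the middle bin (bin 2), assuming neither
maximal stringency nor maximal leniency.  Default per-bin
allele-frequency cutoffs (most → least constrained):

| cutoff          | bin 0 | bin 1 | bin 2  | bin 3  | bin 4 |
|-----------------|-------|-------|--------|--------|-------|
| PM2 standard    | 1e-6  | 2e-6  | 5e-6   | 1e-5   | 2e-5  |
| PM2 supporting  | 5e-6  | 1e-5  | 2.5e-5 | 5e-5   | 1e-4  |
| BS1 supporting  | 5e-4  | 1e-3  | 2e-3   | 5e-3   | 1e-2  |
| BS1 standard    | 2.5e-3| 5e-3  | 1e-2   | 2.5e-2 | 5e-2  |
| BA1             | 5e-3  | 1e-2  | 2e-2   | 5e-2   | 5e-2  |

Validation enforces `pm2_standard < pm2_supporting ≤ bs1_supporting <
bs1_standard ≤ ba1` per bin (the last comparison is non-strict because
the least-constrained bin saturates at 5e-2: there BS1-strong ends
exactly where BA1 begins) and non-decreasing cutoffs across bins.  The
frequency driving PM2/BS1/BA1 is the larger of the non-null gnomAD and
1000 Genomes AFs — the conservative choice when the resources disagree.
A direct consequence is that BA1 and PM2 (and BA1 and BS1) can never
co-fire, which is property-tested.

## Per-code choices that were genuinely open

* **PVS1** starts at very strong and loses one step per failed
  confidence check: LOEUF not below 1.0 (or unavailable); for splice
  donor/acceptor variants, ABSplice below the low-impact cutoff (0.2);
  and a further step below the minimal-impact cutoff (0.05).  The floor
  is supporting.  The multi-transcript rule counts all listed
  transcripts.  The "extreme 3' end" exclusion is implemented as the
  last 50 bp of any transcript's final coding exon (configurable); the
  final-exon table is a direct input, not derived from an annotation
  database.
* **PS1/PM5** take the indexed record's review weight, capped at strong
  for PS1 and moderate for PM5 so dynamic weighting cannot exceed the
  codes' nominal levels.  An exact nucleotide match to the index is
  skipped — that evidence belongs to PP5, and a ClinVar variant must not
  support itself.
* **PS3** publication tiers: 1 publication → supporting, 2–4 → moderate,
  ≥5 → strong (defaults; the counts are configuration).
* **PS4** GWAS tiers: p < 5e-8 with OR ≥ 3 → strong, p < 5e-8 with OR ≥
  1.5 → moderate, p < 1e-5 with OR > 1 → supporting.  Without a GWAS
  entry, TOPMed rarity (alternate alleles < 5, or 3–9 homozygotes) is a
  supporting-level proxy.
* **PM1** picks the overlapping domain with the highest pathogenic
  fraction (ties broken by domain id) and applies moderate by default,
  supporting when the domain is < 75% pathogenic *and* > 15% benign,
  strong when > 90% pathogenic *and* < 10% benign.
* **PM4** treats stop-loss substitutions as extension events at the
  minimum supporting strength (their nucleotide length change is 0).
* **PP3/BP4** are two sides of one consensus routine.  Each tool's score
  maps through a per-tool ladder (REVEL uses the published interval
  calibration; PhyloP's pathogenic-supporting bound is 7.367; ABSplice
  tiers follow its authors' high/medium/low cutoffs; DANN and GERP use
  conservative community defaults — all configuration data, not code).
  A side is disqualified when any tool crosses the opposite side's
  strong threshold.  Additionally, if **both** sides survive, neither
  code is applied: a consensus that simultaneously argues pathogenic and
  benign is not evidence either way.  This mutual cancellation is what
  guarantees the tested invariant that PP3 and BP4 never co-fire on the
  same score vector; disqualification at the strong threshold alone
  cannot guarantee it.
* **BS1** is implemented as high-frequency evidence with two tiers
  (supporting between its supporting and standard cutoffs, strong from
  the standard cutoff up to the BA1 cutoff).
* **BS2** thresholds: recessive homozygote 2, dominant allele count 5,
  X-linked 2, dominant AF bound 0.05 (per bin, constant by default).
  The recessive branch applies moderate between the threshold and twice
  the threshold, strong at or above twice.  The dominant branch requires
  LOEUF < 0.5; missing allele counts are treated as 0, which excludes
  the variant (observation in *every* resource is required).
* **BP3** excludes indels shorter than one codon unless they cause stop
  loss; shorter repeat indels score *higher* (strong below 15 nt,
  supporting from 15 to below 60 nt) — implemented exactly as specified
  even though the direction is surprising.
* **BP7** eligibility matches consequence terms by substring
  ("synonymous" first, then "intron", "intergenic"); both PhyloP and
  ABSplice must be present.

## Combining and conflicts

Order: (1) if both polarity score sums (sum of applied strengths) reach
the high threshold (default 4) → Uncertain, high-conflict; (2) the
pathogenic tables, extended with a pathogenic stand-alone rule; (3) the
benign tables (stand-alone, or two strong); (4) if both sums reach the
low threshold (default 2) → Uncertain, low-conflict; (5) the
likely-pathogenic tables; (6) the likely-benign tables; (7) Uncertain.

Codes count at their **exact effective level**: a very-strong code does
not also count as strong.  One consequence worth knowing: two
very-strong codes with nothing else match no published combination and
classify as Uncertain — the tables are applied literally rather than
patched.  The combiner is verified exhaustively (all 8,008 evidence
multisets of up to six codes over both polarities and levels 1–5)
against an independently written rule-table oracle, including the
monotonicity property that adding pathogenic supporting evidence never
moves a call benign-ward unless a conflict stage triggers.

Manual codes participate identically to automated ones at their
user-given level; a manual strength of 0 removes the code for that
variant.

## Reference builders

Boundary comparators follow the printed filter wording literally and
are unit-tested at each boundary: PM1 keeps a domain at exactly 50%
pathogenic, exactly 50% VUS, exactly 25% benign, and drops it at 4
variants; PP2 keeps a gene at missense O/E exactly 0.4; BP1 keeps a
gene at exactly 75% truncating pathogenic variants and exactly 25%
benign truncating.  "Truncating" means frameshift or stop-gained;
splice-disrupting consequences are not counted.  Records with review
weight 0 are dropped before PM1 counting, and conflicting-significance
records are dropped as neither pathogenic, benign nor VUS.  Bundles
serialise to a directory of TSV/text files plus a manifest with SHA-256
checksums; save → load → save is byte-identical.

## The synthetic generator

Each scenario constructs one variant (replicated `n_per_scenario`
times) together with exactly the reference-bundle entries needed to
trigger its target codes, and nothing that would trigger others:
non-frequency scenarios draw allele frequencies from the neutral band
between their gene's PM2-supporting and BS1-supporting cutoffs; genes
whose seeded ClinVar-like records would qualify them for the PP2 list
are given a missense O/E of 0.5 to keep them out.  Seeded randomness
only jitters continuous values inside their decision bands, so
generation is a pure function of (spec, seed) and byte-deterministic.
Truth labels are taken from the scenario table, not recomputed by the
engine.

What the fixtures do **not** emulate: annotation noise and missing
fields, disagreement between population resources, multi-code
interactions beyond the designed combination scenarios, real linkage
between consequence and sequence context, and real-world class
imbalance.  Passing the suite therefore shows that every rule and the
combiner implement their stated logic exactly; it does not estimate
accuracy on clinical data.

The default suite is 28 scenarios × 1 replicate (28 variants), which
keeps the full generate–classify–validate cycle under a second; the
acceptance sweeps use grids of 11–801 points per boundary.

## Numerical notes and degenerate inputs

Percentages are reported to two decimals with half-up rounding;
undefined metric denominators yield null, never 0.  Grid sweeps round
each point to the grid's decimal precision so threshold comparisons are
exact at the printed cutoffs.  A variant record that fails validation
inside a stream degrades to an Uncertain result carrying the error
rather than aborting the run.  Unknown JSON fields are ignored; missing
optional fields are null.  The streaming JSON reader keeps only one
record's tail in memory.

## Known limitations

No indel normalisation (see above); no NMD-escape logic beyond the
final-exon window; no per-gene expert-panel rule specifications; no
coverage/QC gating of population frequencies; PP3/BP4 multi-tool
consensus rather than the newer single-calibrated-tool recommendation
(restricting to one tool is possible by editing the ladder
configuration).
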