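# Methods

`asedit` post-processes transcriptome variant calls from a two-condition
bulk RNA-seq design (two groups of five biological replicates, modelled on
a pig pituitary implantation-vs-cycle comparison). It covers five
analyses: a multi-stage SNV filter cascade, differential allele-specific
expression (ASE) testing with imbalance classification and localization,
RNA-editing candidate discovery, consensus lncRNA identification, and
lncRNA–gene interaction triage. Everything runs end-to-end on synthetic
cohorts with planted truth, so each stage is auditable exactly.

## Coordinate conventions

Internal coordinates are 0-based half-open everywhere. GTF (1-based
closed) and VCF (1-based positions) are converted on ingest;
`VariantSite.pos` retains the printed VCF position and exposes `pos0` for
interval arithmetic. BED stays native. One convention internally removes
an entire class of off-by-one errors; the boundary examples in the test
suite (junction distance, paralog flank edges, SINE interval edges) pin
the arithmetic down.

## SNV filter cascade

Stages run in a fixed order, each recorded in a chained accounting report:

1. **Quality** — hard thresholds on GATK-style annotations: RMS mapping
   quality > 40, total depth > 10, quality-by-depth > 2, read-position
   rank sum > −8, mapping-quality rank sum > −12.5. All inequalities are
   strict. Absent annotations pass by default (variant callers emit the
   rank-sum statistics only when both alleles are observed in reads);
   `strict_quality` inverts that choice.
2. **Context** — removes sites within 5 bp of any splice junction
   (boundary coordinate to variant base, both sides), within 50 bp of a
   paralog interval, inside a microsatellite (SSR) mask, or inside a
   bidirectional-gene region. "Bidirectional" is read minimally: bases
   covered by gene bodies on both strands; the whole overlap is masked.
   Removal reasons are recorded and a site may carry several.
3. **Proximity** — any site in a pair within 45 bp or a triplet spanning
   ≤ 35 bp is removed; all participants go. At the default windows the
   triplet rule is implied by the pair rule, but both are implemented
   independently so non-default windows behave as documented.
4. **Prevalence** — keeps sites with alternative-allele expression
   (AAF > 0) in at least ⌈fraction × n⌉ samples; default fraction 0.5,
   i.e. "at least half".

A note on monotonicity: each stage is monotone in its own thresholds, but
the composed cascade is not jointly monotone — loosening the context rule
can rescue a neighbour that then forms a new proximity pair and removes a
previously surviving site. The tests assert per-stage monotonicity and
composition over the downstream thresholds, where it genuinely holds.

## Microsatellite scanner

The SSR mask is produced natively: maximal perfect tandem runs with motif
length 1–6 nt, reported once under their shortest period (primitive-motif
rule) at the leftmost phase, with whole-copy intervals
(length = period × count). `N` never matches, so runs break at ambiguous
bases. Default minimum copy numbers are conservative, GMATo-like
conventions: mono 12, di 7, tri 5, tetra/penta/hexa 4 — configurable,
since the mask exists for conservative exclusion rather than repeat
biology. A deliberately naive (start, period, count) enumeration ships
alongside as the scanner's oracle; property tests assert exact agreement
on random and adversarial sequences. Imperfect and compound repeats are
out of scope.

## Differential ASE test

Per site, each sample's alternative count is modelled
Binomial(depth, AAF) with the AAF shared at group level. The test is a
likelihood-ratio test: H₀ one shared AAF, H₁ one AAF per group; the
statistic 2(ℓ₁−ℓ₀) is referred to χ² with 1 df. With group-level
parameters the per-sample likelihoods pool, so the statistic reduces to
the 2×2 G-test on pooled group × allele counts — deterministic,
closed-form, and validated two ways: against `scipy`'s log-likelihood
contingency test and by Monte-Carlo calibration (empirical type-I error
0.046 at α = 0.05 on 2,000 null sites at the study design, within the
accepted [0.035, 0.065] band).

ΔAAF is the difference of *pooled* group AAFs (Σalt/Σdepth), weighting
samples by coverage; per-sample AAFs are reported for diagnostics. A site
is flagged ASE when |ΔAAF| > 0.1, BH-adjusted FDR < 0.001 (family = all
testable sites), **and** the χ² confirmation passes. The confirmation is
the 1:1 goodness-of-fit test on pooled ref/alt coverage (no continuity
correction) rejecting at p < 0.05. Under this literal gate a flagged ASE
is never a balanced heterozygote; the three-way category
(`true_heterozygote` / `HeteroRef` / `HeteroAlt`) is still computed and
reported for every tested site. BH is implemented in-package (step-up
with monotonicity enforcement) and cross-checked against statsmodels.

### Localization / consequence classes

Each site receives exactly one class by severity precedence
CDS > UTR > noncoding exon > intron > upstream/downstream > intergenic,
ties across transcripts broken by lowest transcript id. For CDS sites the
codon is read on the coding strand (strand-aware complementation), and
ref/alt codons are translated with the standard genetic code
(synonymous vs missense). The upstream/downstream flank defaults to
1000 bp (no published value; configurable). A reference-allele mismatch
against the genome is a hard error — it indicates inconsistent inputs.

## RNA-editing branch

Canonical editing reads as A>G on the edited strand (A-to-I) or C>T
(C-to-U). Strand comes from the overlapping gene; for intergenic sites
both readings are evaluated and the single canonical one (there can never
be two) is used. Candidates then must satisfy all of:

* no sample with AAF > 0.7 (an editing efficiency above 70% is treated as
  implausible; exactly 0.7 passes — the ceiling is strict),
* no known SNP identifier (VCF ID field),
* positional overlap with a PRE-1 SINE interval (flank 0 bp — the
  minimal reading of "along" the repeat; configurable),
* FDR < 0.05 and |ΔAAF| > 0.1 from the differential test.

The filter emits an audit naming every violated rule per removed
candidate. Survivors can be intersected with a known-editing-site table
on (chrom, pos, editing type). Hyper-editing clusters and editing-index
summaries are out of scope.

## lncRNA consensus identification

Structural filters first: length ≥ 200 nt, ≥ 2 exons, biotype not
protein-coding, mean expression above a floor (default 0 — no published
threshold; the knob is exposed). Surviving transcripts face a 3-of-5
coding-potential vote over externally produced scores: CPAT < 0.78,
CPC2 < 0, FEELnc < 0.558, CNCI and PLEK labelled noncoding — all strict
inequalities. Fewer than three available verdicts means exclusion for
insufficient evidence; with three or four available the 3-of-5 bar is
unchanged. Voted candidates are then excluded on domain evidence: a Pfam
hit at e-value ≤ 10⁻³ or any Rfam hit removes them. Transcripts already
annotated with an lncRNA biotype are curated knowledge: they join the
final pool after the structural filter, bypassing vote and domain
exclusion. The five predictors themselves are never run here — their
scores are inputs.

## Interaction triage

*cis*: a differentially expressed lncRNA (DEL) and gene (DEG) on the same
chromosome within 10,000 bp. The gap is edge-to-edge (overlap = 0), the
most inclusive literal reading, since no anchor (TSS vs boundary) is
published. *trans*: Pearson correlation across all ten samples (both
groups pooled — co-expression, not differential behaviour), retained when
|r| > 0.9 and p < 0.05 **and** binding evidence supports the pair:
LncTar-style ndG < −0.1 or lncPro-style probability > 0.9. The p-value is
the two-sided t transform on n−2 df; constant expression vectors are
skipped with a warning. Raw p-values are used, as the triage rule states
them; no multiplicity adjustment is applied at this step.

## Synthetic data and what it does (not) show

The generator reproduces the study's *statistical* structure, not its
biology: random 4 × 300 kb genome; 40+ multi-exon genes with CDS/UTRs on
both strands including designed opposite-strand overlaps; SINE-like and
paralog intervals; literal SSR runs (pattern-broken at both ends so the
planted interval is exactly the maximal run); 10,000 sites with
per-sample depth ~ Poisson(50) and alternative counts Binomial(depth,
AAF) with group-level AAFs (optional beta-binomial overdispersion).
Randomness comes from independent streams keyed by (seed, purpose), so
adding a generator never perturbs another's draws and identical configs
give byte-identical outputs.

Planted site classes (each violating exactly one rule, or none):

* **null** — shared AAF ~ U(0.05, 0.95); a subset carries designed
  localization classes, with synonymous/missense plants chosen from the
  generator's own hard-coded codon table (independent of the annotation
  path).
* **ase** — group AAFs (a, a + 0.3), a ~ U(0.10, 0.55), random sign.
  ASE sites are allelically imbalanced by construction, which the χ²
  confirmation requires; plants whose pooled AAF lands near 0.5 are the
  honest power cost of the confirmation gate, and measured sensitivity at
  this design is ≈ 0.80, not 1.
* **editing** — canonical substitution consistent with the local gene
  strand, inside a SINE interval, no rs identifier; counts redrawn until
  every sample AAF ≤ 0.65 and the realized pooled |ΔAAF| ≥ 0.15, because
  the branch's acceptance contract is survival by construction.
* **editing decoys** — four kinds, one per editing rule, each violating
  only its rule deterministically (the significance decoy enforces
  realized |ΔAAF| ≤ 0.08 so the ΔAAF premise fails regardless of q).
* **quality/context/proximity/sparse failures** — engineered to be
  removed at exactly one stage, so stage accounting equals class counts.

Non-editing plants are kept outside SINE intervals so the editing
branch's exact-recovery contract is well defined. Prevalence is enforced
by redraw for classes that must reach later stages, mildly conditioning
their count distributions — the study conditions are "prevalent sites".

The generator does **not** emulate mapping bias toward the reference
allele, sequencing error, correlated depth between samples, repeat-driven
mismapping, or real SINE sequence content. Passing tests therefore
demonstrate the correctness and calibration of the *rules and statistics*
under the stated sampling model, not robustness to alignment artifacts.

Expression tables for the interaction step plant ten DEL–DEG pairs at
|r| ≥ 0.95 with binding evidence, correlation-only and binding-only
decoys (the latter redrawn to |r| ≤ 0.85), and free noise features;
transcript score tables encode the 3-of-5 vote truth including boundary
cases (CPAT exactly 0.78, lengths 199/200).

## Numerical choices and degenerate inputs

* Likelihoods use `xlogy`, so zero counts contribute zero terms; the LRT
  statistic is clipped at 0 before the χ² tail.
* A group with zero total depth makes a site untestable (absent p/q);
  untestable sites never enter the BH family.
* Multiallelic VCF records are split into biallelic sites by default
  (droppable by option); indel alleles are skipped with a warning count.
  Missing `AD` for a sample records 0/0 and flags the sample.
* χ² balance test guards the impossible "equal counts but rejected"
  corner by construction.
* Result tables are written with fixed float formatting (`%.6g`) and
  sorted keys, making reruns byte-identical.

## Problem sizes

Defaults were chosen so the whole battery — cohort generation, cascade,
ASE/editing, lncRNA, interactions, calibration — completes in well under
a minute on one core: 10,000 sites for power/FDR measurement (1,000
planted ASE), 2,000 sites for type-I calibration, 100 × 10 kb sequences
for scanner-oracle equivalence, 1,000 random layouts for the proximity
oracle. These sizes give the stochastic metrics standard errors around a
percentage point, adequate for the acceptance bands used.

## Known limitations

* The differential test is this package's own definition (a pooled
  binomial LRT); the study it emulates used a hierarchical
  variant-discovery tool whose model is not reproduced here.
* Pooling counts within groups ignores replicate-level overdispersion;
  the generator's beta-binomial knob exists precisely to probe that
  assumption, and calibration degrades as ρ grows.
* The χ² confirmation gate makes near-balanced true ASE undetectable by
  design; sensitivity at planted ΔAAF = 0.3 is ≈ 0.80 for this reason.
* Paralog regions are consumed as a user-provided BED; no paralogy
  inference is attempted.
* lncRNA identification trusts external predictor scores; no sequence
  model is applied.
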