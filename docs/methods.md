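# Methods

`liquidpanel` models the computational half of a targeted circulating-tumour-DNA
(ctDNA) assay for neuroblastoma: deep (~2000×) UMI-consensus sequencing of a
42-gene panel on plasma cell-free DNA, followed by somatic variant filtering,
pathogenicity tiering, within-sample copy-number calling from coverage,
cross-compartment/longitudinal comparison, and droplet digital PCR (ddPCR)
quantification. This note records the models, the defaults and why, and what
the synthetic data does and does not establish.

## Sample QC and the filtering cascade

A plasma sample enters analysis only if its cfDNA fraction is at least 0.20;
the gate is `fail` strictly below the threshold. Variant filtering then runs
four per-record stages:

1. **Depth/VAF floor.** Keep depth ≥ 100× and VAF ≥ 0.5% (both inclusive:
   the floors describe what is *removed*, so the boundary survives). Records
   flagged as recurrent artefacts or PCR duplicates are dropped; these flags
   are inputs (they come from the upstream caller's artefact models), not
   recomputed. Records with *missing* depth are retained — the same
   absence-of-evidence semantics used for population frequencies below; this
   matters for transcriptions of published tables that print VAF but not
   coverage.
2. **Population-germline removal.** Drop records whose dbSNP-common MAF
   (maximum over the five continental super-populations AFR/AMR/EAS/EUR/SAS)
   is ≥ 1%, or whose gnomAD exome frequency is > 1%. Missing frequencies
   retain the record: only demonstrably common variants are germline by this
   rule.
3. **Matched-germline subtraction.** Where a patient has constitutional
   sequencing, any record whose (chrom, pos, ref, alt) key appears in the
   germline call set is removed. Absence of a germline set is a warning, not
   an error — most patients lack it.
4. **Reporting threshold.** After tiering, only driver-tier variants with
   VAF strictly > 1% are reported.

Because each stage is a pure per-record predicate, the cascade is idempotent,
its stages commute, and raising any threshold can only shrink the retained
set; the test suite asserts all three laws.

**VAF definition.** Alt UMI families / total UMI families at the locus, a
fraction in [0, 1]. Missing scores are explicit (NaN/None), never 0-coded —
a SIFT score of 0 is maximal deleteriousness.

## Pathogenicity tiers

Evidence: REVEL (ensemble missense score), SIFT, PolyPhen-2, COSMIC presence,
and consequence. Rules fire in fixed order:

1. `pathogenic` — REVEL > 0.7 **and** COSMIC entry present.
2. `likely_pathogenic` — COSMIC **and** SIFT deleterious **and** PolyPhen
   damaging (rescues hotspots with no REVEL annotation, e.g. NRAS Q61K-type
   variants); **or** a truncating consequence (frameshift, splice donor,
   nonsense) in a known driver gene (rescues loss-of-function events that
   missense scorers do not rate).
3. `VUS` — any single line of damaging evidence short of the above.
4. `benign` — no damaging evidence.

"SIFT deleterious" is the vendor call, falling back to score ≤ 0.05 when only
a score is present. "PolyPhen damaging" is a call in {PRD, POD}; the score
fallback is ≥ 0.446, the conventional possibly-damaging boundary. The tier
is monotone in evidence: adding a fired rule never demotes a variant (tested
by enumerating the evidence lattice). Driver = pathogenic or
likely_pathogenic. The rule order was chosen so that the bundled published
cohort table is reproduced deterministically — no printed driver demotes
below likely_pathogenic — because the in-silico columns alone admit several
near-equivalent rule sets; ours is fixed and documented rather than tuned
per cohort.

Cohort summaries count per-gene *pathogenic* variants over patient-derived
materials (ctDNA and germline DNA) only; cell-line controls are tallied
separately, matching how patient cohorts are reported.

## Coverage z-score amplification calling

The caller is within-sample: there is no reference-normal panel, so a
sample's own copy-neutral targets form the baseline.

- **Baseline**: exclude targets of known-amplified genes and X-chromosomal
  genes (chrX dosage reflects sex, not tumour copy number), then
  symmetrically trim the top and bottom `trim_fraction` (default 5%) of the
  remaining per-target depths. On a 42-gene/168-target panel this trims ~8
  targets per tail — enough to remove an unanticipated amplified gene's
  targets (4/gene) without prior knowledge. μ and σ (population SD) are
  computed on the survivors; fewer than 5 survivors is an error.
- **Scores**: every target, including excluded ones, gets
  z = (x − μ)/σ. z over baseline-included targets has mean 0 and SD 1 by
  construction, and z is invariant to rescaling all depths.
- **Calls**: gene z = median of its targets' z (robust to a single
  dropped-out target); `amplified` at z ≥ 5, `gain` at 2 ≤ z < 5, else
  `neutral`. The thresholds are configurable; true amplification signals
  (e.g. MYCN at copy number ~50) sit an order of magnitude above baseline,
  so calls are insensitive to the exact cut in that regime. The trimmed σ
  slightly underestimates the raw spread, so borderline `gain` calls can
  occur in copy-neutral data at z ≥ 2; `amplified` calls do not (verified
  over 100 copy-neutral simulations).

A gene amplified only in genome regions the panel does not cover is
invisible by construction — the caller sees only its targets. The synthetic
negative control encodes this: spiking a gene with no panel footprint
changes nothing.

## Concordance, trajectories, purity

ctDNA and tumour call sets from the same patient are compared by genomic
key; the union partitions into `shared`, `ctDNA_only`, `tumour_only` (a
two-set Venn). Longitudinal series label each variant by presence
transitions (present = VAF > reporting threshold) and monotone relative VAF
change (default 20%): `emergent`, `lost`, `rising`, `falling`, `stable`,
and `lost_then_emergent` for a clone that clears and returns. Raw
below-threshold VAFs are kept in the output for inspection.

Tumour purity from VAF uses explicit two-population mixing models:

- heterozygous diploid: VAF = p/2, so p = 2·VAF (error at VAF = 1, which a
  heterozygous variant cannot reach);
- homozygous after LOH (hemizygous-mutant tumour at copy number 1, diploid
  reference normal): VAF = p/(2 − p), so p = 2·VAF/(1 + VAF).

Other copy states are rejected explicitly rather than approximated. Both
inversions round-trip the forward map to 1e-9. A homozygous-LOH VAF of
10.5% implies ~19% tumour content — the model's account of how a
post-chemotherapy tumour with a homozygous TP53 variant at modest VAF can
have low tumour-cell content.

## ddPCR Poisson quantification

Template partitions over ~20,000 droplets as Poisson, so per channel
λ = −ln(1 − n_pos/n_total) copies/droplet; concentration = λ / droplet
volume (default 0.85 nL, reported as copies/µL); mutant fractional
abundance = λ_mut/(λ_mut + λ_wt). 95% CIs are Clopper–Pearson intervals on
the positive fraction mapped through the monotone −ln(1 − ·). A saturated
channel (all droplets positive) is an error, not infinity. Detection
requires ≥ 3 mutant-positive droplets by default — a common field
convention; the threshold is configurable. Channel independence is assumed
(no competition model, no rain handling).

## Synthetic data: what it emulates, what it does not

The generator produces post-calling artefacts of the assay, with truth
labels carried alongside:

- **Variant tables**: somatic clone variants at expected VAF given purity,
  clonal fraction and copy state (through the same mixing models the
  analysis inverts); alt reads drawn binomially at a lognormal per-target
  depth centred on 2228× (the assay's working depth; CV 0.3 by default,
  chosen as a realistic panel depth spread since only the mean is pinned
  down); germline SNPs at VAF ≈ 50%/100% with genotype by Hardy–Weinberg
  conditional on carrying the allele, population MAF recorded; artefacts
  uniform below 0.5% VAF at a configurable per-target rate, never
  COSMIC-flagged. Pathogenic variants draw REVEL from [0.72, 0.99], benign
  from [0, 0.5] (deliberately non-overlapping so truth recovery is
  well-posed); a configurable fraction of pathogenic variants has REVEL
  missing to exercise the COSMIC+SIFT+PolyPhen rescue path. Calls with zero
  alt reads are not emitted — a caller only reports supported alleles.
- **Coverage**: expected relative coverage (2(1−p) + C·p)/2 at tumour copy
  number C and purity p, multiplicative lognormal noise with configurable
  CV (default 0.1), chrX targets scaled by configured sex ploidy.
- **Droplets**: per-channel positives ~ Binomial(n, 1 − e^{−λ}).
- **Clonal-evolution scenario**: a two-clone ALK case — minor R1275Q and
  major F1174L clones in diagnosis plasma (expected VAFs 2.85%/28.5%),
  single-site diagnostic tumour carrying only R1275Q (32%), remission
  plasma with zero tumour purity, relapse with F1174L alone (tumour 46.1%;
  plasma ~98% via loss of the wild-type allele). The scenario uses mean
  depth 5000 and depth CV 0.1 so that presence/absence truth labels are
  recovered with overwhelming margin across seeds.

Not modelled: read-level data, UMI family statistics, base-context error
profiles, GC/mappability coverage bias, correlated noise between targets of
a gene, contamination, structural variants. Passing tests therefore show the
*analysis logic* is correct under the stated statistical model, not that the
thresholds are optimal for any particular real instrument run.

All simulators are deterministic given their seed (NumPy `default_rng`).

## Numerical and interface choices

- Positions are 1-based (VCF) in variant tables, 0-based half-open (BED) in
  panel definitions; conversion is confined to the I/O layer.
- VCF INFO scores are serialized as full-precision strings (htslib `Float`
  INFO is 32-bit and would truncate on round trip); depth is an Integer
  INFO field. Multi-sample tables are written as site records with a
  `SAMPLE` INFO key — the pipeline is per-sample throughout.
- Baseline σ uses the population convention (ddof 0), matching the plain
  z-score definition; with σ = 0 (constant coverage) scoring is an error
  with advice rather than a division by zero.
- Stage order in the driver is fixed (QC → filter → classify → CNV →
  concordance → report) but the filter stages commute, so the order is a
  presentation choice, not a semantic one.
- Problem sizes in tests (100 seeds for detection power, 50 for cascade
  truth recovery, 300–1000 ddPCR replicates) are chosen to give ~3-standard-
  error resolution on the quantities asserted while keeping the suite quick
  to run during development.

## Known limitations

- The driver-gene set defaults to the panel's gene list; tiering a variant
  in a gene off-panel still works but the truncating-in-driver-gene rescue
  will not fire unless the set is extended.
- The within-sample baseline cannot detect broad gains affecting most of
  the panel (they would *become* the baseline), nor deletions/LOH — by
  design, those are array/WGS territory.
- Purity estimation ignores subclonality (assumes the variant is clonal in
  the tumour fraction) and non-default copy states.
- The bundled cohort table transcribes a published table, including one
  internal inconsistency (the same TP53 coding change printed with two
  protein changes in two samples); it is preserved verbatim rather than
  corrected.
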