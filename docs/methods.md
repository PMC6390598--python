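# Methods

## Problem and model

Amplicon-based targeted deep sequencing can detect somatic mutations from
small amounts of tumour DNA, but PCR and sequencing errors set a noise
floor well above the allele frequencies at which clinically relevant minor
mutations occur. In EGFR-mutated lung adenocarcinoma, rare *compound*
genotypes — a TKI-sensitizing common mutation (exon 19 deletion, L858R,
L861Q, T790M, G719A/S/C) coexisting with an uncommon coding mutation
(E709G, R776H, D761Y, G598V, ...) — matter for therapy choice but sit at
allele frequencies down to 0.5%, where raw read counting cannot separate
them from artifacts.

The molecular-barcoding system (MBS) modelled here resolves this by
tagging each input DNA molecule with a unique random oligonucleotide
before amplification. Reads are aligned, grouped into *molecular families*
by identical barcode, and each family is consolidated to one consensus
read. Errors introduced during PCR or sequencing are private to a minority
of a family's reads and are removed by the majority vote; true variants are
present in every read of the families derived from a mutant molecule. The
variant allele frequency on the consensus ("MBS") arm is the fraction of
consensus families carrying the alternate allele — an estimate of the
molecule fraction — while the "raw" comparison arm counts reads and keeps
the error floor.

## Pipeline

1. **Simulation** (`synthetic_data`). A deterministic seven-amplicon panel
   stands in for EGFR exons 15–21 (150 bp each on a 1450 bp synthetic
   contig), with the hotspot catalog embedded at fixed coordinates. For
   each amplicon, `molecules_per_amplicon` molecules are tagged with
   uniform random barcodes; each molecule carries each truth variant
   independently with probability equal to its allele fraction
   (ploidy-free molecule fractions). Amplification draws a family size per
   molecule, injects PCR errors on a single simulated copy shared by about
   half of the family's reads (correlated within-family errors), then adds
   independent per-base sequencing errors to each mate.
2. **Consensus** (`barcode_consensus`). Reads are assigned to amplicons by
   primer-anchored placement verified by mismatch count (16-mer anchor
   lookup, exhaustive sliding fallback), with a gapped second pass only at
   catalogued deletion hotspots. Mates are merged into one
   reference-projected record (disagreements become `N`). Families are
   exact-match groups on (barcode, amplicon); consensus is a column-wise
   majority vote.
3. **Calling** (`variant_calling`). Non-reference alleles with AF ≥ 0.5%
   and alternate support ≥ 3 units are called; calls are classified
   common/uncommon against the clamp-detectable list; sites recurring in
   strictly more than half of a cohort's call sets are removed as
   systematic artifacts before any comparison.
4. **Concordance** (`replication_concordance`). Replicate pairs are
   matched on the variant key; reproducibility = 100·matched/(matched +
   orphan); AF agreement is the OLS R² over matched calls. The artifact
   census tabulates raw-arm-only calls by cross-sample sharing.
5. **Statistics** (`cohort_stats`). Exact 2×2 Fisher and r×c
   Freeman–Halton tests by full enumeration under the multivariate
   hypergeometric null, Pearson chi-square, and pooled-variance t-tests
   from group summaries.

## Parameters

| Parameter | Default | Meaning / rationale |
|---|---|---|
| `molecules_per_amplicon` | 2000 | input molecules per amplicon; sets the AF quantisation floor (1/2000 = 0.05%) comfortably below the 0.5% calling threshold |
| `barcode_length` | 12 | expected barcode collisions per amplicon = n²/(2·4¹²) ≈ 0.12 < 1 at the default molecule count (birthday bound) |
| `reads_per_molecule` | (5.0, 1.0) | mean family size and Fano factor (0 = constant, 1 = Poisson, >1 = negative binomial); mean 5 keeps >95% of families at size ≥ 2 |
| `pcr_error_rate` | 1e-4 /base | per-base error on the simulated PCR copy; creates family-correlated errors |
| `seq_error_rate` | 0.005 /base | independent per-read substitution rate, a generic short-read figure |
| `read_length` | 100 | mates anchor at both amplicon ends and overlap mid-amplicon |
| `min_family_size` | 2 | singleton families carry unsuppressable errors; the vendor's threshold is unpublished, so this is a CLI knob |
| `min_agreement` | 0.7 | majority fraction required to emit a consensus base; ties at the threshold are kept (≥), ambiguous positions never support a call |
| `min_af` | 0.5% | detection threshold, boundary inclusive |
| `min_alt_support` | 3 | floor on alternate units so a bare percentage cannot call single-molecule noise at low depth |

Error rates and molecule counts are simulation choices made for
testability: the assay this models publishes no input molecule counts,
family-size distribution, or platform error rates.

## What the simulator does and does not emulate

It emulates the features consensus calling depends on: unique molecular
tagging, family-correlated PCR errors versus independent sequencing
errors, primer-defined read positions, true variants at controlled
molecule fractions, and injectable systematic (shared by >half the
cohort) and singleton artifacts carried on fresh size-1 families. It does
not emulate barcode sequencing errors (a config toggle, default off, as
no barcode-error model is published), quality-score profiles (constant
Q30), adapter/primer chemistry, strand information (no duplex consensus),
or the full 47-gene panel content. Passing tests therefore show that the
consensus machinery suppresses the modelled error classes at the stated
rates — not that real libraries achieve these exact figures.

## Numerical and design choices

- **Coordinates** are 0-based half-open internally; 1-based only in the
  TSV/VCF-dialect reports. Indels are left-aligned with a shared anchor
  base; the exon-19 deletion is matched as a class (any catalogued
  in-frame deletion overlapping the hotspot window) since the clinical
  assay treats "exon 19 deletions" as one genotype.
- **Barcode transport**: read-name suffix after the last `:`; a reader
  shim accepts a separate index-read FASTQ.
- **Alignment** is gapless with a catalogued-indel second pass rather than
  full Smith–Waterman: amplicon reads are reference-anchored by design,
  which keeps the engine dependency-free and exactly testable. The
  16-mer anchor lookup is an optimisation with the exhaustive sliding
  placement as fallback; reads whose best placement exceeds 20%
  mismatches are dropped and counted.
- **Exact tests** use the minimum-likelihood two-sided convention (sum of
  probabilities of all margin-fixed tables no more likely than the
  observed one, ties included), which reproduces the published 0.24, 0.22
  and 0.0052 values. Likelihood ties are compared in log space with a
  1e-7 relative tolerance. Enumerated probabilities are checked to sum to
  1 within 1e-9 on every call; a composition bound of 1e7 states guards
  the enumeration, beyond which a seeded Monte-Carlo sampler of
  margin-fixed tables (Patefield algorithm) is the documented fallback.
- **t-tests from summaries** use the pooled-variance form; the Welch form
  is grossly inconsistent with the published age and tumour-size values.
- **Reproducibility** uses the union denominator (matched + orphan),
  derived from the published "6/11" arithmetic; reported as whole
  percent, concordance to one decimal. R² is computed on matched calls
  only, on the percent scale.
- **MBS-arm depth** is the retained-family count at the position; whether
  the assay's published AFs are family- or read-denominated is unstated,
  so the family denominator is defined as this package's convention.
- **AF difference** between a sample's common and uncommon mutation is
  reported to two decimals (sub-percent differences between
  almost-identical pairs are meaningful in the source tables).

## Problem sizes used by the test and acceptance runs

The replicate-reproducibility experiment simulates six samples with 2–3
hotspot variants each at allele fractions 0.05–0.66 on a two-amplicon
subpanel (exons 20–21), 2000 molecules per amplicon, two independent
libraries per sample, over 20 seeds — about 4.8 million read pairs in
total. The parameter-recovery check runs one four-variant sample (molecule
fractions 0.005–0.5) at the same depth over 20 seeds. The error-bound and
artifact-census checks use a few hundred molecules per amplicon. These
sizes give binomial standard errors small enough for 3-SD assertions while
keeping a full run in the minutes range on one CPU.

## Known limitations

- Known pStage ambiguity in the source tables: the published stage
  comparison value matches the Pearson chi-square (0.012), not the exact
  test (0.025), despite being footnoted as a Fisher test; the stats report
  emits both methods for the stage row.
- The published replicate R² (0.989) is not reproducible because the
  underlying per-variant allele frequencies are only available as a
  figure; the R² machinery is instead validated on simulated replicates
  and closed-form oracles.
- Orphan counting is per variant key; whether the source deduplicates
  multi-allelic sites is unstated.
- Insertions are not representable in the reference-projected read
  vectors; the only catalogued indel class is the exon-19 deletion.
- Barcode grouping is exact-match; no edit-distance clustering of
  barcodes (simulation v1 has error-free barcodes by default).
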