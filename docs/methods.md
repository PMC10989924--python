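# Methods

This note documents the statistical procedures implemented in `microtraits`,
the assumptions behind them, the defaults and why they were chosen, and what
the synthetic generator does and does not emulate.

## Codon usage bias: ENC, ENC′, ΔENC′

**Model.** For each synonymous codon family (amino acid) with degeneracy
`m ∈ {2, 3, 4, 6}` and `n` observed codons with frequencies `p̂ᵢ`, Wright's
codon homozygosity is

    F̂ = (n·Σ p̂ᵢ² − 1) / (n − 1).

Families are grouped by degeneracy; class means `F̄ₘ` are unweighted over
amino acids, and

    ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆,

capped at 61 (sampling fluctuation can push the raw value past the
theoretical maximum; no floor is forced). The composition-corrected variant
replaces `F̂` with

    F̂′ = (χ²ₐ + n − m) / (m·(n − 1)),   χ²ₐ = n·Σ (p̂ᵢ − eᵢ)²/eᵢ,

where the expected frequencies `eᵢ` are products of the background
nucleotide frequencies over the three codon positions, normalized within the
family. Under a uniform background `eᵢ = 1/m` and `F̂′ ≡ F̂` algebraically,
so ENC′ reduces exactly to ENC — a property-tested identity.

    ΔENC′ = (ENC′_all − ENC′_rib) / ENC′_all

compares the pooled codon counts of all coding sequences against the pooled
ribosomal-protein subset, both corrected against the same background (the
mean nucleotide frequency of the pooled coding set). Positive ΔENC′ means
ribosomal genes are more biased than the coding average — the signature of
translational selection and high maximum growth rate.

**Numerical choices.**
* The three sixfold families (Leu, Ser, Arg) are treated whole, not split
  2+4.
* Families with `n < 2` are skipped. Families with `F̂ ≤ 0` (possible at
  small `n`, e.g. `n = 2` with two distinct codons) are also skipped, since a
  zero homozygosity breaks the harmonic assembly; the same rule applies to
  `F̂′` so the uniform-background identity is preserved.
* A missing threefold class mean (Ile unobserved) is imputed as
  `(F̄₂ + F̄₄)/2`; a missing 2-, 4- or 6-fold class makes ENC undefined and
  raises an error.
* Codon counts are pooled across genes within a set. Per-gene averaging is a
  legitimate alternative with different small-sample behaviour; pooling was
  chosen because the estimator targets the gene *set*, and is the variant
  the tests validate.
* Only the standard genetic code is supported. Met, Trp and stops are
  excluded from families.
* ΔENC′ is only asymptotically invariant to duplicating every gene: `F̂`
  depends on `n`, not just on frequencies, so duplication shifts ENC′ by
  O(1/n). At ≥10⁴ codons the shift is below 5×10⁻³.

**ORF calling.** Open reading frames are maximal stop-to-stop runs of
non-stop codons, scanned over all three frames of both strands, reported
with 0-based half-open coordinates on the forward strand, minimum length
450 nt by default. Bounding stop codons are excluded; non-ACGT characters
break a run. Ribosomal-protein genes are identified by a supplied ID list —
homology search against a reference database is out of scope.

## Community traits

**Weighted rRNA operon copy number.** OTU taxonomies (semicolon-ranked,
optional `g__`-style prefixes) are matched against a copy-number reference
at the deepest named rank (species → domain). Unmatched OTUs are excluded
and relative abundances renormalized over assigned OTUs (the count of
exclusions is logged); dataset-mean imputation was rejected as the default
because it shrinks the very signal the trait measures, and true
nearest-relative placement would need a phylogeny.

**Mean genome size.** Genome equivalents = arithmetic mean of per-gene
coverage (`aligned_bp / gene_length`) over single-copy genes; size =
sample total bp / genome equivalents. The arithmetic mean (not the median)
matches the "average coverage" convention; a median variant would be more
robust to single-gene outliers but is not currently exposed.

**GC statistics.** Mean and unbiased (n−1) sample variance of *per-read* GC
fractions — across reads, not across taxa.

**Alpha diversity.** Shannon–Wiener (natural log), Gini–Simpson (1 − Σp²),
and bias-corrected Chao1 `S_obs + F₁(F₁−1)/(2(F₂+1))`, which stays defined
when no doubletons are observed. Computed via scikit-bio; frozen
hand-computed values in the tests act as the independent check.

## Biomarker assays

**PLFA.** `conc_m = (area_m / area_19:0) × standard_nmol / dry_mass_g`.
No molar-response correction is applied beyond the single internal standard.
The default marker→group map (G+: i15:0, a15:0, i16:0, i17:0, a17:0;
G−: 16:1ω7c, 18:1ω7c, cy17:0, cy19:0; fungi: 18:2ω6,9c, 18:1ω9c; general
bacterial: 15:0, 17:0) follows standard literature assignments and is fully
overridable. F:B divides fungal by all bacterial markers; K:r is defined as
the G+:G− concentration ratio. Zero denominators yield `None`, not errors.

**Fumigation–extraction.** `biomass = (fumigated − nonfumigated)/k` with
k = 0.45 (C), 0.54 (N), 0.40 (P). A negative flush warns and reports as-is
rather than censoring.

**Enzyme activities.** The MUB standard curve (defaults 0–100 µM) is fit by
ordinary least squares; the fit must have R² ≥ 0.98 (configurable) and a
positive slope. Net fluorescence = (test − control)/quench_factor; since
1 µM = 1 nmol/mL, MUB released = net/slope × well volume (mL); activity =
nmol / (soil equivalent × incubation). Defaults reflect the assay protocol:
250 µL well (100 µL homogenate + 150 µL buffer), 0.01 g dry-soil
equivalent per well (4 g soil / 40 mL slurry × 0.1 mL), 3 h incubation,
quench factor 1 unless measured.

**GeoChip filtering.** In order: spots with signal < 2× background are
zeroed; spots with SNR < 2 are zeroed; detections supported by fewer than
two replicates within a replicate group are zeroed; probes detected in
< 10 % of samples are dropped. The published wording on the prevalence rule
is ambiguous ("annotations with a minimum abundance of 10 % were removed");
it is implemented as *remove below 10 % prevalence*, the only reading
consistent with quality filtering. Normalization (per-probe relative
abundance across samples, then ln(x+1)) changes scale and is therefore a
separate step, which keeps the drop-rule filter idempotent.

## Co-occurrence networks

The 500 most abundant OTUs (by total relative abundance, ties broken
lexicographically) are candidates. Spearman correlations on relative
abundances — hence invariant to per-sample sequencing depth — are computed
for all candidate pairs; p-values are Benjamini–Hochberg adjusted across all
pairs; edges require |r| > 0.75 **and** q < 0.05. SparCC is a documented
alternative estimator, not implemented; the Spearman+BH route is exact and
testable against a per-pair oracle.

Topology: mean degree 2E/N; mean local clustering (degree < 2 contributes
0); unweighted path length and diameter on the largest connected component
(component count reported); modularity from greedy agglomerative community
detection on the unsigned graph (deterministic). Edgeless networks report
path metrics as undefined (`None`).

## Synthetic chronosequence generator

**What it emulates.** A 6-age (1, 5, 10, 15, 25, 30 yr) × 3 plot × 3
quadrat design (54 samples). Two guilds with planted traits:

| parameter | copiotroph | oligotroph |
|---|---|---|
| rRNA operon copies | uniform {5..10} | uniform {1..2} |
| genome size | lognormal(ln 5.0 Mbp, 0.12) | lognormal(ln 3.5 Mbp, 0.12) |
| GC content | N(0.55, 0.03) | N(0.62, 0.03) |
| ribosomal bias s | 2.0 | 0.5 |
| PLFA signature | G− rich, fungus-poor | G+ rich, fungus-rich |

The copiotroph mixing weight π(age) rises linearly from 0.1 to 0.9 across
the gradient, so weighted copy number, ΔENC′, genome size and bacterial
dominance all increase with age while F:B, K:r and GC decrease — the
qualitative directions the trait framework predicts. Per-sample OTU
abundances are Dirichlet(α = 0.3 × guild weight per taxon) → multinomial
(default 20,000 reads over 200 taxa), giving realistic overdispersion.
Coding sequences draw codons within each family with weights
∝ exp(s·prefᵢ), where the preference vector per family is fixed per world;
s = 0 gives uniform synonymous usage, so ΔENC′ ≈ 0 is the planted null.
Biomass and enzyme planted values interpolate linearly between realistic
young-/old-site endpoints (e.g. MBC 340→420 mg kg⁻¹). All measurement
noise levels (PLFA CV 5 %, fumigation CV 3 %, plate fluorescence SD 2 RFU,
GeoChip dropout 15 %) are config keys.

**What it does not emulate.** Raw reads with error profiles, chimeras, OTU
picking; phylogenetic structure (the taxonomy is a flat two-guild
hierarchy); spatial/temporal autocorrelation between plots; library-size
variation; more than two guilds per default world. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
generative model, not robustness to the full messiness of field data.

**Problem sizes.** Recovery checks use 20 replicate seeds with reduced
worlds (40 taxa/guild, 4,000 reads) and 20-replicate genome sets of
55 genes × 150 codons — large enough that planted gradients are resolved
with wide margins, small enough that the whole suite runs in well under a
minute per stage.

## Pipeline and reproducibility

All randomness flows from a single seed through `numpy` `SeedSequence`
spawning. Artifacts are written with LF line endings and 17-significant-
digit floats (binary-exact round trip); metadata sidecars carry stage,
seed and resolved parameters but no timestamps or absolute paths, so a
fixed seed reproduces a byte-identical output tree. Stage failures halt the
pipeline with the stage named; artifacts already written are retained.

## Known limitations

* Copy-number fallback is name-based; without a phylogeny, novel clades
  inherit nothing rather than a nearest-relative estimate.
* ENC for extremely sparse gene sets depends on the family-skipping rules
  above; values from < ~100 codons should not be compared across samples.
* The K:r ratio equals G+:G− by definition here; studies using different
  marker partitions will not be numerically comparable.
* Network modularity uses greedy agglomeration, which can return slightly
  suboptimal partitions on degenerate graphs; the seed-free algorithm was
  preferred over stochastic alternatives for determinism.
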