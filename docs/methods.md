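# Methods notes

## Scope and assumptions

`phenoprof` starts from a dereplicated ASV table; read QC, denoising,
chimera removal, multiple sequence alignment and tree inference are
upstream concerns (trees enter as newick inputs). The reference Binary
Phenotype Matrix is likewise an input: phenotype calls are assumed to
come from curated genome-scale metabolic reconstruction, and the package
treats them as error-free binary facts. Three modelling assumptions do
the heavy lifting:

1. **Probabilistic projection.** An ASV is an ensemble of unresolved
   strains. Mapping weights are a probability distribution over
   reference genomes, so the Phenotype Index `PI = Σ WᵢPᵢ` is a carrier
   probability, and its binomial variance `PI(1 − PI)` measures mapping
   ambiguity — not biological variability within the sample.
2. **Independent co-occurrence.** `Var(CPI) = Σ Aᵢ²Var(PIᵢ)` adds ASV
   variances as if mapping errors were independent across ASVs. Mixing
   two *certain* ASVs (PI 0 and 1) therefore yields Var(CPI) = 0: the
   uncertainty tracks ignorance about identity, not community
   composition.
3. **Equal-weight species split.** When several species (or strains) are
   equally compatible with an ASV, weight is divided equally across
   unique species first, then across each species' strains. No abundance
   prior over reference genomes is used.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `s_scale` (S) | 4 | width of the accepted identity window below the best hit, `F ≥ M − (1−M)/S`; larger S = narrower window |
| `drop_threshold` (D) | 0.85 | identity floor (fraction, 0–1); ASVs whose best hit is ≤ D are unassignable/unmapped, since phenotype heterogeneity below ~85% 16S identity makes predictions uninformative |
| `consensus` | 0.51 | CBTA per-rank weighted majority; any value > 0.5 makes the winning label unique, so no tie-break is needed |
| `carrier_threshold` | 0.6 | strict PI cut-off defining carrier sub-communities for PAD/PBD |
| mapped rank | family | taxonomy-scheme ASVs matched only above family rank are reported unmapped |

All are dimensionless fractions except S (pure scale factor).

## The mock community generator

The generator emulates a strain-level gut-like reference and the
sampling process of a 16S experiment:

* **Taxonomy:** ~3 species per genus, with a shallow consistent
  hierarchy above (ratios 2:1 per rank). 120 species and 1–6 strains per
  species by default, giving a reference of roughly 400 genomes.
* **Phenotypes:** species-level Bernoulli(0.5) values; each strain
  inherits its species value flipped independently with probability
  `species_flip_prob` (default 0.1; the accuracy-ordering experiments
  use 0.2), modelling phylogenetic microheterogeneity.
* **Sequences:** 1,200 nt, genus consensus mutated from a common root
  (4% substitutions), species consensus from genus (1%), strain copies
  from species (0.25%), chosen to mirror typical 16S identity bands
  (within-species ≳ 99%, within-genus ~97–98%, cross-genus ≲ 95%).
  Forward/reverse primer sites are embedded unmutated at fixed
  coordinates (window length 420 nt), and full-length strain sequences
  are forced unique by rejection.
* **Communities:** unique species count `S ~ round(N(30, 5))` with
  `10 < S < 60`; species drawn without replacement weighted by pool mean
  abundance `A` (lognormal, σ = 1.25, normalised — a heavy-tailed
  abundance distribution); strains per species uniform on
  `[1, ceil(√available)]`; species abundance `R ~ N(A, 0.4A)` with
  `0.1A < R < 3A`, rescaled to 1; strain fractions `Q` uniform, rescaled
  per species; total count `T ~ round(N(20000, 4000))` with
  `4000 < T < 40000`; per-strain counts `C = round(Q·R·T)`, zero-count
  strains dropped. The community records both the sampled `T` (the
  quantity the rejection bounds constrain) and the realised `Σ C`, which
  can differ by rounding.

What the generator does **not** emulate: sequencing error, chimeras,
read-level depth variation, GCN variation between the synthetic taxa
(identical copy numbers, so the renormalisation stage is exercised with
real tables only in unit tests), and nomenclature mismatches between an
external taxonomy database and the reference (the mock reference *is*
the taxonomy database). Passing mock-based tests therefore demonstrates
correctness of the mapping/index machinery under clean sequences, not
robustness to noisy reads or taxonomy curation conflicts.

## Numerical and design choices

* **Identity fraction.** The built-in reference search uses exact infix
  alignment (edlib) with identity = matched columns / alignment
  columns; external 12-column tabular hits use percent identity / 100.
  Both cuts (`F` window and `D`) are applied after computing `M` over
  all hits for the ASV.
* **Hit window edge cases.** `F ≥ lower` is inclusive; `F > D` strict;
  `M ≤ D` empties the result. Filtering is order- and
  duplicate-invariant.
* **GCN fallback.** Each MTA entry contributes the copy number at its
  deepest tabulated rank (species → domain); assignments with no
  tabulated rank use the table-wide mean, so no ASV is dropped by the
  renormalisation.
* **Unmapped abundance.** CPIs are computed over the mapped subset with
  abundances renormalised to 1; the mapped fraction is reported
  alongside as coverage so no information is silently lost.
* **rSTD at CPI = 0** is reported as missing (NaN), not infinity.
* **Percentiles** use linear interpolation between order statistics;
  CPI summaries (Q50, 10–90 percentile range) are reported on the ×100
  percent scale.
* **Weighted UniFrac** is the unnormalised variant by default (a
  normalised variant is available via a flag) and is computed by exact
  postorder accumulation on float proportions. scikit-bio's
  implementation quantises abundance vectors to integer counts, which
  discards renormalised relative abundances, so it serves as an
  integer-count cross-check in the tests rather than as the
  implementation. Faith PD (root-inclusive) and midpoint rooting go
  through scikit-bio, except the degenerate two-tip midpoint case,
  which is handled directly.
* **Empty carrier sets** are excluded from PAD/PBD per phenotype (with
  a logged count) rather than scored 0, since 0 would conflate absence
  with zero diversity. Tree tips absent from the ASV table are pruned
  before computation.
* **Rounding** of sampled integer quantities (S, T, C) is to nearest;
  rejection bounds are applied to the rounded value.
* **SEQ weighting ambiguity.** The sequence scheme follows the same
  species-then-strain weight split as the taxonomy schemes; a flat
  per-genome weighting is available behind
  `per_species_weighting=False` for sensitivity analysis. Genomes with
  several 16S copies contribute only their best-identity copy.

## Problem sizes

The test suite and `scripts/acceptance.py` run the generator constraint
checks on 1,000 sampled communities, ground-truth recovery and
scheme-accuracy comparisons on 100 communities each against a
~400-genome reference, formula oracles on 200 random fixtures, Faith PD
exhaustively on all subsets of random trees up to 8 tips, and UniFrac
metric axioms on 1,000 random triples.

## Known limitations

* The built-in all-vs-all search is exact but quadratic; for real
  datasets, supply tabular hits from a dedicated aligner instead.
* Unit edit costs in the built-in search can, in principle, pick a
  slightly different optimal alignment than an affine/semi-global
  scorer; at the > 85% identity regime enforced by D the accepted hit
  sets coincide in practice.
* CBTA/MTA accuracy depends on the reference taxonomy's nomenclature
  matching the ASV taxonomy source; label matching is case-insensitive
  exact matching, with no synonym resolution.
* No statistical testing between cohorts is provided beyond descriptive
  summaries (intragroup means, rPBD); classification workflows are out
  of scope.
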