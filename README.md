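# phenoprof

Binary metabolic phenotype profiling of 16S rRNA amplicon data.

Taxonomic profiles of microbiome samples say *who* is there but not *what
the community can do*. `phenoprof` converts per-sample tables of amplicon
sequence variants (ASVs) into metabolic capability profiles by projecting
curated **binary metabolic phenotypes** — per-genome 0/1 encodings of
complete pathways (vitamin biosynthesis, SCFA production, carbohydrate
utilisation, amino-acid biosynthesis) — from a reference genome collection
onto the ASVs observed in each sample. It is aimed at microbiome
researchers who have a dereplicated ASV table (e.g. from dada2) plus a
reference Binary Phenotype Matrix, and want interpretable, probability-
scale functional summaries per sample.

## The model

A reference collection supplies a Binary Phenotype Matrix (BPM): genomes
× phenotypes with entries `P ∈ {0, 1}` (1 = carrier) and a seven-rank
taxonomy per genome. Each ASV is mapped to reference genomes under one of
three schemes:

* **CBTA** — consensus-based taxonomic assignment: a single taxonomy kept
  down to the last rank with ≥ 51% weighted agreement, matched level by
  level against the reference.
* **MTA** — multi-taxonomic assignment: all species-level taxonomies of
  the top alignment hits, equally weighted. Hits are accepted within the
  identity window `F ≥ M − (1 − M)/S` above a drop threshold `F > D`,
  where `M` is the best identity fraction, `S = 4`, `D = 0.85`.
* **SEQ** — direct alignment of ASVs against the reference 16S sequences
  (same `S`, `D`), giving partial strain-level resolution.

Mapping weights `Wᵢ` are split equally over unique species and then over
each species' strains, and sum to 1 per mapped ASV (mapped = matched at
family rank or deeper for taxonomy schemes, best `F > D` for SEQ).
Abundances are first corrected for 16S gene copy number (GCN): each ASV's
abundance is divided by the mean GCN of its assignment and the sample is
rescaled to 1.

Per ASV and phenotype the **Phenotype Index** is the map-weighted mean

    PI = Σᵢ Wᵢ Pᵢ,      Var(PI) = PI (1 − PI)

(a carrier probability with binomial uncertainty). Per sample the
**Community Phenotype Index** is the abundance-weighted mean

    CPI = Σᵢ Aᵢ PIᵢ,    Var(CPI) = Σᵢ Aᵢ² Var(PIᵢ),    rSTD = √Var(CPI)/CPI

— the fractional representation of carriers in the sample, with a
propagated mapping-uncertainty estimate.

Diversity of the carriers themselves is measured on a midpoint-rooted
phylogeny of the ASVs: **PAD** (Phenotype Alpha Diversity) is the Faith
phylogenetic diversity of the sub-community with `PI > 0.6`, **PBD**
(Phenotype Beta Diversity) the weighted UniFrac distance between carrier
sub-communities, and **rPBD** the ratio of intragroup mean PBD to
intragroup mean total beta diversity (≈ 1 when carriers are no more or
less dissimilar across samples than whole communities).

A built-in mock community generator produces a strain-level synthetic
reference (taxonomy, phenotypes conserved at species level with
configurable strain-level flips, 16S sequences whose identity tracks
taxonomic distance) and samples communities with known ground truth, so
every prediction can be scored against exact community indices.

## Worked example

```python
import phenoprof as pp

fixture = pp.generate_reference_fixture(n_species=60, seed=42)
pool = pp.make_species_pool(fixture.bpm, pool_size=60, seed=42)
mocks = pp.generate_mock_dataset(fixture, pool, 20, seed=42)

amap = pp.map_by_sequence(mocks.table.sequences, fixture.sequences, fixture.bpm)
profile = pp.compute_phenotype_indices(amap, fixture.bpm)
community = pp.community_profile(profile, mocks.table)
truth = pp.true_community_profile(mocks, fixture.bpm)
change = pp.relative_cpi_change(community, truth)

print("mapped ASVs:", len(amap.mapped_ids), "of", len(mocks.table.asv_ids))
print(pp.summarize_cpi(community.cpi).loc[["B12", "Butyrate", "Fuc"]].round(1))
print("mean |relative CPI error| vs truth:",
      round(float(change.abs().mean().mean()), 4))
```

prints

```
mapped ASVs: 174 of 174
           q50  pr_10_90
B12       67.8      14.1
Butyrate  58.1      16.4
Fuc       34.8      15.7
mean |relative CPI error| vs truth: 0.0169
```

i.e. every ASV of the 20 mock communities maps back into the reference;
across samples the median vitamin-B12-synthesis CPI is 67.8% with a
10–90 percentile spread of 14.1 points (the carrier fraction varies
moderately between communities); and the sequence-based predictions land
within ~1.7% of the exact ground-truth community indices on average.

The same stages are available from the shell:

```
phenoprof mock --n 20 --seed 42 --out mockdir
phenoprof run --scheme seq --counts mockdir/mock_counts.tsv \
    --fasta mockdir/mock_asvs.fasta --bpm mockdir/reference_bpm.tsv \
    --bpm-taxonomy mockdir/reference_taxonomy.tsv \
    --ref-16s mockdir/reference_16s.fasta --out outdir
```

which writes `map.tsv`, `pi.tsv`, `cpi.tsv` (plus `pad.tsv`,
`pbd_<phenotype>.tsv`, `rpbd.tsv` when `--tree`/`--groups` are given) and
a structured `run.log`.

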