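"""In-silico mock community generator with known ground truth.

Builds a synthetic strain-level reference collection (taxonomy, binary
phenotypes conserved at species level with configurable strain flips,
16S sequences whose identity tracks taxonomic distance), samples mock
communities from it, truncates amplicons to the V3-V4 window and
collapses identical truncations into ASVs.  Every community carries a
truth map from ASVs to the genomes that produced them, so downstream
mapping schemes can be scored against exact community phenotype
indices.

Community sampling follows a fixed recipe: the number of unique
species S ~ round(N(30, 5)) restricted to 10 < S < 60; species drawn
without replacement weighted by their pool mean abundance A; per
species, the strain count is uniform on [1, ceil(sqrt(available))];
species abundance R ~ N(A, 0.4 A) restricted to 0.1 A < R < 3 A and
rescaled to sum 1; within-species strain fractions Q uniform, rescaled
to 1; total amplicon count T ~ round(N(20000, 4000)) restricted to
4,000 < T < 40,000; per-strain counts C = round(Q * R * T) with
zero-count strains dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .reference import (
    ASVTable,
    BinaryPhenotypeMatrix,
    RANKS,
    Taxonomy,
    write_asv_table,
    write_bpm,
    write_fasta,
)

#: The 24 representative metabolic phenotypes used for gut profiling:
#: B-vitamin, lipoate and vitamin K biosynthesis, SCFA production,
#: carbohydrate utilisation, and two amino-acid biosyntheses.
PHENOTYPE_PANEL: tuple[str, ...] = (
    "B1", "B2", "B3", "B5", "B6", "B7", "B9", "B12",
    "Lipoate", "K",
    "Butyrate", "Propionate",
    "Glc", "Gal", "Fru", "Man", "Xyl", "Ara", "Fuc", "Rha", "Rib", "Lac",
    "His", "Trp",
)

#: Literal primer motifs framing the amplified window (forward-strand
#: site sequences; configurable in the generator).
PRIMER_341F = "CCTACGGGAGGCAGCAG"
PRIMER_806R_SITE = "ATTAGATACCCTGGTAGTCC"

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# Fixed 16S layout of the synthetic reference: full length 1200 nt,
# forward primer site at 300, reverse primer site at 737.
_SEQ_LEN = 1200
_P1_START = 300
_P2_START = 737


@dataclass
class ReferenceFixture:
    """Synthetic reference collection: phenotypes plus 16S sequences."""

    bpm: BinaryPhenotypeMatrix
    sequences: dict[str, str]
    primers: tuple[str, str] = (PRIMER_341F, PRIMER_806R_SITE)

    def write(self, outdir: str | Path, prefix: str = "reference") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_bpm(
            self.bpm,
            outdir / f"{prefix}_bpm.tsv",
            outdir / f"{prefix}_taxonomy.tsv",
        )
        write_fasta(self.sequences, outdir / f"{prefix}_16s.fasta")


@dataclass
class SpeciesPool:
    """Species available to community sampling with mean abundances A."""

    records: list[tuple[Taxonomy, float]]

    def __post_init__(self) -> None:
        if any(a <= 0 for _, a in self.records):
            raise ValueError("pool mean abundances must be positive")
        keys = [t.key for t, _ in self.records]
        if len(set(keys)) != len(keys):
            raise ValueError("pool species must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def write(self, path: str | Path) -> None:
        rows = [
            {**dict(zip(RANKS, tax.labels)), "mean_abundance": a}
            for tax, a in self.records
        ]
        pd.DataFrame(rows, columns=[*RANKS, "mean_abundance"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def read(cls, path: str | Path) -> "SpeciesPool":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        records = [
            (
                Taxonomy(tuple(r[rank] for rank in RANKS)),
                float(r["mean_abundance"]),
            )
            for r in df.to_dict("records")
        ]
        return cls(records)


@dataclass
class StrainRecord:
    genome_id: str
    species: Taxonomy
    species_abundance: float  # R
    strain_fraction: float  # Q
    count: int  # C


@dataclass
class MockCommunity:
    """One sampled community: strains with counts and bookkeeping.

    ``total`` is the sampled total amplicon count T (the quantity the
    rejection bounds apply to); ``realized_total`` is the sum of the
    rounded per-strain counts, which can differ from T by rounding.
    """

    sample_id: str
    strains: list[StrainRecord]
    species_count: int  # S
    total: int  # sampled T
    #: full sampled strain fractions Q per species, before zero-count
    #: strains are dropped (each vector sums to 1)
    strain_fractions: dict[tuple[str, ...], list[float]] = field(
        default_factory=dict
    )
    realized_total: int = field(init=False)

    def __post_init__(self) -> None:
        self.realized_total = sum(s.count for s in self.strains)

    def species_abundances(self) -> dict[tuple[str, ...], float]:
        out: dict[tuple[str, ...], float] = {}
        for s in self.strains:
            out.setdefault(s.species.key, s.species_abundance)
        return out


@dataclass
class TruthMap:
    """Known ASV composition: asv_id -> {genome_id: weight}."""

    weights: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for asv, w in self.weights.items():
            if abs(sum(w.values()) - 1.0) > 1e-9:
                raise ValueError(f"truth weights of '{asv}' do not sum to 1")

    def true_pi(self, bpm: BinaryPhenotypeMatrix) -> pd.DataFrame:
        """Exact per-ASV phenotype indices implied by the truth weights."""
        rows = {}
        for asv, w in self.weights.items():
            gids = list(w)
            wvec = np.array([w[g] for g in gids])
            rows[asv] = wvec @ bpm.values.loc[gids].to_numpy()
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=bpm.phenotypes
        )


# ---------------------------------------------------------------------------
# reference fixture generation
# ---------------------------------------------------------------------------


def _mutate(
    seq: np.ndarray, rate: float, rng: np.random.Generator, mutable: np.ndarray
) -> np.ndarray:
    """Substitute bases at ``rate`` on mutable positions only."""
    out = seq.copy()
    hits = np.flatnonzero((rng.random(seq.size) < rate) & mutable)
    for i in hits:
        choices = _BASES[_BASES != out[i]]
        out[i] = rng.choice(choices)
    return out


def _force_substitution(
    seq: np.ndarray, rng: np.random.Generator, mutable: np.ndarray
) -> np.ndarray:
    out = seq.copy()
    i = rng.choice(np.flatnonzero(mutable))
    choices = _BASES[_BASES != out[i]]
    out[i] = rng.choice(choices)
    return out


def generate_reference_fixture(
    n_species: int = 120,
    strains_per_species: tuple[int, int] = (1, 6),
    phenotype_names: Sequence[str] = PHENOTYPE_PANEL,
    species_flip_prob: float = 0.1,
    seed: int = 0,
    primers: tuple[str, str] = (PRIMER_341F, PRIMER_806R_SITE),
    genus_divergence: float = 0.04,
    species_divergence: float = 0.01,
    strain_divergence: float = 0.0025,
) -> ReferenceFixture:
    """Build a strain-level synthetic reference collection.

    Species-level phenotype values are Bernoulli(0.5); each strain
    inherits its species value, flipped independently with probability
    ``species_flip_prob`` (modelling phylogenetic microheterogeneity).
    16S sequences derive from a genus consensus mutated into species
    consensuses and then strain copies, so pairwise identity is highest
    within species; the primer sites are embedded unmutated at fixed
    coordinates so every amplicon truncates cleanly.
    """
    if n_species < 1:
        raise ValueError("need at least one species")
    lo, hi = strains_per_species
    if lo < 1 or hi < lo:
        raise ValueError("invalid strains_per_species range")
    if not 0.0 <= species_flip_prob <= 0.5:
        raise ValueError("species_flip_prob must be in [0, 0.5]")
    rng = np.random.default_rng(seed)

    p1, p2 = primers
    root = rng.choice(_BASES, size=_SEQ_LEN)
    root[_P1_START : _P1_START + len(p1)] = np.frombuffer(
        p1.encode(), dtype="S1"
    )
    root[_P2_START : _P2_START + len(p2)] = np.frombuffer(
        p2.encode(), dtype="S1"
    )
    mutable = np.ones(_SEQ_LEN, dtype=bool)
    mutable[_P1_START : _P1_START + len(p1)] = False
    mutable[_P2_START : _P2_START + len(p2)] = False

    # shallow taxonomic hierarchy scaled to the species count
    n_genera = max(1, round(n_species / 3))
    n_families = max(1, round(n_genera / 2))
    n_orders = max(1, round(n_families / 2))
    n_classes = max(1, round(n_orders / 2))
    n_phyla = max(1, round(n_classes / 2))

    genus_seqs = [_mutate(root, genus_divergence, rng, mutable) for _ in range(n_genera)]

    taxonomy: dict[str, Taxonomy] = {}
    sequences: dict[str, str] = {}
    seen_seqs: set[bytes] = set()
    rows: list[np.ndarray] = []
    genome_ids: list[str] = []
    phenotype_names = list(phenotype_names)

    for sp in range(n_species):
        g = sp % n_genera
        fam = g % n_families
        order = fam % n_orders
        cls = order % n_classes
        phy = cls % n_phyla
        species_tax = Taxonomy(
            (
                "Bacteria",
                f"Phylum{phy + 1:02d}",
                f"Class{cls + 1:02d}",
                f"Order{order + 1:02d}",
                f"Family{fam + 1:02d}",
                f"Genus{g + 1:03d}",
                f"Genus{g + 1:03d} sp{sp + 1:03d}",
            )
        )
        species_seq = _mutate(genus_seqs[g], species_divergence, rng, mutable)
        species_pheno = rng.integers(0, 2, size=len(phenotype_names))
        n_strains = int(rng.integers(lo, hi + 1))
        for st in range(n_strains):
            gid = f"G{sp + 1:03d}.{st + 1}"
            strain_seq = _mutate(species_seq, strain_divergence, rng, mutable)
            for _ in range(200):
                if strain_seq.tobytes() not in seen_seqs:
                    break
                strain_seq = _force_substitution(strain_seq, rng, mutable)
            else:  # pragma: no cover - astronomically unlikely
                raise RuntimeError("could not generate a unique 16S sequence")
            seen_seqs.add(strain_seq.tobytes())
            flips = rng.random(len(phenotype_names)) < species_flip_prob
            rows.append(np.where(flips, 1 - species_pheno, species_pheno))
            genome_ids.append(gid)
            taxonomy[gid] = species_tax
            sequences[gid] = strain_seq.tobytes().decode()

    values = pd.DataFrame(rows, index=genome_ids, columns=phenotype_names)
    bpm = BinaryPhenotypeMatrix(values, taxonomy)
    return ReferenceFixture(bpm, sequences, primers)


def make_species_pool(
    bpm: BinaryPhenotypeMatrix,
    pool_size: int = 120,
    seed: int = 0,
    lognormal_sigma: float = 1.25,
) -> SpeciesPool:
    """Draw a species pool with heavy-tailed mean abundances.

    Mean abundances A are lognormal (heavy-tailed, as observed for
    dominant gut species) and normalised to sum 1 over the pool.
    """
    rng = np.random.default_rng(seed)
    species: dict[tuple[str, ...], Taxonomy] = {}
    for tax in bpm.taxonomy.values():
        species.setdefault(tax.key, tax)
    taxa = list(species.values())
    if pool_size < len(taxa):
        idx = rng.choice(len(taxa), size=pool_size, replace=False)
        taxa = [taxa[i] for i in idx]
    a = rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=len(taxa))
    a /= a.sum()
    return SpeciesPool(list(zip(taxa, map(float, a))))


# ---------------------------------------------------------------------------
# community sampling
# ---------------------------------------------------------------------------


def _reject_normal(
    rng: np.random.Generator,
    mean: float,
    std: float,
    lo: float,
    hi: float,
    integral: bool = False,
    max_tries: int = 100_000,
) -> float:
    for _ in range(max_tries):
        x = rng.normal(mean, std)
        if integral:
            x = float(np.rint(x))
        if lo < x < hi:
            return x
    raise RuntimeError("rejection sampling failed to converge")


def sample_community(
    pool: SpeciesPool,
    bpm: BinaryPhenotypeMatrix,
    seed: int | np.random.Generator = 0,
    sample_id: str = "MC1",
    species_mean: float = 30.0,
    species_std: float = 5.0,
    species_bounds: tuple[int, int] = (10, 60),
    total_mean: float = 20_000.0,
    total_std: float = 4_000.0,
    total_bounds: tuple[int, int] = (4_000, 40_000),
    abundance_rel_std: float = 0.4,
    abundance_bounds: tuple[float, float] = (0.1, 3.0),
) -> MockCommunity:
    """Sample one mock community from the pool (see module docstring)."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    s_lo, s_hi = species_bounds
    s = int(
        _reject_normal(rng, species_mean, species_std, s_lo, s_hi, integral=True)
    )
    if s > len(pool):
        raise ValueError(f"pool of {len(pool)} species cannot supply S={s}")

    weights = np.array([a for _, a in pool.records])
    weights = weights / weights.sum()
    chosen_idx = rng.choice(len(pool), size=s, replace=False, p=weights)

    # species abundances R with rejection around their pool means
    r_vals = []
    for i in chosen_idx:
        a = pool.records[i][1]
        lo_f, hi_f = abundance_bounds
        r_vals.append(
            _reject_normal(rng, a, abundance_rel_std * a, lo_f * a, hi_f * a)
        )
    r_vals = np.array(r_vals)
    r_vals /= r_vals.sum()

    t = int(
        _reject_normal(
            rng, total_mean, total_std, total_bounds[0], total_bounds[1],
            integral=True,
        )
    )

    strains: list[StrainRecord] = []
    fractions: dict[tuple[str, ...], list[float]] = {}
    for i, r in zip(chosen_idx, r_vals):
        tax = pool.records[i][0]
        gids = bpm.strains_of_species(tax.key)
        if not gids:
            raise ValueError(f"species '{tax.species}' absent from reference")
        n_max = math.ceil(math.sqrt(len(gids)))
        n = int(rng.integers(1, n_max + 1))
        picked = rng.choice(len(gids), size=n, replace=False)
        q = rng.random(n)
        q /= q.sum()
        fractions[tax.key] = [float(v) for v in q]
        for j, qj in zip(picked, q):
            c = int(np.rint(qj * r * t))
            if c == 0:
                continue
            strains.append(StrainRecord(gids[j], tax, float(r), float(qj), c))
    return MockCommunity(sample_id, strains, s, t, fractions)


# ---------------------------------------------------------------------------
# amplicon truncation and ASV collapse
# ---------------------------------------------------------------------------


def truncate_amplicons(
    sequences: Mapping[str, str],
    primers: tuple[str, str] | None = (PRIMER_341F, PRIMER_806R_SITE),
    coordinates: tuple[int, int] | None = None,
) -> tuple[dict[str, str], list[tuple[str, str]]]:
    """Cut each sequence down to the amplified window.

    Primer mode extracts the subsequence strictly between the two
    primer sites (primers excluded); each motif must occur exactly
    once.  Coordinate mode slices ``[start, end)`` directly.  Returns
    the truncated sequences and a list of ``(seq_id, reason)`` error
    records for skipped sequences.
    """
    out: dict[str, str] = {}
    errors: list[tuple[str, str]] = []
    if coordinates is not None:
        start, end = coordinates
        for sid, seq in sequences.items():
            if not (0 <= start <= end <= len(seq)):
                errors.append((sid, f"coordinates ({start}, {end}) out of bounds"))
                continue
            out[sid] = seq[start:end]
        return out, errors
    if primers is None:
        raise ValueError("either primers or coordinates must be given")
    p1, p2 = primers
    for sid, seq in sequences.items():
        n1, n2 = seq.count(p1), seq.count(p2)
        if n1 != 1 or n2 != 1:
            errors.append(
                (sid, f"primer occurrences forward={n1}, reverse={n2}")
            )
            continue
        i = seq.index(p1) + len(p1)
        j = seq.index(p2)
        if j < i:
            errors.append((sid, "reverse primer site precedes forward site"))
            continue
        out[sid] = seq[i:j]
    return out, errors


def collapse_to_asvs(
    truncated: Mapping[str, str], community: MockCommunity
) -> tuple[dict[str, int], TruthMap, dict[str, str]]:
    """Merge identical truncated amplicons into ASVs.

    Returns per-ASV aggregated counts, the truth map with weights
    proportional to member counts, and the ASV sequences.  ASV ids
    within a community are the truncated sequences' first contributing
    genome id prefixed by the sequence rank (stable for a fixed
    community).
    """
    by_seq: dict[str, list[StrainRecord]] = {}
    for strain in community.strains:
        if strain.genome_id not in truncated:
            continue  # truncation failure already logged upstream
        by_seq.setdefault(truncated[strain.genome_id], []).append(strain)
    counts: dict[str, int] = {}
    weights: dict[str, dict[str, float]] = {}
    seqs: dict[str, str] = {}
    for k, (seq, members) in enumerate(by_seq.items()):
        asv_id = f"{community.sample_id}.A{k + 1:04d}"
        total = sum(m.count for m in members)
        counts[asv_id] = total
        weights[asv_id] = {m.genome_id: m.count / total for m in members}
        seqs[asv_id] = seq
    return counts, TruthMap(weights), seqs


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


@dataclass
class MockDataset:
    """A set of mock communities collapsed into one multi-sample table.

    ASV ids are assigned dataset-wide by sequence, so the same
    truncated sequence appearing in several communities is one ASV
    column-shared across samples.  Truth maps stay per sample because
    the strain mixture behind a shared sequence differs by community.
    """

    table: ASVTable
    truth: dict[str, TruthMap]
    communities: list[MockCommunity]

    def write(self, outdir: str | Path, prefix: str = "mock") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_asv_table(
            self.table,
            outdir / f"{prefix}_counts.tsv",
            outdir / f"{prefix}_asvs.fasta",
        )
        rows = []
        for sample, tm in self.truth.items():
            for asv, w in tm.weights.items():
                for gid, wt in w.items():
                    rows.append(
                        {"sample": sample, "asv_id": asv,
                         "genome_id": gid, "weight": wt}
                    )
        pd.DataFrame(
            rows, columns=["sample", "asv_id", "genome_id", "weight"]
        ).to_csv(outdir / f"{prefix}_truth_map.tsv", sep="\t", index=False)


def true_community_profile(dataset: MockDataset, bpm: BinaryPhenotypeMatrix):
    """Ground-truth community phenotype indices of a mock dataset.

    Uses each sample's truth map (exact per-ASV phenotype indices) and
    the sample's relative abundances; this is the reference against
    which the predictive mapping schemes are scored.
    """
    from .indices import CommunityProfile

    cpi_rows = {}
    var_rows = {}
    phenos = bpm.phenotypes
    rel = dataset.table.relative
    for sample, tmap in dataset.truth.items():
        pi = tmap.true_pi(bpm)
        a = rel.loc[pi.index, sample].to_numpy()
        a = a / a.sum()
        p = pi.to_numpy()
        cpi_rows[sample] = a @ p
        var_rows[sample] = (a**2) @ (p * (1 - p))
    coverage = pd.Series(1.0, index=list(dataset.truth))
    return CommunityProfile(
        pd.DataFrame.from_dict(cpi_rows, orient="index", columns=phenos),
        pd.DataFrame.from_dict(var_rows, orient="index", columns=phenos),
        coverage,
    )


def generate_mock_dataset(
    fixture: ReferenceFixture,
    pool: SpeciesPool,
    n_communities: int,
    seed: int = 0,
    truncate: bool = True,
) -> MockDataset:
    """Sample communities and collapse them into a shared ASV table.

    With ``truncate=False`` the full-length amplicons are kept (the
    ground-truth dataset: one ASV per strain, all truth weights 1);
    with ``truncate=True`` amplicons are cut to the V3-V4 window first,
    so within-species collapse occurs (the realistic dataset).
    """
    rng = np.random.default_rng(seed)
    if truncate:
        trunc, errors = truncate_amplicons(fixture.sequences, fixture.primers)
        if errors:
            raise ValueError(f"reference truncation failed: {errors[:3]}")
    else:
        trunc = dict(fixture.sequences)

    seq_to_asv: dict[str, str] = {}
    asv_seqs: dict[str, str] = {}
    col_counts: dict[str, dict[str, int]] = {}
    truth: dict[str, TruthMap] = {}
    communities: list[MockCommunity] = []
    for k in range(n_communities):
        sample = f"MC{k + 1:04d}"
        comm = sample_community(pool, fixture.bpm, rng, sample_id=sample)
        counts, tmap, seqs = collapse_to_asvs(trunc, comm)
        remap: dict[str, str] = {}
        sample_counts: dict[str, int] = {}
        for local_id, seq in seqs.items():
            if seq not in seq_to_asv:
                seq_to_asv[seq] = f"ASV{len(seq_to_asv) + 1:05d}"
                asv_seqs[seq_to_asv[seq]] = seq
            remap[local_id] = seq_to_asv[seq]
            sample_counts[seq_to_asv[seq]] = counts[local_id]
        col_counts[sample] = sample_counts
        truth[sample] = TruthMap(
            {remap[a]: w for a, w in tmap.weights.items()}
        )
        communities.append(comm)

    counts_df = (
        pd.DataFrame(col_counts).reindex(list(asv_seqs)).fillna(0).astype(int)
    )
    table = ASVTable(counts_df, asv_seqs)
    return MockDataset(table, truth, communities)
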