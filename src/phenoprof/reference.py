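"""Reference-collection data model and tabular I/O.

Holds the building blocks every other stage consumes: seven-rank
taxonomies, the Binary Phenotype Matrix (reference genomes x 0/1
metabolic phenotypes), 16S gene copy number tables, and per-sample ASV
abundance tables.  All on-disk formats are plain TSV/FASTA so fixtures
round-trip exactly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Fixed rank order, domain down to species.
RANKS: tuple[str, ...] = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

SPECIES_DEPTH = len(RANKS)
FAMILY_DEPTH = RANKS.index("family") + 1


class FormatError(ValueError):
    """A file or table violates the expected format."""


def _norm(label: str) -> str:
    """Normalised form used for label comparison: trimmed, case-folded."""
    return label.strip().casefold()


@dataclass(frozen=True)
class Taxonomy:
    """A seven-rank taxonomic description.

    Unassigned ranks are empty strings and must form a contiguous
    suffix: once a rank is blank every deeper rank is blank too.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(RANKS):
            raise ValueError(
                f"taxonomy needs {len(RANKS)} ranks, got {len(self.labels)}"
            )
        labels = tuple(lbl.strip() for lbl in self.labels)
        object.__setattr__(self, "labels", labels)
        seen_blank = False
        for rank, lbl in zip(RANKS, labels):
            if lbl == "":
                seen_blank = True
            elif seen_blank:
                raise ValueError(
                    f"rank '{rank}' assigned below a blank rank: {labels!r}"
                )

    @property
    def depth(self) -> int:
        """Number of assigned ranks (0 = fully blank)."""
        n = 0
        for lbl in self.labels:
            if lbl == "":
                break
            n += 1
        return n

    @property
    def key(self) -> tuple[str, ...]:
        """Comparison key over assigned ranks (normalised labels)."""
        return tuple(_norm(lbl) for lbl in self.labels[: self.depth])

    def prefix_key(self, depth: int) -> tuple[str, ...]:
        return tuple(_norm(lbl) for lbl in self.labels[:depth])

    @property
    def species(self) -> str:
        return self.labels[-1]

    def truncated(self, depth: int) -> "Taxonomy":
        """Copy with every rank deeper than ``depth`` blanked."""
        return Taxonomy(self.labels[:depth] + ("",) * (len(RANKS) - depth))

    def __str__(self) -> str:
        return "; ".join(lbl for lbl in self.labels if lbl)


@dataclass(frozen=True)
class MultiTaxonomy:
    """Several species-level taxonomies held with equal weights.

    This is the multi-taxonomic assignment of an ASV whose top
    alignment hits span more than one reference species; the display
    form joins alternatives with ``/`` per rank.
    """

    entries: tuple[Taxonomy, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("MultiTaxonomy needs at least one entry")
        if len(self.entries) != len(self.weights):
            raise ValueError("entries and weights differ in length")
        keys = [t.key for t in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("MultiTaxonomy entries must be unique")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("MultiTaxonomy weights must sum to 1")
        if any(w <= 0 for w in self.weights):
            raise ValueError("MultiTaxonomy weights must be positive")

    @classmethod
    def from_entries(cls, entries: Iterable[Taxonomy]) -> "MultiTaxonomy":
        uniq: list[Taxonomy] = []
        seen: set[tuple[str, ...]] = set()
        for t in entries:
            if t.key not in seen:
                seen.add(t.key)
                uniq.append(t)
        w = 1.0 / len(uniq)
        return cls(tuple(uniq), tuple(w for _ in uniq))

    def __str__(self) -> str:
        """Slash-joined display form, e.g. ``...; ovatus/vulgatus``."""
        parts = []
        for i in range(len(RANKS)):
            alts = []
            for t in self.entries:
                if t.labels[i] and t.labels[i] not in alts:
                    alts.append(t.labels[i])
            parts.append("/".join(alts))
        return "; ".join(p for p in parts if p)


@dataclass
class ReferenceGenome:
    """One reference genome: id, species-level taxonomy, 16S copies."""

    genome_id: str
    taxonomy: Taxonomy
    sequences: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.taxonomy.depth != SPECIES_DEPTH:
            raise ValueError(
                f"genome {self.genome_id}: taxonomy must be species-level"
            )


class BinaryPhenotypeMatrix:
    """Reference genomes x binary metabolic phenotypes (0/1).

    Rows are genomes (each with a species-resolved taxonomy), columns
    are phenotype names, and a cell is 1 when the genome encodes a
    complete pathway for the phenotype (a carrier).
    """

    def __init__(
        self,
        values: pd.DataFrame,
        taxonomy: Mapping[str, Taxonomy],
    ) -> None:
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()][0]
            raise FormatError(f"duplicate genome_id '{dup}'")
        arr = values.to_numpy()
        bad = ~np.isin(arr, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise FormatError(
                f"non-binary value {arr[r, c]!r} at genome "
                f"'{values.index[r]}', phenotype '{values.columns[c]}'"
            )
        missing = [g for g in values.index if g not in taxonomy]
        if missing:
            raise FormatError(f"genome '{missing[0]}' has no taxonomy")
        self.values = values.astype(np.int8)
        self.taxonomy = {g: taxonomy[g] for g in values.index}
        self._prefix_index: dict[int, dict[tuple[str, ...], list[str]]] | None = None

    # -- basic accessors -------------------------------------------------
    @property
    def genome_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def phenotypes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genomes(self) -> int:
        return len(self.values.index)

    def phenotype_vector(self, genome_id: str) -> pd.Series:
        return self.values.loc[genome_id]

    # -- taxonomy lookup -------------------------------------------------
    def _index(self) -> dict[int, dict[tuple[str, ...], list[str]]]:
        if self._prefix_index is None:
            idx: dict[int, dict[tuple[str, ...], list[str]]] = {
                d: {} for d in range(1, SPECIES_DEPTH + 1)
            }
            for gid, tax in self.taxonomy.items():
                for d in range(1, SPECIES_DEPTH + 1):
                    idx[d].setdefault(tax.prefix_key(d), []).append(gid)
            self._prefix_index = idx
        return self._prefix_index

    def genomes_matching(self, tax: Taxonomy) -> tuple[int, list[str]]:
        """Deepest-rank match of a taxonomy against the collection.

        Returns ``(depth, genome_ids)`` where depth is the deepest
        number of leading ranks on which at least one reference genome
        agrees with ``tax``; ``(0, [])`` when nothing matches or the
        taxonomy is fully blank.
        """
        idx = self._index()
        for d in range(tax.depth, 0, -1):
            hit = idx[d].get(tax.prefix_key(d))
            if hit:
                return d, list(hit)
        return 0, []

    def strains_of_species(self, species_key: tuple[str, ...]) -> list[str]:
        return list(self._index()[SPECIES_DEPTH].get(species_key, []))

    def species_keys(self) -> list[tuple[str, ...]]:
        return list(self._index()[SPECIES_DEPTH])


def read_bpm(path: str | Path, taxonomy_path: str | Path) -> BinaryPhenotypeMatrix:
    """Read a Binary Phenotype Matrix and its companion taxonomy table.

    The matrix TSV has ``genome_id`` in the first column and one 0/1
    column per phenotype; the taxonomy TSV has columns ``genome_id``
    plus the seven ranks (blank = unassigned).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("genome_id")
    df.index.name = None
    try:
        values = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric phenotype value in {path}: {exc}") from exc
    tax = read_taxonomy_table(taxonomy_path)
    return BinaryPhenotypeMatrix(values, tax)


def write_bpm(
    bpm: BinaryPhenotypeMatrix, path: str | Path, taxonomy_path: str | Path
) -> None:
    out = bpm.values.copy()
    out.index.name = "genome_id"
    out.to_csv(path, sep="\t")
    write_taxonomy_table(bpm.taxonomy, taxonomy_path)


def read_taxonomy_table(path: str | Path) -> dict[str, Taxonomy]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("genome_id", *RANKS) if c not in df.columns]
    if missing:
        raise FormatError(f"taxonomy table missing columns {missing}")
    out: dict[str, Taxonomy] = {}
    for row in df.to_dict("records"):  # "class" is a keyword: no itertuples
        gid = row["genome_id"]
        if gid in out:
            raise FormatError(f"duplicate genome_id '{gid}' in taxonomy table")
        out[gid] = Taxonomy(tuple(row[r] for r in RANKS))
    return out


def write_taxonomy_table(taxonomy: Mapping[str, Taxonomy], path: str | Path) -> None:
    rows = [
        {"genome_id": gid, **dict(zip(RANKS, tax.labels))}
        for gid, tax in taxonomy.items()
    ]
    pd.DataFrame(rows, columns=["genome_id", *RANKS]).to_csv(
        path, sep="\t", index=False
    )


@dataclass
class GCNTable:
    """Per-taxon mean 16S rRNA gene copy numbers at named ranks."""

    records: dict[tuple[str, str], float] = field(default_factory=dict)

    def add(self, taxon: str, rank: str, mean_gcn: float) -> None:
        if rank not in RANKS:
            raise FormatError(f"unknown rank '{rank}'")
        if not mean_gcn > 0:
            raise FormatError(
                f"non-positive GCN {mean_gcn} for ({taxon}, {rank})"
            )
        key = (_norm(taxon), rank)
        if key in self.records:
            raise FormatError(f"duplicate GCN entry for ({taxon}, {rank})")
        self.records[key] = float(mean_gcn)

    def lookup(self, taxon: str, rank: str) -> float | None:
        return self.records.get((_norm(taxon), rank))

    def deepest_gcn(self, tax: Taxonomy) -> float | None:
        """GCN at the deepest assigned rank present in the table."""
        for d in range(tax.depth - 1, -1, -1):
            g = self.lookup(tax.labels[d], RANKS[d])
            if g is not None:
                return g
        return None

    @property
    def global_mean(self) -> float:
        if not self.records:
            raise ValueError("empty GCN table has no mean")
        return float(np.mean(list(self.records.values())))

    def __len__(self) -> int:
        return len(self.records)


def read_gcn_table(path: str | Path) -> GCNTable:
    df = pd.read_csv(path, sep="\t", dtype={"taxon": str, "rank": str})
    missing = [c for c in ("taxon", "rank", "mean_gcn") if c not in df.columns]
    if missing:
        raise FormatError(f"GCN table missing columns {missing}")
    table = GCNTable()
    for row in df.itertuples(index=False):
        table.add(row.taxon, row.rank, float(row.mean_gcn))
    return table


def write_gcn_table(table: GCNTable, path: str | Path) -> None:
    rows = [
        {"taxon": taxon, "rank": rank, "mean_gcn": gcn}
        for (taxon, rank), gcn in table.records.items()
    ]
    pd.DataFrame(rows, columns=["taxon", "rank", "mean_gcn"]).to_csv(
        path, sep="\t", index=False
    )


class ASVTable:
    """Per-sample ASV counts, sequences, and relative abundances.

    ``counts`` is ASVs x samples (raw integer counts); ``relative``
    holds per-sample relative abundances which start as count /
    sample-total and may later be replaced by their gene-copy-number
    renormalised form.  Columns of ``relative`` always sum to 1.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        sequences: Mapping[str, str],
        relative: pd.DataFrame | None = None,
    ) -> None:
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()][0]
            raise FormatError(f"duplicate asv_id '{dup}'")
        if (counts.to_numpy() < 0).any():
            raise FormatError("negative count in ASV table")
        missing = set(counts.index) - set(sequences)
        if missing:
            raise FormatError(f"ASV '{sorted(missing)[0]}' has no sequence")
        extra = set(sequences) - set(counts.index)
        if extra:
            raise FormatError(
                f"sequence id '{sorted(extra)[0]}' absent from counts"
            )
        totals = counts.sum(axis=0)
        empty = totals[totals == 0]
        if len(empty):
            raise FormatError(f"empty sample '{empty.index[0]}'")
        self.counts = counts
        self.sequences = dict(sequences)
        if relative is None:
            relative = counts / totals
        self._set_relative(relative)

    def _set_relative(self, relative: pd.DataFrame) -> None:
        if not relative.index.equals(self.counts.index) or not (
            relative.columns.equals(self.counts.columns)
        ):
            raise ValueError("relative table shape mismatch")
        sums = relative.sum(axis=0)
        if (np.abs(sums - 1.0) > 1e-9).any():
            bad = sums.index[np.abs(sums - 1.0) > 1e-9][0]
            raise ValueError(f"relative abundances of '{bad}' do not sum to 1")
        self.relative = relative

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def with_relative(self, relative: pd.DataFrame) -> "ASVTable":
        return ASVTable(self.counts, self.sequences, relative)


def read_asv_table(counts_path: str | Path, fasta_path: str | Path) -> ASVTable:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    counts.index.name = None
    seqs = read_fasta(fasta_path)
    return ASVTable(counts, seqs)


def write_asv_table(
    table: ASVTable, counts_path: str | Path, fasta_path: str | Path
) -> None:
    out = table.counts.copy()
    out.index.name = "asv_id"
    out.to_csv(counts_path, sep="\t")
    write_fasta(table.sequences, fasta_path)


def read_fasta(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"duplicate FASTA id '{rec.id}'")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
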