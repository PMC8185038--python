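"""ASV-to-reference-genome maps under the CBTA, MTA and SEQ schemes.

A map assigns each ASV a weighted set of reference genomes (weights
sum to 1) from which phenotype indices are later averaged.  The
taxonomy-based schemes match taxonomic descriptions level by level
against the reference collection; the sequence-based scheme aligns
ASVs directly against the reference 16S sequences.  In both cases
weight is split equally across the unique species reached, then
equally across each species' strains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .assign import (
    AlignmentHit,
    DEFAULT_DROP_THRESHOLD,
    DEFAULT_S_SCALE,
    filter_top_hits,
    search_reference,
)
from .reference import (
    ASVTable,
    BinaryPhenotypeMatrix,
    FAMILY_DEPTH,
    MultiTaxonomy,
    Taxonomy,
)


@dataclass
class ASVMap:
    """Per-ASV weighted genome lists plus mapped flags.

    Unmapped ASVs are present with an empty weight dict so coverage
    accounting can see them.
    """

    scheme: str
    weights: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for asv, w in self.weights.items():
            if w and abs(sum(w.values()) - 1.0) > 1e-9:
                raise ValueError(f"weights of ASV '{asv}' do not sum to 1")

    def is_mapped(self, asv_id: str) -> bool:
        return bool(self.weights.get(asv_id))

    @property
    def mapped_ids(self) -> list[str]:
        return [a for a, w in self.weights.items() if w]

    def write(self, path: str | Path) -> None:
        rows = []
        for asv, w in self.weights.items():
            if not w:
                rows.append(
                    {"asv_id": asv, "genome_id": "", "weight": "",
                     "mapped": 0, "scheme": self.scheme}
                )
            for gid, wt in w.items():
                rows.append(
                    {"asv_id": asv, "genome_id": gid, "weight": wt,
                     "mapped": 1, "scheme": self.scheme}
                )
        pd.DataFrame(
            rows, columns=["asv_id", "genome_id", "weight", "mapped", "scheme"]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "ASVMap":
        df = pd.read_csv(path, sep="\t", dtype={"asv_id": str, "genome_id": str})
        scheme = str(df["scheme"].iloc[0]) if len(df) else "unknown"
        weights: dict[str, dict[str, float]] = {}
        for row in df.itertuples(index=False):
            w = weights.setdefault(row.asv_id, {})
            if int(row.mapped):
                w[row.genome_id] = float(row.weight)
        return cls(scheme, weights)


def species_strain_weights(
    genome_ids: Sequence[str], bpm: BinaryPhenotypeMatrix
) -> dict[str, float]:
    """Split unit weight equally over unique species, then strains."""
    by_species: dict[tuple[str, ...], list[str]] = {}
    for gid in genome_ids:
        by_species.setdefault(bpm.taxonomy[gid].key, []).append(gid)
    n_species = len(by_species)
    out: dict[str, float] = {}
    for strains in by_species.values():
        w = 1.0 / (n_species * len(strains))
        for gid in strains:
            out[gid] = out.get(gid, 0.0) + w
    return out


def map_by_taxonomy(
    assignments: Mapping[str, Taxonomy | MultiTaxonomy | None],
    bpm: BinaryPhenotypeMatrix,
    scheme: str = "cbta",
    min_depth: int = FAMILY_DEPTH,
) -> ASVMap:
    """Level-by-level taxonomic mapping of ASVs onto the reference.

    For each (simple) taxonomy the deepest rank with at least one
    reference match determines the matched genome set; an ASV counts
    as mapped only when that rank is family or deeper.  Multi-taxonomy
    assignments repeat the procedure per entry, scaled by the entry
    weight, summing weights of genomes reached via several entries.
    """
    weights: dict[str, dict[str, float]] = {}
    for asv, assignment in assignments.items():
        combined: dict[str, float] = {}
        if assignment is not None:
            if isinstance(assignment, MultiTaxonomy):
                parts = list(zip(assignment.entries, assignment.weights))
            else:
                parts = [(assignment, 1.0)]
            for tax, mta_w in parts:
                depth, gids = bpm.genomes_matching(tax)
                if depth < min_depth:
                    continue
                for gid, w in species_strain_weights(gids, bpm).items():
                    combined[gid] = combined.get(gid, 0.0) + mta_w * w
        total = sum(combined.values())
        if total > 0:
            combined = {g: w / total for g, w in combined.items()}
        weights[asv] = combined
    return ASVMap(scheme, weights)


def map_by_sequence(
    asv_seqs: Mapping[str, str],
    ref_seqs: Mapping[str, str],
    bpm: BinaryPhenotypeMatrix,
    ref_to_genome: Mapping[str, str] | None = None,
    hits_by_asv: Mapping[str, Sequence[AlignmentHit]] | None = None,
    s_scale: float = DEFAULT_S_SCALE,
    drop_threshold: float = DEFAULT_DROP_THRESHOLD,
    per_species_weighting: bool = True,
) -> ASVMap:
    """Sequence-based mapping: align ASVs straight onto reference 16S.

    The top-hit window (same S and D as the taxonomic profiling) picks
    the accepted genomes; a genome with several 16S copies contributes
    only its best-identity copy.  An ASV is mapped when its best
    identity exceeds the drop threshold.  By default weight follows
    the species-then-strain split over accepted genomes; with
    ``per_species_weighting=False`` every accepted genome gets equal
    weight instead.
    """
    if not ref_seqs and hits_by_asv is None:
        raise ValueError("empty reference collection")
    if ref_to_genome is None:
        ref_to_genome = {rid: rid for rid in ref_seqs}
    if hits_by_asv is None:
        hits_by_asv = search_reference(asv_seqs, ref_seqs)

    weights: dict[str, dict[str, float]] = {}
    for asv in asv_seqs:
        hits = list(hits_by_asv.get(asv, ()))
        # best copy per genome
        best: dict[str, AlignmentHit] = {}
        for h in hits:
            gid = ref_to_genome.get(h.ref_id)
            if gid is None:
                raise KeyError(f"reference id '{h.ref_id}' has no genome")
            if gid not in best or h.identity > best[gid].identity:
                best[gid] = AlignmentHit(h.asv_id, gid, h.identity)
        accepted = filter_top_hits(
            list(best.values()), s_scale, drop_threshold
        )
        if not accepted:
            weights[asv] = {}
            continue
        gids = [h.ref_id for h in accepted]
        if per_species_weighting:
            weights[asv] = species_strain_weights(gids, bpm)
        else:
            weights[asv] = {g: 1.0 / len(gids) for g in gids}
    return ASVMap("seq", weights)


def mapping_coverage(asv_map: ASVMap, table: ASVTable) -> pd.Series:
    """Per-sample summed relative abundance of mapped ASVs."""
    mapped = [a for a in table.asv_ids if asv_map.is_mapped(a)]
    return table.relative.loc[mapped].sum(axis=0)
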