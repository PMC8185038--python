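"""Taxonomic assignment of ASVs and gene-copy-number renormalisation.

An ASV's alignment hits against a reference 16S collection are reduced
to the top-identity window (scale S, drop threshold D), yielding a
multi-taxonomic assignment (MTA): the unique species-level taxonomies
of the accepted hits with equal weights.  A consensus-based taxonomy
(CBTA) collapses the MTA rank by rank with a 51% majority rule.
Abundances are then corrected for 16S rRNA gene copy number (GCN)
variation between taxa.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .reference import (
    ASVTable,
    FormatError,
    GCNTable,
    MultiTaxonomy,
    RANKS,
    Taxonomy,
)

DEFAULT_S_SCALE = 4.0
DEFAULT_DROP_THRESHOLD = 0.85
DEFAULT_CONSENSUS = 0.51


@dataclass(frozen=True)
class AlignmentHit:
    """One ASV-vs-reference alignment with identity fraction F."""

    asv_id: str
    ref_id: str
    identity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity {self.identity} outside [0, 1]")


def read_hits_table(path: str | Path) -> dict[str, list[AlignmentHit]]:
    """Read 12-column tabular alignment output (headerless TSV).

    Only query id, subject id and percent identity are consumed;
    F = percent identity / 100.
    """
    df = pd.read_csv(path, sep="\t", header=None)
    if df.shape[1] < 3:
        raise FormatError("hits table needs at least 3 columns")
    out: dict[str, list[AlignmentHit]] = {}
    for q, s, pid in zip(df[0], df[1], df[2]):
        out.setdefault(str(q), []).append(
            AlignmentHit(str(q), str(s), float(pid) / 100.0)
        )
    return out


def filter_top_hits(
    hits: Sequence[AlignmentHit],
    s_scale: float = DEFAULT_S_SCALE,
    drop_threshold: float = DEFAULT_DROP_THRESHOLD,
) -> list[AlignmentHit]:
    """Keep hits in the top identity window above the drop threshold.

    With M the best identity, hits with F >= M - (1 - M) / S and
    F > D are accepted; when M <= D the ASV is unassignable and the
    result is empty.  Order-independent and duplicate-safe.
    """
    if s_scale <= 0:
        raise ValueError("s_scale must be positive")
    if not 0.0 <= drop_threshold < 1.0:
        raise ValueError("drop_threshold must be in [0, 1)")
    if not hits:
        return []
    m = max(h.identity for h in hits)
    if m <= drop_threshold:
        return []
    lower = m - (1.0 - m) / s_scale
    return [
        h for h in hits if h.identity >= lower and h.identity > drop_threshold
    ]


def build_mta(
    accepted: Sequence[AlignmentHit],
    taxonomy_lookup: Callable[[str], Taxonomy | None] | Mapping[str, Taxonomy],
) -> MultiTaxonomy | None:
    """Equal-weight multi-taxonomy over the accepted hits' species.

    Returns ``None`` for an empty hit list (unassignable ASV).
    """
    if not accepted:
        return None
    if isinstance(taxonomy_lookup, Mapping):
        lookup = taxonomy_lookup.get
    else:
        lookup = taxonomy_lookup
    taxa = []
    for h in accepted:
        tax = lookup(h.ref_id)
        if tax is None:
            raise KeyError(f"reference id '{h.ref_id}' has no taxonomy")
        taxa.append(tax)
    return MultiTaxonomy.from_entries(taxa)


def build_cbta(
    mta: MultiTaxonomy, consensus: float = DEFAULT_CONSENSUS
) -> Taxonomy:
    """Rank-by-rank majority consensus of a multi-taxonomy.

    Walking from domain downward, a rank keeps the label whose
    MTA-weighted share reaches the consensus fraction; the first rank
    without such a label and all deeper ranks are left blank.
    """
    if not 0.5 < consensus <= 1.0:
        raise ValueError("consensus must be in (0.5, 1]")
    labels: list[str] = []
    for d in range(len(RANKS)):
        shares: dict[str, float] = {}
        display: dict[str, str] = {}
        for tax, w in zip(mta.entries, mta.weights):
            lbl = tax.labels[d]
            key = lbl.strip().casefold()
            shares[key] = shares.get(key, 0.0) + w
            display.setdefault(key, lbl)
        key, share = max(shares.items(), key=lambda kv: kv[1])
        if key == "" or share < consensus:
            break
        labels.append(display[key])
    return Taxonomy(tuple(labels) + ("",) * (len(RANKS) - len(labels)))


def assign_taxonomies(
    hits_by_asv: Mapping[str, Sequence[AlignmentHit]],
    taxonomy_lookup: Callable[[str], Taxonomy | None] | Mapping[str, Taxonomy],
    s_scale: float = DEFAULT_S_SCALE,
    drop_threshold: float = DEFAULT_DROP_THRESHOLD,
) -> dict[str, MultiTaxonomy | None]:
    """Windowed-hit MTA for every ASV (None = unassignable)."""
    return {
        asv: build_mta(
            filter_top_hits(list(hits), s_scale, drop_threshold),
            taxonomy_lookup,
        )
        for asv, hits in hits_by_asv.items()
    }


# ---------------------------------------------------------------------------
# built-in reference search
# ---------------------------------------------------------------------------


def _identity_from_cigar(cigar: str) -> float:
    """Fraction of matched columns in an extended-cigar alignment."""
    matches = 0
    columns = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            columns += n
            if ch == "=":
                matches += n
    return matches / columns if columns else 0.0


def align_identity(query: str, target: str) -> float:
    """Identity fraction of the best infix alignment of query in target.

    The shorter sequence is aligned as an infix of the longer one
    (free end gaps on the longer sequence); identity is matched
    columns over alignment columns.
    """
    if len(query) > len(target):
        query, target = target, query
    res = edlib.align(query, target, mode="HW", task="path")
    return _identity_from_cigar(res["cigar"])


def search_reference(
    asv_seqs: Mapping[str, str],
    ref_seqs: Mapping[str, str],
    min_identity: float = 0.0,
) -> dict[str, list[AlignmentHit]]:
    """All-vs-all identity search of ASVs against a reference FASTA.

    An exact (non-heuristic) search intended for fixture-scale
    references; hits below ``min_identity`` are not reported.
    """
    if not ref_seqs:
        raise ValueError("empty reference collection")
    out: dict[str, list[AlignmentHit]] = {}
    for asv, seq in asv_seqs.items():
        hits = []
        for rid, rseq in ref_seqs.items():
            f = align_identity(seq, rseq)
            if f >= min_identity:
                hits.append(AlignmentHit(asv, rid, f))
        out[asv] = hits
    return out


# ---------------------------------------------------------------------------
# gene copy number renormalisation
# ---------------------------------------------------------------------------


def mean_gcn(
    assignment: MultiTaxonomy | Taxonomy | None,
    gcn: GCNTable,
    default: float,
) -> float:
    """Mean copy number of an assignment's entries.

    Each entry contributes the copy number at its deepest rank present
    in the table (walking species to domain); entries (or whole
    assignments) with no tabulated rank use ``default``.
    """
    if assignment is None:
        return default
    entries = (
        assignment.entries
        if isinstance(assignment, MultiTaxonomy)
        else (assignment,)
    )
    vals = []
    for tax in entries:
        g = gcn.deepest_gcn(tax)
        vals.append(default if g is None else g)
    return float(np.mean(vals))


def renormalize_by_gcn(
    table: ASVTable,
    assignments: Mapping[str, MultiTaxonomy | Taxonomy | None],
    gcn: GCNTable,
) -> ASVTable:
    """Divide abundances by per-ASV mean GCN and rescale per sample.

    ASVs whose assignment has no copy number at any rank fall back to
    the table-wide mean copy number.
    """
    if len(gcn) == 0:
        raise ValueError("GCN table is empty")
    default = gcn.global_mean
    factors = pd.Series(
        {
            asv: mean_gcn(assignments.get(asv), gcn, default)
            for asv in table.asv_ids
        }
    )
    adj = table.relative.div(factors, axis=0)
    adj = adj / adj.sum(axis=0)
    return table.with_relative(adj)
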