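"""End-to-end pipeline: profiling -> renormalisation -> mapping -> indices.

`run_pipeline` executes the stages in order on file inputs and writes
TSV outputs plus a structured run log: taxonomic profiling of ASVs,
gene-copy-number renormalisation, ASV-to-genome mapping under the
configured scheme, phenotype index computation, community indices,
and (when a tree is supplied) phenotype diversity metrics.
"""

from __future__ import annotations

import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import assign, diversity, indices, mapping, reference

SCHEMES = ("cbta", "mta", "seq")


@dataclass
class RunConfig:
    """Pipeline configuration; defaults are the method's stated values."""

    scheme: str = "seq"
    s_scale: float = assign.DEFAULT_S_SCALE  # top-hit window scale S
    drop_threshold: float = assign.DEFAULT_DROP_THRESHOLD  # identity floor D
    consensus: float = assign.DEFAULT_CONSENSUS  # CBTA majority fraction
    carrier_threshold: float = diversity.DEFAULT_CARRIER_THRESHOLD  # PI cut
    seed: int = 0
    # inputs
    counts: str = ""
    fasta: str = ""
    bpm: str = ""
    bpm_taxonomy: str = ""
    ref_16s: str = ""
    hits: str = ""
    gcn: str = ""
    tree: str = ""
    groups: str = ""
    # outputs
    outdir: str = "phenoprof_out"

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if self.s_scale <= 0:
            raise ValueError("s_scale must be positive")
        if not 0 <= self.drop_threshold < 1:
            raise ValueError("drop_threshold must be in [0, 1)")
        if not 0.5 < self.consensus <= 1:
            raise ValueError("consensus must be in (0.5, 1]")
        if not 0 < self.carrier_threshold < 1:
            raise ValueError("carrier_threshold must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


class _RunLog:
    def __init__(self, path: Path) -> None:
        self.path = path
        self.lines: list[str] = []

    def stage(self, name: str, **fields) -> None:
        parts = [f"stage={name}"] + [f"{k}={v}" for k, v in fields.items()]
        line = "\t".join(parts)
        self.lines.append(line)
        print(line, file=sys.stderr)

    def flush(self) -> None:
        self.path.write_text("\n".join(self.lines) + "\n")


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages; returns the output directory.

    Raises a ``ValueError`` naming the first stage whose required
    input is missing.  Identical config and seed give byte-identical
    outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _RunLog(outdir / "run.log")
    t0 = time.time()
    before = set(outdir.iterdir())
    try:
        _run(config, outdir, log)
    except Exception:
        # remove partial outputs of this run, keeping the log
        for path in set(outdir.iterdir()) - before:
            if path != log.path:
                path.unlink()
        log.stage("failed", elapsed=f"{time.time() - t0:.2f}s")
        log.flush()
        raise
    log.stage("done", elapsed=f"{time.time() - t0:.2f}s")
    log.flush()
    return outdir


def _require(value: str, stage: str, what: str) -> str:
    if not value:
        raise ValueError(f"stage '{stage}' requires {what}")
    return value


def _run(config: RunConfig, outdir: Path, log: _RunLog) -> None:
    # inputs
    table = reference.read_asv_table(
        _require(config.counts, "input", "an ASV counts table (--counts)"),
        _require(config.fasta, "input", "ASV sequences (--fasta)"),
    )
    bpm = reference.read_bpm(
        _require(config.bpm, "input", "a binary phenotype matrix (--bpm)"),
        _require(config.bpm_taxonomy, "input", "a genome taxonomy (--bpm-taxonomy)"),
    )
    log.stage(
        "input", n_asvs=len(table.asv_ids), n_samples=len(table.samples),
        n_genomes=bpm.n_genomes, n_phenotypes=len(bpm.phenotypes),
    )

    ref_seqs = (
        reference.read_fasta(config.ref_16s) if config.ref_16s else {}
    )

    # alignment hits (needed for taxonomy schemes and for GCN mapping)
    hits = None
    if config.hits:
        hits = assign.read_hits_table(config.hits)
    need_taxonomy = config.scheme in ("cbta", "mta") or bool(config.gcn)
    if need_taxonomy and hits is None:
        if not ref_seqs:
            raise ValueError(
                "stage 'taxonomic profiling' requires alignment hits (--hits) "
                "or a reference 16S FASTA (--ref-16s)"
            )
        hits = assign.search_reference(table.sequences, ref_seqs)

    mtas = {}
    if need_taxonomy:
        mtas = assign.assign_taxonomies(
            hits, lambda rid: bpm.taxonomy.get(rid),
            config.s_scale, config.drop_threshold,
        )
        n_assigned = sum(1 for m in mtas.values() if m is not None)
        log.stage("taxonomic_profiling", n_in=len(table.asv_ids),
                  n_assigned=n_assigned,
                  dropped=len(table.asv_ids) - n_assigned)

    # GCN renormalisation
    if config.gcn:
        gcn = reference.read_gcn_table(config.gcn)
        table = assign.renormalize_by_gcn(table, mtas, gcn)
        log.stage("gcn_renormalization", n_gcn_records=len(gcn))

    # mapping
    if config.scheme == "seq":
        _require(config.ref_16s, "mapping", "a reference 16S FASTA (--ref-16s)")
        asv_map = mapping.map_by_sequence(
            table.sequences, ref_seqs, bpm,
            hits_by_asv=hits,
            s_scale=config.s_scale, drop_threshold=config.drop_threshold,
        )
    else:
        if config.scheme == "cbta":
            assignments = {
                asv: (None if m is None else assign.build_cbta(m, config.consensus))
                for asv, m in mtas.items()
            }
        else:
            assignments = mtas
        asv_map = mapping.map_by_taxonomy(assignments, bpm, scheme=config.scheme)
    asv_map.write(outdir / "map.tsv")
    coverage = mapping.mapping_coverage(asv_map, table)
    log.stage(
        "mapping", scheme=config.scheme,
        n_mapped=len(asv_map.mapped_ids),
        n_unmapped=len(table.asv_ids) - len(asv_map.mapped_ids),
        mean_coverage=f"{coverage.mean():.4f}",
    )

    # phenotype indices
    profile = indices.compute_phenotype_indices(asv_map, bpm)
    profile.write(outdir / "pi.tsv")
    community = indices.community_profile(profile, table)
    community.write(outdir / "cpi.tsv")
    log.stage("indices", n_asvs=len(profile.pi.index),
              n_phenotypes=len(profile.pi.columns))

    # diversity
    if config.tree:
        tree = diversity.midpoint_root(diversity.read_tree(config.tree))
        tree = diversity.prune_to(
            tree, set(table.asv_ids) & set(diversity.tip_names(tree))
        )
        groups = None
        if config.groups:
            gdf = pd.read_csv(config.groups, sep="\t", dtype=str)
            groups = dict(zip(gdf["sample"], gdf["group"]))
            whole = {
                s: table.relative.loc[
                    [a for a in table.asv_ids
                     if a in set(diversity.tip_names(tree))], s
                ]
                for s in table.samples
            }
            whole = {s: v / v.sum() for s, v in whole.items()}
            bd = diversity.unifrac_matrix(whole, tree)
            bd.to_csv(outdir / "bd.tsv", sep="\t")
        pad_rows = {}
        rpbd_rows = []
        for ph in profile.pi.columns:
            sub = diversity.carrier_subcommunity(
                profile, table, ph, config.carrier_threshold
            )
            pad_rows[ph] = diversity.pad(sub, tree)
            if groups and len(sub.abundances) >= 2:
                pbd, _ = diversity.pbd_matrix(sub, tree)
                pbd.to_csv(outdir / f"pbd_{ph}.tsv", sep="\t")
                pbd_means = diversity.intragroup_mean_distance(pbd, groups)
                bd_means = diversity.intragroup_mean_distance(bd, groups)
                for grp in pbd_means.index:
                    rpbd_rows.append(
                        {
                            "group": grp,
                            "phenotype": ph,
                            "intragroup_pbd": pbd_means[grp],
                            "intragroup_bd": bd_means.get(grp),
                            "rpbd": diversity.relative_pbd(
                                pbd_means[grp], bd_means.get(grp, float("nan"))
                            ),
                        }
                    )
        pd.DataFrame(pad_rows).rename_axis("sample").to_csv(
            outdir / "pad.tsv", sep="\t"
        )
        if rpbd_rows:
            pd.DataFrame(rpbd_rows).to_csv(
                outdir / "rpbd.tsv", sep="\t", index=False
            )
        log.stage("diversity", n_phenotypes=len(profile.pi.columns),
                  tree_tips=len(diversity.tip_names(tree)))
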