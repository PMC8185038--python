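"""Phenotype indices: per-ASV probabilities and community aggregates.

For each ASV and phenotype the Phenotype Index PI = sum_i W_i * P_i is
the map-weighted mean of the reference genomes' binary values, i.e.
the probability that the ASV is a carrier.  Treating the binary values
as binomial draws gives the prediction uncertainty Var(PI) =
PI * (1 - PI).  Per sample, the Community Phenotype Index CPI =
sum_i A_i * PI_i is the abundance-weighted mean PI (the fractional
representation of carriers), with Var(CPI) = sum_i A_i^2 * Var(PI_i)
under independent co-occurrence, and rSTD = sqrt(Var(CPI)) / CPI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mapping import ASVMap
from .reference import ASVTable, BinaryPhenotypeMatrix


@dataclass
class PhenotypeProfile:
    """Per-ASV phenotype indices (rows: mapped ASVs, cols: phenotypes)."""

    pi: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.pi.to_numpy()
        if ((arr < -1e-12) | (arr > 1 + 1e-12)).any():
            raise ValueError("PI values must lie in [0, 1]")

    @property
    def var(self) -> pd.DataFrame:
        return self.pi * (1.0 - self.pi)

    def write(self, path: str | Path) -> None:
        long = self.pi.stack().rename("pi").reset_index()
        long.columns = ["asv_id", "phenotype", "pi"]
        long["var"] = long["pi"] * (1.0 - long["pi"])
        long.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "PhenotypeProfile":
        df = pd.read_csv(path, sep="\t", dtype={"asv_id": str})
        return cls(df.pivot(index="asv_id", columns="phenotype", values="pi"))


@dataclass
class CommunityProfile:
    """Per-sample community phenotype indices with uncertainty.

    ``rstd`` is NaN where CPI = 0 (the ratio is undefined there);
    ``coverage`` is the mapped fraction of each sample's abundance.
    """

    cpi: pd.DataFrame
    var: pd.DataFrame
    coverage: pd.Series

    @property
    def rstd(self) -> pd.DataFrame:
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.sqrt(self.var.to_numpy()) / self.cpi.to_numpy()
        r = np.where(self.cpi.to_numpy() == 0, np.nan, r)
        return pd.DataFrame(r, index=self.cpi.index, columns=self.cpi.columns)

    def write(self, path: str | Path) -> None:
        rows = []
        rstd = self.rstd
        for sample in self.cpi.index:
            for ph in self.cpi.columns:
                rows.append(
                    {
                        "sample": sample,
                        "phenotype": ph,
                        "cpi": self.cpi.at[sample, ph],
                        "var": self.var.at[sample, ph],
                        "rstd": rstd.at[sample, ph],
                        "coverage": self.coverage[sample],
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def phenotype_index(
    weights: dict[str, float], phenotype_values: dict[str, int]
) -> tuple[float, float]:
    """PI and Var(PI) for one ASV-to-genome weight vector."""
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("mapping weights must sum to 1")
    pi = sum(w * phenotype_values[g] for g, w in weights.items())
    return pi, pi * (1.0 - pi)


def compute_phenotype_indices(
    asv_map: ASVMap, bpm: BinaryPhenotypeMatrix
) -> PhenotypeProfile:
    """Map-weighted PI for every mapped ASV and every phenotype."""
    rows = {}
    values = bpm.values
    for asv in asv_map.mapped_ids:
        w = asv_map.weights[asv]
        gids = list(w)
        wvec = np.array([w[g] for g in gids])
        rows[asv] = wvec @ values.loc[gids].to_numpy()
    pi = pd.DataFrame.from_dict(rows, orient="index", columns=bpm.phenotypes)
    return PhenotypeProfile(pi)


def community_profile(
    profile: PhenotypeProfile, table: ASVTable
) -> CommunityProfile:
    """Abundance-weighted CPI per sample with propagated variance.

    Sample abundances are renormalised over the ASVs present in the
    profile (the mapped set); the discarded fraction is reported as
    1 - coverage.  A sample with no mapped abundance gets NaN indices.
    """
    mapped = [a for a in table.asv_ids if a in profile.pi.index]
    rel = table.relative
    coverage = rel.loc[mapped].sum(axis=0) if mapped else pd.Series(
        0.0, index=rel.columns
    )
    pi = profile.pi.loc[mapped].to_numpy()
    var = (profile.pi.loc[mapped] * (1 - profile.pi.loc[mapped])).to_numpy()
    cpi_rows = {}
    var_rows = {}
    for sample in table.samples:
        cov = coverage[sample]
        if cov <= 0:
            warnings.warn(f"sample '{sample}' has no mapped abundance")
            cpi_rows[sample] = np.full(pi.shape[1], np.nan)
            var_rows[sample] = np.full(pi.shape[1], np.nan)
            continue
        a = rel.loc[mapped, sample].to_numpy() / cov
        cpi_rows[sample] = a @ pi
        var_rows[sample] = (a**2) @ var
    cols = profile.pi.columns
    return CommunityProfile(
        pd.DataFrame.from_dict(cpi_rows, orient="index", columns=cols),
        pd.DataFrame.from_dict(var_rows, orient="index", columns=cols),
        coverage,
    )


def relative_cpi_change(
    predicted: CommunityProfile, truth: CommunityProfile
) -> pd.DataFrame:
    """Signed (CPI_pred - CPI_true) / CPI_true per sample and phenotype.

    Entries with CPI_true = 0 are NaN (excluded); callers can count
    them via ``isna``.
    """
    pred = predicted.cpi
    true = truth.cpi.loc[pred.index, pred.columns]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (pred.to_numpy() - true.to_numpy()) / true.to_numpy()
    out = np.where(true.to_numpy() == 0, np.nan, out)
    return pd.DataFrame(out, index=pred.index, columns=pred.columns)


def summarize_relative_change(change: pd.DataFrame) -> pd.DataFrame:
    """Per-phenotype median, mean absolute and percentile summary."""
    return pd.DataFrame(
        {
            "median": change.median(),
            "mean_abs": change.abs().mean(),
            "p10": change.quantile(0.10),
            "p90": change.quantile(0.90),
            "n_excluded": change.isna().sum(),
        }
    )


def summarize_cpi(cpi: pd.DataFrame) -> pd.DataFrame:
    """Per-phenotype median (Q50) and 10-90 percentile range.

    Reported on the percent (x100) scale; percentiles use linear
    interpolation between order statistics.
    """
    q = cpi.quantile([0.10, 0.50, 0.90])
    return pd.DataFrame(
        {
            "q50": q.loc[0.50] * 100.0,
            "pr_10_90": (q.loc[0.90] - q.loc[0.10]) * 100.0,
        }
    )
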