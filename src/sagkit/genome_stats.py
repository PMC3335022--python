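"""CSCG-based completeness/size estimation and hydrolytic-gene statistics.

A set of conserved single-copy genes (CSCGs) is derived from a panel of
reference genomes of the clade; the fraction R_CSCG of that set detected in
a partial single-cell assembly estimates assembly completeness, and the
expected complete genome size is G_S = A_S / R_CSCG where A_S is the
assembly size.  Gene-class frequencies (glycoside hydrolases, sulfatases,
peptidases, lyases/esterases) per genome and their per-taxon enrichment
summaries quantify hydrolytic potential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CSCGModel",
    "CompletenessEstimate",
    "derive_cscg",
    "cscg_recovery",
    "estimate_genome_size",
    "gh_frequency",
    "taxon_enrichment",
    "count_size_correlation",
]


@dataclass(frozen=True)
class CSCGModel:
    """Conserved single-copy gene set derived from reference genomes."""

    reference_ids: tuple[str, ...]
    cscg_set: frozenset[str]
    mode: str  # "strict" (copy == 1 everywhere) or "relaxed" (copy >= 1)

    @property
    def n_cscg(self) -> int:
        return len(self.cscg_set)


def derive_cscg(presence: pd.DataFrame, mode: str = "strict") -> CSCGModel:
    """Derive the CSCG set from a gene-family x reference copy-count matrix.

    ``mode='strict'`` (default) keeps families with copy count exactly 1 in
    every reference; ``mode='relaxed'`` keeps families present (>= 1 copy)
    in every reference.  The mode is recorded on the model.
    """
    if presence.size == 0:
        raise ValueError("empty presence matrix")
    if mode not in ("strict", "relaxed"):
        raise ValueError("mode must be 'strict' or 'relaxed'")
    values = presence.to_numpy()
    if mode == "strict":
        keep = np.all(values == 1, axis=1)
    else:
        keep = np.all(values >= 1, axis=1)
    return CSCGModel(
        reference_ids=tuple(presence.columns),
        cscg_set=frozenset(presence.index[keep]),
        mode=mode,
    )


def cscg_recovery(sag_families: Iterable[str], model: CSCGModel) -> float:
    """Fraction (in percent) of the CSCG set detected in a SAG.

    R_CSCG = |detected ∩ cscg_set| / n_cscg * 100.  Full precision is
    returned; reports round to one decimal.
    """
    if model.n_cscg == 0:
        raise ValueError("empty CSCG set; recovery is undefined")
    found = len(set(sag_families) & model.cscg_set)
    return 100.0 * found / model.n_cscg


@dataclass(frozen=True)
class CompletenessEstimate:
    """Genome-size estimate G_S = A_S / R_CSCG with a propagated interval."""

    sag_id: str
    assembly_size_bp: float
    n_found: int
    n_cscg: int
    r_cscg: float  # fraction in (0, 1]
    genome_size_bp: float
    ci_low_bp: float
    ci_high_bp: float

    @property
    def genome_size_mb(self) -> float:
        """Size in Mb rounded to one decimal, mirroring field reporting."""
        return round(self.genome_size_bp / 1e6, 1)


def estimate_genome_size(
    assembly_size_bp: float,
    n_found: int,
    n_cscg: int,
    sag_id: str = "",
    conf_level: float = 0.95,
) -> CompletenessEstimate:
    """Expected complete genome size from CSCG recovery.

    G_S = A_S / R_CSCG with R_CSCG = n_found / n_cscg.  The Clopper-Pearson
    binomial interval on R_CSCG (n = n_cscg trials) is propagated to G_S:
    a higher recovery bound gives the lower size bound and vice versa; when
    recovery may be complete the upper size bound is A_S-consistent, and a
    zero lower recovery bound yields an unbounded upper size.
    """
    if assembly_size_bp <= 0:
        raise ValueError("assembly size must be > 0")
    if n_cscg <= 0:
        raise ValueError("n_cscg must be > 0")
    if n_found <= 0:
        raise ValueError("genome size is undefined when no CSCG is detected")
    if n_found > n_cscg:
        raise ValueError("n_found cannot exceed n_cscg")
    r = n_found / n_cscg
    alpha = 1.0 - conf_level
    r_lo = (
        stats.beta.ppf(alpha / 2, n_found, n_cscg - n_found + 1)
        if n_found > 0
        else 0.0
    )
    r_hi = (
        stats.beta.ppf(1 - alpha / 2, n_found + 1, n_cscg - n_found)
        if n_found < n_cscg
        else 1.0
    )
    return CompletenessEstimate(
        sag_id=sag_id,
        assembly_size_bp=float(assembly_size_bp),
        n_found=int(n_found),
        n_cscg=int(n_cscg),
        r_cscg=float(r),
        genome_size_bp=float(assembly_size_bp / r),
        ci_low_bp=float(assembly_size_bp / r_hi),
        ci_high_bp=float(assembly_size_bp / r_lo) if r_lo > 0 else math.inf,
    )


_REQUIRED_ANNOT_COLUMNS = ("genome_id", "gene_id", "class", "copies")


def _check_annotations(annot: pd.DataFrame) -> None:
    for col in _REQUIRED_ANNOT_COLUMNS:
        if col not in annot.columns:
            raise KeyError(f"annotation table is missing required column {col!r}")


def gh_frequency(
    annot: pd.DataFrame, genome_id: str, gene_class: str = "GH"
) -> float:
    """Fraction of a genome's genes annotated with one functional class.

    Total gene count and class count are copy-weighted sums; with the
    default single-copy annotation this is genes-of-class / genes-total.
    """
    _check_annotations(annot)
    rows = annot[annot["genome_id"] == genome_id]
    if len(rows) == 0:
        raise KeyError(f"unknown genome id {genome_id!r}")
    total = rows["copies"].sum()
    if total == 0:
        raise ValueError(f"genome {genome_id!r} has zero annotated genes")
    n_class = rows.loc[rows["class"] == gene_class, "copies"].sum()
    return float(n_class / total)


def taxon_enrichment(
    annot: pd.DataFrame,
    taxon_of: Mapping[str, str],
    gene_class: str = "GH",
) -> pd.DataFrame:
    """Per-taxon mean +/- SD of per-genome gene-class frequencies.

    SD is the sample standard deviation (n-1), reported as NaN for
    single-genome taxa.  A final ``__all__`` row carries the domain-wide
    average over all genomes.  Raises when a listed taxon has no genomes.
    """
    _check_annotations(annot)
    freqs = {
        gid: gh_frequency(annot, gid, gene_class)
        for gid in annot["genome_id"].unique()
    }
    per_genome = pd.DataFrame(
        {
            "genome_id": list(freqs),
            "taxon": [taxon_of[g] for g in freqs],
            "frequency": list(freqs.values()),
        }
    )
    missing = set(taxon_of.values()) - set(per_genome["taxon"])
    if missing:
        raise ValueError(f"taxa with zero genomes: {sorted(missing)}")
    rows = []
    for taxon, grp in per_genome.groupby("taxon", sort=True):
        vals = grp["frequency"].to_numpy()
        rows.append(
            {
                "taxon": taxon,
                "n_genomes": len(vals),
                "mean_frequency": float(vals.mean()),
                "sd_frequency": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
            }
        )
    all_vals = per_genome["frequency"].to_numpy()
    rows.append(
        {
            "taxon": "__all__",
            "n_genomes": len(all_vals),
            "mean_frequency": float(all_vals.mean()),
            "sd_frequency": float(all_vals.std(ddof=1))
            if len(all_vals) > 1
            else float("nan"),
        }
    )
    return pd.DataFrame(rows)


def count_size_correlation(counts: np.ndarray, sizes: np.ndarray) -> float:
    """Squared Pearson correlation (OLS R^2) of gene counts vs assembly sizes."""
    c = np.asarray(counts, dtype=float)
    s = np.asarray(sizes, dtype=float)
    if c.size != s.size or c.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(c) == 0 or np.ptp(s) == 0:
        raise ValueError("zero variance in counts or sizes")
    r = np.corrcoef(c, s)[0, 1]
    return float(r**2)
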