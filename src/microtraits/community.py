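"""Community-level genomic traits from OTU tables and read summaries.

Implements the abundance-weighted rRNA operon copy number (a copiotroph /
oligotroph life-history index: copiotrophs carry more rRNA operons), the
mean genome size estimated from single-copy-gene coverage, GC content
statistics of quality-filtered reads, and standard alpha-diversity indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio.diversity import alpha as skbio_alpha

logger = logging.getLogger(__name__)

__all__ = [
    "OtuTable",
    "ScgHits",
    "assign_copy_numbers",
    "weighted_copy_number",
    "mean_genome_size",
    "gc_stats",
    "alpha_diversity",
    "community_trait_table",
]

RANK_PREFIXES = ("d__", "k__", "p__", "c__", "o__", "f__", "g__", "s__")


class NoAssignmentError(ValueError):
    """Raised when no OTU matches any entry of the copy-number reference."""


@dataclass
class OtuTable:
    """OTU counts (rows = OTU ids, columns = sample ids) plus taxonomy strings."""

    counts: pd.DataFrame
    taxonomy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("OTU counts must be nonnegative")
        missing = [o for o in self.counts.index if o not in self.taxonomy]
        if self.taxonomy and missing:
            raise ValueError(f"taxonomy missing for OTUs: {missing[:5]}")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=0)
        return self.counts.div(totals.replace(0, np.nan), axis=1)


@dataclass
class ScgHits:
    """Single-copy-gene alignment summary for one sample.

    ``hits`` columns: gene, length_bp, aligned_bp.  Genome equivalents are
    the average per-gene coverage; the mean genome size is the sample's total
    sequenced base pairs divided by genome equivalents.
    """

    hits: pd.DataFrame
    total_bp: float

    def __post_init__(self) -> None:
        if (self.hits["length_bp"] <= 0).any():
            raise ValueError("gene lengths must be positive")
        if (self.hits["aligned_bp"] < 0).any():
            raise ValueError("aligned bp must be nonnegative")


def _split_ranks(taxonomy: str) -> list[str]:
    ranks = []
    for part in taxonomy.split(";"):
        name = part.strip()
        for pref in RANK_PREFIXES:
            if name.startswith(pref):
                name = name[len(pref):]
                break
        if name:
            ranks.append(name)
    return ranks


def assign_copy_numbers(
    taxonomy: dict[str, str], ref: dict[str, float]
) -> dict[str, float]:
    """Assign each OTU the rRNA operon copy number of its deepest named rank.

    Ranks are searched species -> domain; the first (deepest) name present in
    the reference wins.  OTUs with no match at any rank are excluded (the
    caller renormalizes over assigned OTUs); the number excluded is logged.
    """
    if not ref:
        raise ValueError("copy-number reference is empty")
    assigned: dict[str, float] = {}
    unmatched = 0
    for otu, tax in taxonomy.items():
        for name in reversed(_split_ranks(tax)):
            if name in ref:
                assigned[otu] = float(ref[name])
                break
        else:
            unmatched += 1
    if not assigned:
        raise NoAssignmentError("no OTU matched any reference taxon")
    if unmatched:
        logger.info("copy-number assignment: %d OTUs unmatched and excluded", unmatched)
    return assigned


def weighted_copy_number(table: OtuTable, copies: dict[str, float]) -> pd.Series:
    """Abundance-weighted mean rRNA operon copy number per sample.

    Sum over OTUs of (relative abundance x assigned copy number), with
    relative abundances renormalized over the OTUs that have an assignment.
    Samples whose assigned OTUs have zero total count come back NaN.
    """
    otus = [o for o in table.otu_ids if o in copies]
    if not otus:
        raise NoAssignmentError("no OTU in the table has an assigned copy number")
    sub = table.counts.loc[otus]
    totals = sub.sum(axis=0)
    copy_vec = pd.Series({o: copies[o] for o in otus})
    weighted = sub.mul(copy_vec, axis=0).sum(axis=0) / totals.replace(0, np.nan)
    weighted.name = "weighted_rrn_copies"
    return weighted


def mean_genome_size(scg: ScgHits) -> float:
    """Mean genome size (bp) = total base pairs / genome equivalents."""
    coverage = scg.hits["aligned_bp"] / scg.hits["length_bp"]
    genome_equivalents = float(coverage.mean())
    if genome_equivalents <= 0:
        raise ValueError("zero genome equivalents: no single-copy-gene coverage")
    return float(scg.total_bp) / genome_equivalents


def gc_stats(gc_fractions: np.ndarray | pd.Series | list[float]) -> tuple[float, float]:
    """Arithmetic mean and unbiased sample variance of per-read GC fractions."""
    values = np.asarray(gc_fractions, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two GC values for a variance")
    return float(values.mean()), float(values.var(ddof=1))


def alpha_diversity(table: OtuTable) -> pd.DataFrame:
    """Shannon–Wiener (natural log), Gini–Simpson, and bias-corrected Chao1.

    Chao1 = S_obs + F1(F1-1)/(2(F2+1)) with F1, F2 the singleton and
    doubleton counts, defined even when no doubletons are observed.
    """
    rows = []
    for sample in table.sample_ids:
        counts = table.counts[sample].to_numpy().astype(int)
        if counts.sum() == 0:
            raise ValueError(f"sample {sample!r} has zero total count")
        rows.append(
            {
                "sample": sample,
                "shannon": float(skbio_alpha.shannon(counts, base=np.e)),
                "simpson": float(skbio_alpha.simpson(counts)),
                "chao1": float(skbio_alpha.chao1(counts, bias_corrected=True)),
            }
        )
    return pd.DataFrame(rows).set_index("sample")


def community_trait_table(
    table: OtuTable,
    ref: dict[str, float],
    scg_by_sample: dict[str, ScgHits] | None = None,
    gc_by_sample: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """One row of community life-history traits per sample."""
    copies = assign_copy_numbers(table.taxonomy, ref)
    out = alpha_diversity(table)
    out["weighted_rrn_copies"] = weighted_copy_number(table, copies)
    if scg_by_sample is not None:
        out["mean_genome_size"] = pd.Series(
            {s: mean_genome_size(h) for s, h in scg_by_sample.items()}
        )
    if gc_by_sample is not None:
        gc = {s: gc_stats(v) for s, v in gc_by_sample.items()}
        out["gc_mean"] = pd.Series({s: v[0] for s, v in gc.items()})
        out["gc_variance"] = pd.Series({s: v[1] for s, v in gc.items()})
    return out
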