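"""Habitat-preference scoring of taxa across body sites.

A deterministic screen, not a statistical test.  Given a taxon-by-site
clone count table: (1) each site column is normalised to a common total
(default 20,000 clones) so sites with unequal sampling depth are
comparable; (2) each taxon's normalised counts are expressed as percent
of that taxon's own total across sites; (3) the focal-site percent is
divided by the percent expected under an even spread across all sites
(100 / n_sites) to give an enrichment ratio; (4) taxa are ranked by
focal-site abundance; and (5) a taxon is called focal-site-preferred
only if it is within the top ``top_k`` (default 20) of that ranking and
its ratio is >= ``min_ratio`` (default 2).  The rank gate makes the call
a conservative lower bound: rare taxa are never called on ratio alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

__all__ = [
    "HabitatConfig",
    "HabitatScore",
    "HabitatCall",
    "read_count_table",
    "normalize_sites",
    "score_taxa",
    "call_preferred",
]


@dataclass(frozen=True)
class HabitatConfig:
    focal_site: str
    normalization_total: float = 20000.0
    top_k: int = 20
    min_ratio: float = 2.0
    n_sites: Optional[int] = None  # default: number of table columns

    def __post_init__(self):
        if self.normalization_total <= 0 or self.top_k <= 0 or self.min_ratio <= 0:
            raise ValueError("all HabitatConfig parameters must be positive")


@dataclass
class HabitatScore:
    taxon: str
    site_percents: pd.Series  # percent of the taxon's normalised total per site
    focal_ratio: float
    focal_rank: int  # 1-based rank by focal-site normalised abundance


@dataclass
class HabitatCall:
    taxon: str
    call: str  # focal_site_preferred | no_call
    focal_ratio: float
    focal_rank: int


def read_count_table(path) -> pd.DataFrame:
    """Read a taxon (rows) x site (columns) count table from TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_table(df)
    return df


def _check_table(table: pd.DataFrame):
    if table.shape[1] < 2:
        raise ValueError("count table needs at least 2 site columns")
    if (table.to_numpy() < 0).any():
        raise ValueError("count table contains negative entries")


def normalize_sites(table: pd.DataFrame, total: float = 20000.0) -> pd.DataFrame:
    """Rescale every site column to sum to ``total`` (real-valued)."""
    _check_table(table)
    sums = table.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"site column(s) sum to zero: {', '.join(map(str, zero.index))}")
    return table * (total / sums)


def score_taxa(table: pd.DataFrame, cfg: HabitatConfig) -> list:
    """Per-taxon site percents, focal enrichment ratio and focal rank.

    ``table`` is the raw count table; normalisation is applied here so
    scores are invariant to rescaling any column.  Taxa with a zero
    total across all sites are excluded (reported via the returned
    scores simply not containing them).  Ranking is by descending
    focal-site normalised count with lexicographic taxon-id tie-break.
    """
    if cfg.focal_site not in table.columns:
        raise KeyError(f"focal site {cfg.focal_site!r} not in table")
    norm = normalize_sites(table, cfg.normalization_total)
    n_sites = cfg.n_sites if cfg.n_sites is not None else norm.shape[1]
    totals = norm.sum(axis=1)
    kept = norm.loc[totals > 0]
    totals = totals[totals > 0]
    percents = kept.div(totals, axis=0) * 100.0
    expected = 100.0 / n_sites
    focal = kept[cfg.focal_site]
    order = sorted(kept.index, key=lambda t: (-focal[t], str(t)))
    ranks = {t: i + 1 for i, t in enumerate(order)}
    scores = []
    for taxon in kept.index:
        scores.append(
            HabitatScore(
                taxon=taxon,
                site_percents=percents.loc[taxon],
                focal_ratio=float(percents.loc[taxon, cfg.focal_site] / expected),
                focal_rank=ranks[taxon],
            )
        )
    return scores


def call_preferred(scores: list, cfg: HabitatConfig) -> list:
    """Apply the top-k + min-ratio rule; everything else is no_call."""
    calls = []
    for s in scores:
        preferred = s.focal_rank <= cfg.top_k and s.focal_ratio >= cfg.min_ratio
        calls.append(
            HabitatCall(
                taxon=s.taxon,
                call="focal_site_preferred" if preferred else "no_call",
                focal_ratio=s.focal_ratio,
                focal_rank=s.focal_rank,
            )
        )
    return calls
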