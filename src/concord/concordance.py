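"""Direction-concordance analysis across screens.

The central object is the reference-symbol x screen matrix of signed
log2 fold changes from the filtered, reference-mapped screens.  A gene's
tier is the number of screens in which it is significantly changed with
a common direction; genes whose significant fold changes disagree in
sign are discordant (tier 0).  Screens in which a gene was not measured
or not significant are ignored, not treated as disagreement, because
platform coverage differs across species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats

from concord.io import ScreenResult


@dataclass
class ConcordanceMatrix:
    """Symbols x screens fold-change matrix with per-symbol calls.

    ``log2fc`` uses NaN for a gene absent from (not significant in) a
    screen.  ``direction`` is up/down/discordant; ``tier`` equals the
    number of screens the gene is present in, or 0 when discordant.
    """

    log2fc: pd.DataFrame
    n_present: pd.Series
    direction: pd.Series
    tier: pd.Series

    @property
    def ref_symbols(self) -> list[str]:
        return list(self.log2fc.index)

    @property
    def screens(self) -> list[str]:
        return list(self.log2fc.columns)

    def summary(self) -> pd.DataFrame:
        out = self.log2fc.copy()
        out["n_screens"] = self.n_present
        out["direction"] = self.direction
        out["tier"] = self.tier
        return out


@dataclass
class TierCounts:
    """Concordant-gene counts per tier, exact and cumulative.

    Both are reported because "altered in k screens" can be read as an
    exclusive tier (disjoint lists) or cumulatively; the exclusive
    counts are the headline.  Discordant genes are excluded from every
    tier and tallied separately.
    """

    n_screens: int
    exact: pd.DataFrame       # index k, columns total/up/down
    at_least: pd.DataFrame    # index k, columns total/up/down
    n_discordant: int

    def exact_k(self, k: int) -> int:
        return int(self.exact.loc[k, "total"])

    def at_least_k(self, k: int) -> int:
        return int(self.at_least.loc[k, "total"])


@dataclass(frozen=True)
class QuadrantCounts:
    """Sign-quadrant tally for a pair of screens (zeros kept separate)."""

    up_up: int
    up_down: int
    down_up: int
    down_down: int
    n_zero: int

    @property
    def same_direction(self) -> int:
        return self.up_up + self.down_down

    @property
    def total_nonzero(self) -> int:
        return self.up_up + self.up_down + self.down_up + self.down_down


def build_matrix(screens: Sequence[ScreenResult]) -> ConcordanceMatrix:
    """Assemble filtered, reference-mapped screens into one matrix.

    Takes the union of symbols over screens; each cell is the screen's
    log2 fold change or NaN where the gene did not pass that screen's
    filter.  Duplicate screen ids, or duplicate symbols within one
    screen (which the homology step should have resolved), are errors.
    """
    if len(screens) < 2:
        raise ValueError("concordance needs at least 2 screens")
    ids = [s.screen_id for s in screens]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate screen ids: {ids}")

    columns = {}
    for screen in screens:
        if screen.records["gene"].duplicated().any():
            dup = screen.duplicated_symbols
            raise ValueError(
                f"{screen.screen_id}: duplicate symbols not resolved: {dup[:5]}"
            )
        columns[screen.screen_id] = screen.records.set_index("gene")["log2fc"]

    log2fc = pd.DataFrame(columns)
    log2fc.index.name = "ref_symbol"
    values = log2fc.to_numpy(float)
    n_present = pd.Series((~np.isnan(values)).sum(axis=1), index=log2fc.index)

    n_pos = pd.Series(np.nansum(values > 0, axis=1), index=log2fc.index)
    n_neg = pd.Series(np.nansum(values < 0, axis=1), index=log2fc.index)
    direction = pd.Series("discordant", index=log2fc.index)
    direction[(n_pos == n_present) & (n_present > 0)] = "up"
    direction[(n_neg == n_present) & (n_present > 0)] = "down"
    tier = n_present.where(direction != "discordant", 0).astype(int)

    return ConcordanceMatrix(
        log2fc=log2fc,
        n_present=n_present.astype(int),
        direction=direction,
        tier=tier,
    )


def tier_counts(matrix: ConcordanceMatrix) -> TierCounts:
    """Exact-k and at-least-k concordant-gene counts, split by direction."""
    n_screens = len(matrix.screens)
    ks = range(1, n_screens + 1)
    exact = pd.DataFrame(0, index=list(ks), columns=["total", "up", "down"])
    for k in ks:
        in_tier = matrix.tier == k
        exact.loc[k, "total"] = int(in_tier.sum())
        exact.loc[k, "up"] = int((in_tier & (matrix.direction == "up")).sum())
        exact.loc[k, "down"] = int((in_tier & (matrix.direction == "down")).sum())
    at_least = exact[::-1].cumsum()[::-1]
    n_discordant = int((matrix.direction == "discordant").sum())
    return TierCounts(
        n_screens=n_screens, exact=exact, at_least=at_least, n_discordant=n_discordant
    )


def quadrant_counts(
    screen_a: str, screen_b: str, matrix: ConcordanceMatrix
) -> QuadrantCounts:
    """Fold-change sign quadrants over symbols shared by two screens.

    Mirrors a pairwise scatter plot of the two screens: counts of
    shared symbols in the (+,+), (+,-), (-,+) and (-,-) quadrants.
    Symbols with a zero fold change in either screen sit on an axis and
    are excluded from the quadrants but counted.
    """
    for sid in (screen_a, screen_b):
        if sid not in matrix.screens:
            raise KeyError(f"screen {sid!r} not in matrix (has {matrix.screens})")
    pair = matrix.log2fc[[screen_a, screen_b]].dropna()
    a, b = pair[screen_a], pair[screen_b]
    on_axis = (a == 0) | (b == 0)
    a, b = a[~on_axis], b[~on_axis]
    return QuadrantCounts(
        up_up=int(((a > 0) & (b > 0)).sum()),
        up_down=int(((a > 0) & (b < 0)).sum()),
        down_up=int(((a < 0) & (b > 0)).sum()),
        down_down=int(((a < 0) & (b < 0)).sum()),
        n_zero=int(on_axis.sum()),
    )


def overlap_pvalue(n_a: int, n_b: int, n_overlap: int, universe: int) -> float:
    """Hypergeometric upper-tail P(X >= n_overlap) for two gene lists.

    The chance that two random subsets of sizes ``n_a`` and ``n_b``
    drawn from ``universe`` genes share at least ``n_overlap`` members.
    A sensible universe is the set of reference symbols measured in both
    screens — unmeasured genes cannot overlap.
    """
    if not (0 <= n_overlap <= min(n_a, n_b) <= max(n_a, n_b) <= universe):
        raise ValueError(
            f"inconsistent counts: overlap={n_overlap}, a={n_a}, b={n_b}, "
            f"universe={universe}"
        )
    return float(stats.hypergeom.sf(n_overlap - 1, universe, n_a, n_b))


def select_candidates(
    matrix: ConcordanceMatrix,
    cluster_annotations: Mapping[str, Set[str]] | None = None,
    clusters_wanted: Set[str] | None = None,
    min_tier: int = 3,
) -> pd.DataFrame:
    """Candidate modifiers for functional validation.

    The union of (a) genes concordant in at least ``min_tier`` screens
    and (b) genes concordant in at least 2 screens that belong to one of
    the wanted functional clusters.  Each candidate carries its
    qualifying rule and its screening arm: genes up-regulated in
    vulnerable neurons go to the knockdown arm, down-regulated genes to
    the overexpression arm.
    """
    if min_tier < 2:
        raise ValueError("min_tier must be >= 2")
    cluster_annotations = cluster_annotations or {}
    clusters_wanted = set(clusters_wanted or set())

    rows = []
    for symbol in matrix.ref_symbols:
        tier = int(matrix.tier[symbol])
        by_tier = tier >= min_tier
        by_cluster = (
            tier >= 2
            and bool(set(cluster_annotations.get(symbol, set())) & clusters_wanted)
        )
        if not (by_tier or by_cluster):
            continue
        direction = matrix.direction[symbol]
        rows.append(
            {
                "symbol": symbol,
                "tier": tier,
                "direction": direction,
                "rule": "both" if (by_tier and by_cluster)
                        else ("tier" if by_tier else "cluster"),
                "arm": "knockdown" if direction == "up" else "overexpression",
            }
        )
    return pd.DataFrame(rows, columns=["symbol", "tier", "direction", "rule", "arm"])
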