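"""Cross-species gene-identifier harmonisation.

Screens are performed in mouse, rat and human; before concordance can be
assessed every screen is re-keyed to the reference (mouse) official gene
symbol through a homology-group table.  The module also implements the
best-match filtering policy applied to weighted ortholog-prediction
scores when translating mouse candidates to fly lines: drop scores of 2
or below, then keep every candidate tied at the maximum score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from concord.io import KNOWN_SPECIES, ScreenResult, _sep_for

REFERENCE_SPECIES = "mouse"

#: minimum weighted ortholog-prediction score (strictly greater than)
DIOPT_MIN_SCORE = 2


def canonical_symbol(symbol: str, species: str) -> str:
    """Normalise a symbol to its species' convention.

    Mouse and rat official symbols are title-case (Snca); human symbols
    are upper-case (SNCA).  Matching in :class:`HomologyMap` is
    case-insensitive, so canonicalisation only matters for output.
    """
    symbol = symbol.strip()
    if species == "human":
        return symbol.upper()
    return symbol[:1].upper() + symbol[1:].lower()


@dataclass
class HomologyMap:
    """Homology groups linking symbols across species.

    ``groups`` has columns group_id, species, symbol.  Within a group
    there is normally at most one symbol per species; additional symbols
    mark a one-to-many relationship and are handled explicitly by
    :func:`map_to_reference`.
    """

    groups: pd.DataFrame
    reference_species: str = REFERENCE_SPECIES

    def __post_init__(self) -> None:
        missing = [c for c in ("group_id", "species", "symbol") if c not in self.groups.columns]
        if missing:
            raise ValueError(f"homology table missing columns: {missing}")
        bad = set(self.groups["species"]) - set(KNOWN_SPECIES)
        if bad:
            raise ValueError(f"unknown species in homology table: {sorted(bad)}")
        g = self.groups.copy()
        g["_key"] = g["symbol"].str.strip().str.casefold()
        self._by_symbol = g.groupby(["species", "_key"])["group_id"].agg(list)
        self._members = g.groupby("group_id")

    def species_known(self, species: str) -> bool:
        return species in set(self.groups["species"])

    def reference_symbols(self, species: str, symbol: str) -> list[str]:
        """Mouse symbols homologous to ``symbol`` in ``species`` (may be
        empty, or >1 for a one-to-many relationship)."""
        key = (species, symbol.strip().casefold())
        if key not in self._by_symbol.index:
            return []
        refs: list[str] = []
        for gid in self._by_symbol.loc[key]:
            members = self._members.get_group(gid)
            refs.extend(
                members.loc[members["species"] == self.reference_species, "symbol"]
            )
        return sorted(set(refs))


@dataclass
class MappedScreen:
    """A screen re-keyed to the reference namespace, with an audit trail.

    Record-level conservation: every input record is exactly one of
    emitted, unmapped, collapsed (lost to the duplicate-resolution
    policy) or conflicted, except that one-to-many homology duplicates a
    record to several reference symbols (counted in ``n_expanded``).
    """

    screen: ScreenResult
    n_input: int
    n_unmapped: int
    n_collapsed: int
    n_conflicted: int
    n_expanded: int
    conflicted_symbols: list[str] = field(default_factory=list)
    one_to_many_symbols: list[str] = field(default_factory=list)

    @property
    def n_emitted(self) -> int:
        return len(self.screen.records)

    def check_conservation(self) -> None:
        total = self.n_emitted + self.n_unmapped + self.n_collapsed + self.n_conflicted
        if total - self.n_expanded != self.n_input:
            raise AssertionError(
                f"record conservation violated: {total} - {self.n_expanded} "
                f"!= {self.n_input}"
            )


def map_to_reference(
    screen: ScreenResult,
    homology: HomologyMap,
    *,
    sig_q: float = 0.05,
) -> MappedScreen:
    """Re-key a screen's records to reference (mouse) symbols.

    Unmapped records are dropped and counted.  When several source
    records land on one reference symbol the record with the largest
    |log2fc| among significant ones (q < ``sig_q``; all records if none
    is significant) is kept; if the considered records disagree in sign
    the symbol is marked direction-conflicted and excluded, because a
    direction fabricated by averaging would corrupt concordance calls.
    """
    if not homology.species_known(screen.species):
        raise ValueError(f"species {screen.species!r} not present in homology map")

    rows = []
    n_unmapped = 0
    n_expanded = 0
    one_to_many: set[str] = set()
    for rec in screen.records.itertuples(index=False):
        refs = homology.reference_symbols(screen.species, rec.gene)
        if not refs:
            n_unmapped += 1
            continue
        if len(refs) > 1:
            n_expanded += len(refs) - 1
            one_to_many.add(rec.gene)
        for ref in refs:
            rows.append(
                {
                    "gene": canonical_symbol(ref, homology.reference_species),
                    "log2fc": rec.log2fc,
                    "p": rec.p,
                    "q": rec.q,
                    "source_symbol": rec.gene,
                }
            )

    mapped = pd.DataFrame(
        rows, columns=["gene", "log2fc", "p", "q", "source_symbol"]
    )

    kept_rows = []
    n_collapsed = 0
    n_conflicted = 0
    conflicted: list[str] = []
    for ref, group in mapped.groupby("gene", sort=False):
        sig = group[group["q"] < sig_q]
        considered = sig if len(sig) else group
        signs = set(considered["log2fc"].pipe(lambda s: s[s != 0]).apply(lambda v: v > 0))
        if len(signs) > 1:
            n_conflicted += len(group)
            conflicted.append(ref)
            continue
        best = considered.loc[considered["log2fc"].abs().idxmax()]
        n_collapsed += len(group) - 1
        kept_rows.append(best)

    records = (
        pd.DataFrame(kept_rows)[["gene", "log2fc", "p", "q"]].reset_index(drop=True)
        if kept_rows
        else pd.DataFrame(columns=["gene", "log2fc", "p", "q"])
    )
    result = MappedScreen(
        screen=ScreenResult(screen.screen_id, homology.reference_species, records),
        n_input=len(screen.records),
        n_unmapped=n_unmapped,
        n_collapsed=n_collapsed,
        n_conflicted=n_conflicted,
        n_expanded=n_expanded,
        conflicted_symbols=sorted(conflicted),
        one_to_many_symbols=sorted(one_to_many),
    )
    result.check_conservation()
    return result


@dataclass(frozen=True)
class OrthologCandidate:
    """One predicted fly ortholog of a mouse gene with its weighted score."""

    source_symbol: str
    target_symbol: str
    score: int

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("ortholog prediction score must be non-negative")


def diopt_filter(
    candidates: Sequence[OrthologCandidate],
) -> list[OrthologCandidate]:
    """Best-match filter over one source gene's ortholog candidates.

    Drops candidates scoring 2 or below (the threshold is strict), then
    keeps every candidate tied at the maximum surviving score — when
    several homologs have an equivalent weighted score, all are
    included.
    """
    sources = {c.source_symbol for c in candidates}
    if len(sources) > 1:
        raise ValueError(f"candidates span several source symbols: {sorted(sources)}")
    survivors = [c for c in candidates if c.score > DIOPT_MIN_SCORE]
    if not survivors:
        return []
    best = max(c.score for c in survivors)
    return [c for c in survivors if c.score == best]


def diopt_filter_all(
    candidates: Iterable[OrthologCandidate],
) -> dict[str, list[OrthologCandidate]]:
    """Apply :func:`diopt_filter` per source symbol; empty results kept."""
    by_source: dict[str, list[OrthologCandidate]] = {}
    for cand in candidates:
        by_source.setdefault(cand.source_symbol, []).append(cand)
    return {src: diopt_filter(cands) for src, cands in by_source.items()}


def read_homology_table(path: str | Path) -> HomologyMap:
    """TSV/CSV with columns group_id, species, symbol."""
    path = Path(path)
    return HomologyMap(groups=pd.read_csv(path, sep=_sep_for(path), dtype=str))


def read_ortholog_candidates(path: str | Path) -> list[OrthologCandidate]:
    """TSV/CSV with columns source_symbol, target_symbol, score."""
    path = Path(path)
    table = pd.read_csv(path, sep=_sep_for(path))
    return [
        OrthologCandidate(str(r.source_symbol), str(r.target_symbol), int(r.score))
        for r in table.itertuples(index=False)
    ]
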