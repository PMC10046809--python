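"""Partition of the gene universe into housekeeping (HG) and integrative (IntG) groups.

The housekeeping group is read from an external list (HRT-Atlas-style file);
every other gene in the expression matrix falls into the integrative group.
Names flagged by the duplicate rule — present in both candidate groups under
the active normalization — are removed from both sides. Named gene blocks
(DNA repair, developmental blocks) are resolved against the catalog.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

HG = "HG"
INTG = "IntG"

_HEADER_TOKENS = {"gene", "genes", "symbol", "gene_symbol", "gene symbol", "name"}

__all__ = [
    "HG",
    "INTG",
    "GeneCatalog",
    "GeneBlock",
    "load_gene_list",
    "partition",
    "flag_duplicates",
    "expand_prefix_variants",
    "load_block",
    "make_block",
]


@dataclass(frozen=True)
class GeneCatalog:
    """Total partition of the gene universe.

    ``entries`` maps each retained gene name to its group label; ``removed``
    holds names dropped by the duplicate rule; ``unmatched_hk`` records
    housekeeping-list names absent from the universe (reconciliation, not an
    error).
    """

    entries: dict[str, str]
    removed: frozenset[str] = frozenset()
    unmatched_hk: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        bad = set(self.entries) & set(self.removed)
        if bad:
            raise ValueError(f"genes both retained and removed: {sorted(bad)[:5]}")

    @property
    def hg_genes(self) -> tuple[str, ...]:
        return tuple(g for g, grp in self.entries.items() if grp == HG)

    @property
    def intg_genes(self) -> tuple[str, ...]:
        return tuple(g for g, grp in self.entries.items() if grp == INTG)

    @property
    def n_hg(self) -> int:
        return sum(1 for grp in self.entries.values() if grp == HG)

    @property
    def n_intg(self) -> int:
        return sum(1 for grp in self.entries.values() if grp == INTG)

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    @property
    def total(self) -> int:
        return len(self.entries) + len(self.removed)

    def group(self, label: str) -> tuple[str, ...]:
        if label == HG:
            return self.hg_genes
        if label == INTG:
            return self.intg_genes
        raise KeyError(f"unknown group label: {label!r}")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"gene": list(self.entries), "group": list(self.entries.values())}
        )

    def export(self, path: str | Path, report_path: str | Path | None = None) -> None:
        """Write the gene→group table as TSV, optionally a JSON reconciliation report."""
        self.to_frame().to_csv(path, sep="\t", index=False)
        if report_path is not None:
            report = {
                "total": self.total,
                "n_hg": self.n_hg,
                "n_intg": self.n_intg,
                "n_removed": self.n_removed,
                "removed": sorted(self.removed),
                "unmatched_hk": list(self.unmatched_hk),
            }
            Path(report_path).write_text(json.dumps(report, indent=2))


@dataclass(frozen=True)
class GeneBlock:
    """A named, ordered set of genes (e.g. the DNA-repair block)."""

    name: str
    genes: tuple[str, ...]
    unresolved: tuple[str, ...] = ()

    @property
    def size(self) -> int:
        return len(self.genes)


def _dedupe(names: Iterable[str], source: str) -> list[str]:
    seen: dict[str, None] = {}
    dups = []
    for n in names:
        if n in seen:
            dups.append(n)
        else:
            seen[n] = None
    if dups:
        warnings.warn(
            f"{source}: {len(dups)} duplicate gene name(s) "
            f"(e.g. {dups[:3]}); first occurrence kept",
            stacklevel=3,
        )
    return list(seen)


def load_gene_list(path: str | Path, *, case_insensitive: bool = False) -> list[str]:
    """Read gene symbols from a list file.

    Accepts a headered TSV/CSV whose first column is the gene symbol
    (optional second column = functional category), or a plain
    one-symbol-per-line file. Names are whitespace-trimmed; matching is
    case-sensitive unless ``case_insensitive`` (mouse symbols are
    case-meaningful, but list sources vary — then names are casefolded).
    Duplicates emit a warning and keep the first occurrence.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"empty gene list: {path}")
    sep = "\t" if "\t" in lines[0] else ("," if "," in lines[0] else None)
    names = [(ln.split(sep)[0] if sep else ln).strip() for ln in lines]
    if names and names[0].lower() in _HEADER_TOKENS:
        names = names[1:]
        if not names:
            raise ValueError(f"empty gene list: {path}")
    if case_insensitive:
        names = [n.casefold() for n in names]
    return _dedupe(names, str(path))


def flag_duplicates(
    hk_names: Sequence[str],
    other_names: Sequence[str],
    *,
    case_insensitive: bool = False,
) -> set[str]:
    """Names present in both candidate groups under the active normalization.

    Under exact matching the two groups are disjoint by construction and the
    set is empty; the rule fires when normalization (e.g. casefolding) makes
    distinct spellings collide, or when the housekeeping list itself carries
    names that also occur in the remainder.
    """
    if case_insensitive:
        hk = {n.casefold() for n in hk_names}
        other = {n.casefold() for n in other_names}
        collide = hk & other
        return {
            n
            for n in (*hk_names, *other_names)
            if n.casefold() in collide
        }
    return set(hk_names) & set(other_names)


def expand_prefix_variants(names: Sequence[str], universe: Sequence[str]) -> list[str]:
    """Optional variant expansion: add universe symbols that extend a listed
    symbol with a purely numeric suffix (e.g. ``Hoxa`` -> ``Hoxa1``..``Hoxa13``).

    Off by default throughout the package; order-preserving, listed names first.
    """
    out: dict[str, None] = dict.fromkeys(names)
    for base in names:
        for g in universe:
            if g.startswith(base) and g[len(base):].isdigit():
                out.setdefault(g, None)
    return list(out)


def partition(
    all_genes: Sequence[str],
    hk_names: Sequence[str],
    *,
    duplicate_flagged: Iterable[str] | None = None,
    case_insensitive: bool = False,
) -> GeneCatalog:
    """Assign every gene of the universe to HG or IntG.

    Genes named in ``hk_names`` become HG, the remainder IntG. Names in
    ``duplicate_flagged`` (default: :func:`flag_duplicates` on the two
    candidate groups) are removed from both. Housekeeping names absent from
    the universe are recorded in ``unmatched_hk``, not fatal.
    """
    if not all_genes:
        raise ValueError("empty gene universe")
    norm = (lambda s: s.strip().casefold()) if case_insensitive else str.strip
    universe = _dedupe([norm(g) for g in all_genes], "gene universe")
    hk = {norm(g) for g in hk_names}
    unmatched = tuple(sorted(hk - set(universe)))
    if duplicate_flagged is None:
        rest = [g for g in universe if g not in hk]
        hg_candidates = [g for g in universe if g in hk]
        flagged = flag_duplicates(hg_candidates, rest, case_insensitive=False)
    else:
        flagged = {norm(g) for g in duplicate_flagged}
    entries = {
        g: (HG if g in hk else INTG) for g in universe if g not in flagged
    }
    return GeneCatalog(
        entries=entries,
        removed=frozenset(g for g in universe if g in flagged),
        unmatched_hk=unmatched,
    )


def make_block(
    name: str, genes: Sequence[str], catalog: GeneCatalog, *, within: str | None = None
) -> GeneBlock:
    """Resolve ``genes`` against the catalog into a :class:`GeneBlock`.

    Unresolvable names are reported on the block, never silently dropped.
    ``within`` restricts resolution to one group (the DNA-repair block must
    resolve within HG). Raises if nothing resolves.
    """
    pool = set(catalog.entries) if within is None else set(catalog.group(within))
    resolved = tuple(g for g in genes if g in pool)
    unresolved = tuple(g for g in genes if g not in pool)
    if not resolved:
        raise ValueError(f"block {name!r}: no gene resolves against the catalog")
    if unresolved:
        warnings.warn(
            f"block {name!r}: {len(unresolved)} unresolved name(s): {unresolved[:5]}",
            stacklevel=2,
        )
    return GeneBlock(name=name, genes=resolved, unresolved=unresolved)


def load_block(
    path: str | Path,
    catalog: GeneCatalog,
    *,
    name: str | None = None,
    within: str | None = None,
    case_insensitive: bool = False,
) -> GeneBlock:
    """Read a block definition file and resolve it against the catalog."""
    path = Path(path)
    genes = load_gene_list(path, case_insensitive=case_insensitive)
    return make_block(name or path.stem, genes, catalog, within=within)
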