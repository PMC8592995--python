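"""Overrepresentation analysis (ORA) of protein sets against annotation terms.

Given a query set of proteins (e.g. the members of an SPA-associated
cluster), a universe (the quantified proteins), and a collection of
annotation terms, each term is scored by the upper-tail hypergeometric
probability of observing at least the realized overlap; Benjamini–Hochberg
q-values control the false-discovery rate across the tested terms.  The
term-by-condition ``-log10(p)`` matrix (zero where p >= alpha) is the
standard heatmap export for such results.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "ora",
    "bh_fdr",
    "neglog_p_matrix",
]


@dataclass(frozen=True)
class GeneSet:
    """One annotation term: an identifier, a free-text description, members."""

    name: str
    description: str
    members: frozenset[str]

    def __init__(self, name: str, description: str, members: Iterable[str]) -> None:
        mem = frozenset(str(m) for m in members)
        if not mem:
            raise ValueError(f"term {name!r} has no members")
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "description", str(description))
        object.__setattr__(self, "members", mem)


@dataclass(frozen=True)
class GeneSetCollection:
    """An ordered collection of annotation terms keyed by term identifier."""

    terms: dict[str, GeneSet]

    def __init__(self, terms: Iterable[GeneSet]) -> None:
        mapping: dict[str, GeneSet] = {}
        for t in terms:
            if t.name in mapping:
                raise ValueError(f"duplicate term identifier {t.name!r}")
            mapping[t.name] = t
        object.__setattr__(self, "terms", mapping)

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.terms[name]


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one term per line, ``name<TAB>description<TAB>member...``."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line {lineno}: need >= 3 fields")
            sets.append(GeneSet(parts[0], parts[1],
                                [m for m in parts[2:] if m]))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for t in collection:
            fh.write("\t".join([t.name, t.description, *sorted(t.members)]) + "\n")


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        bad = p[(~np.isfinite(p)) | (p <= 0) | (p > 1)]
        raise ValueError(f"p-values must lie in (0, 1]; offenders: {bad[:5]}")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def ora(query: Iterable[str], universe: Iterable[str],
        collection: GeneSetCollection, min_term_size: int = 3,
        alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric overrepresentation analysis of ``query`` within ``universe``.

    For each term with at least ``min_term_size`` members inside the
    universe, computes the upper-tail probability ``P(X >= k)`` of drawing
    ``k`` or more term members in a size-``n`` query from a size-``N``
    universe containing ``K`` term members, plus BH q-values over the tested
    terms.  Rows are sorted by ascending p-value.
    """
    query = {str(x) for x in query}
    universe = {str(x) for x in universe}
    if not universe:
        raise ValueError("universe must be non-empty")
    stray = query - universe
    if stray:
        raise ValueError(f"query proteins outside the universe: {sorted(stray)[:5]}")
    N, n = len(universe), len(query)
    rows = []
    for t in collection:
        members = t.members & universe
        K = len(members)
        if K < min_term_size:
            continue
        k = len(members & query)
        p = float(hypergeom.sf(k - 1, N, K, n))
        p = min(p, 1.0)
        rows.append((t.name, t.description, N, K, n, k, p))
    out = pd.DataFrame(rows, columns=[
        "term", "description", "universe_size", "term_size",
        "query_size", "overlap", "p_value"])
    if len(out):
        out["q_value"] = bh_fdr(out["p_value"].to_numpy())
        out["neglog10_p"] = -np.log10(out["p_value"].to_numpy())
        out = out.sort_values(["p_value", "term"], kind="mergesort")
    else:
        out["q_value"] = []
        out["neglog10_p"] = []
    return out.reset_index(drop=True)


def neglog_p_matrix(results: Mapping[str, pd.DataFrame],
                    alpha: float = 0.05) -> pd.DataFrame:
    """Term-by-condition matrix of ``-log10(p)`` (base 10), zero where p >= alpha.

    ``results`` maps a condition (or cluster) label to an ORA result frame.
    Only terms significant (p < alpha, strict) in at least one condition are
    retained; absent term/condition combinations are zero.
    """
    conditions = list(results)
    cells: dict[str, dict[str, float]] = {}
    for cond in conditions:
        frame = results[cond]
        for term, p in zip(frame["term"], frame["p_value"]):
            if p < alpha:
                cells.setdefault(term, {})[cond] = float(-np.log10(p))
    matrix = pd.DataFrame(0.0, index=sorted(cells), columns=conditions)
    for term, by_cond in cells.items():
        for cond, v in by_cond.items():
            matrix.loc[term, cond] = v
    matrix.index.name = "term"
    return matrix
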