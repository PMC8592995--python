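"""Tissue-cohort clustering and androgen-regulated biomarker triage.

Clinical prostate samples fall into four groups — normal adjacent tissue
(NAT), benign prostatic hyperplasia (BPH), localized prostate cancer (PCa),
and metastatic PCa (mPCa).  Glycoprotein profiles are clustered with
Pearson-correlation distance and complete linkage (samples fixed, proteins
clustered — "supervised" clustering), displayed on a capped log scale, and
triaged for candidate biomarkers: proteins that respond to androgen in the
cell-line experiment (non-flat ternary pattern) *and* are upregulated in
tumor tissue relative to benign tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .patterns import PatternCode
from .quant import validate_quant_table

__all__ = [
    "TISSUE_GROUPS",
    "CohortDesign",
    "read_design",
    "write_design",
    "log_cap_transform",
    "pearson_distance",
    "pairwise_pearson_distances",
    "Dendrogram",
    "hierarchical_cluster",
    "group_contrast",
    "candidate_biomarkers",
]

TISSUE_GROUPS = ("NAT", "BPH", "PCa", "mPCa")


@dataclass(frozen=True)
class CohortDesign:
    """Sample metadata: group labels plus optional tumor↔NAT pairing.

    ``groups`` maps sample id → group label (tissue group or a cell-line
    dose label).  ``pairing`` maps a tumor sample to the normal-adjacent
    sample from the same case; each NAT sample may serve only one tumor.
    """

    groups: dict[str, str]
    pairing: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", dict(self.groups))
        object.__setattr__(self, "pairing", dict(self.pairing))
        for tumor, nat in self.pairing.items():
            if tumor not in self.groups or nat not in self.groups:
                raise ValueError(f"pairing refers to unknown sample: {tumor}/{nat}")
        nats = list(self.pairing.values())
        if len(nats) != len(set(nats)):
            raise ValueError("each NAT sample may be paired with only one tumor")

    def samples_in(self, *labels: str) -> list[str]:
        return [s for s, g in self.groups.items() if g in labels]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.groups)


def read_design(path, *, sep: str = "\t") -> CohortDesign:
    """Read a design table: columns ``sample``, ``group``, optional ``paired_nat``."""
    frame = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    if not {"sample", "group"} <= set(frame.columns):
        raise ValueError("design table needs 'sample' and 'group' columns")
    groups = dict(zip(frame["sample"], frame["group"]))
    pairing = {}
    if "paired_nat" in frame.columns:
        for s, nat in zip(frame["sample"], frame["paired_nat"]):
            if isinstance(nat, str) and nat:
                pairing[s] = nat
    return CohortDesign(groups=groups, pairing=pairing)


def write_design(design: CohortDesign, path, *, sep: str = "\t") -> None:
    rows = [{"sample": s, "group": g, "paired_nat": design.pairing.get(s, "")}
            for s, g in design.groups.items()]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def log_cap_transform(table: pd.DataFrame, cap: float = 5.0,
                      pseudo_intensity: float | None = None) -> pd.DataFrame:
    """Display-scale transform: ``min(log10(1 + x/pseudo), cap)``; missing → 0.

    Monotone below the cap, zero for undetected proteins, saturating at
    ``cap`` (default 5, the conventional ceiling of such clustergrams).
    ``pseudo_intensity`` anchors the zero point of the display scale;
    by default it is the table's smallest positive intensity (the detection
    floor), so the scale reads as decades above the faintest quantified
    signal.
    """
    if not cap > 0:
        raise ValueError(f"cap must be positive, got {cap}")
    x = table.to_numpy(dtype=float)
    if pseudo_intensity is None:
        positive = x[np.isfinite(x) & (x > 0)]
        pseudo_intensity = float(positive.min()) if positive.size else 1.0
    with np.errstate(invalid="ignore"):
        z = np.log10(1.0 + x / pseudo_intensity)
    z = np.where(np.isnan(x), 0.0, np.minimum(z, cap))
    return pd.DataFrame(z, index=table.index, columns=table.columns)


def pearson_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """``1 - r`` over pairwise-complete positions; range [0, 2].

    Raises ``ValueError`` with fewer than two complete pairs or when either
    vector is constant on the complete positions (correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    mask = ~(np.isnan(x) | np.isnan(y))
    if mask.sum() < 2:
        raise ValueError("fewer than 2 pairwise-complete positions")
    xs, ys = x[mask], y[mask]
    sx, sy = xs.std(), ys.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero variance on pairwise-complete positions")
    r = float(np.mean((xs - xs.mean()) * (ys - ys.mean())) / (sx * sy))
    r = min(1.0, max(-1.0, r))
    return 1.0 - r


def pairwise_pearson_distances(matrix: pd.DataFrame,
                               axis: Literal["rows", "columns"] = "rows"
                               ) -> np.ndarray:
    """Condensed pairwise Pearson-distance vector over rows or columns.

    Undefined pairs raise ``ValueError`` naming the offending item pair.
    """
    data = matrix if axis == "rows" else matrix.T
    ids = list(data.index)
    values = data.to_numpy(dtype=float)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    if not np.isnan(values).any() and values.shape[1] >= 2:
        # complete data: vectorized correlation, same result as the loop
        sd = values.std(axis=1)
        flat = np.flatnonzero(sd == 0)
        if flat.size:
            i = int(flat[0])
            raise ValueError(
                f"distance undefined for pair ({ids[i]!r}, ...): zero variance")
        r = np.clip(np.corrcoef(values), -1.0, 1.0)
        iu = np.triu_indices(n, k=1)
        return (1.0 - r)[iu]
    out = np.empty(n * (n - 1) // 2)
    pos = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            try:
                out[pos] = pearson_distance(values[i], values[j])
            except ValueError as exc:
                raise ValueError(
                    f"distance undefined for pair ({ids[i]!r}, {ids[j]!r}): {exc}"
                ) from exc
            pos += 1
    return out


@dataclass(frozen=True)
class Dendrogram:
    """An agglomerative clustering result.

    ``merges`` is an ordered list of ``(node_a, node_b, height)`` triples
    where leaves are numbered 0..n-1 and the i-th merge creates node n+i;
    ``leaf_order`` is the display order of the leaf labels.
    """

    merges: tuple[tuple[int, int, float], ...]
    leaf_order: tuple[str, ...]
    labels: tuple[str, ...]

    @property
    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h in self.merges])

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        n = len(self.labels)
        height_of = {i: 0.0 for i in range(n)}
        node_str = {i: _escape_newick(lbl) for i, lbl in enumerate(self.labels)}
        for i, (a, b, h) in enumerate(self.merges):
            node = n + i
            la = max(h - height_of[a], 0.0)
            lb = max(h - height_of[b], 0.0)
            node_str[node] = (f"({node_str[a]}:{la:.6g},{node_str[b]}:{lb:.6g})")
            height_of[node] = h
        return node_str[n + len(self.merges) - 1] + ";"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.merges, columns=["node_a", "node_b", "height"])


def _escape_newick(label: str) -> str:
    if any(c in label for c in "(),:; \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def hierarchical_cluster(matrix: pd.DataFrame,
                         axis: Literal["rows", "columns"] = "rows",
                         method: str = "complete") -> Dendrogram:
    """Agglomerative clustering with Pearson distance (default complete linkage).

    Merge heights of complete linkage equal the maximum pairwise distance
    across the merged groups and are therefore non-decreasing.
    """
    data = matrix if axis == "rows" else matrix.T
    ids = tuple(str(i) for i in data.index)
    condensed = pairwise_pearson_distances(matrix, axis=axis)
    Z = linkage(condensed, method=method)
    merges = tuple((int(a), int(b), float(h)) for a, b, h, _ in Z)
    order = tuple(ids[i] for i in leaves_list(Z))
    return Dendrogram(merges=merges, leaf_order=order, labels=ids)


def group_contrast(table: pd.DataFrame, design: CohortDesign,
                   group_a: str, group_b: str,
                   pseudo_intensity: float = 1.0) -> pd.DataFrame:
    """Per-protein mean log10 intensity difference: group_a minus group_b.

    Means are taken over quantifying (non-missing) samples only; the counts
    of quantifying samples per group are reported alongside.  Antisymmetric
    in its two groups.
    """
    validate_quant_table(table)
    known = set(design.groups.values())
    for g in (group_a, group_b):
        if g not in known:
            raise ValueError(f"unknown group label {g!r}; design has {sorted(known)}")
    samples_a = [s for s in design.samples_in(group_a) if s in table.columns]
    samples_b = [s for s in design.samples_in(group_b) if s in table.columns]
    if not samples_a or not samples_b:
        raise ValueError("both groups must have at least one sample in the table")
    log_a = np.log10(table[samples_a] + pseudo_intensity)
    log_b = np.log10(table[samples_b] + pseudo_intensity)
    out = pd.DataFrame({
        "log10_fc": log_a.mean(axis=1, skipna=True) - log_b.mean(axis=1, skipna=True),
        "n_a": log_a.notna().sum(axis=1),
        "n_b": log_b.notna().sum(axis=1),
    })
    out.index.name = "protein_id"
    return out


def candidate_biomarkers(cell_line_patterns: Mapping[str, PatternCode],
                         tissue: pd.DataFrame, design: CohortDesign,
                         min_log10_fc: float = 0.5,
                         require_pairs: bool = False,
                         pseudo_intensity: float = 1.0,
                         tumor_groups: Sequence[str] = ("PCa", "mPCa"),
                         reference_group: str = "BPH") -> pd.DataFrame:
    """Rank androgen-regulated, tumor-upregulated candidate biomarkers.

    A protein passes when (1) its cell-line dose-response pattern is
    non-flat (androgen-regulated), (2) its tumor (PCa ∪ mPCa) vs reference
    (BPH) contrast is at least ``min_log10_fc`` decades, and (3) if
    ``require_pairs``, the median paired tumor−NAT log10 difference is
    positive.  All overlapping proteins are returned sorted by descending
    tumor contrast (``rank_score``), with a boolean ``passes`` column.
    """
    shared = [p for p in tissue.index if p in cell_line_patterns]
    if not shared:
        raise ValueError("no overlapping proteins between cell-line patterns "
                         "and tissue table")
    tumor_label = "+".join(tumor_groups)
    merged_groups = {s: (tumor_label if g in tumor_groups else g)
                     for s, g in design.groups.items()}
    merged = CohortDesign(groups=merged_groups, pairing=design.pairing)
    contrast = group_contrast(tissue, merged, tumor_label, reference_group,
                              pseudo_intensity=pseudo_intensity).loc[shared]

    paired_delta = pd.Series(np.nan, index=pd.Index(shared))
    if require_pairs:
        pairs = [(t, n) for t, n in design.pairing.items()
                 if t in tissue.columns and n in tissue.columns]
        if not pairs:
            raise ValueError("require_pairs=True but design has no usable pairs")
        deltas = pd.concat(
            [np.log10(tissue[t] + pseudo_intensity)
             - np.log10(tissue[n] + pseudo_intensity) for t, n in pairs],
            axis=1)
        paired_delta = deltas.median(axis=1, skipna=True).loc[shared]

    rows = []
    for pid in shared:
        pattern = cell_line_patterns[pid]
        fc = float(contrast.loc[pid, "log10_fc"])
        passes = (not pattern.is_flat) and np.isfinite(fc) and fc >= min_log10_fc
        if require_pairs:
            passes = passes and (paired_delta[pid] > 0)
        rows.append({
            "protein_id": pid,
            "cell_line_pattern": str(pattern),
            "tumor_vs_reference_log10_fc": fc,
            "paired_tumor_vs_nat_log10_fc": float(paired_delta[pid])
            if np.isfinite(paired_delta[pid]) else np.nan,
            "passes": bool(passes),
            "rank_score": fc,
        })
    out = pd.DataFrame(rows).sort_values(
        ["rank_score", "protein_id"], ascending=[False, True], kind="mergesort")
    return out.set_index("protein_id")
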