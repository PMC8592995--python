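"""Quantification tables, PSM filtering, spike-in normalization, and qPCR fold changes.

The central in-memory object of the pipeline is the *quantification table*: a
:class:`pandas.DataFrame` whose rows are proteins, whose columns are samples,
and whose float entries are non-negative label-free intensities (``NaN`` =
not quantified in that sample).  On disk the table is tab-separated text with
the protein identifier in the first column and empty cells for missing values;
lines starting with ``#`` are treated as comments.

Search-engine output enters the pipeline as peptide-spectrum-match (PSM)
records which are filtered on four spectral-quality scores and rolled up to
protein level, then normalized to an externally spiked standard (bovine serum
albumin) to correct for unequal sample loading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "read_quant_table",
    "write_quant_table",
    "validate_quant_table",
    "PsmRecord",
    "PsmFilterThresholds",
    "read_psm_table",
    "write_psm_table",
    "filter_psms",
    "aggregate_psms",
    "SpikeKey",
    "normalize_to_spike",
    "QpcrRecord",
    "ddct_fold_change",
]

PSM_COLUMNS = (
    "protein_id",
    "sequence",
    "score",
    "fwd_rev_score",
    "rank12_score",
    "spi_percent",
    "intensity",
    "sample_id",
)


def validate_quant_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check quantification-table invariants, returning the table unchanged.

    Raises ``ValueError`` on duplicate protein/sample identifiers, negative
    intensities, or an empty sample axis.
    """
    if table.shape[1] < 1:
        raise ValueError("quantification table must have at least one sample column")
    if table.index.has_duplicates:
        dup = table.index[table.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate protein identifiers: {dup[:5]}")
    if table.columns.has_duplicates:
        dup = table.columns[table.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample identifiers: {dup[:5]}")
    values = table.to_numpy(dtype=float)
    if np.nanmin(values, initial=0.0) < 0:
        bad = table.index[(values < 0).any(axis=1)].tolist()
        raise ValueError(f"negative intensities for proteins: {bad[:5]}")
    return table


def read_quant_table(path, *, sep: str = "\t") -> pd.DataFrame:
    """Read a protein-by-sample intensity table from delimited text.

    First column = protein identifier, header row = sample identifiers,
    empty cells parse as missing.  ``#``-prefixed lines are skipped.
    """
    table = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    table.index = table.index.astype(str)
    table.columns = table.columns.astype(str)
    table = table.astype(float)
    return validate_quant_table(table)


def write_quant_table(table: pd.DataFrame, path, *, sep: str = "\t",
                      header_comment: str | None = None) -> None:
    """Write a quantification table as tab-separated text (missing → empty cell)."""
    validate_quant_table(table)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        table.to_csv(fh, sep=sep, na_rep="", float_format="%.10g")


@dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match from the search-engine output."""

    protein_id: str
    sequence: str
    score: float
    fwd_rev_score: float
    rank12_score: float
    spi_percent: float
    intensity: float
    sample_id: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.spi_percent <= 100.0:
            raise ValueError(f"spi_percent must be in [0, 100], got {self.spi_percent}")
        if self.intensity < 0:
            raise ValueError(f"intensity must be non-negative, got {self.intensity}")


@dataclass(frozen=True)
class PsmFilterThresholds:
    """Post-search spectral-quality thresholds (Spectrum Mill conventions).

    Defaults are the standard post-search filter: forward-reverse score 1.2,
    rank 1–2 score 2, identification score 3, and 30 scored-peak-intensity
    percent.  All comparisons are inclusive (record kept at the boundary).
    """

    fwd_rev_min: float = 1.2
    rank12_min: float = 2.0
    score_min: float = 3.0
    spi_min_percent: float = 30.0

    def __post_init__(self) -> None:
        for name in ("fwd_rev_min", "rank12_min", "score_min", "spi_min_percent"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def filter_psms(records: Iterable[PsmRecord],
                thresholds: PsmFilterThresholds | None = None) -> list[PsmRecord]:
    """Keep PSMs passing all four quality thresholds (inclusive), order preserved."""
    t = thresholds or PsmFilterThresholds()
    return [
        r for r in records
        if r.fwd_rev_score >= t.fwd_rev_min
        and r.rank12_score >= t.rank12_min
        and r.score >= t.score_min
        and r.spi_percent >= t.spi_min_percent
    ]


def read_psm_table(path, *, sep: str = "\t") -> list[PsmRecord]:
    frame = pd.read_csv(path, sep=sep, comment="#")
    missing = set(PSM_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"PSM table missing columns: {sorted(missing)}")
    return [
        PsmRecord(
            protein_id=str(row.protein_id),
            sequence=str(row.sequence),
            score=float(row.score),
            fwd_rev_score=float(row.fwd_rev_score),
            rank12_score=float(row.rank12_score),
            spi_percent=float(row.spi_percent),
            intensity=float(row.intensity),
            sample_id=str(row.sample_id),
        )
        for row in frame.itertuples(index=False)
    ]


def write_psm_table(records: Sequence[PsmRecord], path, *, sep: str = "\t") -> None:
    frame = pd.DataFrame([r.__dict__ for r in records], columns=list(PSM_COLUMNS))
    frame.to_csv(path, sep=sep, index=False)


def aggregate_psms(records: Sequence[PsmRecord],
                   method: Literal["sum", "mean", "median"] = "sum") -> pd.DataFrame:
    """Roll filtered PSM intensities up to a protein-by-sample table.

    The protein-level intensity in a sample is the sum (default), mean, or
    median of its member PSM intensities there.  Protein and sample order
    follow first appearance in ``records``; (protein, sample) cells with no
    PSM are missing.
    """
    proteins: list[str] = []
    samples: list[str] = []
    cells: dict[tuple[str, str], list[float]] = {}
    for r in records:
        if r.protein_id not in proteins:
            proteins.append(r.protein_id)
        if r.sample_id not in samples:
            samples.append(r.sample_id)
        cells.setdefault((r.protein_id, r.sample_id), []).append(r.intensity)
    reduce = {"sum": np.sum, "mean": np.mean, "median": np.median}[method]
    table = pd.DataFrame(np.nan, index=pd.Index(proteins), columns=pd.Index(samples))
    for (pid, sid), values in cells.items():
        table.loc[pid, sid] = float(reduce(values))
    return validate_quant_table(table)


@dataclass(frozen=True)
class SpikeKey:
    """Which rows of a table are the spiked standard, and the loading reference.

    ``reference_sample`` may be a sample identifier or the literal string
    ``"first"`` (the table's first sample column).
    """

    spike_protein_ids: frozenset[str]
    reference_sample: str = "first"

    def __init__(self, spike_protein_ids: Iterable[str],
                 reference_sample: str = "first") -> None:
        ids = frozenset(str(p) for p in spike_protein_ids)
        if not ids:
            raise ValueError("spike_protein_ids must be non-empty")
        object.__setattr__(self, "spike_protein_ids", ids)
        object.__setattr__(self, "reference_sample", reference_sample)


def normalize_to_spike(table: pd.DataFrame, key: SpikeKey) -> pd.DataFrame:
    """Scale every sample to the spiked standard, then drop the spike rows.

    Each sample's intensities are multiplied by
    ``reference spike total / sample spike total``, equalizing the recovered
    amount of the external standard (hence correcting loading differences).
    Missing values pass through unchanged; the reference sample itself is
    left fixed.  Raises ``ValueError`` if any sample's spike total is zero or
    entirely missing, naming the sample.
    """
    validate_quant_table(table)
    missing_ids = key.spike_protein_ids - set(table.index)
    if missing_ids:
        raise ValueError(f"spike proteins absent from table: {sorted(missing_ids)}")
    reference = key.reference_sample
    if reference == "first":
        reference = str(table.columns[0])
    if reference not in table.columns:
        raise ValueError(f"reference sample {reference!r} not in table")
    spike = table.loc[sorted(key.spike_protein_ids)]
    totals = spike.sum(axis=0, skipna=True)
    bad = totals.index[(totals <= 0) | ~np.isfinite(totals)].tolist()
    if bad:
        raise ValueError(f"zero or missing spike total in samples: {bad}")
    factors = totals[reference] / totals
    out = table.drop(index=sorted(key.spike_protein_ids))
    return out.mul(factors, axis=1)


@dataclass(frozen=True)
class QpcrRecord:
    """One qPCR measurement: target and reference-gene Ct for a gene/condition."""

    gene: str
    condition: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for name in ("ct_target", "ct_reference"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v}")


def ddct_fold_change(treated: QpcrRecord, vehicle: QpcrRecord) -> float:
    """Relative expression by the comparative-Ct method: ``2**(-ddCt)``.

    ``ddCt = (Ct_target - Ct_reference)_treated - (Ct_target - Ct_reference)_vehicle``;
    a treated dCt one cycle smaller than vehicle doubles the fold change.
    """
    if treated.gene != vehicle.gene:
        raise ValueError(
            f"gene mismatch: treated={treated.gene!r}, vehicle={vehicle.gene!r}")
    ddct = (treated.ct_target - treated.ct_reference) - (
        vehicle.ct_target - vehicle.ct_reference)
    return float(2.0 ** (-ddct))
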