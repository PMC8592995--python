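"""Synthetic data with the statistical structure the analysis assumes.

Three generators cover the pipeline's inputs:

* :func:`simulate_dose_response` — a label-free glycoprotein quantification
  table over a four-condition androgen dose series (vehicle plus 0.1, 1.0,
  10 nM), with log10-normal intensities, planted ternary response patterns,
  per-condition missingness, and a spiked external standard (BSA-like) that
  is exactly equal across samples before any loading distortion.
* :func:`simulate_gene_sets` — an annotation collection in which designated
  terms preferentially sample members from one response-pattern class.
* :func:`simulate_tissue_cohort` — a tissue cohort (NAT/BPH/PCa/mPCa) with
  planted tumor-upregulated markers, including one androgen-biphasic
  tumor-upregulated archetype whose cell-line profile peaks at the 1 nM dose
  and collapses at the supraphysiologic 10 nM dose.

Every generator is deterministic given its seed, and every planted truth is
recorded so recovery can be measured downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import TISSUE_GROUPS, CohortDesign
from .enrichment import GeneSet, GeneSetCollection
from .patterns import DoseDesign, PatternCode, enumerate_theoretical_patterns
from .quant import validate_quant_table

__all__ = [
    "SPIKE_ID",
    "SimulationConfig",
    "SimulatedStudy",
    "SimulatedCohort",
    "simulate_dose_response",
    "simulate_gene_sets",
    "simulate_tissue_cohort",
]

#: Row identifier used for the spiked external standard.
SPIKE_ID = "BSA_SPIKE"

#: Union and per-condition protein counts the default configuration emulates.
_UNION_SIZE = 3341
_CONDITION_COUNTS = (1540, 1558, 1668, 1586)


def _default_missing_rates() -> tuple[float, ...]:
    return tuple(1.0 - c / _UNION_SIZE for c in _CONDITION_COUNTS)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the dose-response generator.

    Defaults emulate the reference experiment: a 3,341-protein union over
    four conditions whose per-condition presence counts are roughly
    1540/1558/1668/1586, log10-normal intensities around 1e7 spanning the
    observed 1e4–2.8e9 range, a one-decade regulation step, 0.2-decade
    measurement noise, and a BSA-like spike at a 1:75 fraction of sample
    protein.  ``pattern_frequencies`` defaults to the uniform distribution
    over all 27 ternary patterns; ``loading_log10_sd`` > 0 adds a per-sample
    loading distortion (applied to every row including the spike) for
    normalization to undo.
    """

    n_proteins: int = _UNION_SIZE
    doses: tuple[str, ...] = ("0", "0.1", "1.0", "10")
    pattern_frequencies: Mapping[PatternCode, float] | None = None
    base_log10_intensity_mean: float = 7.0
    base_log10_intensity_sd: float = 1.0
    effect_log10: float = 1.0
    noise_log10_sd: float = 0.2
    missing_rate_per_condition: tuple[float, ...] = field(
        default_factory=_default_missing_rates)
    spike_fraction: float = 1.0 / 75.0
    loading_log10_sd: float = 0.0
    intensity_dependent_missingness: bool = False
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if len(self.doses) < 2:
            raise ValueError("need a baseline dose plus at least one treated dose")
        if not self.effect_log10 > 0:
            raise ValueError("effect_log10 must be > 0")
        if self.noise_log10_sd < 0 or self.loading_log10_sd < 0:
            raise ValueError("noise/loading sds must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        rates = tuple(float(r) for r in self.missing_rate_per_condition)
        if len(rates) != len(self.doses):
            raise ValueError("missing_rate_per_condition must have one entry per dose")
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("missing_rate_per_condition entries must be in [0, 1]")
        object.__setattr__(self, "missing_rate_per_condition", rates)
        if not 0.0 <= self.spike_fraction:
            raise ValueError("spike_fraction must be non-negative")
        if self.pattern_frequencies is not None:
            freqs = dict(self.pattern_frequencies)
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"pattern_frequencies must sum to 1 (got {total!r})")
            if any(v < 0 for v in freqs.values()):
                raise ValueError("pattern_frequencies must be non-negative")
            n_treated = len(self.doses) - 1
            bad = [p for p in freqs if len(p.digits) != n_treated]
            if bad:
                raise ValueError(
                    f"pattern_frequencies keys must have {n_treated} digits: {bad[:3]}")
            object.__setattr__(self, "pattern_frequencies", freqs)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        ids = []
        for d in self.doses:
            if self.n_replicates == 1:
                ids.append(f"{d}nM")
            else:
                ids.extend(f"{d}nM_r{r + 1}" for r in range(self.n_replicates))
        return tuple(ids)

    @property
    def design(self) -> DoseDesign:
        """The dose design of the generated table (single-replicate layout)."""
        if self.n_replicates != 1:
            raise ValueError("design property is defined for n_replicates=1")
        ids = self.sample_ids
        return DoseDesign(baseline_sample=ids[0], treated_samples=ids[1:])


@dataclass(frozen=True)
class SimulatedStudy:
    """A simulated dose-response study plus its recorded ground truth."""

    quant: pd.DataFrame
    spike_rows: tuple[str, ...]
    truth_patterns: dict[str, PatternCode]
    config: SimulationConfig
    gene_sets: GeneSetCollection | None = None
    truth_enriched_terms: frozenset[str] = frozenset()

    @property
    def design(self) -> DoseDesign:
        return self.config.design


@dataclass(frozen=True)
class SimulatedCohort:
    """A simulated tissue cohort with planted marker classes.

    ``truth_markers`` maps protein → one of ``tumor-up``, ``BPH-up``,
    ``androgen-biphasic-tumor-up``, ``null`` (disjoint classes);
    ``cell_line_patterns`` carries each protein's paired cell-line
    dose-response code, and ``archetype_id`` names the planted biphasic
    tumor-upregulated marker.
    """

    quant: pd.DataFrame
    design: CohortDesign
    truth_markers: dict[str, str]
    cell_line_patterns: dict[str, PatternCode]
    archetype_id: str


def _draw_patterns(config: SimulationConfig,
                   rng: np.random.Generator) -> list[PatternCode]:
    n_treated = len(config.doses) - 1
    if config.pattern_frequencies is None:
        codes = enumerate_theoretical_patterns(n_treated)
        probs = np.full(len(codes), 1.0 / len(codes))
    else:
        codes = sorted(config.pattern_frequencies, key=lambda p: p.index)
        probs = np.array([config.pattern_frequencies[p] for p in codes])
        probs = probs / probs.sum()
    picks = rng.choice(len(codes), size=config.n_proteins, p=probs)
    return [codes[i] for i in picks]


def _missing_mask(config: SimulationConfig, log_intensity: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Boolean (protein, sample) mask of entries to blank out."""
    n = config.n_proteins
    mask = np.zeros((n, len(config.sample_ids)), dtype=bool)
    col = 0
    for rate in config.missing_rate_per_condition:
        for _ in range(config.n_replicates):
            if rate == 0:
                col += 1
                continue
            if config.intensity_dependent_missingness:
                # low-abundance proteins drop out preferentially
                z = (log_intensity[:, col] - log_intensity[:, col].mean())
                weights = np.exp(-z)
                weights /= weights.sum()
                k = int(round(rate * n))
                idx = rng.choice(n, size=min(k, n), replace=False, p=weights)
                mask[idx, col] = True
            else:
                mask[:, col] = rng.random(n) < rate
            col += 1
    return mask


def simulate_dose_response(config: SimulationConfig | None = None
                           ) -> SimulatedStudy:
    """Generate a dose-response quantification table with recorded truth.

    Each protein draws a ternary pattern; its log10 intensity at a treated
    dose is ``base + step * effect_log10 + noise`` (step -1/0/+1 per the
    pattern digit).  The vehicle baseline is the reference level
    ``10**base``: noise is modeled on the dose-response (log fold-change)
    scale, so ``noise_log10_sd`` is directly the dispersion of an observed
    log10 fold change against vehicle.  Missingness is applied per
    condition; a spike row whose value is identical across samples (the
    externally added standard) is appended, after which an optional
    per-sample loading distortion multiplies every row.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    patterns = _draw_patterns(config, rng)
    n, samples = config.n_proteins, config.sample_ids
    base = rng.normal(config.base_log10_intensity_mean,
                      config.base_log10_intensity_sd, size=n)
    steps = np.array([(0,) + p.steps for p in patterns], dtype=float)
    steps = np.repeat(steps, config.n_replicates, axis=1)
    noise = rng.normal(0.0, config.noise_log10_sd, size=(n, len(samples)))
    noise[:, :config.n_replicates] = 0.0  # vehicle columns are the reference level
    log_intensity = base[:, None] + steps * config.effect_log10 + noise
    intensity = 10.0 ** log_intensity

    mask = _missing_mask(config, log_intensity, rng)
    intensity[mask] = np.nan

    # spike: equal across samples before distortion, scaled to sample protein
    spike_value = config.spike_fraction * float(np.nansum(intensity) / len(samples))
    spike = np.full((1, len(samples)), spike_value)
    values = np.vstack([intensity, spike])

    if config.loading_log10_sd > 0:
        loading = 10.0 ** rng.normal(0.0, config.loading_log10_sd,
                                     size=len(samples))
        values = values * loading[None, :]

    width = len(str(n))
    protein_ids = [f"P{i + 1:0{width}d}" for i in range(n)]
    table = pd.DataFrame(values, index=protein_ids + [SPIKE_ID],
                         columns=list(samples))
    validate_quant_table(table)
    return SimulatedStudy(
        quant=table, spike_rows=(SPIKE_ID,),
        truth_patterns=dict(zip(protein_ids, patterns)), config=config)


def simulate_gene_sets(n_terms: int, set_size_range: tuple[int, int],
                       n_enriched: int, enrichment_factor: float,
                       truth_patterns: Mapping[str, PatternCode], seed: int,
                       target_pattern: PatternCode | None = None,
                       ) -> tuple[GeneSetCollection, set[str]]:
    """Generate annotation terms, some enriched for one pattern class.

    Null terms sample members uniformly from the universe (the keys of
    ``truth_patterns``); the first ``n_enriched`` terms sample members of
    the target pattern class with odds multiplied by ``enrichment_factor``
    (``inf`` restricts sampling to the class).  The default target class is
    the most populous non-flat pattern.  Returns the collection and the set
    of enriched term identifiers.
    """
    if not truth_patterns:
        raise ValueError("truth_patterns is empty: no universe to sample from")
    if n_enriched > n_terms:
        raise ValueError("n_enriched cannot exceed n_terms")
    lo, hi = set_size_range
    if lo < 1 or hi < lo:
        raise ValueError("set sizes must satisfy 1 <= lo <= hi")
    if enrichment_factor <= 0:
        raise ValueError("enrichment_factor must be positive")
    rng = np.random.default_rng(seed)
    universe = np.array(sorted(truth_patterns))
    if target_pattern is None:
        counts: dict[int, int] = {}
        for p in truth_patterns.values():
            if not p.is_flat:
                counts[p.index] = counts.get(p.index, 0) + 1
        if not counts:
            raise ValueError("no non-flat patterns to target")
        best = max(sorted(counts), key=lambda i: counts[i])
        n_digits = len(next(iter(truth_patterns.values())).digits)
        target_pattern = PatternCode.from_index(best, n_digits)
    in_class = np.array([truth_patterns[p] == target_pattern for p in universe])

    weights = np.ones(len(universe))
    if math.isinf(enrichment_factor):
        weights = in_class.astype(float)
    else:
        weights[in_class] = enrichment_factor
    weights = weights / weights.sum()

    sets, enriched_ids = [], set()
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(universe))
        if i < n_enriched:
            avail = int(np.count_nonzero(weights))
            members = rng.choice(universe, size=min(size, avail),
                                 replace=False, p=weights)
            name = f"T{i + 1:04d}_enriched"
            enriched_ids.add(name)
        else:
            members = rng.choice(universe, size=size, replace=False)
            name = f"T{i + 1:04d}"
        sets.append(GeneSet(name, f"simulated term {i + 1}", members))
    return GeneSetCollection(sets), enriched_ids


def simulate_tissue_cohort(n_per_group: Mapping[str, int] | None = None,
                           n_markers: int = 20, effect_log10: float = 1.0,
                           seed: int = 0, *, n_proteins: int = 400,
                           noise_log10_sd: float = 0.2,
                           base_log10_intensity_mean: float = 7.0,
                           base_log10_intensity_sd: float = 1.0,
                           ) -> SimulatedCohort:
    """Generate a tissue cohort with planted marker classes.

    Tumor-upregulated markers get ``effect_log10`` added to their mean log10
    intensity in PCa and mPCa samples; an equal number of BPH-upregulated
    markers get it in BPH samples; one additional marker is the
    androgen-biphasic tumor-upregulated archetype, tumor-upregulated in
    tissue with a cell-line pattern that rises through physiologic doses and
    falls at the supraphysiologic dose (up/up/down).  NAT samples are paired
    with tumor samples of the same simulated case.  Default group sizes are
    8 NAT / 10 BPH / 4 PCa / 6 mPCa.
    """
    n_per_group = dict(n_per_group) if n_per_group is not None else {
        "NAT": 8, "BPH": 10, "PCa": 4, "mPCa": 6}
    unknown = set(n_per_group) - set(TISSUE_GROUPS)
    if unknown:
        raise ValueError(f"unknown tissue groups: {sorted(unknown)}")
    if any(c < 1 for c in n_per_group.values()):
        raise ValueError("group counts must be >= 1")
    if effect_log10 < 0:
        raise ValueError("effect_log10 must be non-negative")
    n_planted = 2 * n_markers + 1
    if n_planted > n_proteins:
        raise ValueError(
            f"{n_planted} planted markers exceed n_proteins={n_proteins}")
    rng = np.random.default_rng(seed)

    samples, groups = [], {}
    for g in TISSUE_GROUPS:
        for i in range(n_per_group.get(g, 0)):
            sid = f"{g}_{i + 1:02d}"
            samples.append(sid)
            groups[sid] = g
    tumor_samples = [s for s in samples if groups[s] in ("PCa", "mPCa")]
    nat_samples = [s for s in samples if groups[s] == "NAT"]
    pairing = dict(zip(tumor_samples, nat_samples))
    design = CohortDesign(groups=groups, pairing=pairing)

    width = len(str(n_proteins))
    protein_ids = [f"P{i + 1:0{width}d}" for i in range(n_proteins)]
    classes = dict.fromkeys(protein_ids, "null")
    order = rng.permutation(n_proteins)
    tumor_up = [protein_ids[i] for i in order[:n_markers]]
    bph_up = [protein_ids[i] for i in order[n_markers:2 * n_markers]]
    archetype = protein_ids[order[2 * n_markers]]
    for p in tumor_up:
        classes[p] = "tumor-up"
    for p in bph_up:
        classes[p] = "BPH-up"
    classes[archetype] = "androgen-biphasic-tumor-up"

    base = rng.normal(base_log10_intensity_mean, base_log10_intensity_sd,
                      size=n_proteins)
    shift = np.zeros((n_proteins, len(samples)))
    idx = {p: i for i, p in enumerate(protein_ids)}
    tumor_cols = [j for j, s in enumerate(samples)
                  if groups[s] in ("PCa", "mPCa")]
    bph_cols = [j for j, s in enumerate(samples) if groups[s] == "BPH"]
    for p in tumor_up + [archetype]:
        shift[idx[p], tumor_cols] = effect_log10
    for p in bph_up:
        shift[idx[p], bph_cols] = effect_log10
    noise = rng.normal(0.0, noise_log10_sd, size=shift.shape)
    table = pd.DataFrame(10.0 ** (base[:, None] + shift + noise),
                         index=protein_ids, columns=samples)
    validate_quant_table(table)

    non_flat = [p for p in enumerate_theoretical_patterns(3) if not p.is_flat]
    all_patterns = enumerate_theoretical_patterns(3)
    cell_patterns: dict[str, PatternCode] = {}
    for p in protein_ids:
        if p == archetype:
            cell_patterns[p] = PatternCode(("up", "up", "down"))
        elif classes[p] in ("tumor-up", "BPH-up"):
            cell_patterns[p] = non_flat[rng.integers(len(non_flat))]
        else:
            cell_patterns[p] = all_patterns[rng.integers(len(all_patterns))]

    return SimulatedCohort(quant=table, design=design, truth_markers=classes,
                           cell_line_patterns=cell_patterns,
                           archetype_id=archetype)
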