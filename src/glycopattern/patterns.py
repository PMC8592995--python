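"""Ternary dose-response patterns and the 27-pattern clustering framework.

A protein challenged with an ordered series of androgen doses can, at each
dose, go *up*, go *down*, or stay the *same* relative to the vehicle
(0 nM) baseline.  With three treated doses this yields 3**3 = 27 theoretical
response patterns.  The biologically interesting subset are the patterns
associated with supraphysiologic androgen (SPA), the highest dose, which
paradoxically inhibits proliferation: a pattern is *SPA-associated* when its
response at the SPA dose is discordant with the response at every
proliferation-stimulating (physiologic) dose — and hence concordant with the
non-proliferative baseline state.  Exactly 12 of the 27 patterns qualify.

Empirically, standardized log-intensity profiles are partitioned by K-means
and each cluster's per-dose median raw profile is direction-coded, matching
empirical clusters to theoretical patterns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "DOWN",
    "SAME",
    "UP",
    "DIGITS",
    "PatternCode",
    "DoseDesign",
    "DirectionParams",
    "enumerate_theoretical_patterns",
    "call_directions",
    "call_directions_table",
    "select_spa_associated",
    "is_spa_associated",
    "standardize_profiles",
    "ClusterModel",
    "kmeans_profiles",
    "ClusterPatternMatch",
    "match_clusters_to_patterns",
    "matches_to_frame",
]

DOWN, SAME, UP = "down", "same", "up"
#: Digit order defines the base-3 encoding: down=0, same=1, up=2.
DIGITS = (DOWN, SAME, UP)
_DIGIT_VALUE = {DOWN: 0, SAME: 1, UP: 2}
_DIGIT_STEP = {DOWN: -1, SAME: 0, UP: +1}


@dataclass(frozen=True)
class PatternCode:
    """A ternary direction triple (or k-tuple), one digit per treated dose.

    The integer ``index`` encodes the digits in base 3 (down=0, same=1, up=2)
    with the first treated dose as the most significant digit, so for three
    doses indices run 0..26 and (same, same, same) is index 13.
    """

    digits: tuple[str, ...]

    def __init__(self, digits: Sequence[str]) -> None:
        digits = tuple(digits)
        if not digits:
            raise ValueError("pattern must have at least one digit")
        bad = [d for d in digits if d not in _DIGIT_VALUE]
        if bad:
            raise ValueError(f"invalid pattern digits {bad}; expected one of {DIGITS}")
        object.__setattr__(self, "digits", digits)

    @property
    def index(self) -> int:
        value = 0
        for d in self.digits:
            value = value * 3 + _DIGIT_VALUE[d]
        return value

    @classmethod
    def from_index(cls, index: int, n_doses: int = 3) -> "PatternCode":
        if not 0 <= index < 3 ** n_doses:
            raise ValueError(f"index {index} out of range for {n_doses} doses")
        digits = []
        for _ in range(n_doses):
            index, rem = divmod(index, 3)
            digits.append(DIGITS[rem])
        return cls(tuple(reversed(digits)))

    @property
    def steps(self) -> tuple[int, ...]:
        """Signed steps (-1, 0, +1) per treated dose."""
        return tuple(_DIGIT_STEP[d] for d in self.digits)

    @property
    def is_flat(self) -> bool:
        """True when the protein is unchanged at every dose (all ``same``)."""
        return all(d == SAME for d in self.digits)

    def __str__(self) -> str:
        return "/".join(self.digits)

    @classmethod
    def from_string(cls, text: str) -> "PatternCode":
        return cls(tuple(text.split("/")))


@dataclass(frozen=True)
class DoseDesign:
    """Which sample is the vehicle baseline, which are treated, and where SPA sits."""

    baseline_sample: str
    treated_samples: tuple[str, ...]
    spa_index: int = -1

    def __post_init__(self) -> None:
        treated = tuple(self.treated_samples)
        object.__setattr__(self, "treated_samples", treated)
        if self.baseline_sample in treated:
            raise ValueError("baseline sample cannot also be a treated sample")
        if len(treated) < 1:
            raise ValueError("need at least one treated sample")
        if not -len(treated) <= self.spa_index < len(treated):
            raise ValueError(f"spa_index {self.spa_index} out of range")

    @property
    def spa_position(self) -> int:
        return self.spa_index % len(self.treated_samples)

    @property
    def all_samples(self) -> tuple[str, ...]:
        return (self.baseline_sample,) + self.treated_samples


@dataclass(frozen=True)
class DirectionParams:
    """Direction-calling parameters.

    ``fold_threshold`` bounds the "unchanged" band: a dose is *up* when
    intensity ≥ threshold × baseline, *down* when ≤ baseline / threshold
    (boundaries inclusive toward a change).  ``missing_policy`` governs
    profiles with missing values: ``error`` raises, ``drop-protein`` returns
    no code, ``treat-as-down`` reads absence as disappearance
    (presence/absence semantics).
    """

    fold_threshold: float = 1.5
    missing_policy: Literal["error", "treat-as-down", "drop-protein"] = "drop-protein"

    def __post_init__(self) -> None:
        if not self.fold_threshold > 1:
            raise ValueError(f"fold_threshold must be > 1, got {self.fold_threshold}")
        if self.missing_policy not in ("error", "treat-as-down", "drop-protein"):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")


def enumerate_theoretical_patterns(n_doses: int = 3) -> list[PatternCode]:
    """All 3**n_doses ternary patterns in ascending base-3 index order."""
    if n_doses < 1:
        raise ValueError(f"n_doses must be >= 1, got {n_doses}")
    return [PatternCode(c) for c in itertools.product(DIGITS, repeat=n_doses)]


def _is_missing(x: float | None) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x))


def call_directions(profile: Sequence[float],
                    params: DirectionParams | None = None) -> PatternCode | None:
    """Direction-code one intensity profile (baseline first, then treated doses).

    Returns the ternary :class:`PatternCode`, or ``None`` when the profile
    has missing values under the ``drop-protein`` policy.  A non-positive
    baseline is always an error (ratios are undefined).
    """
    params = params or DirectionParams()
    profile = [float("nan") if _is_missing(x) else float(x) for x in profile]
    if len(profile) < 2:
        raise ValueError("profile needs a baseline plus at least one treated dose")
    baseline, treated = profile[0], profile[1:]
    any_missing = np.isnan(baseline) or any(np.isnan(x) for x in treated)
    if any_missing:
        if params.missing_policy == "error":
            raise ValueError("profile contains missing intensities")
        if params.missing_policy == "drop-protein":
            return None
    if not np.isnan(baseline) and baseline <= 0:
        raise ValueError(f"baseline intensity must be positive, got {baseline}")
    thr = params.fold_threshold
    digits = []
    for x in treated:
        if np.isnan(baseline):
            # presence/absence semantics: detected where baseline was not
            digits.append(SAME if np.isnan(x) else UP)
            continue
        if np.isnan(x):
            digits.append(DOWN)
            continue
        ratio = x / baseline
        if ratio >= thr:
            digits.append(UP)
        elif ratio <= 1.0 / thr:
            digits.append(DOWN)
        else:
            digits.append(SAME)
    return PatternCode(tuple(digits))


def call_directions_table(table: pd.DataFrame, design: DoseDesign,
                          params: DirectionParams | None = None) -> pd.DataFrame:
    """Direction-code every protein in a quantification table.

    Returns a frame indexed by protein with columns ``pattern`` (slash-joined
    digits), ``index`` (base-3 code), and ``spa_associated``.  Proteins
    dropped by the missing-value policy are excluded.
    """
    params = params or DirectionParams()
    missing_cols = [s for s in design.all_samples if s not in table.columns]
    if missing_cols:
        raise ValueError(f"design samples absent from table: {missing_cols}")
    rows = {}
    for pid, profile in table[list(design.all_samples)].iterrows():
        code = call_directions(profile.to_numpy(dtype=float), params)
        if code is None:
            continue
        rows[pid] = (str(code), code.index,
                     is_spa_associated(code, design))
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["pattern", "index", "spa_associated"])
    out.index.name = "protein_id"
    return out


def is_spa_associated(pattern: PatternCode, design: DoseDesign | None = None) -> bool:
    """True when the SPA-dose digit differs from every physiologic-dose digit."""
    spa = design.spa_position if design is not None else len(pattern.digits) - 1
    digits = pattern.digits
    return all(digits[spa] != d for i, d in enumerate(digits) if i != spa)


def select_spa_associated(patterns: Sequence[PatternCode],
                          design: DoseDesign | None = None) -> list[PatternCode]:
    """Keep patterns whose SPA response is discordant with every physiologic dose.

    The SPA digit must differ from the digit at each other treated dose;
    on the full 3-dose frame this selects exactly 12 of the 27 patterns.
    """
    return [p for p in patterns if is_spa_associated(p, design)]


def standardize_profiles(table: pd.DataFrame, design: DoseDesign,
                         pseudo_intensity: float = 1.0) -> pd.DataFrame:
    """Per-protein standardized log10 profiles over the design's samples.

    Each row is log10(intensity + pseudo_intensity), centered and scaled to
    unit (population) variance across the baseline + treated samples.
    Zero-variance rows map to all zeros; rows with missing values in the
    design's samples are dropped.
    """
    cols = list(design.all_samples)
    missing_cols = [s for s in cols if s not in table.columns]
    if missing_cols:
        raise ValueError(f"design samples absent from table: {missing_cols}")
    sub = table[cols].dropna(axis=0, how="any")
    logged = np.log10(sub.to_numpy(dtype=float) + pseudo_intensity)
    mean = logged.mean(axis=1, keepdims=True)
    sd = logged.std(axis=1, keepdims=True, ddof=0)
    centered = logged - mean
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, centered / sd, 0.0)
    return pd.DataFrame(z, index=sub.index, columns=cols)


@dataclass(frozen=True)
class ClusterModel:
    """A K-means partition of standardized profiles.

    ``assignments`` maps each protein to a cluster id in 1..k; ``centroids``
    is the (k, n_samples) array of cluster centers in standardized space.
    """

    k: int
    assignments: pd.Series
    centroids: np.ndarray
    inertia: float
    seed: int

    def members(self, cluster_id: int) -> pd.Index:
        return self.assignments.index[self.assignments == cluster_id]


def kmeans_profiles(standardized: pd.DataFrame, k: int = 27, seed: int = 0,
                    n_init: int = 10, max_iter: int = 300) -> ClusterModel:
    """Partition standardized profiles with seeded K-means (k-means++ init).

    Best of ``n_init`` restarts by inertia; deterministic given ``seed``.
    """
    n = standardized.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of proteins ({n})")
    if k < 1:
        raise ValueError("k must be >= 1")
    km = KMeans(n_clusters=k, n_init=n_init, max_iter=max_iter,
                random_state=seed, init="k-means++")
    labels = km.fit_predict(standardized.to_numpy(dtype=float))
    assignments = pd.Series(labels + 1, index=standardized.index, name="cluster")
    return ClusterModel(k=k, assignments=assignments, centroids=km.cluster_centers_,
                        inertia=float(km.inertia_), seed=seed)


@dataclass(frozen=True)
class ClusterPatternMatch:
    """One empirical cluster matched to a theoretical ternary pattern."""

    cluster_id: int
    matched_pattern: PatternCode | None
    spa_associated: bool
    n_members: int
    representative_profile: tuple[float, ...]
    empty: bool = False


def match_clusters_to_patterns(model: ClusterModel, table: pd.DataFrame,
                               design: DoseDesign,
                               params: DirectionParams | None = None,
                               ) -> list[ClusterPatternMatch]:
    """Direction-code each cluster's per-dose median raw profile.

    The representative profile of a cluster is the per-sample median of its
    members' raw intensities (medians ignore missing values), which keeps the
    fold threshold interpretable on the measurement scale.  Empty clusters
    are reported with ``empty=True`` rather than dropped.  The mapping from
    clusters to theoretical patterns may be many-to-one.
    """
    params = params or DirectionParams()
    unknown = model.assignments.index.difference(table.index)
    if len(unknown):
        raise ValueError(f"cluster members absent from table: {list(unknown[:5])}")
    cols = list(design.all_samples)
    matches = []
    for cid in range(1, model.k + 1):
        members = model.members(cid)
        if len(members) == 0:
            matches.append(ClusterPatternMatch(
                cluster_id=cid, matched_pattern=None, spa_associated=False,
                n_members=0, representative_profile=(), empty=True))
            continue
        profile = table.loc[members, cols].median(axis=0, skipna=True)
        code = call_directions(profile.to_numpy(dtype=float), params)
        spa = bool(code is not None and is_spa_associated(code, design))
        matches.append(ClusterPatternMatch(
            cluster_id=cid, matched_pattern=code, spa_associated=spa,
            n_members=int(len(members)),
            representative_profile=tuple(float(x) for x in profile)))
    return matches


def matches_to_frame(matches: Sequence[ClusterPatternMatch]) -> pd.DataFrame:
    """Tabulate cluster-pattern matches for export."""
    rows = []
    for m in matches:
        rows.append({
            "cluster": m.cluster_id,
            "pattern": "" if m.matched_pattern is None else str(m.matched_pattern),
            "pattern_index": -1 if m.matched_pattern is None else m.matched_pattern.index,
            "spa_associated": m.spa_associated,
            "n_members": m.n_members,
            "empty": m.empty,
        })
    return pd.DataFrame(rows).set_index("cluster")
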