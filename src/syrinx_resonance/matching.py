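"""Matching predicted bulla resonances to spectral peaks of call types.

A species "matches" at a tolerance when the Helmholtz prediction for any of
its bullae falls within that tolerance of a peak in the power spectrum of
any of its call types (optionally restricted to courtship calls).  The
500/1000 Hz tolerances bracket the uncertainty that ±1 mm measurement error
on neck geometry induces in the predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PeakMatch",
    "MatchResult",
    "MatchSummary",
    "match_prediction",
    "species_summary",
    "permutation_chance_rate",
]

DEFAULT_TOLERANCES_HZ = (500.0, 1000.0)


@dataclass(frozen=True)
class PeakMatch:
    """Nearest-peak lookup for a single prediction.

    ``nearest_peak_hz`` and ``distance_hz`` are None when the peak list is
    empty; ``within`` maps each tolerance to a boolean (inclusive
    boundary).
    """

    prediction_hz: float
    nearest_peak_hz: float | None
    distance_hz: float | None
    within: dict = field(default_factory=dict)

    @property
    def within_500(self) -> bool:
        return self.within.get(500.0, False)

    @property
    def within_1000(self) -> bool:
        return self.within.get(1000.0, False)


@dataclass(frozen=True)
class MatchResult:
    """Match outcome for one species x call type, possibly two bullae."""

    species_name: str
    call_type: str
    side_matches: dict  # side label -> PeakMatch

    def best_distance(self) -> float | None:
        ds = [
            m.distance_hz
            for m in self.side_matches.values()
            if m.distance_hz is not None
        ]
        return min(ds) if ds else None

    def within(self, tolerance_hz: float) -> bool:
        return any(
            m.within.get(tolerance_hz, False)
            for m in self.side_matches.values()
        )


@dataclass(frozen=True)
class MatchSummary:
    """Species-level tolerance counts over all call-type results."""

    n_species: int
    n_within: dict  # tolerance -> count of matched species
    per_species: dict  # species -> list of MatchResult

    @property
    def n_within_500(self) -> int:
        return self.n_within.get(500.0, 0)

    @property
    def n_within_1000(self) -> int:
        return self.n_within.get(1000.0, 0)


def match_prediction(
    prediction_hz: float,
    peaks_hz: Sequence[float],
    tolerances_hz: Sequence[float] = DEFAULT_TOLERANCES_HZ,
) -> PeakMatch:
    """Distance from a predicted resonance to the nearest spectral peak.

    Ties between equidistant peaks break toward the lower frequency; the
    tolerance boundary is inclusive (a distance of exactly 500 Hz counts
    as within 500 Hz).
    """
    tolerances = [float(t) for t in tolerances_hz]
    if sorted(tolerances) != tolerances:
        raise ValueError("tolerances must be ascending")
    if not peaks_hz:
        return PeakMatch(
            prediction_hz=float(prediction_hz),
            nearest_peak_hz=None,
            distance_hz=None,
            within={t: False for t in tolerances},
        )
    peaks = sorted(float(p) for p in peaks_hz)
    dists = [abs(prediction_hz - p) for p in peaks]
    best = int(np.argmin(dists))  # argmin takes the first, i.e. lower, peak
    return PeakMatch(
        prediction_hz=float(prediction_hz),
        nearest_peak_hz=peaks[best],
        distance_hz=dists[best],
        within={t: dists[best] <= t for t in tolerances},
    )


def species_summary(
    results: Iterable[MatchResult],
    tolerances_hz: Sequence[float] = DEFAULT_TOLERANCES_HZ,
    courtship_only: bool = False,
) -> MatchSummary:
    """Aggregate match results to species-level counts.

    A species counts as matched at a tolerance when *any* of its call-type
    x bulla-side results is within the tolerance.  With
    ``courtship_only=True``, only call types whose name contains
    "courtship" (case-insensitive) are considered.
    """
    tolerances = [float(t) for t in tolerances_hz]
    per_species: dict[str, list[MatchResult]] = {}
    for r in results:
        if courtship_only and "courtship" not in r.call_type.lower():
            continue
        per_species.setdefault(r.species_name, []).append(r)
    n_within = {
        t: sum(
            1
            for species_results in per_species.values()
            if any(r.within(t) for r in species_results)
        )
        for t in tolerances
    }
    return MatchSummary(
        n_species=len(per_species),
        n_within=n_within,
        per_species=per_species,
    )


def permutation_chance_rate(
    predictions_hz: Mapping[str, float],
    peaks_by_species: Mapping[str, Sequence[float]],
    tolerance_hz: float = 500.0,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> float:
    """Chance rate of tolerance matches under prediction shuffling.

    Randomly reassigns predictions to species' peak lists and returns the
    mean fraction of species matched at the tolerance — a reference point
    for judging whether an observed match fraction exceeds chance.
    """
    rng = np.random.default_rng(seed)
    species = list(peaks_by_species)
    preds = np.asarray([predictions_hz[s] for s in species])
    fractions = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(len(species))
        hits = sum(
            match_prediction(preds[perm[j]], peaks_by_species[s], [tolerance_hz])
            .within[tolerance_hz]
            for j, s in enumerate(species)
        )
        fractions[i] = hits / len(species)
    return float(fractions.mean())
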