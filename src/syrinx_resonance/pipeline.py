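"""High-level analysis chains built from the per-stage modules.

These are the compositions the command-line interface and the test-suite
run: geometry table -> predictions; recording -> harmonic profile; cohort
of recordings -> per-session summaries and sex trajectories.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .geometry import (
    AcousticConstants,
    BullaSpecimen,
    ResonancePrediction,
    helmholtz_frequency,
)
from .ontogeny import SessionSummary, Trajectory, build_trajectory, summarise_session
from .spectra import (
    CallRecording,
    HarmonicProfile,
    central_segment,
    estimate_fundamental,
    harmonic_amplitudes,
    power_spectrum,
)

__all__ = [
    "predict_table",
    "analyse_call",
    "analyse_cohort",
]


def predict_table(
    specimens: Iterable[BullaSpecimen],
    constants: AcousticConstants | None = None,
) -> list[ResonancePrediction]:
    """Helmholtz predictions for every specimen in a table."""
    constants = constants or AcousticConstants()
    return [helmholtz_frequency(s, constants) for s in specimens]


def analyse_call(
    recording: CallRecording,
    segment_fraction: float = 0.5,
    search_hz: tuple[float, float] = (500.0, 6000.0),
) -> HarmonicProfile | None:
    """Extract the harmonic profile of one call.

    Estimates the mean fundamental over the central segment of the call,
    then reads the relative amplitudes of FF/F2/F3 off the call's power
    spectrum.  Returns None when no periodicity is found.
    """
    seg = central_segment(0.0, recording.duration_s, segment_fraction)
    ff = estimate_fundamental(recording, segment=seg, search_hz=search_hz)
    if ff is None:
        return None
    spectrum = power_spectrum(recording)
    return harmonic_amplitudes(spectrum, ff, segment=seg)


def analyse_cohort(
    recordings: Sequence[CallRecording],
    segment_fraction: float = 0.5,
) -> tuple[list[SessionSummary], Trajectory, Trajectory]:
    """Run the full ontogeny chain on a cohort of annotated recordings.

    Recordings must carry ``bird_id, sex, age_days`` metadata (as the
    cohort simulator provides).  Unvoiced calls are dropped.  Returns the
    per-bird-per-age session summaries and the male and female
    trajectories.
    """
    sessions: dict[tuple[str, str, int], list[HarmonicProfile]] = {}
    for rec in recordings:
        meta = rec.metadata
        key = (str(meta["bird_id"]), str(meta["sex"]), int(meta["age_days"]))
        profile = analyse_call(rec, segment_fraction)
        if profile is not None:
            sessions.setdefault(key, []).append(profile)
    summaries = [
        summarise_session(profiles, bird_id=k[0], sex=k[1], age_days=k[2])
        for k, profiles in sorted(sessions.items())
    ]
    traj_m = build_trajectory([s for s in summaries if s.sex == "M"], "M")
    traj_f = build_trajectory([s for s in summaries if s.sex == "F"], "F")
    return summaries, traj_m, traj_f
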