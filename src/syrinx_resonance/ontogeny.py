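"""Developmental trajectories of duckling contact calls.

Mallard ducklings of both sexes give loud contact (isolation) calls whose
fundamental frequency declines as the birds grow.  Because only males grow
a syringeal bulla, comparing the harmonic energy distribution of male and
female calls across ontogeny tests whether the bulla shapes the juvenile
call spectrum: a resonance match would boost a specific harmonic in males
only, at the age where the harmonic sweeps through the bulla's resonance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .spectra import HarmonicProfile

__all__ = [
    "SessionSummary",
    "Trajectory",
    "summarise_session",
    "build_trajectory",
    "sex_contrast",
    "sessions_to_frame",
]

_BANDS = ("FF", "F2", "F3")


@dataclass(frozen=True)
class SessionSummary:
    """Per-recording-session call statistics for one bird.

    ``sd_rel_amp_db`` (and ``sd_ff_hz``) are NaN when the session holds a
    single call — an n-1 standard deviation is undefined there and a NaN
    flag is more honest than a zero.
    """

    bird_id: str
    sex: str
    age_days: int
    n_calls: int
    mean_ff_hz: float
    sd_ff_hz: float
    mean_rel_amp_db: dict
    sd_rel_amp_db: dict


@dataclass(frozen=True)
class Trajectory:
    """Group mean ± sd of FF and harmonic amplitudes per age, one sex."""

    sex: str
    ages: tuple[int, ...]
    mean_ff_hz: np.ndarray
    sd_ff_hz: np.ndarray
    mean_rel_amp_db: dict  # band -> array over ages
    sd_rel_amp_db: dict


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else float("nan")
    return mean, sd


def summarise_session(
    calls: Iterable[HarmonicProfile],
    bird_id: str,
    sex: str,
    age_days: int,
) -> SessionSummary:
    """Mean and n-1 sd of FF and relative harmonic amplitudes over the
    calls of one recording session (nominally 15 loud calls)."""
    profiles = list(calls)
    if not profiles:
        raise ValueError("summarise_session needs at least one call profile")
    if sex not in ("M", "F"):
        raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")
    mean_ff, sd_ff = _mean_sd([p.fundamental_hz for p in profiles])
    mean_amp: dict[str, float] = {}
    sd_amp: dict[str, float] = {}
    for band in _BANDS:
        mean_amp[band], sd_amp[band] = _mean_sd(
            [p.rel_amp_db[band] for p in profiles]
        )
    return SessionSummary(
        bird_id=bird_id,
        sex=sex,
        age_days=int(age_days),
        n_calls=len(profiles),
        mean_ff_hz=mean_ff,
        sd_ff_hz=sd_ff,
        mean_rel_amp_db=mean_amp,
        sd_rel_amp_db=sd_amp,
    )


def build_trajectory(
    summaries: Iterable[SessionSummary], sex: str
) -> Trajectory:
    """Cohort trajectory: across-bird mean ± sd per age for one sex.

    Input order is irrelevant; ages are sorted ascending.  All summaries
    must carry the stated sex.
    """
    sessions = [s for s in summaries]
    if any(s.sex != sex for s in sessions):
        raise ValueError(f"all summaries must have sex {sex!r}")
    if not sessions:
        raise ValueError("no sessions supplied")
    by_age: dict[int, list[SessionSummary]] = {}
    for s in sessions:
        by_age.setdefault(s.age_days, []).append(s)
    ages = tuple(sorted(by_age))
    mean_ff = np.empty(len(ages))
    sd_ff = np.empty(len(ages))
    mean_amp = {b: np.empty(len(ages)) for b in _BANDS}
    sd_amp = {b: np.empty(len(ages)) for b in _BANDS}
    for i, age in enumerate(ages):
        group = by_age[age]
        mean_ff[i], sd_ff[i] = _mean_sd([s.mean_ff_hz for s in group])
        for b in _BANDS:
            mean_amp[b][i], sd_amp[b][i] = _mean_sd(
                [s.mean_rel_amp_db[b] for s in group]
            )
    return Trajectory(
        sex=sex,
        ages=ages,
        mean_ff_hz=mean_ff,
        sd_ff_hz=sd_ff,
        mean_rel_amp_db=mean_amp,
        sd_rel_amp_db=sd_amp,
    )


def sex_contrast(traj_m: Trajectory, traj_f: Trajectory) -> pd.DataFrame:
    """Male-minus-female differences per shared age, with propagated sd.

    Returns a DataFrame indexed by age with ``d_ff_hz``, ``d_ff_sd`` and
    ``d_<band>_db`` / ``d_<band>_sd`` columns; sds propagate in quadrature.
    Ages present in only one trajectory are dropped (error if none are
    shared).
    """
    common = sorted(set(traj_m.ages) & set(traj_f.ages))
    if not common:
        raise ValueError("trajectories share no ages")
    im = [traj_m.ages.index(a) for a in common]
    if_ = [traj_f.ages.index(a) for a in common]
    out: dict[str, np.ndarray] = {
        "d_ff_hz": traj_m.mean_ff_hz[im] - traj_f.mean_ff_hz[if_],
        "d_ff_sd": np.hypot(traj_m.sd_ff_hz[im], traj_f.sd_ff_hz[if_]),
    }
    for b in _BANDS:
        out[f"d_{b.lower()}_db"] = (
            traj_m.mean_rel_amp_db[b][im] - traj_f.mean_rel_amp_db[b][if_]
        )
        out[f"d_{b.lower()}_sd"] = np.hypot(
            traj_m.sd_rel_amp_db[b][im], traj_f.sd_rel_amp_db[b][if_]
        )
    return pd.DataFrame(out, index=pd.Index(common, name="age_days"))


def sessions_to_frame(summaries: Iterable[SessionSummary]) -> pd.DataFrame:
    """Flatten session summaries into a tidy DataFrame for CSV export."""
    rows = []
    for s in summaries:
        row = {
            "bird_id": s.bird_id,
            "sex": s.sex,
            "age_days": s.age_days,
            "n_calls": s.n_calls,
            "mean_ff_hz": s.mean_ff_hz,
            "sd_ff_hz": s.sd_ff_hz,
        }
        for b in _BANDS:
            row[f"mean_{b.lower()}_db"] = s.mean_rel_amp_db[b]
            row[f"sd_{b.lower()}_db"] = s.sd_rel_amp_db[b]
        rows.append(row)
    return pd.DataFrame(rows)
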