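"""CSV input/output for specimen geometry and resonance predictions.

The specimen table schema is::

    species,catalog_id,side,volume_mm3,opening_diameter_mm,neck_length_mm

with a mandatory header; unknown columns are carried through as opaque
per-specimen metadata.  A bundled table of µCT-measured bullae from the
Harvard Museum of Comparative Zoology ornithology collection ships with
the package (see :func:`load_reference_specimens`).
"""

from __future__ import annotations

import wave
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import BullaSpecimen, ResonancePrediction, Side
from .spectra import CallRecording, PowerSpectrum

__all__ = [
    "read_specimen_table",
    "write_specimen_table",
    "write_predictions",
    "read_predictions",
    "load_reference_specimens",
    "read_wav",
    "write_wav",
    "write_spectrum",
    "read_spectrum",
]

_CORE_COLUMNS = [
    "species",
    "catalog_id",
    "side",
    "volume_mm3",
    "opening_diameter_mm",
    "neck_length_mm",
]

_GEOMETRY_COLUMNS = ["volume_mm3", "opening_diameter_mm", "neck_length_mm"]


class SpecimenTableError(ValueError):
    """Malformed specimen CSV (missing column, bad value, empty file)."""


def read_specimen_table(path: str | Path) -> list[BullaSpecimen]:
    """Read a specimen geometry CSV into :class:`BullaSpecimen` records.

    Raises :class:`SpecimenTableError` naming the offending row and column
    on missing mandatory columns or non-numeric geometry.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise SpecimenTableError(f"{path}: empty specimen table") from exc
    missing = [c for c in _CORE_COLUMNS if c not in frame.columns]
    if missing:
        raise SpecimenTableError(
            f"{path}: missing mandatory column(s) {', '.join(missing)}"
        )
    extra_cols = [c for c in frame.columns if c not in _CORE_COLUMNS]
    specimens: list[BullaSpecimen] = []
    for idx, row in frame.iterrows():
        geometry = {}
        for col in _GEOMETRY_COLUMNS:
            try:
                geometry[col] = float(row[col])
            except (TypeError, ValueError) as exc:
                raise SpecimenTableError(
                    f"{path}: row {idx + 2}, column {col!r}: "
                    f"non-numeric value {row[col]!r}"
                ) from exc
        try:
            side = Side(str(row["side"]).strip().lower())
        except ValueError as exc:
            raise SpecimenTableError(
                f"{path}: row {idx + 2}, column 'side': {row['side']!r} "
                "is not 'left' or 'right'"
            ) from exc
        specimens.append(
            BullaSpecimen(
                species_name=str(row["species"]),
                catalog_id=str(row["catalog_id"]),
                side=side,
                metadata={c: row[c] for c in extra_cols},
                **geometry,
            )
        )
    return specimens


def _specimen_frame(specimens: Sequence[BullaSpecimen]) -> pd.DataFrame:
    extra_keys: list[str] = []
    for s in specimens:
        for k in s.metadata:
            if k not in extra_keys:
                extra_keys.append(k)
    rows = []
    for s in specimens:
        row = {
            "species": s.species_name,
            "catalog_id": s.catalog_id,
            "side": s.side.value,
            "volume_mm3": s.volume_mm3,
            "opening_diameter_mm": s.opening_diameter_mm,
            "neck_length_mm": s.neck_length_mm,
        }
        row.update({k: s.metadata.get(k) for k in extra_keys})
        rows.append(row)
    return pd.DataFrame(rows, columns=_CORE_COLUMNS + extra_keys)


def write_specimen_table(
    path: str | Path, specimens: Sequence[BullaSpecimen]
) -> None:
    """Write specimens back to CSV (lossless round trip with the reader)."""
    _specimen_frame(specimens).to_csv(path, index=False)


def write_predictions(
    path: str | Path, predictions: Iterable[ResonancePrediction]
) -> None:
    """Write resonance predictions: specimen columns plus
    ``effective_neck_length_mm, resonance_hz, speed_of_sound_m_s``."""
    preds = list(predictions)
    frame = _specimen_frame([p.specimen for p in preds])
    frame["effective_neck_length_mm"] = [p.effective_neck_length_mm for p in preds]
    frame["resonance_hz"] = [p.resonance_hz for p in preds]
    frame["speed_of_sound_m_s"] = [p.speed_of_sound_m_s for p in preds]
    frame.to_csv(path, index=False)


def read_predictions(path: str | Path) -> pd.DataFrame:
    """Read a predictions CSV as a DataFrame (one row per bulla)."""
    frame = pd.read_csv(path)
    missing = [
        c
        for c in _CORE_COLUMNS + ["resonance_hz"]
        if c not in frame.columns
    ]
    if missing:
        raise SpecimenTableError(
            f"{path}: missing column(s) {', '.join(missing)}"
        )
    return frame


def read_wav(path: str | Path, metadata: dict | None = None) -> CallRecording:
    """Read a PCM WAV file (8/16/24/32-bit) into a CallRecording.

    Samples are scaled to [-1, 1]; stereo files are down-mixed to mono by
    channel mean (with a warning) inside CallRecording.
    """
    with wave.open(str(path), "rb") as wf:
        n_channels = wf.getnchannels()
        width = wf.getsampwidth()
        rate = wf.getframerate()
        raw = wf.readframes(wf.getnframes())
    if width == 1:
        data = np.frombuffer(raw, dtype=np.uint8).astype(float)
        data = (data - 128.0) / 128.0
    elif width == 2:
        data = np.frombuffer(raw, dtype="<i2").astype(float) / 32768.0
    elif width == 3:
        b = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 3)
        as32 = (
            b[:, 0].astype(np.int32)
            | (b[:, 1].astype(np.int32) << 8)
            | (b[:, 2].astype(np.int32) << 16)
        )
        as32 = np.where(as32 >= 2**23, as32 - 2**24, as32)
        data = as32.astype(float) / 2**23
    elif width == 4:
        data = np.frombuffer(raw, dtype="<i4").astype(float) / 2**31
    else:
        raise ValueError(f"unsupported WAV sample width: {width} bytes")
    if n_channels > 1:
        data = data.reshape(-1, n_channels)
    return CallRecording(
        samples=data, sample_rate_hz=rate, metadata=dict(metadata or {})
    )


def write_wav(path: str | Path, recording: CallRecording) -> None:
    """Write a CallRecording as 16-bit PCM mono WAV."""
    scaled = np.clip(recording.samples, -1.0, 1.0)
    pcm = (scaled * 32767.0).astype("<i2")
    with wave.open(str(path), "wb") as wf:
        wf.setnchannels(1)
        wf.setsampwidth(2)
        wf.setframerate(recording.sample_rate_hz)
        wf.writeframes(pcm.tobytes())


def write_spectrum(path: str | Path, spectrum: PowerSpectrum) -> None:
    """Write a spectrum as a two-column ``frequency_hz,level_db`` CSV."""
    pd.DataFrame(
        {
            "frequency_hz": spectrum.frequencies_hz,
            "level_db": spectrum.level_db,
        }
    ).to_csv(path, index=False)


def read_spectrum(path: str | Path) -> PowerSpectrum:
    """Read a ``frequency_hz,level_db`` CSV back into a PowerSpectrum."""
    frame = pd.read_csv(path)
    for col in ("frequency_hz", "level_db"):
        if col not in frame.columns:
            raise SpecimenTableError(f"{path}: missing column {col!r}")
    return PowerSpectrum(
        frame["frequency_hz"].to_numpy(), frame["level_db"].to_numpy()
    )


def load_reference_specimens() -> list[BullaSpecimen]:
    """The packaged µCT reference table: 31 bullae from 17 duck species
    (28 left, 3 species with an additional right bulla)."""
    ref = resources.files("syrinx_resonance.data") / "mcz_bulla_specimens.csv"
    with resources.as_file(ref) as path:
        return read_specimen_table(path)
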