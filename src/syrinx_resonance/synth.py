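"""Synthetic inputs with known ground truth for the whole pipeline.

Real duck-call recordings and museum phylogenies cannot be bundled, so
every pipeline stage has a generator here that emulates its input with a
planted, recoverable ground truth: harmonic calls with hat-shaped
fundamental-frequency contours, duckling cohorts with an age-declining FF
and a male-only second-harmonic boost, specimen geometry tables, spectra
with planted peaks, and Brownian trait evolution on trees.  Every
generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .geometry import AcousticConstants, BullaSpecimen, Side, helmholtz_frequency
from .spectra import CallRecording, PowerSpectrum

__all__ = [
    "CallSpec",
    "CohortSpec",
    "hat_contour",
    "synthesize_call",
    "simulate_cohort",
    "simulate_specimens",
    "plant_peak_spectrum",
    "simulate_brownian_traits",
    "random_binary_tree",
    "TABLE_RANGES",
]

#: Geometry envelope of the µCT reference collection, used as the default
#: sampling ranges for simulated specimens (mm^3, mm, mm).
TABLE_RANGES = {
    "volume_mm3": (1055.0, 8432.0),
    "opening_diameter_mm": (2.96, 9.7),
    "neck_length_mm": (0.54, 3.8),
}


def hat_contour(
    plateau_hz: float,
    duration_s: float = 0.2,
    rise_fraction: float = 0.25,
    onset_drop_hz: float = 300.0,
) -> list[tuple[float, float]]:
    """Hat-shaped FF contour: rise at onset, plateau, fall at offset.

    Duckling contact calls rise into a plateau and fall at the offset;
    the default 25% rise/fall segments and a 300 Hz onset/offset drop
    emulate that shape.
    """
    return [
        (0.0, plateau_hz - onset_drop_hz),
        (rise_fraction * duration_s, plateau_hz),
        ((1.0 - rise_fraction) * duration_s, plateau_hz),
        (duration_s, plateau_hz - onset_drop_hz),
    ]


@dataclass(frozen=True)
class CallSpec:
    """Specification of one synthetic harmonic call.

    ``ff_contour`` is a piecewise-linear map time -> Hz;
    ``harmonic_gains_db`` gives the gain of harmonics 1..K relative to the
    loudest (<= 0 dB each, conventionally 0 for the fundamental);
    ``noise_floor_db`` sets the white-noise floor relative to the loudest
    harmonic.
    """

    ff_contour: tuple = ((0.0, 2200.0), (0.05, 2500.0), (0.15, 2500.0), (0.2, 2200.0))
    harmonic_gains_db: tuple = (0.0, -25.0, -35.0)
    duration_s: float = 0.2
    noise_floor_db: float = -60.0
    sample_rate_hz: int = 44100
    seed: int = 0

    def __post_init__(self) -> None:
        times = [t for t, _ in self.ff_contour]
        freqs = [f for _, f in self.ff_contour]
        if any(f <= 0 for f in freqs):
            raise ValueError("FF contour must be strictly positive")
        if sorted(times) != list(times):
            raise ValueError("contour times must be ascending")
        k = len(self.harmonic_gains_db)
        if k * max(freqs) >= self.sample_rate_hz / 2:
            raise ValueError(
                f"harmonic {k} of max FF {max(freqs):.0f} Hz exceeds Nyquist "
                f"({self.sample_rate_hz / 2:.0f} Hz)"
            )


def synthesize_call(spec: CallSpec) -> CallRecording:
    """Render a CallSpec to audio by phase-continuous additive synthesis.

    Each harmonic k tracks k times the instantaneous FF through a shared
    cumulative phase, so the waveform stays periodic under frequency
    modulation; white Gaussian noise is added at the stated floor.
    Bit-identical for identical specs.
    """
    fs = spec.sample_rate_hz
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs
    times = np.array([p[0] for p in spec.ff_contour])
    freqs = np.array([p[1] for p in spec.ff_contour])
    inst_ff = np.interp(t, times, freqs)
    phase = 2.0 * math.pi * np.cumsum(inst_ff) / fs
    x = np.zeros(n)
    for k, gain_db in enumerate(spec.harmonic_gains_db, start=1):
        x += 10.0 ** (gain_db / 20.0) * np.sin(k * phase)
    rng = np.random.default_rng(spec.seed)
    peak_amp = 10.0 ** (max(spec.harmonic_gains_db) / 20.0)
    x += peak_amp * 10.0 ** (spec.noise_floor_db / 20.0) * rng.standard_normal(n)
    x *= 0.9 / np.max(np.abs(x))
    return CallRecording(
        samples=x,
        sample_rate_hz=fs,
        metadata={"synthetic": True, "seed": spec.seed},
    )


@dataclass(frozen=True)
class CohortSpec:
    """A simulated duckling cohort: the study conditions of the ontogeny
    comparison (4 males + 4 females, 7 weekly sessions from day 4, 15
    calls per session) with a planted age-declining FF and a +20 dB
    second-harmonic boost in males at day 32 only."""

    n_per_sex: int = 4
    ages_days: tuple = (4, 11, 18, 25, 32, 39, 46)
    calls_per_session: int = 15
    ff_day4_hz: float = 3400.0
    ff_day46_hz: float = 2200.0
    male_day32_f2_boost_db: float = 20.0
    boost_age_days: int = 32
    baseline_gains_db: tuple = (0.0, -25.0, -35.0)
    bird_ff_jitter_hz: float = 120.0
    call_ff_jitter_hz: float = 40.0
    gain_jitter_db: float = 1.5
    noise_floor_db: float = -60.0
    sample_rate_hz: int = 44100
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.ages_days) != sorted(self.ages_days):
            raise ValueError("ages_days must be ascending")

    def ff_at_age(self, age_days: float) -> float:
        """Planted linear FF decline over the recorded age span."""
        a0, a1 = self.ages_days[0], self.ages_days[-1]
        frac = (age_days - a0) / (a1 - a0)
        return self.ff_day4_hz + frac * (self.ff_day46_hz - self.ff_day4_hz)


def simulate_cohort(
    spec: CohortSpec | None = None,
) -> tuple[list[CallRecording], pd.DataFrame]:
    """Simulate the cohort's recordings with a ground-truth table.

    Returns (recordings, truth) where each recording's metadata carries
    ``bird_id, sex, age_days, call_index`` and ``truth`` is a DataFrame
    with the planted per-call FF and harmonic gains.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    recordings: list[CallRecording] = []
    rows = []
    for sex_i, sex in enumerate(("M", "F")):
        for b in range(spec.n_per_sex):
            bird_id = f"{sex}{b + 1}"
            bird_offset = rng.normal(0.0, spec.bird_ff_jitter_hz)
            for age in spec.ages_days:
                for call_i in range(spec.calls_per_session):
                    ff = (
                        spec.ff_at_age(age)
                        + bird_offset
                        + rng.normal(0.0, spec.call_ff_jitter_hz)
                    )
                    gains = list(spec.baseline_gains_db)
                    if sex == "M" and age == spec.boost_age_days:
                        gains[1] += spec.male_day32_f2_boost_db
                    gains = [
                        g + rng.normal(0.0, spec.gain_jitter_db) if k > 0 else g
                        for k, g in enumerate(gains)
                    ]
                    call_seed = int(
                        rng.integers(0, 2**31 - 1)
                    )  # drawn from the cohort stream: reproducible per spec.seed
                    call = synthesize_call(
                        CallSpec(
                            ff_contour=tuple(hat_contour(ff)),
                            harmonic_gains_db=tuple(gains),
                            noise_floor_db=spec.noise_floor_db,
                            sample_rate_hz=spec.sample_rate_hz,
                            seed=call_seed,
                        )
                    )
                    call.metadata.update(
                        bird_id=bird_id, sex=sex, age_days=age, call_index=call_i
                    )
                    recordings.append(call)
                    rows.append(
                        {
                            "bird_id": bird_id,
                            "sex": sex,
                            "age_days": age,
                            "call_index": call_i,
                            "true_ff_hz": ff,
                            "true_ff_gain_db": gains[0],
                            "true_f2_gain_db": gains[1],
                            "true_f3_gain_db": gains[2],
                        }
                    )
    return recordings, pd.DataFrame(rows)


def simulate_specimens(
    n: int,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
    constants: AcousticConstants | None = None,
) -> pd.DataFrame:
    """Draw n synthetic bulla geometries with ground-truth resonances.

    Geometry is uniform within ``ranges`` (defaults to the reference
    collection's envelope); the returned frame pairs each specimen with
    its Helmholtz prediction.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = dict(TABLE_RANGES, **(ranges or {}))
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        geom = {
            key: float(rng.uniform(*ranges[key]))
            for key in ("volume_mm3", "opening_diameter_mm", "neck_length_mm")
        }
        specimen = BullaSpecimen(
            species_name=f"synthetic_{i}",
            catalog_id=f"SYN:{seed}:{i}",
            side=Side.LEFT,
            **geom,
        )
        pred = helmholtz_frequency(specimen, constants)
        rows.append(
            {
                "species": specimen.species_name,
                "catalog_id": specimen.catalog_id,
                "side": "left",
                **geom,
                "true_resonance_hz": pred.resonance_hz,
            }
        )
    return pd.DataFrame(rows)


def plant_peak_spectrum(
    peaks_hz: Sequence[float],
    widths_hz: Sequence[float] | float = 80.0,
    floor_db: float = -40.0,
    grid_hz: np.ndarray | None = None,
    peak_gains_db: Sequence[float] | None = None,
) -> PowerSpectrum:
    """A spectrum of Lorentzian peaks over a flat noise floor.

    Used to test peak detection and resonance matching against known peak
    positions; an empty peak list yields the flat floor.
    """
    if grid_hz is None:
        grid_hz = np.linspace(0.0, 22050.0, 2206)
    grid_hz = np.asarray(grid_hz, dtype=float)
    peaks = list(peaks_hz)
    if np.isscalar(widths_hz):
        widths = [float(widths_hz)] * len(peaks)
    else:
        widths = [float(w) for w in widths_hz]
    gains = (
        [0.0] * len(peaks)
        if peak_gains_db is None
        else [float(g) for g in peak_gains_db]
    )
    if not (len(peaks) == len(widths) == len(gains)):
        raise ValueError("peaks, widths and gains must align")
    power = np.full(grid_hz.size, 10.0 ** (floor_db / 10.0))
    for f0, w, g in zip(peaks, widths, gains):
        if not 0 <= f0 <= grid_hz[-1]:
            raise ValueError(f"peak at {f0} Hz outside the grid")
        power += 10.0 ** (g / 10.0) * w**2 / ((grid_hz - f0) ** 2 + w**2)
    level = 10.0 * np.log10(power)
    return PowerSpectrum(grid_hz, level - level.max())


def random_binary_tree(
    n_tips: int, seed: int = 0, taxon_prefix: str = "sp"
) -> dendropy.Tree:
    """A random rooted binary tree with positive branch lengths
    (Kingman coalescent topology and times)."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    tns = dendropy.TaxonNamespace(
        [f"{taxon_prefix}{i + 1}" for i in range(n_tips)]
    )
    tree = treesim.pure_kingman_tree(
        taxon_namespace=tns, pop_size=1.0, rng=random.Random(seed)
    )
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None and (
            edge.length is None or edge.length <= 0
        ):
            edge.length = 1e-6
    return tree


def _simulate_brownian(
    tree: dendropy.Tree, sigma: float, rng: np.random.Generator
) -> dict:
    """One Brownian realisation: independent N(0, sigma^2 * t) increments
    per edge, summed root-to-tip."""
    value = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        base = value[parent] if parent is not None else 0.0
        t = node.edge.length or 0.0
        value[node] = base + rng.normal(0.0, sigma * math.sqrt(t))
    return {
        leaf.taxon.label: value[leaf] for leaf in tree.leaf_node_iter()
    }


def simulate_brownian_traits(
    tree: dendropy.Tree,
    slope: float = 1.75,
    sigma_x: float = 1.0,
    sigma_resid: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Correlated trait evolution: x Brownian on the tree, y = slope*x
    plus an independent Brownian residual.

    The PIC (or PGLS) regression of y on x is unbiased for ``slope``;
    ``sigma_resid`` tunes the R² of the recovery.  Returns a DataFrame
    indexed by species with columns ``trait_x, trait_y``.
    """
    rng = np.random.default_rng(seed)
    x = _simulate_brownian(tree, sigma_x, rng)
    resid = _simulate_brownian(tree, sigma_resid, rng)
    species = sorted(x)
    return pd.DataFrame(
        {
            "trait_x": [x[s] for s in species],
            "trait_y": [slope * x[s] + resid[s] for s in species],
        },
        index=pd.Index(species, name="species"),
    )
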