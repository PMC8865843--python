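"""Synthetic vibrotactile study generator.

Emulates the statistical structure of a tool-mediated texture exploration
study: 7 material categories with ~11-12 samples each (81 materials), 11
participants, 10 s acceleration traces at 3200 Hz. Each category has a
distinct spectral envelope built from 2-4 Gaussian bumps in the 20-700 Hz
band; materials perturb their category envelope multiplicatively; each
participant scales the frequency axis by an uncontrolled exploration-speed
factor. Recordings additionally carry sub-10 Hz hand-movement drift and
broadband noise above 800 Hz so the band-pass stage has something to remove.

Ratings are derived from the same spectral structure the autoencoder sees:
descriptor ratings are a linear map of envelope summary attributes plus
participant noise, and category-similarity ratings follow the spectral
correlation between a material's envelope and each category's mean envelope
(peaking at the true category), with a configurable confusion probability.

All randomness flows through explicitly seeded numpy generators; the same
seed reproduces every array bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .perception import DESCRIPTORS, RatingTable
from .preprocessing import VibrationRecording

__all__ = [
    "FREQ_GRID",
    "MaterialSpec",
    "ParticipantSpec",
    "make_material_library",
    "make_participants",
    "synth_recording",
    "synth_dataset",
    "synth_ratings",
    "ground_truth_labels",
    "envelope_distance_matrix",
    "write_recordings",
    "read_recordings",
    "write_ratings",
    "read_ratings",
]

# 1 Hz bins over 0-1600 Hz (Nyquist of the canonical 3200 Hz rate)
FREQ_GRID = np.arange(0.0, 1601.0)

DEFAULT_CATEGORY_SIZES = (12, 12, 12, 12, 11, 11, 11)  # sums to 81


@dataclass
class MaterialSpec:
    """One material sample: category membership plus its spectral signature."""

    material_id: str
    category_id: int
    spectral_envelope: np.ndarray  # gain per FREQ_GRID bin, >= 0
    sample_jitter: np.ndarray  # multiplicative perturbation of the category base

    def __post_init__(self):
        if np.any(self.spectral_envelope < 0):
            raise ValueError("spectral envelope gains must be non-negative")


@dataclass
class ParticipantSpec:
    participant_id: int
    speed_factor: float  # scales temporal-frequency content (exploration speed)
    rating_noise_sd: float

    def __post_init__(self):
        if self.speed_factor <= 0:
            raise ValueError("speed_factor must be positive")


def _gaussian_bumps(rng: np.random.Generator, n_bumps: int, tilt_hz: float,
                    bump_width: tuple, bump_band: tuple) -> np.ndarray:
    centers = rng.uniform(bump_band[0], bump_band[1], n_bumps)
    widths = rng.uniform(bump_width[0], bump_width[1], n_bumps)
    amps = rng.uniform(0.5, 1.0, n_bumps)
    env = np.zeros_like(FREQ_GRID)
    for c, w, a in zip(centers, widths, amps):
        env += a * np.exp(-0.5 * ((FREQ_GRID - c) / w) ** 2)
    if tilt_hz > 0:
        # 1/f-like roll-off: acceleration spectra from natural exploration
        # are low-frequency dominated
        env *= 1.0 / np.sqrt(1.0 + (FREQ_GRID / tilt_hz) ** 2)
    return env


def make_material_library(
    n_categories: int = 7,
    materials_per_category=None,
    seed: int = 0,
    max_base_correlation: float = 0.8,
    jitter_sd: float = 0.5,
    spectral_tilt_hz: float = 150.0,
    bump_width: tuple = (6.0, 25.0),
    bump_band: tuple = (25.0, 450.0),
) -> list[MaterialSpec]:
    """Draw category base envelopes and per-material jittered envelopes.

    Category envelopes are mixtures of 2-4 Gaussian bumps in the 20-700 Hz
    band under a 1/f-like roll-off (corner ``spectral_tilt_hz``), redrawn
    until every pair correlates below ``max_base_correlation`` so categories
    stay spectrally distinct. Each material multiplies its category base by
    a smooth log-normal jitter field (``jitter_sd``), giving the sizeable
    within-category heterogeneity everyday material samples show.
    """
    if n_categories < 2:
        raise ValueError("need at least 2 categories")
    if materials_per_category is None:
        if n_categories == len(DEFAULT_CATEGORY_SIZES):
            materials_per_category = list(DEFAULT_CATEGORY_SIZES)
        else:
            raise ValueError("materials_per_category required when n_categories != 7")
    counts = [int(c) for c in materials_per_category]
    if len(counts) != n_categories:
        raise ValueError("one count per category required")
    if any(c <= 0 for c in counts):
        raise ValueError("material counts must be positive")

    rng = np.random.default_rng(seed)
    bases: list[np.ndarray] = []
    for _ in range(n_categories):
        for _attempt in range(500):
            env = _gaussian_bumps(rng, int(rng.integers(2, 5)), spectral_tilt_hz,
                                  bump_width, bump_band)
            if all(np.corrcoef(env, b)[0, 1] < max_base_correlation for b in bases):
                bases.append(env)
                break
        else:
            raise RuntimeError("could not draw sufficiently distinct category envelopes")

    materials = []
    idx = 0
    for cat, count in enumerate(counts):
        for _ in range(count):
            # smooth multiplicative jitter: a few broad log-gain bumps
            log_jitter = np.zeros_like(FREQ_GRID)
            for _b in range(3):
                c = rng.uniform(20.0, 800.0)
                w = rng.uniform(60.0, 200.0)
                a = rng.normal(0.0, jitter_sd)
                log_jitter += a * np.exp(-0.5 * ((FREQ_GRID - c) / w) ** 2)
            jitter = np.exp(log_jitter)
            materials.append(
                MaterialSpec(
                    material_id=f"m{idx:03d}",
                    category_id=cat,
                    spectral_envelope=bases[cat] * jitter,
                    sample_jitter=jitter,
                )
            )
            idx += 1
    return materials


def make_participants(
    n_participants: int = 11,
    seed: int = 0,
    rating_noise_sd: float = 0.3,
    speed_range: tuple = (0.8, 1.25),
) -> list[ParticipantSpec]:
    """Participants with log-uniform exploration-speed factors."""
    rng = np.random.default_rng(seed)
    lo, hi = np.log(speed_range[0]), np.log(speed_range[1])
    return [
        ParticipantSpec(
            participant_id=i,
            speed_factor=float(np.exp(rng.uniform(lo, hi))),
            rating_noise_sd=rating_noise_sd,
        )
        for i in range(n_participants)
    ]


def _shaped_noise(rng: np.random.Generator, n: int, rate_hz: float, gain: np.ndarray,
                  rms: float) -> np.ndarray:
    """White Gaussian noise spectrally shaped by ``gain`` (on the rfft grid)."""
    spectrum = np.fft.rfft(rng.standard_normal(n)) * gain
    y = np.fft.irfft(spectrum, n)
    cur = np.sqrt(np.mean(y**2))
    if cur > 0 and rms > 0:
        y *= rms / cur
    elif rms == 0:
        y = np.zeros(n)
    return y


def synth_recording(
    material: MaterialSpec,
    participant: ParticipantSpec,
    duration_s: float = 10.0,
    rate_hz: float = 3200.0,
    seed=0,
    drift_amplitude: float = 1.5,
    hf_noise_amplitude: float = 0.3,
    amplitude_jitter_sd: float = 0.2,
    saturation_sigma: float = 2.5,
) -> VibrationRecording:
    """Synthesize one (participant, material) acceleration trace.

    Gaussian noise is spectrally shaped by the material envelope evaluated at
    f / speed_factor (faster exploration shifts energy upward), scaled to
    unit RMS times a log-normal amplitude jitter, softly saturated at
    ``saturation_sigma`` times the texture RMS (sensor range and contact
    mechanics compress rare extreme excursions), then summed with sub-10 Hz
    drift and broadband >800 Hz noise.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    env = material.spectral_envelope
    support = FREQ_GRID[env > 1e-9 * max(env.max(), 1e-300)]
    f_max = float(support.max()) if support.size else 0.0
    if rate_hz <= 2.0 * f_max:
        raise ValueError(
            f"rate {rate_hz} Hz is below Nyquist for envelope support up to {f_max:.0f} Hz"
        )
    n = int(round(duration_s * rate_hz))
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)

    gain = np.interp(freqs / participant.speed_factor, FREQ_GRID, env, left=0.0, right=0.0)
    amp = float(np.exp(rng.normal(0.0, amplitude_jitter_sd))) if amplitude_jitter_sd > 0 else 1.0
    texture = _shaped_noise(rng, n, rate_hz, gain, rms=amp if env.max() > 0 else 0.0)
    if saturation_sigma > 0 and env.max() > 0:
        s = saturation_sigma * amp
        texture = s * np.tanh(texture / s)

    drift_gain = np.exp(-0.5 * ((freqs - 2.0) / 2.0) ** 2) * (freqs < 10.0)
    drift = _shaped_noise(rng, n, rate_hz, drift_gain, rms=drift_amplitude)

    hf_gain = np.clip((freqs - 900.0) / 100.0, 0.0, 1.0)
    hf = _shaped_noise(rng, n, rate_hz, hf_gain, rms=hf_noise_amplitude)

    return VibrationRecording(
        samples=texture + drift + hf,
        rate_hz=rate_hz,
        participant_id=participant.participant_id,
        material_id=material.material_id,
        category_id=material.category_id,
    )


def synth_dataset(materials, participants, duration_s: float = 10.0, rate_hz: float = 3200.0,
                  seed: int = 0, **kwargs) -> list[VibrationRecording]:
    """One recording per (participant, material), child-seeded from ``seed``."""
    out = []
    for participant in participants:
        for mi, material in enumerate(materials):
            child = int(np.random.SeedSequence([seed, participant.participant_id, mi]).generate_state(1)[0])
            out.append(
                synth_recording(material, participant, duration_s, rate_hz, seed=child, **kwargs)
            )
    return out


def _envelope_attributes(materials) -> np.ndarray:
    """Low-dimensional spectral summaries shared within category up to jitter."""
    rows = []
    for m in materials:
        env = m.spectral_envelope
        power = env.sum()
        centroid = (FREQ_GRID * env).sum() / power
        spread = np.sqrt(((FREQ_GRID - centroid) ** 2 * env).sum() / power)
        low = env[FREQ_GRID < 100].sum() / power
        mid = env[(FREQ_GRID >= 100) & (FREQ_GRID < 300)].sum() / power
        rows.append([np.log(power), centroid / 800.0, spread / 400.0, low, mid])
    attrs = np.asarray(rows)
    mean, sd = attrs.mean(axis=0), attrs.std(axis=0)
    sd[sd == 0] = 1.0
    return (attrs - mean) / sd


def _category_bases(materials, smooth_hz: float = 0.0) -> dict[int, np.ndarray]:
    cats = sorted({m.category_id for m in materials})
    out = {}
    for c in cats:
        env = np.mean([m.spectral_envelope for m in materials if m.category_id == c], axis=0)
        out[c] = gaussian_filter1d(env, smooth_hz) if smooth_hz > 0 else env
    return out


def synth_ratings(materials, participants, seed: int = 0, confusion: float = 0.15,
                  category_bonus: float = 0.3, smooth_hz: float = 30.0) -> RatingTable:
    """Simulate descriptor and category-similarity ratings.

    Descriptor ratings are a fixed linear map of each material's spectral
    attributes plus per-participant Gaussian noise. Category similarity is
    the (rescaled) spectral correlation between the material envelope and
    each category's mean envelope (both smoothed by ``smooth_hz``; perceived
    similarity tracks coarse spectral proximity, not line-by-line overlap)
    plus a bonus on the true category, so
    noiseless ratings always peak at the ground-truth category while noisy
    confusions fall on spectrally similar categories. With probability
    ``confusion`` a participant's similarity vector is replaced by uniform
    noise.
    """
    if not materials or not participants:
        raise ValueError("materials and participants must be non-empty")
    if not 0.0 <= confusion <= 1.0:
        raise ValueError("confusion must be a probability")
    rng = np.random.default_rng(seed)
    attrs = _envelope_attributes(materials)
    n_attr = attrs.shape[1]
    desc_map = rng.normal(0.0, 1.0, size=(len(DESCRIPTORS), n_attr))

    bases = _category_bases(materials, smooth_hz=smooth_hz)
    cats = sorted(bases)
    base_mat = np.stack([bases[c] for c in cats])
    sims = np.empty((len(materials), len(cats)))
    for i, m in enumerate(materials):
        env = gaussian_filter1d(m.spectral_envelope, smooth_hz) if smooth_hz > 0 else m.spectral_envelope
        ec = env - env.mean()
        bc = base_mat - base_mat.mean(axis=1, keepdims=True)
        corr = bc @ ec / (np.linalg.norm(bc, axis=1) * np.linalg.norm(ec) + 1e-300)
        sims[i] = 0.5 * (corr + 1.0)  # map [-1, 1] -> [0, 1]
        sims[i, cats.index(m.category_id)] += category_bonus

    desc_rows, cat_rows = [], []
    for p in participants:
        for i, m in enumerate(materials):
            values = desc_map @ attrs[i] + rng.normal(0.0, p.rating_noise_sd, len(DESCRIPTORS))
            for d, v in zip(DESCRIPTORS, values):
                desc_rows.append((p.participant_id, m.material_id, d, float(v)))
            if confusion > 0 and rng.random() < confusion:
                sim_vec = rng.uniform(0.0, 1.0, len(cats))
            else:
                sim_vec = np.clip(
                    sims[i] + rng.normal(0.0, 0.5 * p.rating_noise_sd, len(cats)), 0.0, 1.5
                )
            for c, s in zip(cats, sim_vec):
                cat_rows.append((p.participant_id, m.material_id, c, float(s), m.category_id))
    descriptors = pd.DataFrame(desc_rows, columns=["participant_id", "material_id", "descriptor", "value"])
    categories = pd.DataFrame(
        cat_rows, columns=["participant_id", "material_id", "category_id", "similarity", "true_category_id"]
    )
    return RatingTable(descriptors=descriptors, categories=categories)


def ground_truth_labels(materials) -> pd.Series:
    """material_id -> category_id for a material library."""
    return pd.Series(
        {m.material_id: m.category_id for m in materials}, name="category_id"
    ).sort_index()


def envelope_distance_matrix(materials, smooth_hz: float = 30.0):
    """Ground-truth category distance matrix from mean spectral envelopes.

    Envelopes are smoothed by ``smooth_hz`` before the normalized Euclidean
    distance, so dissimilarity reflects coarse spectral-shape separation.
    """
    from .latent import DistanceMatrix

    bases = _category_bases(materials, smooth_hz=smooth_hz)
    cats = sorted(bases)
    mat = np.stack([bases[c] / np.linalg.norm(bases[c]) for c in cats])
    diff = mat[:, None, :] - mat[None, :, :]
    values = np.sqrt((diff**2).sum(axis=2))
    return DistanceMatrix(labels=cats, values=values, flavor="envelope_truth")


# ---------------------------------------------------------------------------
# disk round-trip: .npy per recording plus a CSV manifest; ratings as long CSV


def write_recordings(recordings, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        name = f"p{rec.participant_id:02d}_{rec.material_id}.npy"
        np.save(outdir / name, rec.samples)
        rows.append(
            {
                "participant_id": rec.participant_id,
                "material_id": rec.material_id,
                "category_id": rec.category_id,
                "path": name,
                "rate_hz": rec.rate_hz,
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_recordings(manifest_path) -> list[VibrationRecording]:
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    return [
        VibrationRecording(
            samples=np.load(base / row.path),
            rate_hz=float(row.rate_hz),
            participant_id=int(row.participant_id),
            material_id=str(row.material_id),
            category_id=int(row.category_id),
        )
        for row in df.itertuples()
    ]


def write_ratings(table: RatingTable, outdir) -> tuple[Path, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    d_path = outdir / "ratings_descriptors.csv"
    c_path = outdir / "ratings_categories.csv"
    table.descriptors.to_csv(d_path, index=False)
    table.categories.to_csv(c_path, index=False)
    return d_path, c_path


def read_ratings(descriptors_path, categories_path) -> RatingTable:
    return RatingTable(
        descriptors=pd.read_csv(descriptors_path),
        categories=pd.read_csv(categories_path),
    )
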