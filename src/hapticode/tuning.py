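"""Temporal-frequency tuning of the latent dimensions.

A bank of sinusoids (830 frequencies up to 800 Hz, several phases each,
offset to mid-range so they are valid normalized segments) is pushed through
the trained encoder and projected into the latent PCs space. A dimension's
response at a frequency is the phase-averaged absolute deviation of its
projection from the response to the constant mid-range signal; curves are
min-max normalized to [0, 1]. Each dimension is summarized by its
sensitivity-weighted mean frequency, the summaries are split into a low and
a high group by 1-D k-means, and the groups are compared against canonical
tuning curves of the two vibration-sensitive tactile afferent classes: RA
(rapidly adapting, peak sensitivity 40-60 Hz) and PC (Pacinian, peak
250-300 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .preprocessing import SegmentSet

__all__ = [
    "TuningCurveSet",
    "AfferentReference",
    "load_afferent_reference",
    "make_sinusoid_bank",
    "probe_tuning",
    "tuning_summary",
    "cluster_tuning",
    "compare_to_afferents",
]

RA_BAND = (40.0, 60.0)
PC_BAND = (250.0, 300.0)


@dataclass
class TuningCurveSet:
    """Per-dimension sensitivity over a frequency grid, normalized to [0, 1]."""

    frequencies: np.ndarray
    sensitivity: np.ndarray  # dimensions x frequencies, min-max normalized
    raw_sensitivity: np.ndarray | None = None  # phase-averaged |response - baseline|
    degenerate_dims: list = field(default_factory=list)

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=np.float64)
        self.sensitivity = np.asarray(self.sensitivity, dtype=np.float64)
        if self.sensitivity.ndim != 2 or self.sensitivity.shape[1] != self.frequencies.size:
            raise ValueError("sensitivity must be (n_dims, n_frequencies)")

    @property
    def n_dims(self) -> int:
        return self.sensitivity.shape[0]

    def active_dims(self) -> np.ndarray:
        return np.array([d for d in range(self.n_dims) if d not in self.degenerate_dims])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for d in range(self.n_dims):
            rows.append(pd.DataFrame({
                "dimension": d,
                "frequency_hz": self.frequencies,
                "sensitivity": self.sensitivity[d],
            }))
        return pd.concat(rows, ignore_index=True)


@dataclass
class AfferentReference:
    """Canonical RA/PC tuning curves (normalized inverse thresholds).

    The bundled default is a constructed synthetic table whose peaks sit
    inside the physiological bands (RA 40-60 Hz, PC 250-300 Hz); supply your
    own CSV (columns curve, frequency_hz, sensitivity) to use measured data.
    """

    curves: pd.DataFrame
    provenance: str = ""

    def __post_init__(self):
        need = {"curve", "frequency_hz", "sensitivity"}
        if not need.issubset(self.curves.columns):
            raise ValueError(f"reference table needs columns {sorted(need)}")
        for name, band in (("RA", RA_BAND), ("PC", PC_BAND)):
            peak = self.peak(name)
            if not band[0] <= peak <= band[1]:
                raise ValueError(f"{name} reference peak {peak:.0f} Hz outside {band}")

    def peak(self, curve: str) -> float:
        sub = self.curves[self.curves["curve"] == curve]
        if sub.empty:
            raise ValueError(f"no reference curve named {curve!r}")
        return float(sub.loc[sub["sensitivity"].idxmax(), "frequency_hz"])


def load_afferent_reference(path=None) -> AfferentReference:
    if path is None:
        ref = resources.files("hapticode.data") / "afferent_tuning_synthetic.csv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
        prov = "bundled synthetic canonical curves (peaks in the RA/PC bands)"
    else:
        df = pd.read_csv(path)
        prov = str(path)
    return AfferentReference(curves=df, provenance=prov)


def make_sinusoid_bank(n: int = 830, f_min: float | None = None, f_max: float = 800.0,
                       length: int = 256, rate_hz: float = 3200.0, amplitude: float = 0.25,
                       n_phases: int = 8) -> SegmentSet:
    """Sinusoid probe bank: ``n`` frequencies x ``n_phases`` phase offsets.

    Frequencies span a uniform grid from 0 to ``f_max`` (step ~0.96 Hz for
    the defaults); the 0 Hz endpoint is replaced by the first positive grid
    frequency, since a true DC probe is the constant baseline signal itself.
    Signals are offset to mid-range 0.5 so they are valid [0, 1] segments.
    """
    if f_max > rate_hz / 2.0:
        raise ValueError("f_max must not exceed the Nyquist frequency")
    if not 0.0 <= amplitude <= 0.5:
        raise ValueError("amplitude must be in [0, 0.5] to keep samples inside [0, 1]")
    if n < 2:
        raise ValueError("need at least two probe frequencies")
    if f_min is None:
        freqs = np.linspace(0.0, f_max, n)
        freqs[0] = freqs[1]
    else:
        freqs = np.linspace(f_min, f_max, n)
    t = np.arange(length) / rate_hz
    phases = np.linspace(0.0, 2.0 * np.pi, n_phases, endpoint=False)
    data = 0.5 + amplitude * np.sin(
        2.0 * np.pi * freqs[:, None, None] * t[None, None, :] + phases[None, :, None]
    )
    meta = pd.DataFrame({
        "frequency_hz": np.repeat(freqs, n_phases),
        "phase_index": np.tile(np.arange(n_phases), n),
    })
    return SegmentSet(data=data.reshape(n * n_phases, length), metadata=meta)


def probe_tuning(model, pcspace, bank: SegmentSet) -> TuningCurveSet:
    """Tuning curves of the latent PCs dimensions under the sinusoid bank.

    ``model`` is anything with a ``transform(segments) -> codes`` method;
    ``pcspace`` (optional) projects codes into the latent PCs space. The
    response is the mean over phases of |projection - baseline|, where the
    baseline is the response to the constant mid-range signal; each
    dimension is then min-max normalized. Dimensions with zero response
    range are flagged degenerate and excluded from clustering.
    """
    codes = model.transform(bank.data)
    baseline_seg = np.full((1, bank.window_length), 0.5)
    base_code = model.transform(baseline_seg)
    if pcspace is not None:
        codes = pcspace.transform(codes)
        base_code = pcspace.transform(base_code)
    freqs_all = bank.metadata["frequency_hz"].values
    freqs = np.unique(freqs_all)
    dev = np.abs(codes - base_code)  # (N, dims)
    n_dims = dev.shape[1]
    sens = np.empty((n_dims, freqs.size))
    for i, f in enumerate(freqs):
        sens[:, i] = dev[freqs_all == f].mean(axis=0)
    raw = sens.copy()
    lo = sens.min(axis=1, keepdims=True)
    rng_ = sens.max(axis=1, keepdims=True) - lo
    degenerate = [int(d) for d in np.flatnonzero(rng_[:, 0] <= 0)]
    rng_[rng_ <= 0] = 1.0
    sens = (sens - lo) / rng_
    return TuningCurveSet(frequencies=freqs, sensitivity=sens, raw_sensitivity=raw,
                          degenerate_dims=degenerate)


def tuning_summary(curves) -> np.ndarray:
    """Sensitivity-weighted mean frequency per dimension (Hz)."""
    if isinstance(curves, TuningCurveSet):
        f, s = curves.frequencies, curves.sensitivity
    else:
        f, s = curves
        s = np.atleast_2d(np.asarray(s, dtype=np.float64))
        f = np.asarray(f, dtype=np.float64)
    totals = s.sum(axis=1)
    out = np.full(s.shape[0], np.nan)
    ok = totals > 0
    out[ok] = (s[ok] * f).sum(axis=1) / totals[ok]
    return out if out.size > 1 else out


@dataclass
class TuningClusters:
    assignments: np.ndarray  # 0 = low-frequency group, 1 = high
    centers: np.ndarray  # Hz, ascending
    degenerate: bool = False


def cluster_tuning(summaries, k: int = 2, seed: int = 0) -> TuningClusters:
    """1-D k-means split of the tuning summaries into low/high groups."""
    x = np.asarray(summaries, dtype=np.float64).reshape(-1, 1)
    if np.isnan(x).any():
        raise ValueError("tuning summaries contain NaN (degenerate dimensions?)")
    if np.allclose(x, x[0]):
        return TuningClusters(
            assignments=np.zeros(x.shape[0], dtype=int),
            centers=np.array([float(x[0, 0])]),
            degenerate=True,
        )
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x)
    order = np.argsort(km.cluster_centers_[:, 0])
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return TuningClusters(
        assignments=remap[km.labels_],
        centers=np.sort(km.cluster_centers_[:, 0]),
        degenerate=False,
    )


def compare_to_afferents(curves: TuningCurveSet, clusters: TuningClusters,
                         reference: AfferentReference) -> dict:
    """Match the low/high tuning groups against the RA/PC reference peaks.

    Each group's mean curve yields a peak frequency; the report states the
    distance from each group peak to the nearest reference band and whether
    the low group lands nearer RA and the high group nearer PC.
    """
    ra_peak, pc_peak = reference.peak("RA"), reference.peak("PC")
    report = {"ra_peak_hz": ra_peak, "pc_peak_hz": pc_peak, "groups": {}}
    if clusters.degenerate or len(np.unique(clusters.assignments)) < 2:
        report["matched"] = False
        report["note"] = "no bimodality: tuning summaries form a single group"
        return report

    def band_distance(peak, band):
        lo, hi = band
        return 0.0 if lo <= peak <= hi else min(abs(peak - lo), abs(peak - hi))

    active = curves.active_dims()
    peaks = {}
    for g, name in ((0, "low"), (1, "high")):
        dims = active[clusters.assignments == g]
        mean_curve = curves.sensitivity[dims].mean(axis=0)
        peak = float(curves.frequencies[np.argmax(mean_curve)])
        peaks[name] = peak
        report["groups"][name] = {
            "dimensions": dims.tolist(),
            "peak_hz": peak,
            "dist_to_ra_band_hz": band_distance(peak, RA_BAND),
            "dist_to_pc_band_hz": band_distance(peak, PC_BAND),
        }
    report["matched"] = bool(
        abs(peaks["low"] - ra_peak) <= abs(peaks["low"] - pc_peak)
        and abs(peaks["high"] - pc_peak) <= abs(peaks["high"] - ra_peak)
    )
    return report
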