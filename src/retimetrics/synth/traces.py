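"""Biphasic mfERG waveform generator.

Each first-order response is the sum of a negative and a positive Gaussian
lobe of width w = 6 ms. The lobe coefficients and centers are calibrated by
Newton iteration so that the noise-free trace's minimum sits exactly at the
requested N1 implicit time with depth N1-A below baseline, and its maximum
at the P1 implicit time with the requested trough-to-peak amplitude P1-A —
the calibration compensates the small cross-pull the overlapping lobes
exert on each other's extremum. White Gaussian noise of the requested SD is
added per sample; the acquisition band-pass (10-300 Hz) is assumed already
applied, matching how clinical systems deliver traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import AnalysisError
from ..types import N_HEXAGONS, MfergTraceSet

#: hexagons per concentric ring R1..R6 of the standard 103-element array
RING_SIZES = (1, 6, 12, 18, 24, 42)

LOBE_WIDTH_MS = 6.0


@dataclass
class WaveTruth:
    """Per-hexagon waveform parameters (ground truth)."""

    n1_amp: float     # nV/deg², isoelectric-to-trough
    p1_amp: float     # nV/deg², trough-to-peak
    n1_it: float      # ms
    p1_it: float      # ms
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.n1_it < self.p1_it:
            raise AnalysisError("need 0 < n1_it < p1_it")
        if self.n1_amp <= 0 or self.p1_amp <= self.n1_amp:
            raise AnalysisError("need 0 < n1_amp < p1_amp")


def _gauss(t: np.ndarray, mu: float, w: float) -> np.ndarray:
    return np.exp(-((t - mu) ** 2) / (2.0 * w ** 2))


def biphasic_template(truth: WaveTruth, t_ms: np.ndarray,
                      w: float = LOBE_WIDTH_MS) -> np.ndarray:
    """Noise-free closed-form waveform for ``truth``, evaluated at ``t_ms``.

    Calibrated so that on a dense grid the minimum is (−n1_amp) at n1_it
    and the maximum is (p1_amp − n1_amp) at p1_it.
    """
    a, b = truth.n1_amp, truth.p1_amp - truth.n1_amp
    mu1, mu2 = truth.n1_it, truth.p1_it
    dense = np.arange(0.0, truth.p1_it + 5 * w, 0.01)
    for _ in range(60):
        f = -a * _gauss(dense, mu1, w) + b * _gauss(dense, mu2, w)
        i_min, i_max = int(np.argmin(f)), int(np.argmax(f))
        t_min, t_max = dense[i_min], dense[i_max]
        err = np.array([
            truth.n1_it - t_min,
            truth.p1_it - t_max,
            (-truth.n1_amp) - f[i_min],
            (truth.p1_amp - truth.n1_amp) - f[i_max],
        ])
        if np.all(np.abs(err) < 1e-9):
            break
        mu1 += err[0]
        mu2 += err[1]
        a -= err[2] / max(_gauss(t_min, mu1, w), 1e-12)
        b += err[3] / max(_gauss(t_max, mu2, w), 1e-12)
    return -a * _gauss(t_ms, mu1, w) + b * _gauss(t_ms, mu2, w)


def default_wave_truth(
    p1_amp_r1: float = 80.0,
    n1_frac: float = 0.5,
    n1_it_ms: float = 15.0,
    p1_it_ms: float = 30.0,
    noise_sd: float = 0.0,
    p1_it_shift_ms: float = 0.0,
) -> list[WaveTruth]:
    """Conventional normative-shaped truth for all 103 hexagons.

    Amplitudes scale with eccentricity as 1/ring (only the relative
    structure matters); the ring-1 P1 amplitude and the implicit times are
    conventional first-order kernel values, not measured normals.
    """
    truths = []
    for ring, count in enumerate(RING_SIZES, start=1):
        p1 = p1_amp_r1 / ring
        for _ in range(count):
            truths.append(WaveTruth(
                n1_amp=n1_frac * p1, p1_amp=p1,
                n1_it=n1_it_ms, p1_it=p1_it_ms + p1_it_shift_ms,
                noise_sd=noise_sd,
            ))
    return truths


def default_geometry() -> tuple[np.ndarray, np.ndarray]:
    """Hexagon ids ``h001..h103`` and their ring assignment, center out."""
    ids = np.array([f"h{i + 1:03d}" for i in range(N_HEXAGONS)])
    rings = np.concatenate([
        np.full(count, ring) for ring, count in enumerate(RING_SIZES, start=1)
    ])
    return ids, rings


def generate_traceset(
    wave_truth: list[WaveTruth] | None = None,
    sampling_rate: float = 1200.0,
    duration_ms: float = 100.0,
    seed: int = 0,
    eye_id: str = "",
) -> MfergTraceSet:
    """Render a 103-trace set from per-hexagon waveform truth."""
    if wave_truth is None:
        wave_truth = default_wave_truth()
    if len(wave_truth) != N_HEXAGONS:
        raise AnalysisError(f"need {N_HEXAGONS} wave truths")
    if sampling_rate < 600:
        raise AnalysisError("sampling_rate must be >= 600 Hz")
    max_p1 = max(t.p1_it for t in wave_truth)
    if duration_ms < max_p1 + 20.0:
        raise AnalysisError("duration must cover p1_it + 20 ms")
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration_ms / 1000.0 * sampling_rate))
    t_ms = np.arange(n_samples) / sampling_rate * 1000.0
    traces = np.empty((N_HEXAGONS, n_samples))
    for i, truth in enumerate(wave_truth):
        clean = biphasic_template(truth, t_ms)
        noise = rng.normal(0.0, truth.noise_sd, n_samples) \
            if truth.noise_sd > 0 else 0.0
        traces[i] = clean + noise
    ids, rings = default_geometry()
    return MfergTraceSet(traces=traces, sampling_rate=sampling_rate,
                         hexagon_ids=ids, ring_of_hexagon=rings,
                         eye_id=eye_id)
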