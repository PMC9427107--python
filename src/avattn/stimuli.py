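"""Auditory stimulus generators and time-frequency representations.

Two stimulus families are modeled:

* the random double sweep (RDS), a receptive-field mapping stimulus made of
  two independent frequency trajectories that wander smoothly between 4 and
  64 kHz with modulation content band-limited to 20 Hz; and
* tone clouds (TC), 1 s decision stimuli built from 50 ms pips at a 25 ms
  hop, drawn log-uniformly from a 1-octave band around a center frequency.

Trajectories are kept in log2(Hz) throughout ("octave" axis); the
time-frequency matrix used for reverse correlation bins each sweep's
instantaneous frequency onto a fixed lag/frequency grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

F_LO_HZ = 4000.0
F_HI_HZ = 64000.0
LOG2_F_LO = float(np.log2(F_LO_HZ))
LOG2_F_HI = float(np.log2(F_HI_HZ))
RDS_MAX_MOD_HZ = 20.0

TC_DURATION_S = 1.0
TC_PIP_DUR_S = 0.050
TC_PIP_HOP_S = 0.025
TC_BAND_OCT = 1.0


@dataclass(frozen=True)
class RDSStimulus:
    """Two independent band-limited log-frequency sweep trajectories."""

    sweep_tracks: np.ndarray  # (2, n_samples) log2-frequency in log2(Hz)
    dt_traj: float  # trajectory sample step, s
    duration: float  # s
    seed: int

    @property
    def n_samples(self) -> int:
        return self.sweep_tracks.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt_traj

    def freqs_hz(self) -> np.ndarray:
        """Instantaneous sweep frequencies in Hz, shape (2, n_samples)."""
        return 2.0 ** self.sweep_tracks

    def slice(self, start: float, stop: float) -> "RDSStimulus":
        """Extract the trajectory segment covering [start, stop) seconds."""
        i0 = int(round(start / self.dt_traj))
        i1 = int(round(stop / self.dt_traj))
        i0 = max(i0, 0)
        i1 = min(i1, self.n_samples)
        if i1 <= i0:
            raise ValueError("empty RDS slice")
        return RDSStimulus(
            sweep_tracks=self.sweep_tracks[:, i0:i1],
            dt_traj=self.dt_traj,
            duration=(i1 - i0) * self.dt_traj,
            seed=self.seed,
        )


@dataclass(frozen=True)
class ToneCloudSpec:
    """Frozen tone-cloud decision stimulus: overlapping pips in a 1-octave band."""

    center_freq: float  # Hz
    pip_onsets: np.ndarray  # s
    pip_freqs: np.ndarray  # Hz
    duration: float = TC_DURATION_S
    pip_dur: float = TC_PIP_DUR_S
    pip_hop: float = TC_PIP_HOP_S


@dataclass(frozen=True)
class TFMatrix:
    """Time x frequency stimulus energy on a fixed grid.

    ``values[t, f]`` holds the fraction of each trajectory sample falling in
    frequency bin ``f`` during time bin ``t``, summed over the two sweeps
    (so with no smoothing each column of a two-sweep stimulus sums to 2).
    """

    values: np.ndarray  # (n_time, n_freq)
    dt: float  # time bin width, s
    freq_edges: np.ndarray  # (n_freq + 1,) log2(Hz)
    t0: float = 0.0  # absolute time of the first bin's left edge, s

    @property
    def n_time(self) -> int:
        return self.values.shape[0]

    @property
    def n_freq(self) -> int:
        return self.values.shape[1]

    @property
    def freq_centers_log2(self) -> np.ndarray:
        return 0.5 * (self.freq_edges[:-1] + self.freq_edges[1:])

    @property
    def freq_centers_hz(self) -> np.ndarray:
        return 2.0 ** self.freq_centers_log2

    @property
    def duration(self) -> float:
        return self.n_time * self.dt


def generate_rds(
    duration: float,
    seed: int,
    dt_traj: float = 0.001,
    max_mod_hz: float = RDS_MAX_MOD_HZ,
    f_lo_hz: float = F_LO_HZ,
    f_hi_hz: float = F_HI_HZ,
) -> RDSStimulus:
    """Generate a random double sweep.

    Each trajectory is band-limited Gaussian noise synthesized in the Fourier
    domain (support strictly at frequencies <= ``max_mod_hz``, DC excluded)
    and then affinely rescaled so that its realized minimum and maximum map
    exactly onto [log2(f_lo), log2(f_hi)].  The affine rescale only touches
    the DC term and overall gain, so the band limit is exact by construction,
    as is the frequency range.  The two sweeps come from independent draws of
    one seeded generator.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    n = int(round(duration / dt_traj))
    if n < 2:
        raise ValueError("duration too short for trajectory synthesis")
    freqs = np.fft.rfftfreq(n, dt_traj)
    band = (freqs > 0) & (freqs <= max_mod_hz)
    if not band.any():
        raise ValueError(
            f"duration {duration} s too short to carry modulation below {max_mod_hz} Hz"
        )
    rng = np.random.default_rng(seed)
    lo, hi = np.log2(f_lo_hz), np.log2(f_hi_hz)
    tracks = np.empty((2, n))
    for k in range(2):
        coef = np.zeros(freqs.size, dtype=complex)
        m = int(band.sum())
        coef[band] = rng.standard_normal(m) + 1j * rng.standard_normal(m)
        x = np.fft.irfft(coef, n)
        xmin, xmax = x.min(), x.max()
        if xmax == xmin:  # degenerate draw; cannot happen for m >= 1 a.s.
            raise RuntimeError("degenerate flat trajectory draw")
        tracks[k] = lo + (x - xmin) * (hi - lo) / (xmax - xmin)
    return RDSStimulus(sweep_tracks=tracks, dt_traj=dt_traj, duration=n * dt_traj, seed=seed)


def _freq_smoothing_matrix(edges: np.ndarray, sigma_oct: float) -> np.ndarray:
    """Column-stochastic Gaussian smoothing kernel across frequency bins.

    Each source bin spreads its mass with a Gaussian of width ``sigma_oct``
    (octaves); columns are renormalized so edge clipping never loses energy.
    """
    centers = 0.5 * (edges[:-1] + edges[1:])
    d = centers[:, None] - centers[None, :]
    k = np.exp(-0.5 * (d / sigma_oct) ** 2)
    return k / k.sum(axis=0, keepdims=True)


def rds_to_tf(
    rds: RDSStimulus,
    dt: float = 0.005,
    bin_oct: float = 0.2,
    smooth_sigma_oct: float = 0.0,
    f_lo_hz: float = F_LO_HZ,
    f_hi_hz: float = F_HI_HZ,
    t0: float = 0.0,
) -> TFMatrix:
    """Bin RDS sweep trajectories onto a time x frequency energy matrix.

    Each trajectory sample deposits ``1 / samples_per_time_bin`` in the
    frequency bin containing its instantaneous frequency, so a single sweep
    contributes unit energy per time bin; the two sweeps are summed.
    ``smooth_sigma_oct > 0`` applies an energy-conserving Gaussian blur
    across frequency.
    """
    lo, hi = np.log2(f_lo_hz), np.log2(f_hi_hz)
    n_freq = int(round((hi - lo) / bin_oct))
    edges = lo + bin_oct * np.arange(n_freq + 1)
    tracks = rds.sweep_tracks
    if tracks.min() < edges[0] - 1e-9 or tracks.max() > edges[-1] + 1e-9:
        raise ValueError("RDS trajectory outside the time-frequency grid range")
    ratio = dt / rds.dt_traj
    per_bin = int(round(ratio))
    if abs(ratio - per_bin) > 1e-9 or per_bin < 1:
        raise ValueError("tf time step must be an integer multiple of dt_traj")
    n_time = tracks.shape[1] // per_bin
    if n_time == 0:
        raise ValueError("RDS shorter than one tf time bin")
    vals = np.zeros((n_time, n_freq))
    fbin = np.clip(((tracks - lo) / bin_oct).astype(int), 0, n_freq - 1)
    tbin = np.arange(tracks.shape[1]) // per_bin
    keep = tbin < n_time
    for k in range(tracks.shape[0]):
        np.add.at(vals, (tbin[keep], fbin[k][keep]), 1.0 / per_bin)
    if smooth_sigma_oct > 0:
        vals = vals @ _freq_smoothing_matrix(edges, smooth_sigma_oct).T
    return TFMatrix(values=vals, dt=dt, freq_edges=edges, t0=t0)


def generate_tone_cloud(center_freq: float, seed: int) -> ToneCloudSpec:
    """Draw a frozen tone cloud: 39 pips at 0, 25, ..., 950 ms.

    Pip frequencies are i.i.d. log-uniform within +-0.5 octave of the center
    frequency.  The same seed always returns the same cloud, mirroring the
    use of frozen clouds throughout a session.
    """
    if center_freq <= 0:
        raise ValueError("center_freq must be positive")
    rng = np.random.default_rng(seed)
    onsets = np.arange(0.0, TC_DURATION_S - TC_PIP_DUR_S + 1e-9, TC_PIP_HOP_S)
    octs = rng.uniform(-TC_BAND_OCT / 2, TC_BAND_OCT / 2, size=onsets.size)
    freqs = center_freq * 2.0 ** octs
    return ToneCloudSpec(center_freq=center_freq, pip_onsets=onsets, pip_freqs=freqs)
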