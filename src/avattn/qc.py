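"""Unit quality control: waveform class, laminar depth, recording stability.

Units are split into narrow-spiking (NS, putative fast-spiking inhibitory)
and broad-spiking (BS, putative excitatory) classes at a trough-to-peak
duration of 0.6 ms.  Laminar depth is the fractional position of a unit's
peak channel within the cortical span estimated from the probe's channel
profile: the bottom border is the deepest channel with a reliable
tone-evoked multi-unit response, the top border the shallowest channel whose
LFP amplitude rises above the probe-wise noise floor.  Stability screening
flags 2-minute bins whose firing rate collapses far below the unit's median
bin rate; units unstable for more than 10% of the recording are excluded
from receptive-field analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NS_BS_BOUNDARY_MS = 0.6
STABILITY_BIN_S = 120.0
STABILITY_DROP_FRACTION = 0.20  # flag bins below this fraction of the median rate
MAX_UNSTABLE_FRACTION = 0.10  # STRF-analysis exclusion threshold
DEPTH_BOUNDARIES = (0.365, 0.505)  # supragranular/granular/infragranular fractions


def classify_waveform(trough_peak_ms: float, boundary_ms: float = NS_BS_BOUNDARY_MS) -> str:
    """NS if trough-to-peak < 0.6 ms, BS otherwise (boundary value -> BS)."""
    if trough_peak_ms <= 0:
        raise ValueError(f"trough_peak_ms must be positive, got {trough_peak_ms}")
    return "NS" if trough_peak_ms < boundary_ms else "BS"


def estimate_cortical_span(
    lfp_amp: np.ndarray,
    mua_responsive: np.ndarray,
    lfp_rise_fraction: float = 0.10,
) -> tuple:
    """Estimate (top_channel, bottom_channel) of cortex; index 0 = shallowest.

    Bottom: deepest channel with a reliable multi-unit sound response that
    is not an isolated outlier (it must have another responsive channel
    within the two channels above it); a single spuriously responsive
    white-matter channel would otherwise stretch the span and distort every
    unit's fractional depth.  Top: shallowest channel whose max LFP
    amplitude first rises above the probe-wise minimum by
    ``lfp_rise_fraction`` of the amplitude range.
    """
    lfp_amp = np.asarray(lfp_amp, dtype=float)
    mua = np.asarray(mua_responsive, dtype=bool)
    if lfp_amp.shape != mua.shape or lfp_amp.size < 2:
        raise ValueError("need >= 2 channels with matching LFP and MUA summaries")
    if not mua.any():
        raise ValueError("no tone-responsive channel: cannot locate white-matter border")
    responsive = np.flatnonzero(mua)
    bottom = int(responsive[-1])
    for ch in responsive[::-1]:
        if mua[max(ch - 2, 0) : ch].any():
            bottom = int(ch)
            break
    thresh = lfp_amp.min() + lfp_rise_fraction * (lfp_amp.max() - lfp_amp.min())
    above = np.flatnonzero(lfp_amp > thresh)
    top = int(above[0]) if above.size else 0
    return top, bottom


def assign_depth(
    peak_channel: int,
    span: tuple,
    boundaries: tuple = DEPTH_BOUNDARIES,
) -> tuple:
    """Fractional cortical depth of a unit's peak channel and its depth group.

    fraction = (peak - top) / (bottom - top); groups split at the configured
    fraction boundaries (defaults approximate the supragranular / granular /
    infragranular division of mouse auditory cortex).
    """
    top, bottom = span
    if not top <= peak_channel <= bottom:
        raise ValueError(f"peak channel {peak_channel} outside cortical span {span}")
    frac = (peak_channel - top) / (bottom - top)
    b1, b2 = boundaries
    group = "superficial" if frac < b1 else ("middle" if frac < b2 else "deep")
    return float(frac), group


@dataclass(frozen=True)
class StabilityResult:
    bin_edges: np.ndarray  # (n_bins + 1,) s, covering the recording exactly once
    valid: np.ndarray  # (n_bins,) bool; False = flagged unstable
    unstable_fraction: float

    def valid_epochs(self) -> list:
        """Merged (start, stop) intervals of stable recording time."""
        out, start = [], None
        for i, ok in enumerate(self.valid):
            if ok and start is None:
                start = self.bin_edges[i]
            if not ok and start is not None:
                out.append((float(start), float(self.bin_edges[i])))
                start = None
        if start is not None:
            out.append((float(start), float(self.bin_edges[-1])))
        return out


def stability_screen(
    spike_times: np.ndarray,
    duration: float,
    bin_s: float = STABILITY_BIN_S,
    drop_fraction: float = STABILITY_DROP_FRACTION,
) -> StabilityResult:
    """Flag epochs where a unit's firing rate collapses.

    The recording is tiled with ``bin_s`` bins (last bin may be partial);
    bins whose rate falls below ``drop_fraction`` of the unit's median bin
    rate are flagged.  An empty spike train flags everything.
    """
    if duration < 2 * bin_s:
        raise ValueError(f"recording duration {duration} s shorter than two stability bins")
    edges = np.arange(0.0, duration, bin_s)
    edges = np.append(edges, duration)
    widths = np.diff(edges)
    counts, _ = np.histogram(spike_times, bins=edges)
    rates = counts / widths
    if counts.sum() == 0:
        valid = np.zeros(rates.size, dtype=bool)
    else:
        med = np.median(rates)
        valid = rates >= drop_fraction * med
        if med == 0:
            valid = rates > 0
    unstable = float(widths[~valid].sum() / duration)
    return StabilityResult(bin_edges=edges, valid=valid, unstable_fraction=unstable)
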