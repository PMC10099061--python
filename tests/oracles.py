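"""Independent oracles used by the acceptance tests.

These predict expected outcomes from first principles (closed forms, naive
exhaustive search, deterministic expectation integrals over the filter
definitions) without running the pipeline under test.
"""
import numpy as np
from scipy import signal as sps
from scipy.ndimage import convolve1d

from fescycling.emg import design_bandpass
from fescycling.intervals import CircularInterval


def brute_force_best_window(values, bin_width, length_deg):
    """Naive exhaustive placement of a fixed-length window maximizing the
    windowed sum (first maximizer wins)."""
    n = len(values)
    win = max(1, min(int(round(length_deg / bin_width)), n))
    best_start, best_sum = None, -np.inf
    for k in range(n):
        s = 0.0
        for j in range(win):
            s += values[(k + j) % n]
        if s > best_sum + 1e-12:
            best_sum = s
            best_start = k
    return best_start * bin_width


def predict_emg_crossings(
    arc: CircularInterval,
    cadence: float,
    snr: float,
    sample_rate: float = 1000.0,
    window_s: float = 0.1,
    threshold: float = 0.25,
):
    """Expected threshold crossings of the processed mean EMG profile.

    Computed as a deterministic expectation from the generator and analysis
    definitions alone: the burst's Hann-squared modulation is spread by the
    power kernel of the generator+analysis filter cascade and by the RMS
    window, the filtered white-baseline power is added, and the crossings of
    the resulting expected envelope at ``threshold`` x its peak are located.
    """
    sos = design_bandpass(sample_rate)
    imp = np.zeros(8001)
    imp[4000] = 1.0
    k = sps.sosfiltfilt(sos, imp)  # zero-phase (filtfilt) kernel of the band-pass
    casc = np.convolve(k, k)  # generator filter then analysis filter
    gain = np.sum(casc**2) / np.sum(k**2)  # power gain on the unit-RMS carrier
    q = casc**2 / np.sum(casc**2)  # envelope-power spreading kernel
    base_pow = (1.0 / snr) ** 2 * np.sum(k**2)  # white baseline after analysis filter

    n = int(round(60.0 / cadence * sample_rate))
    t = np.arange(n) / sample_rate
    theta = (6.0 * cadence * t) % 360.0
    u = ((theta - arc.start) % 360.0) / arc.length
    a_sq = np.where(u <= 1.0, np.sin(np.pi * np.minimum(u, 1.0)) ** 4, 0.0)

    spread = convolve1d(a_sq, q, mode="wrap")
    box = np.ones(int(round(window_s * sample_rate)))
    box /= len(box)
    env = np.sqrt(gain * convolve1d(spread, box, mode="wrap") + base_pow)

    level = threshold * env.max()
    idx = np.flatnonzero(env >= level)
    i0, i1 = idx[0], idx[-1]
    step = 6.0 * cadence / sample_rate

    def interp(i_prev, i_next):
        v0, v1 = env[i_prev], env[i_next]
        return (theta[i_prev] + (level - v0) / (v1 - v0) * step) % 360.0

    return interp(i0 - 1, i0), interp(i1, (i1 + 1) % n)
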