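"""Quadratic phase coupling shows up as a bispectral peak; noise does not.

Averages bispectra of independent triad realizations: when phi3 = phi1 + phi2
the peak at (f1, f2) adds coherently across realizations, otherwise it
cancels toward the background.
"""

import numpy as np

from hrvbispec.bispectrum import (
    SegmentPlan,
    average_bispectra,
    estimate_bispectrum,
    roi_mask,
)
from hrvbispec.synthetic import simulate_qpc_signal

fs, n = 3.41, 512
plan = SegmentPlan(window_len=512, overlap=0.5, nfft=512)
df = fs / 512
k1, k2 = 30, 45
f1, f2 = k1 * df, k2 * df


def peak_ratio(coupled: bool, seed0: int) -> float:
    mats = [
        estimate_bispectrum(
            simulate_qpc_signal(f1, f2, coupled, n, fs, seed=seed0 + i, noise_sd=8.0),
            plan,
        )
        for i in range(120)
    ]
    avg = average_bispectra(mats)
    mask = roi_mask(avg.values.shape[0], avg.nfft)
    vals = np.abs(avg.values[mask])
    return float(abs(avg.values[k1, k2]) / np.median(vals[vals > 0]))


print(f"triad at f1={f1:.3f} Hz, f2={f2:.3f} Hz, f3=f1+f2 (120 realizations)")
print(f"coupled   peak/background: {peak_ratio(True, 100):6.1f}")
print(f"uncoupled peak/background: {peak_ratio(False, 7000):6.1f}")
# A coupled triad stands >=10x above the median ROI magnitude; with random
# phases the same harmonics leave no dominant peak -- the signature the
# HRV analysis exploits to detect nonlinear (phase-coupled) dynamics.
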