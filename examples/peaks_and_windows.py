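"""Peak detection and data-driven early/late temporal windows.

Constructs response functions with known positive and negative deflections,
detects their two largest peaks with the prominence rule, pools latencies
and derives the early/late boundary by 1-D K-means.
"""

import numpy as np

from speechtrf import detect_peaks, response_rms, temporal_window_boundary
from speechtrf.design import LAG_MS


def gauss(mu, sd):
    return np.exp(-0.5 * ((LAG_MS - mu) / sd) ** 2)


rng = np.random.default_rng(0)
latencies = []
for i in range(12):
    early = 80 + rng.normal(0, 10)
    late = 400 + rng.normal(0, 25)
    resp = gauss(early, 25) - 0.8 * gauss(late, 45) + 0.03 * rng.standard_normal(len(LAG_MS))
    peaks = detect_peaks(resp, LAG_MS)
    for lat, amp in peaks:
        latencies.append(lat)
    if i == 0:
        print("example response:")
        for lat, amp in peaks:
            print(f"  peak at {lat:6.1f} ms, amplitude {amp:+.2f}")
        print(f"  RMS over 0-500 ms: {response_rms(resp, LAG_MS):.3f}")

boundary = temporal_window_boundary(latencies)
print(f"\npooled {len(latencies)} peak latencies -> early/late boundary at "
      f"{boundary:.0f} ms")
print("Peaks before the boundary belong to the early window (P1/N1-like), "
      "later ones to the late window (N400-like deflections).")
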