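"""Wavelet multi-scale alpha-entropy of a PAF-like vs a normal tachogram.

Each 5-min RR series is cleaned, resampled at 2 Hz, decomposed with db8
over 8 dyadic scales, and each scale's coefficient-energy distribution is
summarized by the Tsallis entropy at alpha = 1.7.  Higher entropy at a
scale means the energy there is spread over many coefficients — the
irregular-shake signature of fibrillation.
"""

import numpy as np

import pafentropy as pe

for tag in ("NORMAL", "PAF"):
    rr, _ = pe.simulate_rr(pe.RRGenConfig(class_tag=tag, seed=3))
    sig = pe.resample_uniform(pe.clean_rr(rr), fs_hrv=2.0)
    ev = pe.entropy_vector(sig, alpha=1.7)
    bands = [pe.band_group_for_level(j) for j in range(1, 9)]
    print(f"{tag:>7}: " + "  ".join(
        f"H{j}={h:.2f}" for j, h in enumerate(ev.H, 1)))
    if tag == "NORMAL":
        print("         " + "  ".join(f"({b:>7})" for b in bands))
# The PAF record carries visibly different entropies, especially at the
# deep (VLF) scales where episode-level regime switching lives.
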