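"""Calibrate the default quadratic Volterra coefficient.

For a fixed-ISI single-event train the relative gap between the order-2
and order-1 integrated responses is |f2| * sum(x^2) / sum(x), linear in
|f2|.  This script computes the admissible interval of f2 for which the
largest integer ISI whose gap exceeds 10% is exactly 2 s, picks the
value whose 10% crossing sits at the geometric mean of the 2 s and 3 s
gap ratios (symmetric margin on both sides), and prints it.  The result
is frozen as ``fmridesign.bold.DEFAULT_F2``.

Usage: python scripts/calibrate_volterra.py
"""

from __future__ import annotations

import warnings

import numpy as np

from fmridesign import VolterraModel, calibrate_f2, integrated_response
from fmridesign.bold import canonical_hrf
from fmridesign.design import uniform_event_train


def gap_ratio(isi: float, tr: float = 1.5, duration: float = 441.0) -> float:
    hrf = canonical_hrf(dt=tr)
    n_scans = int(round(duration / tr))
    u = uniform_event_train(isi, isi, tr, n_scans, np.random.default_rng(0))
    x = np.convolve(u, hrf.samples)[: len(u)]
    return float(np.sum(x * x) / np.sum(x))


def main() -> None:
    warnings.filterwarnings("ignore", message=".*TR grid.*")
    g2, g3 = gap_ratio(2.0), gap_ratio(3.0)
    lo, hi = 0.10 / g2, 0.10 / g3
    f2 = calibrate_f2()
    print(f"admissible |f2| interval for a 2 s onset: ({lo:.4f}, {hi:.4f}]")
    print(f"calibrated f2 (geometric midpoint):      {f2:.4f}")

    print("\nrelative order-2 vs order-1 gap at the calibrated f2:")
    model2 = VolterraModel(f2=f2)
    model1 = VolterraModel.linear()
    for isi in range(1, 11):
        i2 = integrated_response(isi, isi, model2, n_reps=1,
                                 rng=np.random.default_rng(0))
        i1 = integrated_response(isi, isi, model1, n_reps=1,
                                 rng=np.random.default_rng(0))
        marker = " <-- exceeds 10%" if abs(i2 - i1) / i1 > 0.10 else ""
        print(f"  ISI {isi:2d} s: {abs(i2 - i1) / i1:6.1%}{marker}")


if __name__ == "__main__":
    main()
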