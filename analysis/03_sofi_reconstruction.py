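"""Reconstruct a blinking-emitter movie with second-order cumulant SOFI.

Simulates a two-state blinking movie, applies drift/intensity correction,
computes the XC2 image on the doubled virtual grid and deconvolves it, then
compares spot widths: the cumulant image should be sqrt(2) narrower than the
time-averaged image, and Richardson-Lucy sharpens it further.

Run from the repository root:  python analysis/03_sofi_reconstruction.py
"""

import json
from pathlib import Path

import numpy as np

from exmquant import synthetic as syn
from exmquant.sofi import estimate_spot_sigma, reconstruct

RESULTS = Path("results")
SEED = 3


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    emitters = syn.EmitterTruth(
        positions=np.array([[24.0, 24.0], [24.0, 60.0], [60.0, 40.0]]),
        p_on=0.4, p_off=0.5, psf_sigma=2.0, photon_rate=1500,
    )
    movie, _ = syn.gen_blinking_movie(
        emitters, n_frames=100, background=2.0, seed=SEED, shape=(84, 84)
    )
    result = reconstruct(movie, n_iter=10)

    sigma_mean = estimate_spot_sigma(movie.frames.mean(axis=0))
    sigma_xc2 = estimate_spot_sigma(result.xc2_image) / 2  # virtual grid is 2x denser
    sigma_decon = estimate_spot_sigma(result.deconvolved) / 2
    summary = {
        "n_frames": result.n_frames_used,
        "sigma_mean_image_px": round(sigma_mean, 3),
        "sigma_xc2_px": round(sigma_xc2, 3),
        "sigma_deconvolved_px": round(sigma_decon, 3),
        "xc2_over_mean_ratio": round(sigma_xc2 / sigma_mean, 3),
        "expected_ratio": round(1 / np.sqrt(2), 3),
    }
    (RESULTS / "sofi_summary.json").write_text(json.dumps(summary, indent=2))
    print(json.dumps(summary, indent=2))
    print(
        "\nthe XC2 spot is narrower than the mean image by the cumulant factor "
        f"({summary['xc2_over_mean_ratio']} vs sqrt(1/2) = {summary['expected_ratio']}), "
        "and deconvolution sharpens it further"
    )


if __name__ == "__main__":
    main()
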