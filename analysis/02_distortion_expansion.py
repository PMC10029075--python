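"""Quantify expansion distortion and expansion factors on synthetic pairs.

For each expansion scale this script simulates a pre/post pair, pairs the
images by SIFT + similarity RANSAC, refines matches to subpixel precision,
and reports the keypoint and particle-area expansion-factor estimates, the
RMS measurement-error curve and the plateau percent-distortion scalar.

Run from the repository root:  python analysis/02_distortion_expansion.py
"""

from pathlib import Path

import pandas as pd

from exmquant import synthetic as syn
from exmquant.distortion import analyze_expansion_pair, expansion_factor
from exmquant.image_io import max_project

RESULTS = Path("results")
SEED = 7


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows, curves = [], []
    for scale in (2.0, 4.0, 6.0, 8.0):
        pre, post, truth = syn.gen_expansion_pair(
            scale=scale, warp_amplitude=3.0, seed=SEED + int(scale),
            pre_shape=(128, 128), n_objects=40,
        )
        proj = max_project(post, 0, truth.content_z_window)
        res = analyze_expansion_pair(pre, proj, seed=SEED)

        pre_p, post_p, _ = syn.gen_particle_pair(scale=scale, seed=SEED + int(scale))
        particle = expansion_factor(pre=pre_p, post=post_p, method="particle_area")

        rows.append(
            {
                "true_scale": scale,
                "keypoint_factor": res["expansion"].factor,
                "particle_area_factor": particle.factor,
                "n_inlier_matches": res["matches"].n_inliers,
                "percent_distortion": res["percent_distortion"],
            }
        )
        c = res["curve"]
        curves.append(
            pd.DataFrame(
                {
                    "true_scale": scale,
                    "length_um": c.length_bins,
                    "rms_error_um": c.rms_error,
                    "sem_um": c.sem,
                    "n_pairs": c.n_pairs,
                }
            )
        )

    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "expansion_factors.csv", index=False)
    pd.concat(curves).to_csv(RESULTS / "rms_curves.csv", index=False)
    print(table.round(4).to_string(index=False))
    worst_kp = (abs(table.keypoint_factor - table.true_scale) / table.true_scale).max()
    worst_pa = (abs(table.particle_area_factor - table.true_scale) / table.true_scale).max()
    print(f"\nworst relative error: keypoint {100 * worst_kp:.3f}%, "
          f"particle-area {100 * worst_pa:.3f}%")
    print(f"distortion scalars stay below 1%: the injected 3 px warp at these "
          f"scales is a {table.percent_distortion.max():.2f}% length error at the plateau")


if __name__ == "__main__":
    main()
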