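"""Generate one example of every synthetic input the pipeline consumes.

Images go to scratch/ (bulky, regenerable); a small JSON inventory of the
ground truth goes to results/ so later steps can be checked against it.

Run from the repository root:  python analysis/01_simulate_inputs.py
"""

import json
from pathlib import Path

import numpy as np
import tifffile

from exmquant import synthetic as syn
from exmquant.image_io import write_stack

SCRATCH = Path("scratch/simulated")
RESULTS = Path("results")
SEED = 20240901


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    inventory = {}

    pre, post, pair_truth = syn.gen_expansion_pair(scale=4.0, warp_amplitude=3.0, seed=SEED)
    tifffile.imwrite(SCRATCH / "pre_expansion.tif", pre.astype(np.float32))
    write_stack(SCRATCH / "post_expansion.ome.tif", post)
    inventory["expansion_pair"] = {
        "scale": pair_truth.scale,
        "warp_amplitude_px": pair_truth.warp_amplitude,
        "n_keypoints": len(pair_truth.keypoint_truth),
        "content_z_window": list(pair_truth.content_z_window),
    }

    rounds, series_truth = syn.gen_round_series(n_rounds=3, alpha_per_round=(0.4, 0.4), seed=SEED)
    for i, r in enumerate(rounds, start=1):
        write_stack(SCRATCH / f"round{i}.ome.tif", r)
    inventory["round_series"] = {
        "alpha_per_round": series_truth.alpha_per_round.tolist(),
        "n_rounds": len(rounds),
    }

    emitters = syn.EmitterTruth(
        positions=np.random.default_rng(SEED).uniform(8, 40, (10, 2)),
        p_on=0.3, p_off=0.5, psf_sigma=1.8, photon_rate=400,
    )
    movie, states = syn.gen_blinking_movie(emitters, n_frames=100, seed=SEED)
    tifffile.imwrite(SCRATCH / "blinking_movie.tif", movie.frames.astype(np.float32))
    inventory["blinking_movie"] = {
        "n_frames": movie.n_frames,
        "n_emitters": len(emitters.positions),
        "mean_on_fraction": float(states.mean()),
    }

    mrounds, mtruth = syn.gen_multiplexed_experiment(seed=SEED)
    for i, r in enumerate(mrounds, start=1):
        write_stack(SCRATCH / f"multiplex_round{i}.ome.tif", r)
    inventory["multiplexed"] = {
        "markers": mtruth.marker_names,
        "alpha": mtruth.alpha.tolist(),
        "offsets": mtruth.offsets.tolist(),
        "nonzero_true_coloc_cells": int(
            (mtruth.coloc_matrix > 0).sum() - len(mtruth.marker_names)
        ),
    }

    (RESULTS / "simulated_inventory.json").write_text(json.dumps(inventory, indent=2))
    print(f"wrote images to {SCRATCH}/ and truth inventory to {RESULTS}/simulated_inventory.json")
    for k, v in inventory.items():
        print(f"  {k}: {v}")


if __name__ == "__main__":
    main()
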