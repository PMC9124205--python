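#!/usr/bin/env python
"""Full-scale training and benchmark protocol (extended run, hours on CPU).

Reproduces the complete pipeline at its published scale: 10000 patches of
cell-like scenes (7500/2000/500 split), the full-width BS-CNN
(32-64-128-512 encoder), 120 epochs with validation early stopping, then
Siemens-star inference averaged over N = 1000 illuminations, compared
against SAI and Lucy-Richardson at eta = 2.5.  The headline quantities are
the BS-CNN resolution improvement and fidelity.

This is deliberately not part of the test suite: expect several hours of
CPU time.  Run as

    python scripts/full_scale.py --seed 1 --out results/full_scale.json
"""

from __future__ import annotations

import argparse
import json
import os
import sys
import time

import numpy as np

import blindsim as bs
from blindsim.baselines import LRParams
from blindsim.bscnn import BSCNNConfig, build_model, deconvolve, make_dataset, train
from blindsim.sai import sai_reconstruct

STAR_PX = 128
STAR_FOV = 13.0
ETA = 2.5
N_FRAMES = 1000
D_PSF = STAR_PX / STAR_FOV
D_SP = D_PSF / ETA
N_PATCHES = 10000


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, required=True)
    parser.add_argument("--out", type=str, required=True)
    parser.add_argument(
        "--epochs", type=int, default=120, help="training epochs (120 = full protocol)"
    )
    args = parser.parse_args()

    root = np.random.SeedSequence(args.seed)
    speckle_seed, sai_seed, train_seed = (
        int(s) for s in root.generate_state(3) % (2**31)
    )
    t0 = time.time()

    # ---- dataset: 10000 patches from several large cell-like scenes ------
    patches = []
    scenes_needed = 8
    per_scene = N_PATCHES // scenes_needed
    for i in range(scenes_needed):
        scene = bs.make_cell_like_gt((1024, 1024), seed=train_seed + i)
        patches.extend(
            bs.extract_patches(scene, per_scene, patch_fov_in_dpsf=11.0,
                               seed=train_seed + 100 + i)
        )
    datasets = make_dataset(
        patches, D_SP, D_PSF, seed=train_seed + 1000, m_aux=600,
        split=(0.75, 0.20, 0.05),
    )
    print(f"dataset: {[len(d) for d in datasets]} samples "
          f"({time.time() - t0:.0f}s)", flush=True)

    cfg = BSCNNConfig(epochs=args.epochs, seed=train_seed)
    model = build_model(cfg)
    train(model, datasets, cfg)
    print(f"training done after {len(model.history['val_loss'])} epochs "
          f"({time.time() - t0:.0f}s)", flush=True)

    # ---- star benchmark at N = 1000 --------------------------------------
    star = bs.make_siemens_star(STAR_PX, STAR_FOV)
    psf = bs.airy_psf(D_PSF)
    stack = bs.speckle_stack(
        bs.SpeckleParams(d_sp=D_SP, seed=speckle_seed), N_FRAMES, star.shape
    )
    lr = bs.blur(bs.illuminate(star, stack), psf)
    hp = bs.hp_extract(lr)
    lr_mean = lr.mean_frame()
    radii = bs.default_ftc_radii(STAR_PX, D_SP, D_PSF)
    lr_curve = bs.ftc_curve(lr_mean, 20, radii, center=star.center)

    results: dict[str, dict] = {}

    def score(pixels: np.ndarray, tag: str) -> None:
        fid = bs.fidelity(pixels, star).value
        curve = bs.ftc_curve(pixels, 20, radii, center=star.center)
        try:
            imp = round(bs.resolution_improvement(curve, lr_curve), 4)
        except bs.UnresolvedError:
            imp = None
        results[f"{tag}_fidelity"] = {"value": round(fid, 4), "n": N_FRAMES}
        results[f"{tag}_resolution_improvement"] = {"value": imp, "n": N_FRAMES}

    recon = deconvolve(model, hp, pixel_pitch=star.pixel_pitch)
    score(recon.pixels, "bscnn")
    print(f"bscnn scored ({time.time() - t0:.0f}s)", flush=True)

    sai_result = sai_reconstruct(hp, D_SP, psf, seed=sai_seed, pixel_pitch=star.pixel_pitch)
    score(sai_result.reconstruction.pixels, "sai")
    print(f"sai scored ({time.time() - t0:.0f}s)", flush=True)

    lucy = bs.lucy_richardson(lr_mean, psf, LRParams(n_iter=50))
    score(lucy.pixels, "lucy")

    results["lr_fidelity"] = {"value": round(bs.fidelity(lr_mean, star).value, 4), "n": N_FRAMES}
    results["wall_time_s"] = {"value": round(time.time() - t0, 1), "n": 1}

    os.makedirs(os.path.dirname(os.path.abspath(args.out)), exist_ok=True)
    with open(args.out, "w") as fh:
        json.dump(results, fh, indent=2)
    print(json.dumps(results, indent=2))
    return 0


if __name__ == "__main__":
    sys.exit(main())
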