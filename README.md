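# usinr

Continuous 3D ultrasound reconstruction from sparse rotational 2D
B-mode sweeps, using implicit neural representations (INR).

## The problem

Volumetric ultrasound with 2D matrix arrays is expensive; a cheaper
route is to rotate an ordinary 1D-array transducer with a programmable
motor and stitch the 2D slices into a volume. With the pose known
exactly, the open question is the *representation*: voxel grids and
interpolation scale poorly in 3D, and every resampling needs a new
interpolation pass. This package instead fits a coordinate network

    F(x, y, z) = (I, S)

to one sweep at a time — a SIREN-style MLP over a harmonic positional
encoding that maps a world position (mm) to B-mode intensity `I` and
segmentation probability `S`. Training minimizes

    L = w_img · (1 − SSIM(Î, I)) + w_seg · (BCE(Ŝ, S) + (1 − Dice(Ŝ, S)) + FP(Ŝ, S))

over the acquired frames with Adam, cosine-annealed learning rate
(1e-3 → 1e-6) and EMA-amplified ("grokfast") gradients. The trained
network is a continuous, compressed volume: any plane, grid or
resolution — including ones never imaged — is a single function
evaluation, with cost independent of the dataset size. Objects are
measured by labelling the sampled segmentation volume (26-connected
components) and wrapping each in the convex hull of its voxels
(Dice, IoU, dB contrast and relative volume error 100·|V−V̂|/V are the
reported metrics).

It is intended for researchers working on 2D-to-3D ultrasound with
known probe trajectories: the package includes the rotational-sweep
geometry, a synthetic sphere-phantom simulator with exact masks (the
stand-in for an acoustic simulation pipeline), the dual-head INR and
its training loop (pure NumPy — no GPU or deep-learning framework
required), a nearest-neighbour baseline, and convex-hull volumetry.

## Worked example

Fit a reduced-width network to a 36-frame sweep of a two-sphere
anechoic phantom and measure the recovered volumes
(`examples/03_volumetry.py`, about three minutes on one CPU):

```text
sphere 1: dice 0.951  voxel volume 2.508 cm^3  hull volume 2.532 cm^3  analytic 2.585 cm^3  error 2.99%
sphere 2: dice 0.973  voxel volume 2.664 cm^3  hull volume 2.599 cm^3  analytic 2.657 cm^3  error 0.28%
mean volumetric accuracy: 98.27%
```

Each line compares one reconstructed sphere against its analytic
ground truth: `dice` is the voxel overlap with the rasterized truth,
the voxel volume counts segmented voxels, the hull volume is the
convex hull of those voxels (what a bead or tumour measurement would
use), and `error` is the relative voxel-volume error. The mean
volumetric accuracy is 100 minus the mean per-sphere voxel-count
error.

The other examples cover simulation (`01`), training + arbitrary
reslicing (`02`), the nearest-neighbour baseline comparison (`04`) and
the angular-resolution study (`05`). A thin CLI wraps the same calls:

```bash
usinr simulate --seed 1 --anechoic --step-deg 5 --out data/
usinr train --manifest data/manifest.json --width 24 --n-layers 6 --epochs 300 --out ckpt/
usinr sample --ckpt ckpt/model.npz --grid-n 128 --out volume.nii.gz
usinr extract --ckpt ckpt/model.npz --out meshes/
usinr info ckpt/model.npz
```

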