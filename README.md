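# voxelskel

Curve-skeleton extraction and volume reconstruction for point clouds of
**living architecture** — root bridges, grafted-tree pavilions and other
structures grown by merging trees.  Such structures are anastomotic: shoots
and roots fuse into networks with genuine loops, so any skeleton used for
mechanical or growth analysis must preserve topology exactly.  voxelskel
implements a nine-step workflow: PCA orientation, octree-style
voxelization, 6-connected denoising, recorded surface filling, internal
flood filling, topology-preserving sequential voxel thinning, branch/joint
segmentation, and volume reconstruction from per-voxel *iterations of
exposure*.

## The method in brief

A surface cloud is voxelized into an occupancy lattice and made solid.
Thinning then erodes the solid with 38 directional deletion templates
(four base templates with 6, 12, 8 and 12 unique rotations), deleting a
border voxel only when four criteria hold — its 26-adjacent object voxels
form one 26-connected component (a), its face-adjacent void belongs to one
6-connected component of the 18-neighbourhood void (b), and two
co-candidate arbitration rules (c), (d).  Every deletion is a simple
point, so the Betti triple (b0, b1, b2) — components, loops, cavities,
with b1 derived from the cubical Euler characteristic via
b1 = b0 + b2 − χ — is invariant through thinning.  Curve ends (voxels with
one 26-neighbour on a 1-voxel chain) are protected, so terminal branches
survive.

During erosion the cycle at which each voxel face first meets void is
recorded; the sorted first four values I1 ≤ I2 ≤ I3 ≤ I4 act as local
radius estimates (one cycle ≈ one shell).  The volume is rebuilt by
drawing in-plane disks of radius `radius_scale · I_n` (circular mode), or
ellipses whose ratio of major to minor axis ER is predicted from the
exposure ratio I4:I1 by a linear model fitted on samples of known ER
(elliptical mode).

## Worked example

Library use, on a synthetic cylinder (radius 4, length 48 voxels):

```python
import voxelskel as vs

phantom = vs.make_cylinder(4, 48)
grid = vs.grid_from_phantom(phantom)
skeleton = vs.thin(grid)
recon = vs.reconstruct_circular(skeleton, n=2)
rep = vs.replication_metrics(grid, recon.grid)

print(len(skeleton), skeleton.cycles)             # 40 5
print(skeleton.voxels[20].exposure)               # (4, 4, 4, 4)
print(vs.topology_report(skeleton.as_grid()).betti)  # (1, 0, 0)
print(round(rep.replicated_fraction, 3), round(rep.correct_fraction, 3))
# 0.833 1.0
```

The 2352-voxel solid cylinder thins in 5 cycles to a 40-voxel chain lying
on the axis; mid-chain voxels record I1..I4 = 4 — the true radius in voxel
widths — and the I2-based circular reconstruction recovers 83.3% of the
original voxels with every reconstructed voxel correct (the missing share
is the rounded free ends).

The same pipeline from the shell, on an anastomotic (torus) phantom:

```
$ voxelskel phantom torus --major-radius 8 --minor-radius 2 --seed 3 --out t
phantom: 560 voxels, cloud: 20012 points
$ voxelskel voxelize t_cloud.xyz --voxel-size 1.0 --out grid.txt
grid: dims=(25, 25, 9) occupied=1048
$ voxelskel skeletonize grid.txt --out skel.csv
skeleton: 44 voxels in 5 cycles (denoise removed 0)
$ voxelskel reconstruct skel.csv --exposure-index 2 --out recon.txt
reconstruction: 236 voxels (circular, I2)
$ voxelskel assess recon.txt
betti: b0=1 b1=1 b2=0 (chi=0)
```

The loop (b1 = 1) survives sampling, voxelization, thinning and
reconstruction end to end.  `voxelskel run --input cloud.ply --voxel-size
0.05 --out outdir` drives all nine steps at once and writes every artifact
with a JSON provenance header.

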