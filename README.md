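# vsdir

Volume-subdivision deformable image registration (DIR) for CT ↔ CBCT pairs,
as used in radiotherapy treatment tracking. The method is locally rigid but
globally nonrigid: the reference volume is split into a hierarchical octree,
every subvolume's rigid transform is refined by maximizing joint-histogram
mutual information with a bounded downhill simplex, and the finest-level
transforms are blended into a dense, fold-free deformation field by
quaternion-based cubic (Catmull–Rom) interpolation.

The package also ships the evaluation/QA toolchain (target registration error
from a documented reference point + couch shift, 3D SSIM, forward/reverse
self-consistency "STRE" with a voxel-size pass rule), a one-factor-at-a-time
parameter sweep harness, a queue/worker batch executor, and a deterministic
phantom generator that produces CT-like / CBCT-like pairs with known ground
truth, so no clinical data is needed to exercise anything.

## Layout

| module | contents |
|---|---|
| `vsdir.volume_io` | `Volume3D`, NIfTI / MetaImage / DICOM-series reading, NIfTI/MetaImage writing, grid resampling, deformation-field I/O |
| `vsdir.preprocess` | window/level rescale to [0, 255], per-axis Gaussian smoothing |
| `vsdir.similarity` | joint histogram, mutual information (bits), 3D SSIM |
| `vsdir.rigid` | rigid transforms + algebra, bounded Nelder–Mead, MI-driven rigid registration |
| `vsdir.subdivision` | octree subdivision, displacement caps, `hierarchical_register`, `ParameterSet` |
| `vsdir.deformation` | dense field interpolation, warping, Jacobian check, point mapping |
| `vsdir.evaluation_qa` | TRE, STRE, QA pass rule, parameter sweep |
| `vsdir.phantom` | synthetic pair generator with ground-truth fields and landmarks |
| `vsdir.batch_cli` / `vsdir.cli` | job queue, worker pool, manifest batches, `vsdir` CLI |

## CLI

```bash
# generate a synthetic pair with ground truth
vsdir phantom --out work/pair0 --seed 1 --deform-amplitude 6

# register one pair (optionally with the reverse-registration QA check)
vsdir register work/pair0/reference_cbct.nii work/pair0/floating_ct.nii \
    --annotation work/pair0/annotation.tsv --out work/reg0 --qa

# run a manifest of jobs on a local worker pool
vsdir batch manifest.tsv --workers 4 --ledger done.txt --out results.tsv

# 12-parameter-set sweep over the manifest's pairs
vsdir sweep manifest.tsv --out sweep.tsv

# metrics on existing deformation fields
vsdir evaluate work/reg0/field.nii --annotation work/pair0/annotation.tsv
```

Batch manifests are TSV with header
`job_id  reference  floating  annotation  params  output_dir`
(paths relative to the manifest; `params` is a flat key=value config written
by `ParameterSet.to_config`, or `default`).

## Notes

- Geometry is axis-aligned (index → mm via `origin + index * spacing`);
  oblique acquisitions are rejected rather than silently resampled.
- The deformation field maps reference (CBCT) points to floating (CT) points;
  warping the CT onto the CBCT grid therefore needs no field inversion.
- Registration is fully deterministic for a given input and `ParameterSet`,
  including under concurrent subvolume evaluation and any worker count.
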