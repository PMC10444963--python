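# emgan3d

A 3-D generative-adversarial toolkit that modifies experimental-quality
cryo-EM density maps toward high-resolution simulated maps, together with
the full data-preparation pipeline (grid resampling, normalization,
sliding-cube extraction and overlap-averaged merging), simulated-map
generation from atomic models, and evaluation metrics (cube
cross-correlation, per-residue real-space correlation).

The deep-learning core is implemented directly in NumPy (`emgan3d.nn`):
3-D convolutions, instance/group normalization, PReLU, dropout and Adam,
with hand-written reverse-mode gradients that are verified against finite
differences in the test suite. No GPU or deep-learning framework is
required.

## Layout

| module | role |
| --- | --- |
| `emgan3d.density_io` | MRC/CCP4 read/write, trilinear resampling to a uniform grid, min-max normalization |
| `emgan3d.map_simulation` | PDB parsing and simulated maps (Gaussian kernels, FWHM = nominal resolution), resolution-targeting rule |
| `emgan3d.cube_pipeline` | 25-cube / stride-4 extraction, valid-pair filtering, overlap-averaged merging |
| `emgan3d.gan_model` | generator (ResNet blocks + tanh head), discriminator (doubling channels, group norm), content/adversarial/generator/discriminator losses |
| `emgan3d.training` | map-level train/validation split, alternating GAN training, validation metrics |
| `emgan3d.evaluation` | cube cross-correlation, cube-wise improvement fractions, per-residue RSCC profiles |
| `emgan3d.synthetic_fixtures` | toy helix/strand/coil structures and paired low/high-resolution maps for testing and demos |
| `emgan3d.cli` | `emgan3d` command-line interface and the `enhance_map` pipeline |

## CLI

```bash
emgan3d fixtures --seed 7 --n-structures 5 --out fixtures/       # toy dataset (PDB + MRC pairs)
emgan3d resample --in map.mrc --out map1A.mrc --spacing 1.0
emgan3d normalize --in map1A.mrc --out norm.mrc
emgan3d simulate --pdb model.pdb --resolution 3.0 --out sim.mrc
emgan3d train --fixtures 7 --max-steps 300 --out run/            # desk-scale training demo
emgan3d enhance --in exp.mrc --checkpoint run/checkpoint.npz --out mod.mrc
emgan3d evaluate --map mod.mrc --pdb model.pdb --resolution 3.0 --out report/
```

Maps are canonicalized on read to `(z, y, x)` data order with `(x, y, z)`
physical origin/voxel-size vectors; files with permuted axis headers
(`mapc/mapr/maps`) are handled transparently. Inputs to the cube pipeline
must be resampled to 1.0 Å and normalized first (`enhance_map` does both
automatically).

Note on scale: the default network configuration matches the published
architecture (15 ResNet blocks / 32 channels; 10 discriminator layers up
to 512 channels). Training that configuration for 100 epochs is not
feasible on a laptop CPU in NumPy; the training demos and tests use the
reduced configuration in `emgan3d.presets` (3 blocks / 8 channels, a few
hundred steps), which the same code supports through `GeneratorConfig` /
`DiscriminatorConfig`. The tanh output head is initialized small and with
a sparse-density bias prior (`GeneratorConfig.output_init_scale`,
`output_bias_init`) — without this the head starts saturated on
mostly-zero density targets and gradients vanish.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` carries the property-based acceptance battery
(round-trip identities, loss identities, brute-force oracle comparisons,
simulation physics, supervised-limit and tiny-scale GAN learning,
determinism). The slowest test is the tiny-scale learning property
(a few minutes on one CPU).

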