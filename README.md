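# qlsm

Quantitative lightsheet microscopy (QLSM) analysis of calvarial
neurovascular architecture.

Cleared whole-mount calvaria imaged by lightsheet microscopy yield
multichannel 3D stacks — a pan-neuronal nerve marker plus the endothelial
markers CD31 and Endomucin (Emcn) — at strongly anisotropic resolution
(≈1.3 μm in-plane, 2.5 μm z step).  `qlsm` turns such stacks into the
quantities that characterize the skullcap's neurovascular architecture:

- **volume densities** — nerve or vessel volume normalized by region size;
- **vessel phenotype fractions** — the vasculature partitioned into
  CD31hiEmcn⁻, CD31hiEmcnhi ("type H") and CD31loEmcnhi by binary-mask
  presence/absence logic, each phenotype's volume normalized by the
  overall vessel volume;
- **periosteal / dural nerve fractions** — every ~10 μm nerve object
  assigned to the outer (periosteal) or inner (dural) side of a bone
  mid-surface fitted from the data;
- **spatial association** — the fraction of the nerve segmentation whose
  anisotropic Euclidean distance to each vessel phenotype is within
  d = 10 μm, the statistic behind "nerves preferentially associate with
  type-H vessels";
- **fiber diameters and the capture fraction** — skeleton-based diameter
  estimates, and P(D > r) for D ~ Normal(μ, σ), e.g. ≈95.8% of fibers with
  μ = 4.013 μm, σ = 1.57 μm are wider than a 1.3 μm pixel;
- **group statistics** — Welch t-tests and two-way ANOVA with Tukey HSD,
  written as per-metric CSV reports.

Nerve channels are segmented with a trainable random-forest pixel
classifier over a multi-scale feature stack; vessel channels with 10 μm
rolling background subtraction plus absolute thresholds; both pass a
10⁴ μm³ subcellular volume filter before analysis, and object-level work
happens on 2× down-sampled masks split into ~10 μm pieces by seeded
watershed.

Because the package is developed against no fixed raw dataset, it includes
a first-class **synthetic calvarial phantom**: a curved bone shell with
periosteal and dural layers, three non-interpenetrating vessel phenotype
networks, branching nerve trees with the truncated-normal diameter law
above, a dial (`coupling_rho`) that fixes the true fraction of nerve
segments within 10 μm of type-H vessels, realistic background gradients
and Poisson–Gaussian noise — all bit-reproducible from a seed, with full
voxel- and segment-level ground truth.  See `docs/methods.md` for the
model details and design choices.

## Worked example

```python
from qlsm.phantom import PhantomSpec, generate_phantom
from qlsm.config import PipelineConfig
from qlsm.pipeline import run_pipeline

spec = PhantomSpec(coupling_rho=0.5, rng_seed=1)   # dial: half the nerve
channels, truth = generate_phantom(spec)           # length near type H
cfg = PipelineConfig(phantom=spec.to_dict(), seed=1)
result = run_pipeline(cfg, channels=channels, ground_truth=truth)

print(round(result.densities["nerve"], 5))
print({k: round(v, 3) for k, v in result.phenotype_fractions.items() if k != "overall_vessel_volume_um3"})
print(round(result.association["P2"], 3), "truth:",
      round(truth.association_fraction_truth()["P2"], 3))
```

prints (64×256×256 phantom, ≈40 s on one core):

```
0.00584
{'P1': 0.27, 'P2': 0.425, 'P3': 0.304}
0.535 truth: 0.5
```

— the recovered nerve volume density (the generator placed 0.00579 of the
volume as nerve, so recovery is within 1%), the three phenotype volume
fractions (the generator renders type H slightly denser than the other
two), and the type-H association fraction, which lands on the dialed 0.5
within 0.04.

The same machinery is scriptable from a shell:

```bash
qlsm simulate --seed 1 --out phantom/          # stacks + ground truth
qlsm run-all --config config.yaml --out run1/  # full quantification
qlsm report --results groups.csv --out report/ # group statistics
```

For real data, point `input_paths` in the YAML config at one OME-TIFF per
channel (nerve / cd31 / emcn), supply classifier training labels as a
voxel CSV, and set the per-stain thresholds.

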