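# fiberwalk

Serotonergic axons ("fibers") permeate essentially every region of the
vertebrate brain, and the regional density of this meshwork matters for
neuroplasticity, regeneration and mental disorders — yet single fiber
trajectories are strongly stochastic. `fiberwalk` is a desk-scale, fully
tested simulator of the hypothesis that much of the regional density
pattern is generated by geometry alone: fibers are modeled as paths of
**reflected fractional Brownian motion (rFBM)** walking inside a 3D brain
shape assembled from stacked coronal sections, and the resulting voxel
occupancies are mapped to immunohistochemistry-like optical densities.

## Model

Each fiber is a discrete 3D walk

&nbsp;&nbsp;&nbsp;&nbsp;r<sub>n+1</sub> = r<sub>n</sub> + ξ<sub>n</sub>,

whose steps ξ<sub>n</sub> are three independent components of fractional
Gaussian noise with Hurst index *H* and per-component RMS step σ:

&nbsp;&nbsp;&nbsp;&nbsp;⟨ξ<sub>i,m</sub> ξ<sub>j,m+n</sub>⟩ = ½ δ<sub>ij</sub> σ² ( |n+1|<sup>2H</sup> − 2|n|<sup>2H</sup> + |n−1|<sup>2H</sup> ).

*H* > 0.5 gives persistent, superdiffusive motion (MSD ∝ t<sup>2H</sup>);
serotonergic fibers are well described by *H* ≈ 0.8. Defaults: *H* = 0.8,
σ = 0.4 grid units (one grid unit = 6.6 µm of tissue, so σ ≈ 2.6 µm).
A step whose endpoint would leave the allowed region (outer pial surface,
ventricles, the dorsomedial concavity, or the rostral/caudal stack faces)
is simply not carried out. Positions are pooled into 2×2×2-cell bins,
normalized to total one (d<sub>s</sub>), and transformed to optical
densities d<sub>o</sub> = 1 − exp(−k·d<sub>s</sub>), k = 10<sup>8.3</sup>
by default.

The geometry is a stack of coronal sections, each section a set of
contours stored as rows `(y, x_left, x_right)`; "forbidden" contours carve
out ventricles and concavities. Sections (80 µm apart) are subdivided into
twelve ~6.6 µm virtual slices by linear interpolation. Because no external
contour data are required, `fiberwalk.phantoms` generates slab, sphere and
brain-like geometries (ventricles, dorsomedial notch, embedded raphe-like
start cuboid) for every test.

## Worked example

```python
import numpy as np
import fiberwalk as fw

sections, start = fw.make_brain_phantom()      # synthetic brain-like stack
volume = fw.build_volume(sections)             # 12 virtual slices/section

cfg = fw.WalkConfig(
    noise=fw.NoiseParams(hurst=0.8, sigma=0.4, length=2**16),
    start=start, n_fibers=16, master_seed=42,
)
counts = fw.simulate_cohort(volume, cfg)       # streamed 2x2x2 bin counts
grid = fw.DensityGrid.from_counts(counts, k="auto")

print("positions tallied:", counts.sum())
print("sum d_s:", grid.d_s.sum())
prof = fw.border_distance_profile(grid, volume)
print(prof[["distance", "mean_d_s"]].round(6).to_string(index=False))
```

Output:

```
positions tallied: 1048592
sum d_s: 1.0000000000000002
 distance  mean_d_s
        0  0.000033
        1  0.000006
        2  0.000004
        3  0.000003
        4  0.000002
        5  0.000002
        6  0.000002
        7  0.000001
        8  0.000002
        9  0.000002
       10  0.000002
       11  0.000001
```

`positions tallied` is 16 fibers × (2<sup>16</sup> + 1) recorded positions;
`sum d_s` confirms the normalization. The profile gives the mean
normalized density per Chebyshev-distance shell from the nearest border:
densities in the outermost shell (distance 0) are roughly five-fold higher
than anywhere deeper — the border-accumulation effect of superdiffusive
reflected FBM that mirrors the high serotonergic fiber densities reported
in cortical layer I and periventricular tissue. For subdiffusive noise
(*H* < 0.5) the profile direction reverses.

A command line mirrors the library:

```sh
fiberwalk phantom --kind brainlike --out work/
fiberwalk simulate --stack work/stack.json --steps 65536 --fibers 16 \
    --master-seed 42 --auto-k --out work/run/
fiberwalk analyze hurst --length 65536 --out work/msd.csv
```

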