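# svrecon

Motion-corrected slice-to-volume registration and super-resolution
reconstruction for multi-stack 2D MRI, aimed at fetal cardiovascular imaging.

Fetal MRI acquires T2-weighted single-shot fast-spin-echo stacks — each 2D
slice is sharp, but the fetus moves between slices, so a stack is internally
inconsistent and no single acquisition gives a navigable 3D volume. `svrecon`
takes 6–12 overlapping stacks in three orthogonal orientations (1.25 × 1.25 mm
in-plane, 2.5 mm thick, 1.25 mm overlap), estimates an independent rigid
transform for every slice against an evolving volume estimate, rejects
motion- and noise-corrupted data by EM robust statistics, and solves an
edge-preserving super-resolution problem for an isotropic volume at
0.50–0.75 mm inside a thorax mask.

The forward model treats each acquired pixel as a PSF-weighted average of the
unknown volume `x` under its slice's rigid transform `T_i`:

    y_ij = s_i Σ_k m_ijk(T_i) x_k + ε_ij,   Σ_k m_ijk = 1

with per-slice gain `s_i`, a truncated anisotropic Gaussian slice-profile PSF
(through-plane FWHM = slice thickness), Gaussian-inlier / uniform-outlier
pixel posteriors `p_ij`, slice weights `w_i` from a second mixture, and a
Huber-type edge-preserving penalty on `x`. Reconstruction alternates
slice-to-volume registration (normalised cross-correlation, Powell,
coarse-to-fine) with gain estimation, EM, and gradient updates of `x`.

Because clinical fetal data cannot ship with a package, `svrecon` includes a
full in-silico validation: a digital thorax phantom with black-blood vessels
of known geometry, an acquisition simulator with per-slice fetal-like motion
and ground-truth transform logs, similarity/registration-error metrics, and
the measurement-agreement statistics used to compare 3D reconstructions with
a reference modality (ICC, Bland-Altman, Lilliefors KS, Wilcoxon signed rank,
identification summaries).

## Worked example

```python
from svrecon import (PhantomConfig, ProtocolConfig, ReconConfig,
                     generate_thorax_phantom, simulate_protocol, reconstruct,
                     volume_similarity, slice_tre, measure_vessel_diameter)

truth, vessels, mask = generate_thorax_phantom(PhantomConfig(seed=1))
stacks, motion = simulate_protocol(truth, ProtocolConfig(n_stacks=9, seed=1))

result = reconstruct(stacks, mask, ReconConfig(spacing=0.7))   # blind: no truth
sim = volume_similarity(result.volume, truth, mask)
tre = slice_tre(result.transforms_after, motion, stacks)
print(f"masked NCC {sim.ncc:.3f}, median slice TRE {tre.median:.2f} mm")
for v in vessels[:3]:
    m = measure_vessel_diameter(result.volume, v)
    print(f"{v.name}: true {2*v.radius:.2f} mm, measured {m.diameter_mm:.2f} mm")
```

On the default conditions (96³ phantom at 0.5 mm, 9 stacks, random-walk drift
of 0.1 mm/0.1° per slice with occasional 2 mm/2° jumps, noise σ=3) this
prints, for seed 1:

```
masked NCC 0.959, median slice TRE 0.97 mm
descending_aorta: true 5.50 mm, measured 5.29 mm
transverse_arch: true 5.00 mm, measured 4.92 mm
svc: true 4.50 mm, measured 4.24 mm
```

i.e. the blind reconstruction closely agrees with the hidden ground truth,
slice poses are recovered to well under the 1.25 mm slice spacing, and lumen
diameters measured on the reconstruction match the known vessel geometry to
better than 0.3 mm.

The same workflow is scriptable from the shell:

```
svrecon poc --seed 1 --out runs/poc          # full experiment + report.json
svrecon phantom --out runs/ph --seed 1
svrecon simulate --truth runs/ph/phantom.nii.gz --out runs/sim --seed 1
svrecon reconstruct --stacks runs/sim/stack00_axial.nii.gz ... \
    --mask runs/ph/mask.nii.gz --spacing 0.7 --out recon.nii.gz \
    --log transforms.txt --report exclusions.json
svrecon stats --measurements paired.csv --scores scores.csv --out stats.json
```

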