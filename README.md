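# telolamina

Quantification of telomere–LAP2α association and telomere–nuclear-lamina
distances in 3D structured-illumination (3D-SIM) microscopy volumes, with a
per-nucleus two-channel intensity-correlation stage and a synthetic-volume
generator with full ground truth.

## The problem

In Hutchinson–Gilford progeria (HGPS), the truncated lamin A variant
progerin disturbs the nucleoplasmic pool of LAP2α, a lamin-binding protein
that associates with telomeres. Deciding whether LAP2α sits *on* telomeres
or merely *near* them, and whether telomeres relocate relative to the
nuclear lamina, requires super-resolution imaging and careful spatial
statistics. This package implements that measurement pipeline for
three-channel volumes (lamin A, LAP2α, TRF1 as the telomere marker):

* **Radial profiles** — LAP2α intensity sampled along 8 rays at 45°
  intervals from each telomere center out to 400 nm in a projected 544 nm
  optical section, normalized per nucleus to the LAP2α min/max
  (`I_norm = (I − I_min)/(I_max − I_min)`), then averaged over telomeres
  as mean ± SEM. The distance of the curve's maximum distinguishes direct
  association (peak at ~0 nm) from displaced association (peak at
  360–400 nm).
* **Surface colocalization** — the LAP2α channel is binarized inside the
  nucleus (Otsu); per-nucleus coverage `LAP2c` (% of the nucleus section)
  and per-telomere coverage (% of the telomere's projected surface) feed a
  three-way classification: low (`< LAP2c − σ`), average (`LAP2c ± σ`),
  high (`> LAP2c + σ`).
* **Lamina distances** — exact anisotropic Euclidean distance (nm) from
  each telomere centroid to the nearest lamina-surface voxel, with a
  250 nm proximity criterion.
* **Intensity correlation** — per-nucleus mean intensities of two stains
  in 2-D fields (e.g. a chromatin mark vs progerin), with Pearson r,
  t-based p-value and Fisher-z 95% CI.

Since the study's microscopy data are not public, the `synthetic` module
generates calibrated volumes with known ground truth (ellipsoidal nucleus,
lamina shell, telomere and LAP2α foci, PSF blur, Poisson + Gaussian noise),
so every stage is tested by parameter recovery. See `docs/methods.md` for
the model, defaults and limitations.

## Worked example

Generate and analyze two synthetic conditions — wild-type-like (LAP2α foci
on telomere centers, 15.7% target coverage) and HGPS-like (foci displaced
380 nm, reduced association, 6.7% coverage):

```python
from telolamina import (SyntheticParams, aggregate_profiles,
                        analyses_to_tables, compare_means,
                        run_condition_batch)

conditions = {"wt": (0.0, 0.9, 0.157), "hgps": (380.0, 0.4, 0.067)}
profiles, tables = {}, {}
for name, (offset, assoc, target) in conditions.items():
    params = SyntheticParams(lap2_offset_nm=offset,
                             lap2_association_fraction=assoc,
                             lap2_target_coverage=target)
    prof, analyses = run_condition_batch(params, 5, seed=1)
    profiles[name] = prof
    tables[name] = analyses_to_tables(analyses, condition=name)

agg = aggregate_profiles(profiles)
for name in conditions:
    tel, nuc = tables[name]
    print(f"{name}: peak {agg[name].peak_nm:.0f} nm "
          f"(n={agg[name].n_profiles} telomeres), "
          f"LAP2c {nuc['lap2c_percent'].mean():.1f}%, "
          f"{100 * tel['within_threshold'].mean():.0f}% of telomeres "
          f"within 250 nm of the lamina")
comp = compare_means(tables["wt"][1]["lap2c_percent"],
                     tables["hgps"][1]["lap2c_percent"])
print(f"LAP2c wt vs hgps: t = {comp.statistic:.1f}, p = {comp.p_value:.2g}")
```

prints

```
wt: peak 0 nm (n=32 telomeres), LAP2c 15.3%, 31% of telomeres within 250 nm of the lamina
hgps: peak 400 nm (n=32 telomeres), LAP2c 6.4%, 31% of telomeres within 250 nm of the lamina
LAP2c wt vs hgps: t = 174.6, p = 4.4e-10
```

The aggregated LAP2α profile peaks on the telomere center in the
wild-type-like condition and 400 nm away in the HGPS-like condition; the
recovered section coverages match the generator targets; and the peripheral
telomere fraction is identical across conditions because telomere placement
is seeded independently of the LAP2α geometry (displaced association does
not move telomeres).

The same pipeline is scriptable from the shell:

```sh
telolamina simulate --out sim/ --n-nuclei 3 --seed 0
telolamina segment sim/nucleus_000.ome.tif --out seg/
telolamina analyze --out results/ --n-nuclei 5 --seed 0
telolamina scatter --n-nuclei 200 --target-r -0.43 --out corr/
telolamina report --telomeres results/telomeres.csv \
    --nuclei results/nuclei.csv --profiles results/profiles.csv --out report/
```

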