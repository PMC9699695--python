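# poremetrics

Quantitative analysis of molecular-dynamics simulations of
membrane-pore-forming proteins, built around the gasdermin-D N-terminal
domain (GSDMD^NT), the executor of pyroptotic cell death. After caspase
cleavage, GSDMD^NT assembles on the inner leaflet of the plasma membrane
into arcs and rings whose β-hairpins insert to form large pores; the
mechanics of that process are driven by membrane edge tension, specific
anionic-lipid binding, and the hydrophilicity of the pore lining.

The package implements the analysis layer of such a study as a tested,
reusable library, exercised on synthetic systems with known ground truth:

- **Edge tension from the pressure tensor.** For a bilayer ribbon with
  two open edges along *z* and fixed edge length,

  γ = (1/2) ⟨ Lx·Ly·[ (Pxx + Pyy)/2 − Pzz ] ⟩,

  converted from bar·nm² to pN (×0.1), with the statistical error from
  non-overlapping block averages (`edge_mechanics`).
- **Dual-cutoff lipid–protein contacts.** A contact opens when any lipid
  headgroup heavy atom comes within 3.6 Å of a protein heavy atom and is
  held until the pair distance exceeds 5 Å, suppressing
  rattling-in-a-cage artifacts; per-residue occupancy, per-species
  enrichment over leaflet abundance, and bridging lipids that span two
  adjacent subunits (`lipid_contacts`).
- **Ion permeation and water columns.** Full-traversal (two-boundary)
  crossing counts per species with periodic unwrapping, and a binned
  continuity test for the water column through the pore
  (`ion_transport`).
- **Pore and membrane geometry.** Largest-inscribed-disc pore radius on
  a rasterized midplane slab, crown-shaped membrane deformation
  profiles, hairpin tilt against the membrane plane, Kåsa circle fits
  with interface-crack detection, and local membrane thinning
  (`pore_geometry`).
- **Pore-lining hydrophilicity.** Eisenberg consensus-scale scoring of
  pore-facing β-strand residues and cross-protein comparison
  (`sequence hydrophobicity`).
- **Membrane composition planning.** Largest-remainder integer
  allocation of asymmetric plasma-membrane leaflet recipes, formal
  charge and counterion accounting, and post-clash leaflet rebalancing
  (`composition`).
- **Synthetic systems.** Seeded generators for every input class —
  pressure/box series, bilayer patches with pores/crowns/thinning,
  subunit rings with hairpins, planted contact schedules, ion z-paths —
  each shipping its ground truth for oracle tests (`synthetic`).

## Worked example

```python
import numpy as np
from poremetrics.edge_mechanics import (PressureBoxSeries, edge_tension,
                                        edge_free_energy)
from poremetrics.hydrophobicity import (GSDMD_PORE_FACING_STRANDS,
                                        GSDMA3_PORE_FACING_STRANDS,
                                        sheet_score, hydrophilicity_excess)

n = 500
series = PressureBoxSeries(time=np.arange(n, dtype=float),
                           Pxx=np.ones(n), Pyy=np.ones(n),
                           Pzz=np.full(n, -3.32),
                           Lx=np.full(n, 20.0), Ly=np.full(n, 20.0))
res = edge_tension(series, n_edges=2)
dF_J, dF_kbt = edge_free_energy(res.gamma, 1.0, 298.15)
print(f"gamma = {res.gamma:.1f} pN")
print(f"1 nm edge shortening releases {dF_kbt:.1f} kBT")

d = sheet_score(GSDMD_PORE_FACING_STRANDS)
a3 = sheet_score(GSDMA3_PORE_FACING_STRANDS)
print(f"GSDMD sheet {d.total:.2f} vs GSDMA3 {a3.total:.2f} kcal/mol "
      f"-> {hydrophilicity_excess(d.total, a3.total):.0f}% more hydrophilic")
```

prints

```
gamma = 86.4 pN
1 nm edge shortening releases 21.0 kBT
GSDMD sheet -11.63 vs GSDMA3 -7.19 kcal/mol -> 62% more hydrophilic
```

A 20×20 nm² box with a 4.32 bar normal-vs-lateral pressure anisotropy
carries 86.4 pN of tension per open edge — on the molecular scale a large
force, worth ~21 kBT per nm of edge shortening, which is what drives arc
cracking and pore closure. The GSDMD pore lining is substantially more
hydrophilic than GSDMA3's, rationalizing why membranes detach from one
but not the other.

The same operations are available from the shell:

```sh
poremetrics hydrophobicity
poremetrics plan-membrane --inner 99 --outer 100
poremetrics synth pressure-series --seed 7 --out fx/
poremetrics edge-tension fx/pressure_series.tsv
poremetrics run --config run.yaml --out out/
```

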