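# mbgag

Trajectory analysis of methylene blue–glycosaminoglycan binding: π–π stack
detection, anionic-site contact fractions, the sulfation-dependence
statistic *D*, and MM-GBSA component bookkeeping.

## The problem

Methylene blue (MB) is a planar, monocationic phenothiazine dye and a
classic metachromatic probe for glycosaminoglycans (GAGs) — the linear,
highly anionic polysaccharides (heparin, heparan sulfate, chondroitin
sulfate) of the extracellular matrix. MB binds GAGs electrostatically
through its terminal dimethylamino nitrogens, which carry the most
positive charge, and it self-associates into π–π stacked oligomers with an
inter-plane spacing of about 3.7 Å. Quantifying how many dyes bind a chain
at once, for how long, at which anionic-site types, and how this depends
on the chain's sulfation pattern is what turns MB into a usable GAG
sensor.

`mbgag` implements that analysis for anyone working with simulated (or
suitably coarse-grained) MB/GAG trajectories:

- **gag_models** — seven GAG decasaccharide presets (HP, deHP, CS4, CS6,
  HS1–HS3) with exact anionic-site inventories, plus the rigid planar MB
  template.
- **synthetic_traj** — scripted trajectories with exact ground truth
  (replacing expensive MD for testing), and a Metropolis Monte-Carlo
  generator with a stacking well, screened-Coulomb dye–site attraction and
  hard-core repulsion.
- **stack_analysis** — ring-plane fitting, inter-plane distances,
  parallel/antiparallel classification, stack enumeration as connected
  components of a geometric contact graph.
- **contact_analysis** — distances between terminal nitrogens and sulfate
  sulfurs / carboxylate carbons, per-site-type contact fractions at an
  8 Å cutoff, simultaneous-binder counts, chain-bending ratio.
- **sulfation_metric** — the statistic *D* = *n*<sub>MB</sub> · *t* /
  *n*<sub>SO3</sub>: number of simultaneously bound dyes, times the time
  fraction spent at that count, per sulfate group (undefined for
  desulfated chains).
- **energetics** — MM-GBSA bookkeeping: the ≥3-bound frame filter,
  per-drug normalization, the additivity identity ΔG = ΔG_vdW + ΔG_esurf +
  (ΔG_eel + ΔG_egb), and a transparent surrogate scorer for end-to-end
  synthetic runs.
- **io_cli** — multi-model PDB / extended-XYZ trajectory IO with a
  topology sidecar, TSV tables, and the `mbgag` command-line pipeline.

## Worked example

```python
from mbgag.synthetic_traj import (hp_reference_scenario,
                                  binding_fraction_scenario,
                                  generate_scripted)
from mbgag.stack_analysis import stack_statistics
from mbgag.contact_analysis import binding_summary
from mbgag.gag_models import build_gag
from mbgag.sulfation_metric import compute_D

# the heparin scene: a 4-stack and a 6-stack, bound, all frames
traj, truth = generate_scripted(hp_reference_scenario(n_frames=100))
s = stack_statistics(traj)
print(s.size_histogram)            # {4: 1.0, 6: 1.0}
print(round(s.mean_spacing, 3))    # 3.7
print(s.orientation_counts)        # {'antiparallel': 800}

# ten dyes bound simultaneously in 42% of 1000 frames
traj2, _ = generate_scripted(
    binding_fraction_scenario("HP", 0.42, n_frames=1000, seed=0))
chain = build_gag("HP")
b = binding_summary(traj2, chain)
print(b.n_mb, b.t, chain.n_sulfates)            # 10 0.42 15
print(compute_D(b.n_mb, b.t, chain.n_sulfates).rounded)  # 0.28
```

The first block detects exactly the scripted stacks (one tetramer, one
hexamer per frame, alternating orientations → 8 antiparallel consecutive
pairs × 100 frames) at the scripted 3.7 Å spacing. The second recovers
the scheduled occupancy from coordinates alone — ten binders within the
8 Å cutoff in 42% of frames — and evaluates *D* = 10 × 0.42 / 15 = 0.28
for heparin's 15 sulfates.

The same pipeline runs from the shell:

```bash
mbgag run --gag HP --frames 200 --seed 1 --out out/
mbgag simulate --mode mc --gag CS4 --frames 500 --seed 2 --out sim
mbgag stacks --traj sim.pdb --topology sim_topology.tsv --out stacks.tsv
```

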