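# cypwater

Hydration analysis of buried cytochrome P450 (CYP) binding sites from
molecular-dynamics snapshots.

CYP enzymes (isoforms such as 1A2, 2D6 and 3A4 dominate human drug
metabolism) have buried binding sites next to a heme cofactor. Whether and
how fast water exchanges between such a buried site and the bulk solvent is
a sensitive readout of conformational gating: a rigid protein can seal the
site completely, while the natural conformational ensemble opens transient
channels. This package implements the snapshot-level analyses that quantify
this behaviour, together with a synthetic gated-cavity trajectory generator
so every analysis can be validated against planted ground truth.

## What it computes

- **Iron-seeded water clusters** (`cypwater.network`). Waters form a graph
  with an edge whenever two oxygens are within 3.5 Å (a purely geometric
  hydrogen-bond criterion). The binding-site cluster is the union of
  connected components containing any water ligated to the heme iron
  (O–Fe ≤ 3.5 Å). Cluster sizes are strongly bimodal — isolated clusters of
  at most a few tens of waters versus bulk components of thousands — so a
  frame is classified *bulk-connected* when the cluster reaches a threshold
  (default 1000) inside that gap. Per-stage bulk ratios are averaged across
  replicate trajectories.
- **Alpha-sphere pockets** (`cypwater.pocket`). Pockets are sets of alpha
  spheres (as emitted by fpocket); a water is in the pocket iff its oxygen
  lies within the radius of any sphere. Pocket volume is estimated by Monte
  Carlo rejection sampling of the union of spheres, with a binomial standard
  error. The crystallographic binding-site residue lists for 1A2/2D6/3A4
  (20/34/46 amino acids + heme) ship as packaged reference data.
- **Residence correlation** (`cypwater.kinetics`). For pocket-occupant id
  sets A (time *t*) and B (time *t* + Δ*t*),

      C(Δt) = ⟨ n_persistent / (n_persistent + n_transient) ⟩_t ,

  with n_persistent = |A∩B| and n_transient = |A△B|. C(0) = 1 whenever
  occupancy is non-empty and C = 0 under complete exchange. An exchange
  rate λ can be fitted through the survival-fraction transform
  q = 2C/(1+C), q(Δt) = exp(−λΔt) (an extension beyond the correlation
  curve itself, labelled as model-derived in output).
- **Two-pass RMSF** (`cypwater.rmsf`). Frames are Kabsch-superposed onto a
  reference on all Cα atoms; per-Cα RMSF is computed about the ensemble
  mean; the alignment is repeated using only Cα atoms with first-pass
  RMSF < 2 Å; Cα and per-residue sidechain RMSF (root-mean-square over
  sidechain heavy atoms) are reported from the second alignment.
- **Synthetic gated cavity** (`cypwater.synthetic`). A geometric toy
  enzyme: rigid shell, central iron with a ligated water, lattice-packed
  cavity waters (hydrogen-bond connected by construction), bulk lattice
  outside, and a channel corridor present only when the gate is open.
  Identity exchange at a known per-frame probability and Gaussian jitter
  emulate the staged-flexibility protocols; presets `1A2-like`, `2D6-like`
  and `3A4-like` reproduce the qualitative phenomenology of a sealed
  versus an open binding site.

## Worked example

```
cypwater analyze --preset 1A2-like --n-frames 100 --n-replicates 3 --seed 7 --out demo_out
```

prints (one line per solvation protocol × stage):

```
2A Stage 1: bulk ratio 0.000 ± 0.000, modal volume 600 A^3
2A Stage 2: bulk ratio 0.000 ± 0.000, modal volume 600 A^3
2A Stage 3: bulk ratio 0.317 ± 0.021, modal volume 600 A^3
2A Stage 4.1: bulk ratio 1.000 ± 0.000, modal volume 600 A^3
2A Stage 4.2: bulk ratio 1.000 ± 0.000, modal volume 600 A^3
3A Stage 1: bulk ratio 0.000 ± 0.000, modal volume 600 A^3
3A Stage 2: bulk ratio 0.000 ± 0.000, modal volume 600 A^3
3A Stage 3: bulk ratio 0.277 ± 0.078, modal volume 600 A^3
3A Stage 4.1: bulk ratio 1.000 ± 0.000, modal volume 600 A^3
3A Stage 4.2: bulk ratio 1.000 ± 0.000, modal volume 600 A^3
```

The sealed-cavity preset keeps the binding site isolated while the gate is
closed (stages 1–2: bulk ratio 0), connects it in ~30% of frames under the
intermittent gate (stage 3), and connects essentially every frame once the
gate is open (stages 4.x). The `±` value is the standard deviation of the
ratio across the three replicates; the modal volume is the peak of the
per-frame Monte Carlo pocket-volume distribution. `demo_out/` additionally
contains per-replicate correlation curves, volume and water-count tables,
and the aggregated two-pass RMSF profile as CSV, plus `summary.json` with
provenance (config hash, seed, version).

Other CLI verbs: `generate` (write synthetic fixture trajectories with
ground truth), `cluster`, `correlate`, `volume`, `rmsf` — all thin wrappers
over the library functions.

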