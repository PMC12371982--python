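# knobdyn

Trajectory analysis for hinged two-domain proteins — built for bovine
antibodies with ultralong CDRH3 loops, where a disulfide-stabilized
**knob** minidomain sits at the end of a two-stranded β-ribbon **stalk**
protruding from the antibody **core** (the globular heavy-chain part plus
the light chain). Crystal structures show this assembly in an extended
conformation; in solution the stalk bends and the knob explores a wide
range of positions. `knobdyn` quantifies that motion from simulation
trajectories and locates the hinges and contacts that shape it.

For structural bioinformaticians and simulation practitioners, it
provides:

* **Domain-partitioned RMSD** — per-frame RMSD of the core (fit and
  measure on the core backbone) and of the entire system (fit on the
  core, measure everywhere, so knob excursions register).
* **Knob translational/rotational offsets** via a two-step Kabsch fit:
  superpose each frame on the reference by the core, then fit the
  core-aligned knob onto the reference knob. The centroid shift (Å) and
  the rotation magnitude θ = arccos((tr R − 1)/2) (deg) of the second fit
  are the per-frame offsets.
* **Hinge mapping by torsion-angle fluctuation (TAF)** — the circular
  variance 1 − |mean(cos θ, sin θ)| of each backbone φ/ψ over the
  trajectory, in [0, 1]; stalk residues with TAF > 0.6 are flagged as
  hinges.
* **Knob–light-chain van der Waals energetics** — 12-6 Lennard-Jones
  group interaction energies (AMBER-convention parameters, 12 Å cutoff),
  run-averaged summaries, local-minimum snapshot selection, and
  polar/nonpolar residue contact classification (4.5 Å contact,
  3.5 Å N/O–N/O polar cutoffs).
* **A synthetic benchmark generator** — hinged two-domain trajectories
  with exact ground truth (applied hinge angles, knob displacements, the
  flexible residue, planted contact episodes) so the entire pipeline is
  testable without any external data.

Trajectories are exchanged as multi-model PDB; all tables are CSV. See
`docs/methods.md` for the underlying models and conventions.

## Worked example

Generate a 200-frame benchmark whose knob flips between the extended
state and a 150°-bent state (hinge in the N-terminal stalk strand), with
a knob–light-chain contact episode planted in frames 60–100 and 0.2 Å
coordinate noise, then analyze it:

```bash
knobdyn synth --out bench --n-frames 200 --schedule two_state \
        --amplitude 150 --noise 0.2 --episode 60 100 --seed 1
knobdyn taf     --traj bench/trajectory.pdb --ref bench/reference.pdb \
        --config bench/domains.yaml --out analysis
knobdyn offsets --traj bench/trajectory.pdb --ref bench/reference.pdb \
        --config bench/domains.yaml --out analysis
knobdyn energy  --traj bench/trajectory.pdb --ref bench/reference.pdb \
        --config bench/domains.yaml --out analysis
```

which prints:

```
wrote trajectory (200 frames), ground truth and domain config to bench
1 hinge residue(s) above TAF 0.6: H:44
mean offsets: 9.56 Å / 87.29 deg
mean knob-LC E_vdW -2.94 kcal/mol; 1 local minima
```

Reading the numbers: the TAF scan over the stalk flags exactly residue
H:44 — the residue the generator designated as the hinge. The mean
offsets (9.56 Å translation, 87.29° rotation) reflect a knob that spends
about half its time bent by 150°; per-frame values are in
`analysis/offsets.csv`. The knob–light-chain vdW energy averages
−2.94 kcal/mol and its one detected local minimum (`analysis/minima.csv`,
frame 95, −5.37 kcal/mol) falls inside the planted 60–100 contact
episode. `knobdyn contacts --frame 95 ...` would then list the residue
pairs holding that bent state together, classified polar/nonpolar.

For replicate production runs, `knobdyn report --config analysis.yaml`
executes the whole pipeline (RMSD series → offsets → motion summary →
TAF/hinge map → energy series → run-averaged energy table → minima →
contact reports and snapshots) and writes per-frame CSVs, two-decimal
summary tables, and figures into one output directory. The same
functionality is available as a library (`knobdyn.pipeline.run_full_analysis`).

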