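# pocketswitch

Toy-scale thermodynamics and kinetics of a covalently tethered,
photoswitchable receptor agonist leaving the orthosteric binding pocket.

## The scientific problem

A photoswitchable agonist tethered to an engineered cysteine near a GPCR's
orthosteric pocket can be toggled between its *E* and *Z* isomers while
bound. Whether that photoswitching happens *inside* the pocket (direct
pathway) or only after the ligand has exited the receptor (indirect pathway:
exit → switch → re-entry) decides whether such a compound is usable as a
kinetic probe of receptor activation. The question is settled by comparing
the pocket residence time against the switching rate: if the ligand stays
bound for much longer than a switching cycle, switching is confined to the
pocket.

`pocketswitch` rebuilds the full computational inference chain for this
question at desk scale, replacing the atomistic receptor–ligand system with
analytic model landscapes so that every stage can be validated against exact
oracles:

1. **Synthetic landscapes** (`toy_systems`) — a 2D exit-path surface with a
   deep bound basin (the orthosteric pocket), shallower vestibule
   intermediates, a flat unbound region, funnel-shaped lateral confinement,
   a capped half-harmonic tether emulating the covalent disulfide anchor,
   and paired E/Z surface variants differing only in bound-basin depth.
2. **Overdamped Langevin dynamics** (`dynamics`) — Euler–Maruyama
   integration with reflecting boundaries, mid-run surface switching (the
   in-silico isomerization), and brute-force first-passage oracles.
3. **Multiple-walker well-tempered metadynamics** (`metad`) — shared-bias
   Gaussian hill deposition on the exit coordinate s, free-energy recovery
   via F(s) = −γ/(γ−1)·V(s), final-bias frame reweighting, and
   PLUMED-dialect HILLS/COLVAR text I/O.
4. **Interaction-fingerprint states** (`states`) — frames labelled by
   region, key-contact flag and tether-extension bin; microstates above a
   probability floor; pocket / intermediate / outside macrostates;
   reweighted populations and inter-group ΔF with block-bootstrap errors.
5. **Maximum-Caliber Markov state model** (`maxcal`) — the transition
   matrix maximizing path entropy −Σᵢ πᵢ Σⱼ p_ij ln p_ij subject to row
   normalization, detailed balance against the metadynamics-derived π,
   adjacency support, and a mean jump-rate constraint; solved by a dual
   fixed point (x_ij = λ√(x_ii x_jj)) to near machine precision.
6. **Transition path theory** — committors, set-to-set mean first-passage
   times (MFPT), macrostate residence times, bootstrap uncertainties, and
   the tethered-vs-free comparison that yields the in-pocket switching
   probability P = k_switch/(k_switch + 1/τ_pocket) and the final verdict.

All quantities are in reduced units (kT = 1, unit length, unit friction);
one optional scale factor maps reduced time to physical time.

## Worked example

```python
import pocketswitch as ps
from pocketswitch import pipeline

results = pipeline.run_pipeline({"seed": 1}, "run1")
free = results["conditions"]["free-Z"]
print(free["group_probability"])
print(free["delta_F_groups_kT"]["intermediate->pocket"])
print(free["mfpt"]["pocket->outside"])
print(results["comparison_Z"]["residence_ratio_tethered_over_free"])
print(results["comparison_Z"]["verdict"])
```

prints (seed 1):

```
{'intermediate': 0.00854, 'outside': 0.00114, 'pocket': 0.99032}
[4.75, 0.10]
{'mean': 39304.5, 'sd': 2813.5}
[2.05, 0.14]
in-pocket
```

Read: on the free (non-covalent) Z landscape the pocket holds 99% of the
equilibrium population, the vestibule intermediates sit 4.75 ± 0.10 kT
above it, and the model MFPT from pocket to unbound is ≈3.9×10⁴ reduced
time units (the direct Langevin value is ≈3.4×10⁴, i.e. the MSM is within
a factor 1.2 of brute force). The covalent tether lengthens the pocket
residence time by a factor 2.05 ± 0.14, and because switching (rate 1 per
reduced time) is ~10⁴ times faster than pocket escape, the verdict is that
isomerization happens inside the pocket — the direct pathway.

The same pipeline is available from the shell:

```bash
pocketswitch run-all --seed 1 --outdir run1
pocketswitch report --outdir run1
```

Other subcommands (`simulate`, `metad`, `analyze-states`, `kinetics`,
`fixtures`) expose the individual stages; outputs are plain-text HILLS,
COLVAR, free-energy tables and a deterministic `results.json`
(byte-identical for identical config + seed).

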