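# idrscope

Tools for quantifying the chain dimensions of intrinsically disordered
protein regions (IDRs) from single-molecule FRET, polymer theory and
coarse-grained simulation — aimed at biophysicists who measure transfer
efficiencies on labeled disordered proteins and want to turn them into
distance distributions, scaling exponents and residue-level ensemble
descriptions.

## What it does

* **`seqfeat`** — sequence descriptors of disordered regions: normalized
  Kyte–Doolittle hydrophobicity, FCR, NCPR, the Das–Pappu charge-patterning
  factor κ, sequence charge decoration
  SCD = (1/N) Σ_{i<j} q_i q_j √(j−i), and per-residue/group composition
  fractions.
* **`smfret`** — photon-level burst analysis under pulsed interleaved
  excitation: burst search on interphoton times (<150 µs, ≥50 photons),
  dual-channel filtering, background/crosstalk/direct-excitation/γ
  corrections, stoichiometry S = n_tot,Dex/(n_tot,Dex+n_tot,Aex) and
  efficiency E = n_A/(n_A+n_D), Gaussian peak fits of E histograms.
* **`polymer`** — the SAW-ν model: a self-avoiding-walk-like end-to-end
  distance density P(x) ∝ x^{2+g} e^{−αx^δ} (x = r/R, g = (γ−1)/ν,
  δ = 1/(1−ν)) with R = b·N_eff^ν, inverted from a measured ⟨E⟩ via
  ⟨E⟩ = ∫P(r)/(1+(r/R0)^6)dr.
* **`cgsim`** — a one-bead-per-residue stickiness (HPS) model with explicit
  multi-bead dyes: Ashbaugh–Hatch short-range potential scaled by per-type
  λ, Debye–Hückel electrostatics, BAOAB Langevin dynamics (300 K, 10 fs,
  1 ps⁻¹), bit-reproducible under a seed.
* **`fbopt`** — force-balance optimization of the λ vector (residues + dye
  beads) against measured ⟨E⟩ values, with linear-response gradients and L2
  starting-point regularization.
* **`maxent`** — maximum-entropy ensemble reweighting
  (w_i ∝ w⁰_i e^{−θE_i}) to match a measured ⟨E⟩ within its error, with
  Kullback–Leibler divergence diagnostics and a 0.1-nat flagging cutoff.
* **`dyemap`** — rotamer-library dye attachment to ensemble frames with
  5 Å clash rejection and per-frame Förster efficiencies.
* **`ensana`** — weighted-ensemble analytics: internal scaling profiles and
  homopolymer fits ⟨R⟩(s) = A0·s^ν, scaled distance maps, contact
  maps/networks, Rg/asphericity, Debye-formula SAXS profiles, OLS
  regression with Lin's concordance coefficient.
* **`synthdata`** — seeded generators (sequences, ensembles, photon
  streams) with truth sidecars for every stage.

## Worked example

Invert a mean transfer efficiency into a distance distribution:

```python
from idrscope import polymer

R, nu, model = polymer.infer_R_nu(0.4, R0=6.0)   # N_eff = 68, b = 0.55 nm
print(f"R = {R:.2f} nm, nu = {nu:.3f}")
```

prints

```
R = 7.49 nm, nu = 0.619
```

meaning a chain with mean transfer efficiency 0.4 between dyes with a 6 nm
Förster radius has a root-mean-squared end-to-end distance of about 7.5 nm
and behaves like an excluded-volume coil (ν near 0.6).  Repeating with
⟨E⟩ = 0.9 gives R = 3.68 nm and ν = 0.451, an almost-theta-state chain —
the same measurement scale spans nearly the full conformational range of
disordered proteins.

Run a coarse-grained simulation of a labeled construct and compare:

```python
from idrscope import cgsim

seq = "GSGSC" + "G" * 57 + "CTLGPR"
con = cgsim.FRETConstruct(seq, 4, 62, dye1="Cy3B", dye2="CF660R")
top = cgsim.build_topology(con)
traj = cgsim.run_langevin(top, cgsim.HPSParameterSet.default(),
                          n_steps=2_000_000, seed=1)
e_mean, _ = cgsim.fret_from_trajectory(traj, top.dye_center_beads, 6.0)
```

A command-line interface mirrors the main stages
(`idrscope seqfeat|smfret|polymer|cgsim|maxent|ensana`).

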