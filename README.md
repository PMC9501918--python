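# pegkin

Structure-dependent reactivity modelling of protein amine PEGylation.

Random (amine-targeted) PEGylation of a therapeutic protein produces a
heterogeneous mixture of "PEGmers" — conjugates carrying different numbers
of PEG chains at different lysine ε-amines and N-termini — whose
composition determines yield, purification cost, and therapeutic efficacy.
`pegkin` is for bioconjugation scientists who want to predict that outcome
from a crystal structure instead of a screening campaign: it predicts which
amine sites react and how fast, simulates the full reaction including
reagent hydrolysis and the steric shielding exerted by already-attached
chains, and fits the model's free parameters to measured progress curves.

## The model

**Per-site intrinsic reactivity** (M⁻¹·min⁻¹) is predicted from molecular
descriptors of each amine site — probe-exposed surface area (ESA, Å²,
computed with a Shrake–Rupley rolling ball whose probe mimics the PEG
reagent's size), amine pKa, Coulombic surface charge, and secondary
structure — by one of three models:

- linear: `k = α·ESA + β·pKa + γ`
- tertiary-structure-based: helix sites as above; β-sheet/coil sites gain a
  charge term `+ δ·q`
- machine-learned: a 2×4-node ReLU feed-forward network on standardized
  descriptors.

Sites predicted below a reactivity cutoff (3.9 M⁻¹·min⁻¹) are
non-reactive. The published lysozyme-fitted coefficients
(α₁ = 0.06, β₁ = −1.32, γ₁ = 15.02, …) ship as ready-made models.

**The reaction** is simulated by alternating a Gillespie-like draw — the
next modified site is selected with probability proportional to its
predicted reactivity — with a radial shielding rule: every still-reactive
site within a distance cutoff R of a modified site's amine nitrogen becomes
permanently blocked. The resulting per-step averaged rate constants
k_j,avg drive an N+3 ODE system for the PEGmer concentrations P_j, the
active reagent PEG, and its hydrolysis product PEG_d:

    dP_j/dt   = ε·k_j·φ_j·PEG·P_{j−1} − ε·k_{j+1}·φ_{j+1}·PEG·P_j
    dPEG/dt   = −k_d·PEG − Σ_j ε·k_j·φ_j·PEG·P_{j−1}
    dPEG_d/dt = k_d·PEG

with ε a linker/conditions prefactor, φ_j = exp(−κ·(j−1)·π·R²) a
diffusional attenuation governed by κ, and k_d the linker hydrolysis rate
(0.21 min⁻¹ for mPEG-NHS, ~0.01 min⁻¹ for mPEG-SPA/SMB). Fitting (κ, ε, R)
to experimental curves minimizes the pooled RMSE and reports F-test 95%
confidence intervals. A Flory-radius diagnostic R_f/D = a·N^(3/5)/D
classifies the grafted PEG layer as dumbbell (≤2) or brush (>2).

## Worked example

```python
import numpy as np
import pegkin as pk

pdb_text = pk.make_toy_structure(pk.ToySpec(n_lysines=4, placement="line",
                                            spacing=13.0, helix_fraction=0.5))
structure = pk.parse_pdb(pdb_text)
sites = pk.amine_sites(structure, include_n_terminus=False)
probe = pk.probe_radius_for(peg_mw_kda=5, protein_mw_kda=structure.molecular_weight / 1000)
pk.annotate_sites(sites, structure, probe)
pk.load_site_descriptors(sites, "site_id,pka\n" + "\n".join(f"A:K{i},10.0" for i in range(1, 5)))

model = pk.published_linear_model()
for s in sites:
    print(s.site_id, round(model.predict(s), 2))

seq, k_avg = pk.reaction_sequence(sites, model, shield_radius=11.0, seed=1)
params = pk.KineticParameters(k_d=0.01, kappa=2.8e-3, epsilon=3.0,
                              shield_radius=11.0, protein0=1e-5, peg0=2e-4)
result = pk.simulate(params, k_avg, np.linspace(0, 120, 50))
print("sequence:", seq)
print("PEGmer fractions at 120 min:", np.round(pk.pegmer_distribution(result, 120.0), 3))
```

prints

```
A:K1 128.31
A:K2 77.84
A:K3 77.84
A:K4 126.47
sequence: ['A:K3', 'A:K4', 'A:K1', 'A:K2']
PEGmer fractions at 120 min: [0.018 0.33  0.52  0.126 0.005]
```

The terminal lysines of the toy chain are more exposed, so their
predicted intrinsic rates (128, 126 M⁻¹·min⁻¹) exceed the interior ones
(both 77.8); the seeded stochastic draw picks one modification order out
of the reactivity-weighted ensemble; after 120 min the simulated mixture
is dominated by mono- and di-PEGylated protein, the higher PEGmers being
suppressed by the diffusional attenuation κ and by reagent hydrolysis.

The same pipeline is scriptable from the shell (`pegkin descriptors`,
`predict`, `simulate`, `fit`, `distance-map`, `rfd`); see `pegkin --help`.

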