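# foldpath

Prediction of protein folding routes by optimal control over a
coarse-grained Gaussian network, using only the native structure as
input.

## The problem and the model

Two-state proteins tend to fold by closing small loops first: local
contacts (helices, turns) form before tertiary pairings, because small
loop closures cost little conformational entropy. `foldpath` turns that
principle into a dynamic optimization. Each residue is a bead at its Cα
position; deviations **x** = **R** − **R**ᴺ from the native coordinates
evolve per Cartesian axis under overdamped dynamics

    β dx/dt = Γ x + u,

where Γ = −γ·L is the connectivity (Kirchhoff) matrix of the starting
conformation's contact graph and **u** is a control force field. The
controller minimises the infinite-horizon quadratic objective

    J = ∫₀^∞ ( xᵀQx + α uᵀPu ) dt,

whose first term is the harmonic excess energy above the native state
and whose second term penalises the large forces that high-entropy-loss
routes would need; α tunes the compromise. With the contact map C of the
current conformation (cutoff 7 Å), the energy weight is

    Q = L − L_bb + εI,

the contact Laplacian minus the covalent-backbone Laplacian, shifted by
a small ε > 0 so the translational zero mode is stabilised. The optimal
law is the constant linear feedback u = −Kx from the algebraic Riccati
equation, and K decomposes exactly as

    K = K′ + kI,      k = √(ε/α),

a zero-row-sum spring matrix K′ (pairwise springs the controller adds to
the network) plus identical weak springs k anchoring every bead to its
native position. The closed loop is again a Gaussian network,
A_cl = (Γ − K′ − kI)/β.

Folding is simulated as a *learning* control loop: propagate the closed
loop for one sampling interval, re-measure the contacts, rebuild Q,
re-solve the Riccati equation, repeat until the dynamic contact map
equals the native map. The order in which the dynamic map fills in is
the predicted folding route; contact events, fractional cluster contacts
f(t), radius of gyration and effective contact order (ECO) quantify it.

## Worked example

Fold the built-in 20-residue helix-hairpin (two 8-residue helices, a
4-residue turn, six designed tertiary contacts) from a fully extended
chain:

```
$ foldpath run --fixture helix_hairpin --out routes/
helix_hairpin_20|extended: converged in 20 cycles (final time 20); outputs in routes
```

The run converges: the final contact map equals the native one and the
final RMSD is 0.012 Å. `routes/contact_events.csv` lists every contact
with its initiation time; splitting by sequence separation |i−j|:

* median t_init of local contacts (|i−j| ≤ 6): **1.2**
* median t_init of non-local contacts (|i−j| ≥ 12): **16.7**

— the local clusters form an order of magnitude earlier than the
tertiary pairings, the zipping behaviour the model is built to capture.
Increasing the entropy-penalty weight α slows compaction without
changing the route: the time for the radius-of-gyration gap to halve is
1.6 / 3.4 / 8.0 time units at α = 0.1 / 1 / 10, while the control cost
∫αuᵀPu falls (562 → 229 → 32) and the energy cost ∫xᵀQx rises
(1697 → 2990 → 3430). Times are in the arbitrary units of the
overdamped model (β = γ = 1).

Real structures work the same way, e.g.
`foldpath run --pdb 1bnz.pdb --chain A --out sso7d/` (the PDB file is a
user input; nothing is downloaded). Cluster definitions for f(t) curves
are supplied as a small YAML file of contact-map rectangles, see
`foldpath.observables.load_clusters`.

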