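# Methods

## Model

A protein of n residues is one bead per Cα. All dynamics is written in
the deviation variable x = R − Rᴺ from the native coordinates; the three
Cartesian axes are decoupled and share the same matrices, so every
propagation acts column-wise on an (n, 3) state. The open-loop equation
is the overdamped (inertia-free, noise-free) bead-spring relaxation
β dx/dt = Γx + u with Γ = −γ·L built from the contact graph of the
*initial* conformation (covalent bonds always included). Γ is symmetric,
has zero row sums, and for a connected graph exactly one zero eigenvalue
— the rigid translation the controller must stabilise. The model is
deterministic: the force field u is chosen by optimisation, not drawn
from a thermostat.

The control objective ∫(xᵀQx + αuᵀPu)dt uses P = I (every force
component weighted equally) and Q measuring the squared deviations of
the non-covalent contact vectors from their native values. For a contact
map containing the covalent backbone, that operator equals
L − L_bb + εI with L_bb the path-graph Laplacian. We build L from the
contact map united with the backbone, which keeps the identity
Q − εI = Σ_{non-covalent contacts} Dᵀ_ij D_ij valid for *every* map: during a
simulated run the linear dynamics can transiently stretch a virtual bond
past the cutoff, and the raw L − L_bb would then lose positive
semidefiniteness and break the Riccati solve. The geometric contact map
itself is untouched — it remains exactly the set of pairs within the
cutoff.

## Gain decomposition as an exact statement

Because Γ·1 = 0, Q·1 = ε·1 and B = I/β, span{1} is an invariant subspace
of the Riccati equation; restricted to it the equation is the scalar
quadratic −s²/(αβ²) + ε = 0, giving s = β√(αε) and hence row sums of
K = S/(αβ) all equal to k = √(ε/α). The anchoring constant is therefore
computed analytically, K′ = K − kI has zero row sums by construction,
and the solver *asserts* the row-sum identity to 1e-8 relative after
every synthesis (skipped when the user passes a non-identity P or an
unstructured Γ, where the identity does not hold). The Riccati residual
is likewise checked against 1e-8·‖Q‖ per call; dense `scipy`
solvers are used throughout, appropriate for the n ≤ a few hundred this
model targets.

## The learning loop

Each cycle: measure the contact map of the current conformation → build
Q → solve the Riccati equation → form A_cl = (Γ − K′ − kI)/β → propagate
for t_sample by exact matrix-exponential steps on the recording grid →
repeat. Q is initialised from the initial conformation's map simply by
running the same measurement at t = 0 (for an extended start this gives
Q = εI). Contact maps are re-measured fresh each cycle with no
accumulation, so contacts may break; convergence requires exact set
equality with the native map *and* RMSD ≤ rmsd_tol. Γ stays frozen at
the initial structure by default; `update_gamma` rebuilds it each cycle for
sensitivity studies. Non-convergence within max_cycles returns a flagged
trajectory, never an exception. Excluded volume is not enforced —
transient non-bonded approaches closer than 2 Å are logged as warnings
only, consistent with treating steric control as an average effect of
the entropy penalty.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| cutoff | 7.0 | Å | contact definition |
| ε | 1e-2 | – | Q regularisation; sets anchoring k = √(ε/α); small so pairwise springs dominate |
| α | 1.0 | – | entropy-loss penalty; the main tuning knob |
| β, γ | 1.0 | – | friction and spring constant; make time dimensionless |
| t_sample | 1.0 | time | re-optimisation interval of the learning loop |
| dt_record | 0.1 | time | recording grid (t_init resolution; no interpolation) |
| rmsd_tol | 0.5 | Å | convergence tolerance |
| max_cycles | 200 | – | loop bound |

α, ε, β and t_sample have no canonical physical values in this model;
absolute folding times are arbitrary units and only orderings are
meaningful. Larger α gives smaller gains, slower compaction, a smaller
control integral and a larger energy integral — monotonicities the test
suite asserts on an α-grid {0.1, 1, 10}.

## Synthetic natives

The fixture generator emulates native topologies, not real proteins: an
ideal α-helix (rise 1.5 Å, radius 2.3 Å, 100°/residue, giving the
i/i+3 and i/i+4 contact pattern), an extended chain (3.8 Å virtual
bonds, no non-covalent contacts at 7 Å), a fixed 20-residue
helix-hairpin (two mirrored 8-residue helices 8 Å apart joined by a
4-residue circular-arc turn with exact 3.8 Å bonds; 38 local and 6
non-local native contacts, minimum non-bonded distance 3.97 Å), and a
two-domain chain with a sparse linker. These capture what the method
needs — connected contact graphs with distinct local and tertiary
clusters — but none of real data's features: no sequence, no side
chains, no experimental coordinate noise, no chain breaks. Passing
tests on them demonstrates the control-theoretic machinery and the
local-first mechanism, not agreement with any particular protein's
measured folding kinetics.

Two hairpin native pairs sit ~0.04 Å inside the cutoff; such borderline
contacts form only as the run converges, which is why ordering tests
compare medians rather than extremes.

## Numerical choices and degenerate inputs

Propagation uses one `expm(A_cl·dt)` per cycle applied repeatedly —
exact for the linear dynamics up to floating point, no integrator error.
Contact distances use ≤ cutoff (boundary inclusive). Chains shorter
than 3 residues, residues missing a Cα, and non-positive tuning scalars
are rejected at construction. Coincident beads are geometrically allowed
and simply produce a contact. The extended and scaled-native starting
states are deterministic; the random-coil start is a seeded 3.8 Å-step
walk with a 3.5 Å self-avoidance attempt and bounded retries (an
explicit error suggests another seed on failure). With identical config
and seed every run is bit-reproducible.

## Problem sizes

The shipped studies use the 20-residue hairpin (a full folding run is
~20 Riccati solves of 20×20 matrices, well under a second); random-map
oracle checks use n = 4–40. The dense Riccati/Lyapunov path scales
comfortably to the 36–64 residue proteins this class of model is aimed
at.

## Known limitations

- Linear dynamics cannot preserve bond lengths or prevent chain
  crossing; excluded-volume violations are reported, not prevented.
- The contact map is Cα-geometric and unweighted; no side-chain or
  heavy-atom definitions, no residue-specific springs.
- No thermal noise, no inertia, no finite-horizon or output-feedback
  control.
- f(t) counts all pairs inside a cluster rectangle (so it can exceed 1
  when non-native contacts form there); a native-only mode is available
  behind a flag, and out-of-region non-native contacts appear only in
  the events table.
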