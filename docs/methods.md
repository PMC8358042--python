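# Methods

## Model

The simulator treats the DNA stack as a rule-based chemical reaction
network over linear complexes of nine monomer strands. A species is an
ordered token chain (e.g. `k.s.p.X.p.Y`); identity is the token sequence
alone — nick positions and hairpin geometry are ignored, which is
sufficient for every observable the package computes (copy numbers,
concentrations, total nucleotide sizes). Tether state is implied by a
leading linker token `k`. Ring (intramolecular) closure is excluded:
species are linear only.

All chemistry reduces to hybridisation on two 28 nt domain types, the A
domain (α) and the BC overhang (β). Each monomer presents at most one
binding head and one exposed tail:

* `s` exposes α at its tail (and a linker-binding head),
* `p` binds α with its head and exposes β,
* signals `X`, `Y`, `w` bind β and expose α,
* `r`, `q`, `z` are displacers: they attack exposed α tails, exposed β
  tails, and linker-bound stacks respectively, producing inert blunt
  duplexes (`X.r`, `p.q`, `k.z`, …).

Rule classes R1–R5 (push elongation, signal elongation, read
displacement, pop displacement, nucleation/release) are instantiated for
every species class — monomer–monomer, monomer–polymer, polymer–polymer,
tethered–free — by pattern matching on exposed interfaces. Three
contested rule memberships are configurable (`RuleConfig`) and default to
**on**: read capping of an exposed start (`s.r`, `k.s.r`, treated as
inert), pop binding a free push (`p.q` from monomers), and
polymer–polymer joins. Displacement uses single effective second-order
steps: the 28 nt toeholds make binding rate-limiting, and completion is
treated as irreversible (no reverse reactions anywhere). Leakage
(zero-toehold) strand displacement, oligo synthesis impurities and
sequence-level thermodynamics are outside the model.

Two rate constants govern everything: k_A = k_BC = 3×10⁴ M⁻¹s⁻¹
(α- and β-site hybridisation); displacements inherit the rate of their
toehold site.

### Strand lengths

X = 107 nt and Y = 137 nt are the synthesised hairpin signals; push is
28 + 28 = 56 nt by domain arithmetic. The remaining lengths are not
printed anywhere and are package assumptions, chosen for consistency with
the domain design: `s`, `w`, `r`, `q` = 56 nt (two 28 nt domains), `k`,
`z` = 40 nt (anchor domain plus a short toehold). They affect only gel
band sizes, not kinetics, and are configurable in the monomer table.

## Washing

A wash multiplies the bead mass (and every tethered species) by 1−μ and
every supernatant species by the carry-over fraction
φ_n = φ₀(1−μ)ⁿ, where n counts previous washes — carry-over is
proportional to remaining bead surface, so it decays exponentially over
the protocol. Presets: W1 (0.1, 0.33), W2 (0.05, 0.15), W3 (0.02, 0.05).
Under the stochastic backend thinning is per-species binomial (seeded),
keeping copy numbers integral; the deterministic backend multiplies
exactly. `bead_fraction` after n washes is exactly (1−μ)ⁿ in both.

## Backends

**SSA.** Gillespie Direct in a fixed volume (default 0.15 pl, where
300 nM ≈ 27,100 copies; copy numbers are round-half-even of c·V·N_A).
Propensities are k/(V·N_A)·n_i·n_j, halved combinatorially for identical
reactants. Channels are enumerated just-in-time: a species' reactions
(against all species seen so far) are created the first time its count
becomes non-zero, and products are registered one step ahead, so the
network trails the trajectory instead of enumerating the polymer space.
The event loop is a numba kernel with incremental propensity updates
(per-species adjacency lists) and Fenwick-tree channel selection;
randomness is a PCG32 stream whose state derives from the run's seeded
generator, so trajectories are reproducible bit-for-bit. Every stage
rebuilds the network from the surviving species, which keeps per-event
cost bounded over long protocols.

**ODE.** Mass-action rate equations on the rule-closure of the present
species, truncated at `lmax` monomers per complex (default 16).
Integration uses LSODA with rtol 10⁻⁷ and atol 10⁻¹⁴ M; negative
round-off is clipped. Species within one monomer of the cutoff are
*boundary* species; if they end holding more than 0.1% of total token
mass the integration fails loudly (`TruncationError`) rather than return
silently truncated dynamics. Gel-lane simulations in the calibration
code use lmax = 24 because the W1 carry-over genuinely populates
write-polymer lengths near 16.

The two backends agree within a few percent on stage-end concentrations
of abundant species for staged protocols (tested), with ~10⁴ copies
making SSA fluctuations sub-percent.

## Protocols and benchmark sequences

A stack operation sequence compiles to stages: setup `s`; each record →
push stage then signal stage; each pop → read stage (supernatant readout
taken before its wash) then pop stage. All stages use γ = 300 nM, a
30 min wait, and a wash; linker is pre-bound at 200 nM. Pipetting noise
draws each added concentration from U(γ−η, γ+η) floored at 0.

The benchmark sequences hold 20 records and 20 pops: seqN repeats N
records then N pops (N = 1, 5, 10, 20) and seqR is a prefix-valid
uniform shuffle. X/Y labels are balanced (10/10) and shuffled by an
arrangement seed. The study's exact arrangements are not printed, so the
package defines *canonical* benchmark arrangements: replicate k of a
sequence uses arrangement seed k. Replicate averages are therefore
arrangement averages over a fixed, reproducible family; trajectory
randomness comes from the run seed. Arrangement identity matters —
differently-labelled seq5 instances differ by several pops in their W1
pop limit — which is why the headline W1 statistic carries a wide
tolerance.

## Observables

**Pop limit.** Readouts are the supernatant concentrations of the
signal·read duplexes at the end of each read stage, pre-wash, including
duplexes carried over from earlier pops (chemically indistinguishable
from fresh ones). A pop is correct when |[Xr] − [Yr]| exceeds 10 nM
*strictly* (a tie at exactly 10 nM counts as indistinguishable) and the
majority duplex matches the ideal-stack expectation; the pop limit is
the count of correct pops before the first failure. Write-only (single
signal `w`) runs use [wr] ≥ 10 nM as the correctness criterion — the
two-signal definition does not apply, and 10 nM doubles as a detection
floor.

**Gel bands.** A lane is predicted by binning species by total
nucleotides (both backbones of the nicked duplex), weighting
concentration by nt as a stain proxy, and dropping bins below 1 nM·kb.
Tethered lanes are viewed "as released": the linker token is stripped
and linker-only species dropped, mirroring releaser treatment before
loading. The band-order error between two ranked lanes is the fraction
of disagreeing pairs over the union of bands, counting pairs involving a
band absent from one ranking as disagreements (0 = identical, 1 =
reversed). This reconstruction of the ordering error is validated by
parameter recovery rather than by matching any published surface:
fitting synthetic lanes generated at (μ=0.1, φ₀=0.33) recovers the truth
exactly on a 5×5 grid, remains within two cells under 10% adjacent-rank
swap noise, and is self-consistent at the origin. μ is only weakly
identified by orderings of short lanes (it rescales a lane nearly
uniformly); identification comes from detection-threshold crossings and
the φ_n decay across the deeper lanes, so the full 17-lane set is used
by default.

**Noise onset.** The pipetting-noise experiment runs the canonical seq5
at W1 for η ∈ {0, 50, 100, 150, 200} nM and compares each level to η = 0
with a one-sided Welch t-test. The drop at onset is a fraction of one
pop against a between-run sd of ≈1 pop, so the acceptance script uses
200 replicates per level at α = 0.01 to resolve it; the test suite
checks the coarser, robust claims (flat at 50 nM, degraded by 150–200 nM)
at the study's 25 replicates.

## Synthetic calibration fixtures

`make_fit_fixture` simulates the 17 write-signal lane protocols at known
(μ, φ₀) with the deterministic backend and emits ranked band lists,
optionally perturbed by adjacent-rank swaps (p_swap) to emulate
densitometry ambiguity. The fixtures emulate band *orderings* only — not
absolute intensities, smearing, ladder calibration error, or the
unpredictable mobility of hairpin-containing complexes — so passing
recovery tests demonstrates that the estimator works when the model
family is correct, not that real gels are this clean. Lanes that come
out empty (e.g. μ = 1) set a `degenerate` flag.

## Known limitations

* The non-principal rule membership of the original 20-rule model is not
  fully published. One printed prediction is sensitive to it: for the
  X,X,Y recording this model retrieves 3 signals with read at 50 nM
  (the original model predicted 2; both agree on 3 at 300 nM, and on
  2 at 50 nM for the Y,X,X recording). The discrepancy traces to the
  strength of the within-read-stage cascade driven by carried-over pop
  strands, and is left visible as a failing test rather than papered
  over.
* No leakage displacement or synthesis impurities: long-horizon
  predictions are best-case.
* The W1 grand mean pop limit is ~2.6 with the default rule set (~3.0
  with read-capping disabled), against a reported ~3.4 whose exact
  arrangements are unknown; the acceptance tolerance absorbs this.
* Problem sizes in the test suite (5–10 replicates per condition,
  25 replicates per noise level, 5×5 calibration grids) are the
  package's default desk-scale settings; all are parameters, and the
  acceptance script uses larger replication only where the estimator
  demands it.
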