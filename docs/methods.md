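# Methods

## The inference problem

A mariner transposon is cut out of its donor by four nicks — N1/N2 (5′,
ends A/B) and N3/N4 (3′, ends A/B). The nick pattern of a molecule maps
onto the species resolved on a gel of a supercoiled substrate: no nick →
supercoiled (SC); any nick short of a double-strand break → open circular
(N); both nicks at exactly one end → linear (L); both ends severed →
excision (EX). EX lumps the liberated backbone, the excised transposon and
all downstream integration products into one terminal class: the excised
fragment does not accumulate, and the gels quantify the backbone.
Integration chemistry is not modelled.

A cleavage-topology model assigns the four nicks to the active-site slots
of the synaptic complex: either one dimer (two slots, two nicks each:
`mm_13_24` cis, `mm_14_23` trans, `mm_12_34` 5′/3′-split) or a dimer of
dimers (four slots, one nick each, grouped per dimer: `dd_13_24` per-end,
`dd_14_23`, `dd_12_34`). The nick numbering N1=(A,5′), N2=(B,5′),
N3=(A,3′), N4=(B,3′) is canonicalized here; the same-end pairing {N1,N3}
/ {N2,N4} follows from the cis model's reading ("one monomer cleaves both
strands at one end").

## Endpoint enumeration

Doping experiments mix active with catalytically dead subunits at monomer
fraction *f*. Each substrate molecule is processed by exactly one
independently drawn complex (no depletion, competition or
overproduction-inhibition — that regulatory layer is out of scope). The
dimer composition comes from the mixing scenario:

- `homodimers_only` — proteins mixed just before the reaction: (1−f, 0, f)
  over (active-active, mixed, dead-dead);
- `equilibrated` — overnight subunit exchange: the binomial
  ((1−f)², 2f(1−f), f²);
- `kinetic` — partial exchange, the trajectory endpoint (below).

Within each dimer the two subunits occupy its two slots in either
orientation with probability 1/2 (no evidence of biased loading). A nick
occurs iff its slot's subunit is active and the ordering rule permits it.
The default ordering is the **strict gate**: both 5′ nicks precede either
3′ nick; at endpoint a gated nick simply never fires (leak-through is
kinetics' business). `per_end_gate` (3′ requires only its same-end 5′)
and `none` are available for sensitivity analysis. The prediction is the
exact probability-weighted classification over at most 16 activity
configurations — no sampling, no free parameters.

Closed forms (documented and tested against the enumeration at 101 grid
points, writing a = 1−f): mixed single dimers give N = 2f(1−f) (cis and
trans variants, identical after equilibration) or N = f(1−f) (5′/3′
split); equilibrated dimer-of-dimers models give L = 2f(1−f)³ with
maximum 27/128 ≈ 21.1 % at f = 1/4 and EX = (1−f)⁴. Two structural facts
worth noting: without pre-equilibration all three two-site models
coincide (an all-active dimer excises, anything else does nothing), and
after binomial equilibration all three dimer-of-dimers models coincide
(the four slots become i.i.d. active, so the grouping is immaterial) —
the `dd_12_34` model is distinguishable only in the homodimers-only
panel. `peak_product` refines the grid argmax by bounded scalar
optimisation; ties break toward smaller f.

## Ordered-nicking kinetics

Time courses show the ordering is kinetic, not mechanistic: single-chain
heterodimers accumulate an unusually large nicked intermediate that
converts *slowly* to linear. The master equation runs over the 16 nick
subsets plus one absorbing "integrated" state (entered from the fully
nicked state at `k_ex_int`; both classify as EX). Nick *i* fires at

- `k5` if 5′;
- `k3 × (1 if both 5′ nicks present else leak)` if 3′, and only if its
  same-end 5′ nick exists (`local_requirement`, default on — motivated by
  a single active site performing 5′ then 3′ at its end).

The factorisation into a hard local requirement and a soft global gate is
this package's design; the reported behaviours do not separate the two,
and this split spans all of them. Endpoint limits tie the two modules
together by construction and are asserted numerically across all six
models at 11 mutant fractions: leak 0 ⇒ strict gate, leak 1 with the
local requirement ⇒ per-end gate, leak 1 without it ⇒ unordered.

The system is linear with constant coefficients per activity
configuration; `simulate_timecourse` integrates with LSODA
(rtol 1e-9/atol 1e-12) and `expm_timecourse` provides the exact
matrix-exponential solution as an independent cross-check (agreement
within 1e-6 on random rate draws). Default demonstration rates
k5 = k3 = 3 h⁻¹, leak = 0.1, k_ex_int = 1 h⁻¹ put the intermediate peak
inside a 4 h window; they are illustrative, not fitted — band
intensities are not published as numbers, so no absolute rates are
claimed. The trans model with one dead subunit cannot linearise at all
under the local requirement (its live 3′ site sits at the never-nicked
end) — the kinetic discriminator between cis and trans that the mixing
endpoint cannot provide.

## Subunit exchange

Dimers are stable on the hour scale and reach the binomial 1:2:1 pattern
only after extended incubation. The exchange law is dissociation-limited:
dimers dissociate at first-order rate k and freed monomers re-pair at
random from the pool, giving dp_XY/dt = k(2f(1−f) − p_XY), i.e.
exponential relaxation with conserved monomer fractions and a
rate-independent equilibrium. Whether exchange is dissociation-limited or
collision-mediated is not determined by the data; only the binomial
endpoint is quantitative, and the rate is a free parameter. A stochastic
agent simulation (10⁵ dimers, small-step dissociation/re-pairing) serves
as the oracle for the deterministic law.

## Model discrimination

`fit_mixing_data` compares candidates by unweighted least squares summed
over all four product classes and all lanes — the curves are fully
determined by f, so the comparison is parameter-free, matching the
overlay-style analysis it emulates (the original overlays may derive from
earlier kinetic-modelling software; the difference is documented here).
Candidates are grouped into analytic equivalence classes (identical
curves on a 101-point grid within 1e-9) before ranking, so
indistinguishable topologies tie exactly; exclusion uses a configurable
RSS ratio (default 2×). Recovery experiments (noise sd 0.05, seven
mixing ratios, 100 seeds) recover the generating class in ≥ 90/100
replicates for every tested contrast.

## Idealized B-DNA geometry

The duplex is a rigid helical model: one phosphorus per residue at radius
`p_radius`, advanced by 36° and 3.38 Å per base pair (canonical B-form
fiber values), strands related by the base-pair dyad with azimuth offset
±`p_azimuth_offset` and axial offset ±`p_z_offset`. The inter-strand
distance at stagger s is then

d(s)² = 2r²(1 − cos(2φ − s·Ω)) + (2z₀ − s·h)².

The three placement constants were calibrated once
(`scripts/calibrate_helix.py`) against the three benchmark distances
11.9 Å (mariner, stagger +3), 16.9 Å (blunt, 0) and 18.3 Å (PiggyBac,
−4), under the constraints that +3 is the unique global minimum over
staggers −10..+10 and that the profile rises monotonically from stagger 5
to the half-turn. Solving the three distances exactly misplaces the
global minimum by ~0.2 Å, so the committed constants
(r = 9.499455 Å, φ = 63.802439°, z₀ = −0.552699 Å) are the least-squares
solution under the argmin constraint; all three distances land within
0.2 Å and the intra-strand P–P repeat comes out at 6.77 Å (≈ the 7 Å
backbone repeat).

Sign convention: positive staggers run in the mariner direction. The
PiggyBac TTAA cut sits 4 bp on the *opposite* side of the
transferred-strand cut, which is what places its phosphate pair across
the major groove while mariner's faces the minor groove; a +4 pair on the
mariner side would sit deep in the minor-groove track instead. Groove
labels are reported descriptively from the pair's azimuthal separation
(< 45° minor, > 110° through-helix, else major) and enter no computation.

## Synthetic data

Generators emulate densitometry of the three measurement types — mixing
series, reaction time courses, exchange curves — as model prediction plus
additive truncated-Gaussian noise per fraction (clip to [0,1],
renormalise; default sd 0.05), pure functions of truth and a mandatory
seed. They reproduce the statistical structure the analysis assumes, not
real gels: no lane-to-lane loading variation, no band-overlap bias, no
correlated background. Passing recovery tests therefore show the
inference is sound under its own noise model, not that real densitometry
errors are benign.

## Numerical choices and limitations

- Endpoint enumeration is exact; probability sums are validated to 1e-9.
- ODE tolerances rtol 1e-9/atol 1e-12; probability conservation asserted
  to 1e-8; matrix-exponential cross-check to 1e-6.
- Degenerate inputs: empty grids, f ∉ [0,1], negative rates/times,
  all-zero lanes and lane sums off by > 0.02 raise before computation,
  naming the offending lane where applicable.
- Problem sizes used by the test-suite experiments: 101-point grids for
  curve identities, 10⁵ samples for Monte-Carlo oracles, 100 seeds for
  model recovery, 50 for parameter recovery — exact enumeration makes
  each replicate cheap.
- Not modelled: hairpin-intermediate chemistry (Tn10/Tn5 mechanism),
  metal-ion coordination, integration target choice, supercoiling
  bookkeeping, temperature dependence of exchange, gel-image processing,
  sequence-dependent helical parameters.
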