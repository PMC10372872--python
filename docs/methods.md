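# Methods

This note documents the models, numerical choices and assumptions behind
`metalloms`, in the spirit of the methods sections that accompany packages
like msprime or statsmodels. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The species model: hydrogen displacement

Metallothionein-3 (MT3, 68 residues, 20 cysteines) binds metals through
deprotonated cysteine thiolates. In native electrospray, the observed neutral
mass of a complex is modelled as

    M(species) = M(apo, reduced) + n_Cu·m(Cu) + n_Zn·m(Zn) − n_H·m(H)
    n_H = n_Cu + 2·n_Zn + 2·n_SS

Each Cu(I) displaces one thiol proton, each Zn(II) two (charge-neutral metal
uptake), and each intramolecular disulfide removes two hydrogens
(2 RSH → RSSR + 2 H). This bookkeeping reproduces the characteristic
transitions in the Cu(II) + Zn₇MT3 system: Zn₇ (n_H = 14) → Cu₄Zn₄ with two
disulfides (n_H = 16) is a net loss of exactly two hydrogens at nearly
constant metal mass, which is why envelope fitting rather than centroid mass
is needed. The displacement rule is one function
(`chem.hydrogen_displacement`) so an alternative coordination bookkeeping can
be swapped in.

Admissibility: a species must satisfy n_H ≤ n_Cys (labile thiol hydrogens)
and, by default, the thiol budget n_Cu + n_Zn + 2·n_SS ≤ n_Cys (one dedicated
thiolate per metal, two cysteines per disulfide). Note the budget is implied
by the labile-hydrogen bound (their difference is n_Zn ≥ 0); it is kept as an
explicit, separately relaxable constraint (`enforce_thiol_budget=False`)
because real thiolate clusters bridge metals and users may want to model
denser coordination with a different displacement rule.

Ionization adds protons: m/z = (M + z·1.007276)/z. The proton mass (not the
hydrogen atom mass) is used everywhere.

Masses come from a pinned CSV of isotopic masses and abundances
(CODATA/IUPAC-CIAAW representative values for H, C, N, O, S, Cu, Zn) bundled
with the package so results are bit-stable; residue compositions come from
pyteomics' standard amino-acid table. The tests cross-check our masses
against pyteomics' independent isotope table.

## Isotope patterns

Patterns are built by per-element convolution: the single-atom distribution
is raised to the atom count by binary powering; partial patterns are merged
by outer-sum convolution. After each step, sticks are binned at 1e-4 Da
(abundance-weighted centroid) and sticks below an abundance floor of 1e-10
are pruned. The retained (pre-normalization) abundance is reported on the
pattern; at the defaults it exceeds 0.999 for the ~7.4 kDa complexes here.
Tests require exact agreement (masses 1e-9 Da, abundances 1e-12) with a
brute-force multinomial enumeration oracle on small molecules.

Profile rendering uses Gaussian peaks only, FWHM = (m/z)/R with a default
resolving power R = 20,000 (Synapt-class; the actual instrument resolution is
an assumption, and R is configurable everywhere). Peak *areas* are
proportional to stick abundances. For speed, sticks are pre-merged at
FWHM/10 before rendering — invisible at any realistic R — and each Gaussian
is accumulated only over ±6σ.

## Stoichiometry assignment

Candidates are enumerated on an inclusive (n_Cu, n_Zn, n_SS) grid — default
0–8 × 0–7 × 0–2, which spans apo through the hexacopper species — filtered by
the admissibility rules above and optionally by a mass window.

Scoring is cosine similarity between the theoretical envelope rendered on
the observed grid and the observed intensities (score = 1 iff proportional;
scale-invariant by construction). A global m/z shift bounded at ±0.05 Th
absorbs calibration offset; the bound is deliberately far below the ~0.2 Th
isotopologue spacing at z = 5 so the optimizer cannot hop isotope peaks.
Chi-square-style alternatives can be built from the reported residual (RMS
misfit at the least-squares scale).

`assign_species` scores every candidate at zero shift and refines the
bounded shift (Brent) only for the top 10 — refinement cannot change the
ranking outside that neighbourhood and this keeps an exhaustive
392-envelope sweep (196 species × z ∈ {4, 5}) at about two minutes on one
CPU. Ties break toward parsimony: fewer total metals, then fewer disulfides.
Charge, when not given, is the nearest integer of the reciprocal median
isotopologue spacing.

Overlapping species (the transient intermediates seen as CuCl₂ equivalents
increase) are deconvolved by non-negative least squares on the rendered
candidate basis. Because every basis envelope is rendered with unit stick
abundance (unit area), the NNLS coefficients are envelope areas and are
reported normalized to fractions. A candidate whose envelope lies outside
the recorded m/z window would contribute an all-zero column; this is
rejected as a singular basis rather than silently returning zero.

## TW CCS calibration

The standard power-law protocol for traveling-wave devices:

    t′  = t − EDC·√(m/z)/1000          (flight-delay correction)
    CCS′ = CCS_ref·√μ / z               (reduced-mass/charge scaling)
    ln CCS′ = ln A + B·ln t′            (least squares)

μ = m_ion·m_gas/(m_ion + m_gas); nitrogen (28.0134 Da) is the default drift
gas. The EDC coefficient and the calibrant charge states are instrument
settings with **no silent defaults** — both are required inputs. A bundled,
version-stamped table of representative literature N₂ CCS values for
ubiquitin, cytochrome c and β-lactoglobulin is provided as a starting point;
replace it with your laboratory's calibrant database for quantitative work.
Calibrations carry an optional TW parameter-set tag (e.g. wave velocity
300 vs 480 m/s) and are never applied across sets.

ATD → CCS mapping is point-wise through the power law; intensities are
copied without a Jacobian correction, matching common practice for
apex/FWHM reporting (the summary statistics, not integrals, are the
quantities of interest). Times with non-positive corrected drift time are
dropped and counted. Apex is the argmax after Gaussian smoothing (σ = 2 grid
steps, configurable; ties go to the lowest CCS); FWHM is linearly
interpolated at half maximum on both flanks of the apex mode, with a
single-bin (delta) mode reporting one grid step by convention. Whether the
original distributions were smoothed before apex extraction is unknown, so
smoothing is explicit and switchable.

## CIU fingerprints

Per-CE ATDs of one quadrupole-selected ion are mapped to CCS, resampled to a
common grid, and column-normalized to max = 1 (the standard CIU-fingerprint
convention; area normalization is a one-line switch). Conformer populations
are trapezoid integrals on either side of a CCS boundary, normalized to sum
to 1. The boundary the original analysis used is unstated; the default here
is the minimum of the CE-summed distribution between its two largest modes,
and it can always be overridden. No CIU50 curve fitting is performed — the
quantity of interest is the compact:extended ratio; a CIU50 stage would be a
natural extension.

## Survival yield and E50

SY = precursor/(precursor + products). By default, metal-loss species count
as products (dissociation events), not survivors; this is switchable since
the opposite convention is defensible. Lab-frame energy E_lab = z·V_trap is
normalized to the center-of-mass frame with argon (39.948 Da) as collision
gas. SY(E) is fit with

    SY(E) = bottom + (top − bottom)/(1 + exp((E − E50)/w))

by bounded nonlinear least squares (asymptotes in [0, 1.2]; E50 within the
data range ± one spacing; initial guesses: E50 at the point nearest SY = 0.5,
w = span/4). Fits require ≥ 5 points spanning ≥ 0.5 in SY. The simulation
study in the tests places the recovery bias well below 0.02 eV at 2% noise
over midpoints bracketing the stabilities reported for Zn₇MT3 (0.95 eV) and
Cu₄Zn₄MT3 (1.04 eV).

## Top-down fragment annotation

Only b/y series are generated (CID chemistry; ETD produced no backbone
fragmentation on these complexes, so c/z ions are an extension point in the
type, not generated). Fragment neutral masses use most-abundant-isotope
masses per element; adducts follow the same hydrogen-displacement deltas as
the intact species; disulfides are enumerated by count (positions are
unknowable from mass alone) subject to the fragment's cysteine budget; one
water loss is optional. Matching is greedy one-to-one by ascending |ppm| at
a 20 ppm default tolerance, ties toward the simpler adduct state.

Metal localization: a matched metal-free y_k confines the metal to residues
[1, L−k] *provided* no matched metal-bearing y_j with j ≤ k exists — a
metal-bearing ion at the same index as a metal-free one is ordinary partial
metalation of the precursor ensemble and simply voids that index as
evidence, while a metal-bearing ion strictly inside a longer metal-free run
is contradictory and is flagged (never silenced). Symmetric logic applies to
b ions and the N-terminal prefix. The default MT3 domain boundary places the
β-domain at residues 1–31; the alternative convention of counting the
α-domain as the C-terminal 30 residues (boundary L−30 = 38) is supported by
passing `boundary=38`.

## Synthetic data

Generators are pure functions of (parameters, seed); a seed is mandatory
whenever noise is requested, and all test seeds are fixed literals. Defaults
reflect the study conditions: resolving power 20,000; 1% Gaussian intensity
noise (Poisson counting noise optional); trap CE grids within 0–60 V;
two-conformer ATDs at ~1000 and ~1300 Å² with a logistic unfolding step;
sigmoidal SY curves sampled on 15-point E_com grids; fragment peak lists
with 5 ppm jitter and decoys rejection-sampled to sit ≥ 50 ppm from every
theoretical ion.

What the generators do *not* emulate — and hence what passing tests cannot
show about real data: peak tailing and detector saturation, chemical noise
and adduct salts (Na/K), space-charge effects, charge-state-correlated noise,
drift of the TW calibration within a run, and isotope fine structure below
the 1e-4 Da binning. Results on real spectra will degrade gracefully with
noise (the 1%-noise recovery study is the relevant guide), but none of the
instrument pathologies above are represented.

## Problem sizes in the default suite

The shipped test suite runs the exhaustive noise-free assignment sweep (392
envelopes over the full default grid at z ∈ {4, 5}), a 20-replicate noisy
assignment study, an 80-fit E50 simulation, 100 random localization
fixtures, and the brute-force isotope oracle on molecules up to ~10 atoms —
about four minutes end to end on one CPU. These sizes were chosen as the
smallest that exercise every claim exhaustively rather than by sampling.
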