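# Methods

## Overview

`topospectra` implements a bimodal analysis of simulated brain-like data:
a *topology chain* that tracks how much each region participates in
persistent 1-cycles (ring-like structures) of a functional connectome, and a
*spectral chain* that measures each region's aperiodic (scale-free) band
power. The package then tests whether task-minus-rest changes of the two
regional profiles move together, which is the scientific claim the pipeline
is designed to probe.

## Topology chain

**Connectome and pseudo-distance.** The functional connectome `G` is the
matrix of Pearson correlations `r_ij` between regional time series. Each
retained pair is converted to a pseudo-distance `omega_ij = 1 - r_ij`;
pairs with `r <= 0` are excluded outright, i.e. they are absent at every
filtration threshold. Zero is grouped with the negatives because a zero
correlation carries no coupling evidence, and `omega = 1` would otherwise
tie with genuinely weak positive couplings.

**Filtration and barcode.** The Vietoris-Rips (clique) filtration on
`omega` contains all vertices at 0, each retained edge at its `omega`, and
each triangle at the maximum of its three edge values. Only H1 is analyzed,
so the complex stops at dimension 2. The barcode is computed over Z/2 by
standard column reduction of the triangle boundary matrix (columns as
bitsets); cycle-creating edges are identified by a union-find sweep. Ties in
birth value are broken by dimension and then lexicographic simplex order,
which makes barcodes deterministic. Intervals with `d = b` are discarded
(they cannot contribute scaffold weight); cycles never filled by a triangle
are reported as infinite intervals, excluded from scaffolds, and counted in
the run log.

**Volume-optimal cycles.** For a finite interval `[b, d)` the
representative cycle is chosen to minimize the *volume* of its bounding
2-chain: among all sets `tau` of triangles born no later than `d` that
contain the death triangle and whose mod-2 boundary uses only edges born no
later than `b`, one of minimal cardinality is selected; the cycle is
`boundary(tau)`. Membership is decided by birth *value* (not filtration
position), so tied simplices entering after the death triangle are still
admissible — the 4-ring fixture requires this. The search runs in three
stages:

1. cheap exits — the death triangle alone, or a two-triangle chain
   cancelling the single inadmissible edge (both provably optimal when they
   apply, since two distinct triangles share at most one edge);
2. a real linear-program relaxation with oriented (integer) boundary
   coefficients and the death triangle's coefficient fixed to one, accepted
   when the optimum is integral and its support is parity-feasible;
3. otherwise an exact 0/1 integer program (HiGHS) with one even-parity
   constraint per inadmissible edge (`sum z - 2y = 0`).

If an optimum has an empty boundary (possible only under birth-value ties,
e.g. a tetrahedron shell), the program is re-solved forcing odd parity on
the birth edge. An exhaustive enumerator with the same contract serves as
the test oracle for candidate sets of at most 20 triangles.

**Scaffold and persistence centrality.** The subject-level scaffold weights
each edge by the summed persistence `pi = d - b` of every optimal cycle
containing it. Scaffolds are averaged entrywise across subjects per
condition, and persistence centrality is read off the group scaffold:
`PC(i) = sum_j w_ij / sum_{j,k} w_jk`. The denominator runs over ordered
pairs, which makes PC a probability distribution over regions
(`sum_i PC(i) = 1`); degree centrality `DC` is built identically from the
raw positive correlations, so the two are directly comparable. DC uses the
retained (positive) entries in both numerator and denominator by default —
the graph the topology actually analyses — with an option to include
negative weights.

## Spectral chain

**Welch PSD.** 2-second Hann windows with 50% overlap, one-sided density
normalization; implemented directly on strided segments (mean-detrended,
windowed, rFFT) and verified in the tests to match `scipy.signal.welch`
bit-for-bit. Internals run in float32: the quantities consumed downstream
are band-power *ratios*, and the relative error of float32 spectra
(~1e-7) is many orders below the estimator's own variance.

**IRASA.** For each non-integer factor `h` (default 1.1 to 1.9 in steps of
0.05) the signal is polyphase-resampled up by `h` and down by `h`, and both
copies are treated as if still sampled at the base rate, so all spectral
content is displaced by `1/h` resp. `h`. A power-law spectrum is a fixed
point of the geometric mean of such a pair (the `h^chi` and `h^-chi`
amplitude factors cancel), whereas narrowband peaks move off their
frequency; the median across factors is therefore the aperiodic spectrum
and the residual `total - aperiodic` the periodic one, making the
decomposition additive bit-exactly. Spectra span 1-120 Hz when
`fs >= 2 * 120 * max(h)` (the sped-up copy must still cover the top of the
band); otherwise the estimation band is truncated with a warning. The
anti-alias FIR uses a Kaiser window with half-length `5 * max(up, down)` —
half the scipy default — whose residual ripple is far below spectral
estimation noise at these window counts.

**Band power ratios.** `BPR(region, band)` integrates a chosen component
(default: aperiodic) over the band by the trapezoid rule, interpolating the
piecewise-linear spectrum at the band edges, and divides by the *total*
power over the full 1-90 Hz analysis band. The full-band-total denominator
keeps ratios comparable across regions and conditions and bounds a
partition's ratios by one; an aperiodic-only denominator is available as a
config choice. Canonical bands are delta 2-4, theta 4-8, alpha 8-12,
beta 12-25 and gamma 25-90 Hz; the fine scheme uses 32 bands with
geometrically spaced endpoints in 2-90 Hz. The headline theta-alpha range
is 4-12 Hz, the union of theta and alpha.

## Statistics

Task-minus-rest differences (dPC, dDC, per-band dBPR) are compared by
cosine similarity across regions; angular difference is its arccos.
Kendall's tau-b relates resting PC to each dPC. Hemispheric or group
contrasts use a two-sided Mann-Whitney U test, exact whenever
`n*m <= 400` via a subset-sum dynamic program over midranks (equivalent to
enumerating all labelings, ties included) and a tie-corrected normal
approximation otherwise.

The per-band contrast between `|cos(dBPR, dPC)|` and `|cos(dBPR, dDC)|`
across task conditions uses a cluster-based sign-flip permutation paired
t-test: per band a paired t statistic, clusters as maximal contiguous
same-sign supra-threshold runs (cluster-forming threshold p = 0.05
two-sided, configurable), cluster mass as the summed t, and a null built by
flipping the sign of whole condition-level difference rows. With n
conditions at most 12, all `2^n` flips are enumerated (256 at the default
8 task conditions), so attainable two-sided cluster p-values are exact
multiples of `1/2^n` with minimum `2/2^n = 0.0078125` at n = 8; larger n
falls back to seeded Monte Carlo. Every cluster is tested against the
maximal-cluster-mass null, the standard familywise control.

## Synthetic study generator

The generator emulates the *statistical structure* the analysis assumes,
not the biophysics, and its defaults are the study conditions used
throughout the tests: 10 subjects, 30 regions, 1 resting + 8 task
conditions (mirroring 4 motor + 4 working-memory tasks), 400 BOLD-like
timepoints, and 12-s MEG-like epochs at 500 Hz.

**Connectome side.** Regions are Gaussian with a target correlation matrix:
two planted 6-region rings whose cyclically adjacent pairs correlate at
0.55/0.25 (one ring strong at rest and weak under task, the other
reversed), chords and ring-to-cortex pairs at 0.1, everything else
independent. Requested targets that are not positive semi-definite (ring
values near 0.8 with weak chords cannot be exact correlation matrices on a
6-ring) are projected to the nearest valid correlation matrix by eigenvalue
clipping and diagonal rescaling before sampling. The planted task-minus-rest
PC sign of a ring's members is the sign of its strength change. Gaussian
factors suffice because the topology chain consumes only the Pearson
matrix; no hemodynamic convolution is modelled.

**Spectral side.** Each regional signal is white noise shaped in the
frequency domain to an exact `f^-chi` target PSD above 1 Hz (unit
variance), plus narrowband oscillators (default: one 10 Hz peak of moderate
amplitude) and 5% white measurement noise. The baseline exponent is
chi = 2; under task, each region's exponent moves *opposite* to its planted
PC sign by `0.4 * coupling_strength`. Around chi = 2 the theta-alpha share
of a power-law spectrum is monotonically decreasing in chi, so a flattening
spectrum raises theta-alpha aperiodic band power — regions whose planted PC
rises also raise their theta-alpha aperiodic power, which is exactly the
covariation the pipeline is meant to detect. With `coupling_strength = 0`
the two modalities share nothing but the region labels, giving the null for
type-I-error checks.

Randomness is split into independent streams keyed by (modality, subject,
condition, region) from one master seed, so outputs are bit-reproducible
and subsets are stable.

**What the generator does not emulate.** Hemodynamic response functions,
task block structure and autocorrelated BOLD noise; MEG sensor physics,
source leakage and volume conduction; spatially correlated aperiodic
fluctuations; inter-subject variability beyond independent sampling noise.
Passing tests therefore demonstrate that the *pipeline recovers the
statistical structure it targets when that structure is present and stays
quiet when it is absent* — not that real cortical data possess that
structure.

## Problem sizes and numerical choices

- The end-to-end planted-effect checks run the full 10-subject, 30-region,
  9-condition study over 20 master seeds per coupling arm; the IRASA h-grid
  for these sweeps uses steps of 0.1 (9 factors), which leaves exponent
  recovery well inside its ±0.1 tolerance while halving spectral cost. All
  single-decomposition accuracy checks use the full default grid.
- Exponent-recovery checks use 60-s signals; the null-calibration sweep
  (50 seeds) keeps all 30 regions — the cosine null scale is set by the
  region count — with 2 subjects and 2 task conditions.
- LP/ILP tolerances: solutions are accepted as integral at 1e-6; parity
  feasibility is verified exactly on the rounded support before acceptance.
- Degenerate inputs: all-nonpositive connectomes, all-zero scaffolds, zero
  vectors in cosines, constant vectors in rank statistics, too-short
  signals and invalid resampling factors all raise informative errors
  rather than returning NaNs.

## Known limitations

- Exact H1 only, coefficients in Z/2; no H2+, cohomology or sparse Rips
  approximations, so the topology chain is intended for region counts in
  the hundreds at most.
- The volume-optimal program can in principle return any minimizer under
  ties; volumes are unique but cycle identities may differ between the LP
  and ILP routes on tied inputs.
- IRASA assumes the aperiodic component is a (locally) pure power law;
  spectra with knees are estimated as their local slope within the fitted
  band.
- The Mann-Whitney exact path is quadratic in total rank mass and intended
  for the small samples it is restricted to.
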