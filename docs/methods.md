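# Methods

This note documents the models behind `relicdna`, the defaults and why they
were chosen, the numerical choices, and what the synthetic scenarios do and
do not establish about real data.

## The problem

DNA extracted from ancient frozen sediment is a mixture: intracellular DNA
(iDNA) from living or intact dead cells, and extracellular DNA (eDNA)
liberated by lysis. Three independent physical clocks can separate the
living from the fossil component: (1) post-mortem DNA damage, which living
cells repair continuously but dead material accumulates; (2) the response of
genome recovery to in-vitro enzymatic repair, which helps damaged templates
but is neutral for intact ones; and (3) aspartic-acid racemization, which a
living proteome resets by turnover. `relicdna` implements each assay and a
simulator that generates sequencing data with known ground truth for all of
them.

## Taphonomy model (`simulate`)

**Fragmentation.** Fragment lengths are lognormal(`frag_mu`, `frag_sigma`)
truncated (by clipping) to [30 bp, genome length]. Old-stratum populations
default to a 200 bp median with σ = 0.5, matching the ~100–300 bp regime of
heavily degraded sedimentary DNA; living populations must have median
fragments above ~10.4 kb (validated at construction), the high-integrity
regime observed for intact cells. Strand is Bernoulli(1/2); reverse-strand
fragments are reverse-complemented before lesion placement so lesion offsets
always count from the fragment's own 5′ end.

**Deamination.** A cytosine at 0-based 5′ offset `p` deaminates with
probability `δ_ds + (δ_ss − δ_ds)·q^p` — the overhang-decay law of ancient
DNA phenomenology: single-stranded overhangs deaminate fast (`δ_ss`), duplex
interiors slowly (`δ_ds`), with geometric persistence `q`. The complementary
strand deaminates symmetrically, producing G→A-generating lesions indexed
from the 3′ end (`deam_G` in the lesion enum; `deam_C` is reserved for
fragment-strand reference-C sites). Defaults for fossil material are
δ_ss = 0.3, δ_ds = 0.01, q = 0.6, which reproduce a ~30 % terminal C→T
frequency decaying to ~1 % by position 25. Living populations carry exactly
zero lesion rates.

**Blocking lesions and nicks.** Abasic sites/dimers (`blocker_rate`) and
nicks (`nick_rate`) are Poisson in fragment length with uniform positions.
They do not change the read sequence; they act at library conversion.

**Age.** `simulate_taphonomy` validates and records `age_yr` but the lesion
intensity is carried entirely by `DamageParams`: the damage law has no
explicit time constant, so scenarios encode age through the parameters
(short fragments + high δ_ss = old). This keeps the generator honest about
what is actually known — a damage/age calibration is not part of the model.

**Fractionation.** Lysed populations route fragments to eDNA, living and
intact-dead populations to iDNA, each with a `leakage` probability for the
minority pool (defaults 0.05/0.1/0.05 for living/dead_intact/lysed; lysed
leakage is capped at 0.1 so at least 90 % of lysed material is
extracellular). How much eDNA derives from recently expired cells versus
ancient lysis is unknown in real sediment; leakage is an explicit free
parameter, set to 0 in the default scenario to keep classes separable by
construction.

**Repair.** In-vitro repair reverts every lesion independently with
probability ρ (default 1.0 for repaired libraries): deaminated bases return
to reference, blockers/nicks are resolved. ρ = 0 is the identity. Real
enzyme cocktails have lesion-specific, context-dependent efficiencies; a
single ρ is the minimal model that produces the observed contrasts.

**Library conversion and sequencing.** A sampled fragment converts to the
library with probability `(1 − π)^(#blocking lesions)` (π = `block_prob`,
default 0.9). The number of read attempts per genome is
`target_depth × genome_length / read_length` (scaled by mean-normalised
relative abundances), so realized depth shrinks with the blocked fraction —
this is the mechanism that makes unrepaired fossil libraries under-sequenced
and duplicate-rich, and repaired libraries more complete and more diverse.
Fragments ≤ `max_insert` (500 bp) are read from their own 5′ terminus, which
carries the ancient damage signature; longer fragments are "lab-sheared":
the read starts at a uniform position with a fresh, undamaged end. This
mirrors real library preparation, where tagmentation of intact high-MW DNA
creates new termini while short ancient fragments enter whole. Surviving
deaminations read as T (5′ C→T) or A (3′ G→A); independent substitution
errors are added at `seq_error_rate` (default 10⁻³). SAM records carry true
coordinates (0-based internally, 1-based on disk), reads in FASTQ are in
read orientation, flag-16 SAM records reference-forward.

**Repaired-library yield.** `LibrarySpec.yield_factor` (default 1.0) can
down-scale the sampling effort of repaired libraries to mimic the lower read
yields sometimes seen after enzymatic treatment. The default keeps sampling
effort equal between the paired libraries so that the 1:1-line contrast
isolates the damage effect itself rather than a yield artifact.

**Randomness.** One master seed per scenario; every operation draws from a
child stream keyed by fixed string labels (genome id, library id, operation
name), so toggling repair or adding a library never perturbs fragment
generation. Reruns are byte-identical, including SAM/FASTQ output.

## Damage profiling (`damage`)

The profiler counts, at each read-orientation offset 1..25, reference-C
opportunities and C→T observations (and the mirrored G→A tally from the 3′
end). Reverse-strand alignments are complemented and flipped into read
orientation first. Only reference-C→read-T mismatches enter the numerator;
indel columns and soft-clipped bases are excluded; overlapping reads are
counted independently (no de-overlap); the default MAPQ filter is 0 because
simulated alignments are true. Gapless single-M alignments take a vectorised
fast path; anything else goes through per-column aligned pairs. Profiles are
reported per reference genome, pooled across genomes on request — pooled
counts, not per-contig weighting.

The scalar **damage score** is the terminal frequency ct5[1]; it is
undefined (raises) when no reference-C was observed at position 1, and the
pipeline propagates that as missing evidence. The **fit** is deterministic
box-constrained least squares of `ct5[p] ≈ δ_ds + (δ_ss−δ_ds)·q^(p−1)`,
parametrised as (δ_ds, amplitude, q) so the amplitude bound enforces
δ_ss ≥ δ_ds, multistarted on a fixed q grid (0.05..0.95, 10 points) with the
best residual kept. A flat profile leaves q unidentifiable and is flagged
`degenerate`; it still reports δ_ss ≈ δ_ds ≈ the plateau.

## Repair assay (`repair_assay`)

Completeness is **windowed breadth of coverage**: ceil(L/window) windows
(default 500 bp), a window recovered when its mean depth ≥ `min_depth`
(default 1). Marker-gene completeness would need annotation machinery that
is deliberately out of scope; the paired repaired/unrepaired contrast only
requires a consistent proxy, and breadth responds to exactly the mechanism
being assayed (missing templates). The comparison fixes x = unrepaired,
y = repaired, fits ordinary least squares and the Pearson r, and reports
per-bin deltas; undamaged scenarios sit on the 1:1 line (slope ≈ 1, r ≥
0.98 at ≥ 10 bins with spread in x), damaged ones rise above it. Fewer than
3 bins is an error; constant x leaves r undefined and is flagged rather
than invented.

Duplicates are defined by identical alignment endpoints
(genome, start, end, strand) — optical/PCR duplicates are not simulated, so
endpoint identity is exact. The eDNA/iDNA yield ratio and the cell estimate
`idna_mass / 2×10⁻¹⁵ g` follow the standard single-cell DNA content
assumption.

## Racemization clock (`racemization`)

Rate: `k = A·exp(−Ea/(R·T))` with R fixed at 8.314×10⁻³ kJ K⁻¹ mol⁻¹.
Defaults are the Siberian-permafrost aspartate calibration Ea = 101.7
kJ/mol, A = 1.43×10¹⁵ yr⁻¹ and T = 265.45 K (−7.7 °C mean in-situ
temperature; conversion offset 273.15). Kinetics:
`ln[(1+D/L)/(1−D/L)]` grows by `2kt`, i.e. `D/L(t) = tanh(kt + artanh(D/L₀))`
and `t = (artanh(D/L) − artanh(D/L₀))/k`. The tanh/artanh form is used
instead of exponential ratios to avoid overflow near saturation; outputs are
clamped to [D/L₀, 1) against floating-point saturation of tanh (which hits
exactly 1.0 beyond argument ≈ 19). D/L₀ defaults to 0 — the initial ratio of
the source material is not independently constrained, and at the 26–100 kyr
ages of interest the choice moves predictions by less than the reporting
precision. At the defaults the model predicts D/L ≈ 0.346 at 26 kyr and
≈ 0.883 at 100 kyr; the small-argument linearization (kt) would give 0.362
and 1.39, so the full kinetic form matters from ~0.3 upward. A measured
ratio far below the prediction implies the aspartate pool is being recycled
— the living-population signal surfaced in the report as
`observed_below_predicted`.

## Replication index (`growth`)

Per-bin mean depth (default 1 kb bins, trailing partial bin merged into the
last) is smoothed with a circular moving average (default 10 bins). The
index is smoothed depth at the argmax (ori) over the argmin (ter); ≥ 1 by
construction, exactly invariant to uniform depth scaling and circular
rotation. Validity requires the dnaA locus bin to hold ≥ 0.8 of the peak
coverage, the trough to hold ≥ 0.8 of the dif locus bin coverage, and
strain heterogeneity < 0.3. Two published statements of the 0.8 criterion
disagree in direction; we adopt "ratios ≥ 0.8 ⇒ valid", which is the
direction under which a gradient with correctly placed loci validates.
Heterogeneity is an input (the scenario's strain-admixture fraction), not
estimated — estimating it would require the full published tool chain.
Smoothing biases the index slightly toward 1 (the moving average shaves the
peak and fills the trough — about 4 % at a true ratio of 2 with the default
window on a 200 kb genome), and sampling noise biases the flat case slightly
above 1; both effects stay inside the ±0.1 recovery envelope at ≥ 20×
depth.

## Classification (`classify`)

The decision table (in order): eDNA-only presence ⇒ `fossil_extracellular`;
iDNA presence with damage < 0.1 and |Δcompleteness| < 0.05 in every present
fraction ⇒ `living`; iDNA presence with damage ≥ 0.1 or repair gain ≥ 0.05
⇒ `fossil_intracellular`; otherwise `ambiguous`, upgradeable to `living` by
expressed protein only when the low-damage clause already holds. The 0.1
damage bound is the descriptive threshold separating lightly from heavily
deaminated assemblages; the 0.05 completeness-delta bound is this package's
own free parameter (no published cutoff exists) and both are exposed in
config. The table is total and deterministic, and monotone: raising the
unrepaired damage score can only move calls away from `living`
(property-tested). Taxon-informed priors (e.g. aerobe vs. anaerobe
plausibility) are deliberately not encoded: calls are purely data-driven.

Balanced spectral counts apportion each spectrum evenly across its n
matching proteins (1/n each), conserving totals — the standard shared-
peptide treatment for protein-level quantification.

## Scenario scale and what the tests show

The default scenario uses three 50 kb genomes at 8× target depth (about
48 k reads across the 2×2 grid, ~2 s end to end); the damage-recovery
checks use one 100 kb genome at 10⁵ reads; the regression scenarios use 15
living bins (150 kb, depth ladder 0.6–3×) and 20 fossil bins (50 kb, 10×).
These sizes were chosen so that between-bin signal dominates window-level
sampling noise (e.g. 300 windows/bin gives completeness noise σ ≈ 0.03
against a 0.3 between-bin spread, hence r ≳ 0.99 on the living 1:1 line)
while a full suite run stays in the tens of seconds.

Passing tests establish that the measurements recover known synthetic
ground truth under the stated noise models. They do not establish
performance on real sediment data, where damage is sequence-context
dependent, fragment ends are jagged rather than clean, reference genomes
are incomplete MAGs, mapping is ambiguous across related strains, and
abundances span orders of magnitude. The simulator also omits PCR
amplification bias, paired-end insert geometry, quality-score
miscalibration and adapter artifacts by design.

## Degenerate inputs and tie-breaks

Empty alignment sets give all-undefined profiles (NaN frequencies), never
silent zeros; undefined damage at position 1 raises and is carried as
missing evidence. Fragments shorter than the read length are emitted
full-length (clipped reads), not discarded. Coverage argmax/argmin ties
resolve to the lowest bin index (numpy convention), which the rotation
invariance test exercises. A zero-coverage trough flags the index undefined
rather than reporting infinity. Failed scenario runs remove their staging
directory so no partial bundle survives.
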