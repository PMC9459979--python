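# Methods

## Nomenclature unification

Each row of the alias cross-reference table declares that its non-empty
team cells (Okamoto, Lim, Kim D, other groups) name the same S haplotype;
a parenthesized token inside a cell ("S22 (S7)") is a second label used by
the *same* team, not a cross-team link. Unification takes the transitive
closure of these declarations (union–find over the link graph) so that
chained equivalences collapse into one class even when no direct link was
declared. Similarity percentages in the table are stored as annotations;
they play no role in unification, which relies solely on the declared row
structure.

Classes are numbered `NAU-S1`, `NAU-S2`, … by a deterministic rule: first
by the most senior team represented in the class (okamoto < lim < kim_d <
other), then by the numeric part of that team's smallest primary label.
This regenerates the published numbering for every class anchored by one
of the three main teams (`NAU-S1`–`NAU-S46`). The six classes known only
to "other" groups carry no team-internal ordering that a rule can
recover, so they receive `NAU-S47`–`NAU-S52` in numeric-label order; the
class count and all cross-team lookups are unaffected. Novel haplotypes
get `max existing index + 1`, idempotently per query, so repeated typing
runs cannot burn numbers.

## Virtual PCR

Primer matching is set-membership per position: an ACGT base matches an
IUPAC symbol iff it lies in the symbol's base set. Forward primers are
matched on the top strand as written; reverse primers where the top
strand contains their reverse complement (codes complemented
symbol-wise). The default mismatch budget is 0 — the degenerate codes
already absorb the intended variation. When a budget is allowed, the
three bases at the primer's 3′ end must still match exactly, since
polymerase extension requires a paired terminus. Every compatible
forward/reverse site combination inside the size window (expected product
length ± 20%, reflecting that band sizes are read approximately off a
gel) yields an amplicon; colliding primer placements are discarded as
unamplifiable. Coordinates are 0-based half-open on the top strand.

Class calling is the two-pair truth table: product with the Class I pair
only → Class I; Class II only → Class II; both → Class I/II heterozygote;
neither → unclassified.

## RFLP model

HinfI recognizes `GANTC` and cuts after the G. The recognition site is
its own reverse complement, so one top-strand scan finds every site;
fragment lengths are successive cut-to-cut distances (complete digestion
assumed). Lengths are double-stranded sizes: the 3-nt 5′ overhang does
not affect gel mobility and is ignored. One consequence worth knowing:
reverse-complementing a sequence mirrors the recognition windows exactly
but shifts each cut by the overhang, so mirrored fragment lists agree
only to within 3 nt.

The gel model has two parameters: `min_detect` (default 50 nt — smaller
fragments run off a 6% polyacrylamide gel) and `resolution_pct` (default
2% — roughly what silver-stained PAGE separates). Fragments within the
resolution merge into one band keeping the longest member's length.
Band-pattern equality at finite resolution is not transitive, so panels
are grouped by single linkage over the pairwise equality relation, which
makes profile ids deterministic and independent of input order.

## Identity typing

Queries are scored against each reference with global alignment (match
+1, mismatch −1, gap −2, terminal gaps free; Needleman–Wunsch via
Biopython's PairwiseAligner); identity is matches over aligned columns
excluding terminal-gap columns, so a partial-length amplicon scores
cleanly against a full-length reference. The same-haplotype threshold
defaults to 98.5%: the smallest published within-haplotype similarity
between teams' alleles of one class is 98.7%, while distinct haplotypes
are far more divergent, so 98.5 sits just below the observed
within-class floor. Two references from different classes within 0.1
percentage points of the top hit make the call ambiguous; ambiguous
calls are reported, never silently resolved. Novel calls delegate naming
to the registry so there is exactly one numbering authority.

Frequency tables round percentages half-up to two decimals. Note that
5/48 is 10.4167 and therefore prints as 10.42.

## Cross genetics

SSI phenotype is sporophytic: expression is computed per parent from the
diploid genotype, identically on the stigma and pollen sides — the
simplest symmetric model consistent with the published compatibility
relationships. Class I is dominant over Class II; within-class
heterozygotes are co-dominant. A flower-stage cross is predicted
incompatible iff the parents' expressed sets intersect; bud pollination
bypasses SI and is always compatible.

Observed outcomes are classified from the compatibility index
(seeds/flowers): < 0.5 strong incompatibility, 0.5–2.0 weak (boundaries
inclusive), > 2.0 compatible. The shared-haplotype prediction is binary,
so concordance scoring collapses observed strong/weak incompatibility
into "incompatible"; weakly-incompatible different-haplotype crosses
(observed index 1.85 in the published experiment) are the model's known
discordance mode.

## Synthetic data

The generator's defaults are the study conditions: 23 reference
haplotypes (19 Class I, 4 Class II) on 1.4-kb templates, a 79-genotype
panel of 48 homozygous Class I, 13 homozygous Class II, 17 Class I/II
heterozygotes, and one off-target material that amplifies with neither
pair (the published class frequencies 60.76/16.46/21.52 are out of 79
while the class buckets sum to 78).

Each reference embeds one intact realization of its class's primer pair
at offsets giving the published product size (1200/1000 bp). Cores
derive from a per-class ancestor mutated at `between_divergence`
(default 8% of positions per haplotype, giving pairwise identities well
under 95%); carried alleles in genotypes are re-mutated at
`within_divergence` (default 0.2%, comfortably above the 98.5% typing
threshold). The mutation model is substitution-only so identity
arithmetic stays exact. HinfI maps are planted as explicit `GANTC`
motifs on a 50-nt lattice inside the amplicon; the ancestor is scrubbed
of accidental motifs and every mutation that would create one is
rejected, so the planted map is the true map. (The Class I reverse
primer itself contains one constant `GATTC`, which adds an identical
14-nt terminal fragment to every Class I amplicon — below the detection
floor.) Site maps are drawn without replacement and redrawn until the
resulting gel profiles are pairwise distinguishable, so planted
haplotypes are guaranteed resolvable; requesting more maps than the
lattice supports raises an error.

Pollination counts use a Poisson total-seed model (mean = flowers ×
0.2 for incompatible, × 3.0 for compatible crosses) and per-flower
Bernoulli pods (20% vs 75%), matching the ranges of the published field
data; a noise-free mode pins the index at its mean. At 30 flowers per
cross the index classifier recovers the true state for ≥ 95% of crosses
(Poisson tails at λ = 6 vs λ = 90 barely cross the 0.5/2.0 thresholds).

What the generator does not emulate: indels and recombination at the S
locus, partial digestion, heteroduplex artifacts, primer competition in
multiplex PCR, or real SRK molecular evolution. Passing tests therefore
demonstrate that the pipeline's logic is correct on data with the
published structure, not that the wet-lab assay has these error rates.

## Problem sizes and numerics

The default test panel is the full study scale (79 genotypes, ~96 allele
sequences typed against 23 references at 1.0–1.4 kb), which keeps the
whole suite around a minute. Alignment scoring, gel parameters,
thresholds and rounding (half-up, two decimals, matching the published
table formatting) are fixed constants recorded in the modules; all
randomness flows from a single integer seed per generator call, and
identical configuration yields byte-identical output.
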