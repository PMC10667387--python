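# Methods

This note documents the models inside `tetrarms`, the choices made where the
design space was genuinely open, and what the synthetic fixtures do and do
not demonstrate.

## The ARMS extension-blocking model

Allele-specific PCR rests on one mechanism: Taq polymerase lacks 3′→5′
exonuclease activity, so a primer whose 3′-terminal base mispairs the
template is not extended. The simulator (`tetrarms.pcr`) models a reaction
as three deterministic stages:

1. **Binding-site search.** Every ungapped alignment of a primer on either
   strand with at most `max_internal_mismatches` internal (non-terminal)
   mismatches is a candidate site. The 3′-terminal base is exempt from this
   budget — a terminal mismatch is exactly the configuration ARMS exploits,
   so it must be representable. Each site gets an *effective Tm*: the
   perfect-duplex nearest-neighbor Tm minus `tm_penalty_per_mismatch_c`
   (default 5 °C) per mismatch.
2. **Annealing filter.** A site is kept when its effective Tm is within
   `anneal_margin_c` (default 12 °C) of the programmed annealing
   temperature. The margin reflects PCR practice: primers prime well below
   their Tm, and annealing temperatures are routinely set at or slightly
   above primer Tm. A margin of zero would reject the packaged assays'
   own inner primers on their matched templates (they carry 1–2 deliberate
   mismatches by design and their perfect Tms sit near the 61–62 °C
   annealing temperatures), so the filter is calibrated to discard grossly
   destabilised sites rather than every sub-Tm one. The default margin is
   the smallest round value at which all of the packaged assays' intended
   and blocked band patterns reproduce, with headroom of a few degrees.
3. **Extension and pairing.** Under the `stringent` rule a site extends iff
   its 3′-terminal `min_3prime_exact_run` bases (default 1) are matched.
   The `permissive` rule additionally lets a *weak* terminal mismatch read
   through when the annealing temperature is below 60 °C — the documented
   loss of allele specificity at low stringency, regained at 62 °C. Every
   extendable forward/reverse site pair in amplifiable orientation yields a
   product (size = reverse 3′… forward 5′ span, capped at
   `max_product_bp` = 2000); a diploid band set is the union over the two
   haplotypes.

The model is presence/absence only. It deliberately omits amplification
efficiency, primer-concentration balancing (the wet-lab fix for inner
primers competing with exact-match outer primers), polymerase kinetics and
band intensity. One visible consequence: under the permissive rule both
inner primers can extend on the same haplotype, predicting a tiny
inner-F × inner-R product (45 bp at the X221 locus) alongside the
mis-amplified allele band; on a real 2 % agarose gel a fragment that size
runs with the dye front and is not scored.

## Melting temperatures

No Tm model is prescribed by the assay itself, so the package uses the de
facto standard: unified nearest-neighbor parameters (SantaLucia) with
Owczarzy salt correction, at 50 mM monovalent and 200 nM oligo, via
Biopython. Oligos shorter than 14 nt fall back to the Wallace rule
2(A+T)+4(G+C). The simulator evaluates Tm under a PCR-buffer profile that
adds 2.5 mM Mg²⁺ (matching the assay's 20 µL reaction with 2 µL of 25 mM
MgCl₂), which raises the packaged primers' Tms to 61.8–66.5 °C —
consistent with annealing programs at 61–62 °C. The design-time Tm target
(64 ± 3 °C) brackets exactly that range.

## Mismatch strength and compensation

Strength is ordinal (weak/medium/strong), not thermodynamic: design needs a
rank, and the assay literature reasons in ranks. The default table —

* weak: G·T, T·G, C·A, A·C, G·G
* medium: A·A, T·T, C·T, T·C
* strong: C·C, G·A, A·G

— is anchored by the explicitly weak pairs used in the packaged assays
(G·G as the 5′ escalation mismatch, C·A and G·T as secondaries) and filled
in from common ARMS practice; it is config-overridable entry by entry
because no complete published taxonomy exists for this assay family. The
compensation rule mirrors tetra-primer protocol practice: a strong terminal
allele mismatch gets one weak secondary, medium gets medium, weak gets a
3′-proximal secondary (weak, as in the realized assays) and may escalate
with an extra weak mismatch at position 5–6 from the 5′ end. Secondary
placement defaults to the 3rd-from-3′ position for forward inner primers
and the 2nd for reverse ones (the positions realized in the packaged sets);
positions 2–4 are all legal.

## Assay design

`design_assay` enumerates both allele-to-orientation assignments, chooses
inner primer lengths (18–28 nt) to hit the Tm target after mismatch
introduction, and scans all outer anchor pairs whose three products fall in
the 150–600 bp window with at least 60 bp between any two bands (60 bp
keeps bands resolvable on 2 % agarose; the realized assays separate alleles
by 170+ bp). Candidates are ranked by a weighted score — Tm uniformity
0.4, product-size spread 0.3, GC deviation 0.2, homopolymer runs 0.1 —
exposed in `DesignConstraints.scoring`; the weights are a package choice,
since no objective function is published for this design task. The search
is exhaustive over anchors, hence deterministic; a seed only shuffles
candidates that tie on score. Degenerate inputs (SNP closer to the template
edge than a primer length, templates shorter than the minimum product) fail
with the violated constraints listed.

## Genotype calling

Observed gel sizes are matched to expectations nearest-first within a
relative tolerance (default 5 %, config-exposed), each observed band
consumed at most once, leftovers flagged. The genotype truth table covers
all 8 subsets of {O, A1, A2}; every pattern lacking the control band is
invalid because the outer-outer product is the internal positive control.
Interpretation is sex-aware: females give direct verdicts; a male's single,
maternally inherited X means a homozygous pattern is reported as
`maternal_only` with the lineage recorded (hybrid status undeterminable),
and a heterozygous male pattern is flagged as a conflict since it is
inconsistent with single-X inheritance. Samples of unknown sex route to the
tetra-primer panel (conservative: the assay still reports maternal lineage)
with a warning; known males route to an external COI/SRY barcode panel that
this package only models as a routing decision.

## Synthetic fixtures

No real deer sequence is packaged. The 730 bp template is a *geometric
reconstruction*: anchoring the shared outer-forward site at position 67,
the printed product sizes force the outer-reverse 3′ ends to 552 and 615,
the inner-forward 5′ ends to 201 and 403 and the SNPs to 221 and 428 —
reproducing the coordinates embedded in the primer and locus names and
satisfying the size identity at both loci. Primer footprints carry the
primer sequences with each designed-mismatch position holding the
documented template base; the X428 inner-forward penultimate mismatch type
is not documented anywhere and defaults to A·C (weak). Filler is seeded
random sequence, identical across genotypes so haplotypes differ only at
the SNP columns. The reindeer preset scrambles four bases in each inner
site's 3′ half while preserving the outer sites — the minimal model of a
related species showing only control bands; real reindeer divergence is
not represented. The template length makes the flanking discovery-primer
product exactly 730 bp.

The market panels replay the published survey composition: a 24-lane panel
(10 sika, 8 red, 4 hybrids labelled as sika, 2 reindeer counterfeits under
a generic deer label) and a 40-sample panel adding 12 label-concordant
female lanes and 4 male lanes (three blood, one meat) that sex-based
routing removes, leaving 36 for the tetra-primer panel. Band sizes come
from the simulator, noise-free by default; `add_gel_noise` applies
multiplicative Gaussian sizing error. At cv = 2 % against the 5 % matching
tolerance, a band escapes its window only beyond 2.5 σ (≈ 1.2 % per band),
so about 97 % of per-lane-locus calls survive any given noisy replicate;
the Monte-Carlo test asserts ≥ 96 % over 300 replicates, and a separate
property test proves calls are *always* stable under perturbations up to
half the tolerance.

Passing fixtures therefore demonstrate internal consistency — design,
simulation and calling agree with the published geometry and counts — not
performance on real gels, where ladder calibration error, partial
digestion, faint bands and true sequence context are absent from the model.

## Numerical and interface choices

* Coordinates are 1-based inclusive on the top strand; reverse primers are
  written 5′→3′ and their sites reported by top-strand coordinates with the
  3′ terminus at the left edge.
* Mismatch pairs are ordered (primer base, template base on the annealed
  strand); primer-internal positions count from the 3′ end starting at 1.
* Canonical product sizes are the triplets satisfying the size identity
  (486/352/179 and 549/213/383); variant figures appearing elsewhere in the
  assay's source material are treated as errata and never emitted.
* Canonical primer names follow the reaction-setup text; the variants
  `In-F210w1`, `In-F201w` and `Out-615` are preserved as aliases
  (`fixtures.PUBLISHED_NAME_ALIASES`).
* Ties in design scoring break deterministically (seed-shuffled before a
  stable sort); all fixture randomness flows from a single integer seed,
  default 42.
* The primer-table TSV dialect adds optional `target_allele` and per-assay
  product-size columns to the required schema so band calling can run
  without a template.
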