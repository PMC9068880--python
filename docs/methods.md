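# Methods

## Problem and pipeline

HCR v3 FISH detects a transcript with pairs of 25-nt DNA probes binding
adjacent sites separated by a 2-nt spacer; each probe carries half of an
amplifier initiator, so hairpin amplification triggers only where both
probes of a pair bind. The design problem is to tile a transcript with up
to 36 such pairs that stay duplexed in the hybridization buffer, bind
nowhere else in the genome, and preferentially cover the open reading
frame. The pipeline runs seven stages, each recorded in the design report:
window enumeration → thermodynamic screen → uniqueness screen → pair
assembly → region designation → prioritized selection → oligo assembly.

## Melting temperature

Duplex stability uses the unified nearest-neighbor DNA parameter set: ten
Watson–Crick stack ΔH°/ΔS° values, terminal initiation terms (+0.1 kcal/mol,
−2.8 cal/K/mol per terminal G·C; +2.3, +4.1 per terminal A·T), and a
−1.4 cal/K/mol entropic symmetry correction for self-complementary
sequences. The two-state transition temperature is

    Tm = ΔH° / (ΔS° + R ln(C_T / x)) − 273.15

with R = 1.987 cal K⁻¹ mol⁻¹ and, by default, C_T = 5 nM probe in excess
(x = 1) — the regime of an in situ hybridization where probe far exceeds
target. Both are configurable (`probe_conc_molar`).

Buffer corrections:

- **Monovalent salt** (default `santalucia`): the entropy adjustment
  ΔS°(Na⁺) = ΔS°(1 M) + 0.368 (N−1) ln[Na⁺], N−1 the number of stacks.
  The Owczarzy reciprocal-Tm correction is selectable
  (`salt_correction: owczarzy`); both are identities at 1 M.
- **Formamide**: a linear penalty of 0.65 °C per percent (v/v), the
  conventional coefficient for DNA duplexes; configurable
  (`formamide_coeff_c_per_pct`).

A window passes the screen when corrected Tm ≥ hybridization temperature
plus a margin (default 5 °C, so probes remain duplexed at 37 °C), GC is
within [0.25, 0.75], and the longest homopolymer run is ≤ 4 nt. These
screening defaults are conventional probe-mining values; the buffer
defaults (37 °C, 1 M Na⁺, 30 % formamide) are the standard HCR
hybridization conditions. The screen is a pure per-window filter: verdicts
depend only on the window's own sequence and the parameters.

## Uniqueness

A candidate is multi-mapping when its 25-mer matches more than `max_hits`
(default 1) maximal reference loci, on either strand, with at most
`max_mismatches` (default 2) substitutions. Indels are deliberately not
modeled — a 25-mer probe with an indel against its target is rarely
functional — and users screening against a full genome can instead import
SAM alignments from an external aligner (`--sam`), where primary plus
secondary alignments are counted per candidate (supplementary records are
partial alignments of the same locus and are skipped; an optional AS-tag
score floor is exposed).

The built-in matcher uses an exact k-mer index (default k = 11) over both
strands. Seed lookup is provably complete only when the pigeonhole bound
(max_mismatches + 1) · k ≤ probe_len holds — true at mm ≤ 1 with the
defaults — so above that bound `count_hits` switches to an exact vectorized
full scan of the reference (numpy sliding-window Hamming counts). Hit
counting therefore always agrees with a brute-force scan; the index is the
fast path, not an approximation. Overlapping match starts on one
contig/strand merge into a single locus, so a homopolymer-adjacent repeat
counts once. Candidates with **zero** loci are dropped by default: a probe
absent from the design reference cannot be vetted against it (reversible
with `--keep-unmapped`). This matcher is intended for kilobase-scale
references; genome-scale screening is the SAM route.

## Pairing and oligo assembly

Passing windows whose starts differ by exactly probe_len + spacer_len
(27 nt at defaults) form a candidate pair; overlapping pairs are permitted
until selection. The 5′-ward window ("P1") receives the amplifier's
upstream arm, the 3′-ward window ("P2") the downstream arm:

    oligo1 = initiator_up + linker + revcomp(P1 window)
    oligo2 = revcomp(P2 window) + linker + initiator_down

by exact concatenation with no other edits. Arm placement is a fixed
convention (order sheets must be unambiguous); the shipped config carries
the five standard v3.0 amplifiers B1–B5 as data, each 36-nt initiator split
18/18, and users whose amplifier stocks use the opposite placement can swap
the halves in the config. The linker defaults to `AA` on both sides, the
short spacer customary in v3 probe sets. The 2-nt target spacer is treated
purely as a positional gap; its bases are unconstrained.

## Region designation and selection

With a CDS interval [start, end) the transcript splits into 5′ UTR, ORF,
and 3′ UTR. A pair is designated by the region containing the majority of
its 52-nt footprint; an exact tie resolves toward the earlier region in the
priority order (ORF at defaults). Transcripts without a CDS yield
UNANNOTATED pairs selected purely left-to-right.

Selection is greedy and deterministic: regions are visited in priority
order (ORF, 3′ UTR, 5′ UTR), pairs within a region swept 5′→3′ by footprint
start, and a pair is kept iff its footprint (both windows plus spacer)
shares no transcript base with any pair already kept, until `max_pairs`
(36) is reached. Disjointness is a physical constraint — two probes cannot
occupy the same bases — and the left-to-right sweep gives a maximal-density
tiling without introducing rank heuristics (a Tm-ranked order is a
reserved config hook). Greedy selection is not globally optimal packing;
with dense candidates the difference is at most edge effects.

## Synthetic fixtures

`generate_fixture` emulates the design inputs: a random transcript of
chosen length and GC with a defined CDS, embedded once in a synthetic
genome between 1-kb random flanks, optionally with segments of the
transcript planted a second time to trigger the multi-mapping filter. The
manifest records the planted intervals and every window start lying fully
inside one (such windows must be dropped; windows merely overlapping a
planted copy by all but ≤ 2 nt are also dropped by the mismatch rule, and
windows with larger overhangs drop stochastically depending on flanking
bases, so the manifest lists only the guaranteed core). Base composition
is hit exactly: the generator fixes the G+C count to round(gc·length) and
shuffles positions, so realized GC is within 1/length of the target for
every seed rather than binomially scattered.

What the fixtures do not emulate: real transcripts have local composition
structure (CpG islands, AT-rich UTRs), repeat families far more pervasive
than a few planted duplications, and splice isoforms. Passing tests
demonstrate the pipeline's contracts — geometry, thermodynamics against
independent oracles, exact hit counting, priority and cap arithmetic,
determinism — not that any particular biological transcript yields 36
pairs.

## Problem sizes and numerical notes

Tests and the acceptance script run on kilobase-scale fixtures: 2-kb
transcripts for geometry and funnel checks, a 3-kb genome for the
exhaustive specificity oracle (every window cross-checked against a
literal both-strand scan), and a 6-kb transcript with CDS [200, 5800) for
the selection-cap computation, where ~5,400 of 5,976 windows pass the
default screen and the ORF alone offers far more than 100 mutually
compatible pairs, so the selection fills to exactly 36 ORF pairs. The
pipeline contains no randomness; fixtures take a single explicit seed
(numpy Generator) recorded in the manifest. Coordinates are 0-based
half-open internally and in BED output; the CLI accepts 1-based inclusive
CDS input. Windows containing N are excluded at enumeration (Tm is
undefined over ambiguous bases); N positions in a reference mismatch every
probe base. Ties and degenerate inputs are all given explicit behavior:
empty candidate sets propagate to an empty probe set with a warning (exit
0), an empty probe set refuses to write output files, and a transcript
shorter than one pair footprint (52 nt) yields no design.

## Known limitations

- The built-in matcher is substitution-only and desk-scale; use the SAM
  import for gapped, genome-scale alignment.
- Per-transcript design only: multiple FASTA records are designed
  independently (the 36-pair cap is per transcript), with no isoform
  collapsing or cross-gene multiplex panel planning.
- No secondary-structure (hairpin/dimer) screening, dangling-end terms, or
  Mg²⁺ corrections.
- The amplifier arm sequences are configuration data; verify them against
  your amplifier stocks before ordering.
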