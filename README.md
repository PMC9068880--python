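# hcrprobe

Design of split-initiator probe pairs for third-generation hybridization
chain reaction fluorescence *in situ* hybridization (HCR v3 FISH).

In HCR v3, each mRNA target is detected by pairs of DNA oligos that bind
adjacent 25-nt sites on the transcript, separated by a 2-nt spacer. Each
probe of a pair carries half of an amplifier initiator sequence; the full
initiator — and therefore fluorescent hairpin polymerization — is only
reconstituted when both probes bind side by side, which is what gives the
method its specificity. `hcrprobe` takes a transcript FASTA plus a CDS
annotation and produces an order-ready set of up to 36 probe pairs that

1. satisfy hybridization thermodynamics at 37 °C, 1 M Na⁺, 30 % formamide
   (nearest-neighbor melting temperature with salt and formamide
   corrections, GC bounds, homopolymer cap),
2. map uniquely to a reference genome/transcriptome (built-in mismatch-bounded
   matcher at desk scale, or imported SAM alignments from an external aligner
   at genome scale), and
3. are placed with open-reading-frame > 3′ UTR > 5′ UTR priority, with
   pairwise-disjoint footprints on the transcript.

## The model

For a candidate window *S* of length 25 the duplex melting temperature is
the two-state nearest-neighbor estimate

T_m = ΔH° / (ΔS° + R · ln C_T) − 273.15,

with ΔH°, ΔS° summed over the unified Watson–Crick stack parameters plus
terminal initiation terms, C_T = 5 nM probe in excess. The working-buffer
Tm applies the entropic monovalent-salt adjustment
ΔS°(Na⁺) = ΔS°(1 M) + 0.368 (N−1) ln[Na⁺] and a linear formamide penalty of
0.65 °C per percent (v/v). A window passes when its corrected Tm exceeds the
hybridization temperature by a 5 °C margin, its GC fraction lies in
[0.25, 0.75], and no homopolymer run exceeds 4 nt. Passing windows at
transcript offset exactly 27 nt apart (25 + 2) form candidate pairs;
uniqueness requires both members to match at most one reference locus with
≤ 2 substitutions; selection then sweeps each region 5′→3′ in priority
order, keeping disjoint pairs until the cap of 36 is reached.

## Worked example

Generate a synthetic 2-kb transcript (CDS at 101–1300, one-based) embedded
in a synthetic genome, then design probes against it:

```
hcrprobe fixture --seed 7 --length 2000 --gc 0.5 --cds 101-1300 --out demo
hcrprobe design --fasta demo/transcript.fasta --cds 101-1300 \
    --genome demo/genome.fasta --amplifier B1 --out demo/probes
```

The design log prints the funnel:

```
INFO fixture_tx: 1976 windows -> 1850 pass thermo -> 1850 unique -> 1710 candidate pairs -> 36 selected
```

1976 25-mer windows fit on the 2000-nt transcript; 1850 pass the
thermodynamic screen; all remain unique because the genome contains the
transcript exactly once; 1710 window pairs sit at the exact 27-nt offset;
the greedy prioritized sweep keeps 36 disjoint pairs (here 22 ORF, 13 3′ UTR,
1 5′ UTR). Four files are written: `probes.order.tsv` (oligo name, 96-well
position, sequence), `probes.probes.bed` (binding footprints in 0-based
half-open transcript coordinates), `probes.oligos.fasta`, and
`probes.report.json` (the funnel counts and the effective parameters). The
first order-sheet rows:

```
oligo_name              well  sequence
fixture_tx_pair001_P1   A1    GAGGAGGGCAGCAAACGGAAGCCGACCTCTTGCAACAAGCGCACT
fixture_tx_pair001_P2   B1    GTCGTCGTGGCGCGGTTATTAGTGAAAGAAGAGTCTTCCTTTACG
```

Each 45-nt oligo is an 18-nt amplifier arm, a 2-nt linker, and the 25-nt
binding region (the reverse complement of the transcript window).

The same pipeline is scriptable from Python:

```python
import hcrprobe as hp

tx = hp.read_transcripts("demo/transcript.fasta", {"fixture_tx": (100, 1300)})[0]
amp = hp.get_amplifier(hp.load_config(), "B1")
index = hp.build_index("demo/genome.fasta", k=11)
probe_set = hp.design_probes(tx, amp, reference_index=index)
print(len(probe_set.pairs), probe_set.per_region_counts)
# 36 {'UTR5': 1, 'ORF': 22, 'UTR3': 13}
```

## Layout

- `src/hcrprobe/sequences.py` — domain types, coordinates, FASTA/CDS/BED/TSV I/O
- `src/hcrprobe/thermo.py` — window enumeration, nearest-neighbor Tm, screening
- `src/hcrprobe/pairing.py` — 2-nt-spacer pair assembly, split-initiator arms
- `src/hcrprobe/specificity.py` — k-mer index, mismatch-bounded hit counts, SAM import
- `src/hcrprobe/selection.py` — region designation, prioritized greedy selection
- `src/hcrprobe/pipeline.py` — orchestration and the design report
- `src/hcrprobe/fixtures.py` — synthetic transcript/genome generator with ground truth
- `src/hcrprobe/cli.py` — `hcrprobe design`, `hcrprobe fixture`

See `docs/methods.md` for the scientific and numerical choices.
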