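# oligoblock

Toolkit for designing high-affinity antisense blocking oligonucleotides that
prevent reverse transcription / PCR amplification of unwanted abundant RNA
fragments, together with a depletion-benefit simulator and depletion
efficiency metrics for count data.

## What it does

- **Target finding** (`oligoblock.target_finder`): locates internal
  adenosine-rich RT-priming sites in a transcript (windows of length >= 8
  with A-fraction >= 0.8 by default, merged and trimmed to maximal sites,
  with genuine 3' poly(A) tails excluded) and derives the design window
  immediately 5' of each site — the direction in which reverse transcriptase
  travels from an oligo(dT) primer.
- **Oligo design** (`oligoblock.oligo_design`): tiles every antisense k-mer
  across a design window (a 32-nt fragment tiled with 16-mers gives 17
  candidates), screens each candidate exhaustively against a transcriptome
  for Hamming-distance off-targets within a mismatch budget (default 3),
  scores melting temperature with a two-state nearest-neighbor model
  (unified DNA/DNA parameters + per-position LNA perturbation increments +
  Owczarzy monovalent-salt correction; tables shipped as versioned JSON in
  `oligoblock/data/` with citations), and selects the highest-Tm candidate
  among those with zero off-targets (falling back to the minimal-off-target
  set when none are clean). 2'-O-methyl / 2'-methoxy-ethoxy patterns are
  representable but have no thermodynamic tables; their Tm is only reported
  via a flagged heuristic estimate.
- **Depletion simulation** (`oligoblock.depletion_sim`): multinomial
  resampling of a library over a (depth x initial-fraction x
  depletion-efficiency) grid. Depleted target reads are reallocated to the
  background at fixed total depth — the target's share after depleting a
  fraction `d` is `f0(1-d) / (f0(1-d) + (1-f0))` — and detected genes
  (count >= 10 by default) are tallied per draw with replicates.
- **Metrics** (`oligoblock.metrics`): CPM, seeded without-replacement
  subsampling, target fold-reduction (control/treated mean CPM with a
  flagged +0.5-count continuity correction), per-biotype read fractions,
  detection counts (>= 10 counts; CPM > 0.5 for small RNA features), a
  pluggable differential-expression test (default: Welch t-test on log2-CPM
  with a 10-RPM abundance filter and Benjamini-Hochberg adjustment),
  repeated-subsampling DE concordance (pairwise Jaccard %), and
  standardized-residual off-target flagging (> 2 SD in the same direction in
  every replicate pair).
- **Synthetic data** (`oligoblock.synthetic_data`): seeded generators for
  transcriptomes with planted poly(A) sites and decoy near-matches, count
  tables with a dominant gene over a log-normal background, paired
  control/treated libraries with known depletion efficiency, and two-group
  count data with planted fold changes. Every generator returns a truth
  manifest and is byte-identical given the same seed.

## CLI

One entry point with `design`, `simulate`, `metrics` and `synth`
subcommands. All randomness derives from `--seed`; each run writes a
resolved-config JSON next to its outputs. Exit codes: 0 success, 2
input/validation error, 1 internal error.

```bash
# generate a synthetic transcriptome with planted sites and decoys
oligoblock synth transcriptome --out-dir demo --seed 1

# fragment mode: tile a short RNA fragment (17 candidates for a 32-mer)
oligoblock design --mode fragment --fasta demo/transcriptome.fa \
    --target TCCGATGGTAGTGGGTTCCGATGGTAGTGGGT -k 16 --max-mm 3 \
    --pattern full_lna --out fragment_report.tsv

# polya mode: find internal poly(A) sites and design one blocker per site
oligoblock design --mode polya --fasta demo/transcriptome.fa \
    --target tx_0001 --out polya_report.tsv

# depletion-benefit simulation on a count table
oligoblock synth counts --n-genes 2000 --depth 2e6 --dominant-fraction 0.2 \
    --out-dir counts_demo --seed 2
oligoblock simulate --counts counts_demo/counts.tsv --sample S1 \
    --target-gene TARGET --depths 0.5e6,1e6,2e6 --f0 0:0.9:0.1 \
    --eff 0:1:0.02 --threshold 10 --reps 10 --seed 3 --out surface.tsv

# metrics
oligoblock metrics fold --control control.tsv --treated treated.tsv --gene TARGET
oligoblock metrics concordance --group-a a.tsv --group-b b.tsv --depth 700000
```

Count tables are TSV with a `gene_id` first column and one integer column
per sample; biotype maps are two-column TSV (`transcript_id<TAB>biotype`).
Coordinates are 0-based half-open everywhere; reports additionally print
1-based inclusive coordinates.

## Thermodynamic model notes

Default conditions are 0.25 uM oligo, 50 mM monovalent salt, no divalent
(divalent is folded into a monovalent equivalent when supplied). Each LNA
residue perturbs both adjacent dinucleotide stacks; stacks flanked by two
LNA residues are attenuated (factor 0.5) because strict nearest-neighbor
additivity over-predicts the stability of contiguous LNA runs. Selection
decisions depend only on the Tm ranking, which is robust to the condition
choice; reported absolute temperatures for fully modified oligos are
estimates outside the single-substitution regime the LNA parameters were
fitted in.
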