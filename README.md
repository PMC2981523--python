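# tssmask

Strand-specific masking of genomic locations that cannot initiate
transcription, by running a very-high-sensitivity transcription-start-site
(TSS) classifier *in reverse*.

Most of a mammalian genome never initiates transcription. If a TSS
classifier is tuned so that it (nearly) never misses a genuine TSS, then
every position it *rejects* can be demarcated — strand-specifically and at
single-nucleotide resolution — as a **non-TSS location (NTL)**. The
remaining positions form **transcription-initiation active regions
(TIARs)** that contain the vast majority of genuine TSSs plus the
classifier's false positives. NTL maps are useful for focusing promoter and
gene finding, checking 5′ completeness of cDNAs/ESTs, and designing RACE
primers away from regions that cannot respond.

## The model

The classifier examines 200-nt single-stranded windows read 5′→3′ on the
transcribed strand, with the putative TSS as window character 101 (upstream
positions −100..−1, downstream +1..+100). A window is a potential TSS only
if it passes a *daisy chain* of four filters, each trained to keep 100% of
the training TSSs:

1. **k-mer occurrence envelopes.** For each of the 1,364 k-mers of length
   1–5, count occurrences *u* upstream and *d* downstream
   (*u*, *d* ∈ [0, 100+1−k]). Training stores, per k-mer, min(d)/max(d)
   conditional on each observed *u* and min(u)/max(u) conditional on each
   observed *d*. A window passes only if all 1,364 (u, d) pairs fall inside
   their envelopes; a count value never seen in training fails.
2. **Core PWM.** Windows are split into 16 subsets by the dinucleotide at
   [−1,+1]. Each subset gets a 20-nt position weight matrix over [−10,+10]
   and a threshold s_min equal to the minimum training score
   (pass iff s ≥ s_min).
3. **LDF-40.** The window's 40 non-overlapping 5-nt sections are scored by
   subset-specific section PWMs, giving a 40-dimensional feature vector
   x; a per-subset Fisher linear discriminant
   s_LDF = c₁x₁ + … + c₄₀x₄₀ + c_const is thresholded at the minimum
   training-positive score LDF_min (pass iff s_LDF ≥ LDF_min).
4. **SVM.** A single RBF-kernel support vector machine (γ = 1.28, C = 1,
   TSS class +1, random class −1) over the same 40 features. Its decision
   value s_SVM is compared against the *only user-tunable dial* t_SVM
   (pass iff s_SVM > t_SVM, strictly).

Scanning a sequence classifies the window centered at every position on
both strands: failing positions are NTL, surviving positions TIAR, and
positions whose window overruns an end or contains non-ACGT characters are
UNSCORED. Lowering t_SVM trades specificity for sensitivity; the default
t_SVM = −2.5 is the 100%-training-sensitivity operating point.

No genome downloads are required: a synthetic generator produces training
corpora and genomes with planted TSS-like signal (local GC elevation, a
pyrimidine–purine initiator at [−1,+1], an optional upstream TATA-like
box), so the whole pipeline is testable offline.

## Worked example

```python
import tssmask as tm

corpus = tm.generate_corpus(tm.SynthConfig(n_pos=2000, n_neg=2000, seed=42))
model = tm.train_masker(corpus, tm.TrainConfig(seed=42))

for row in tm.sweep(model, corpus.positives, corpus.negatives, (-2.5, 0.0, 1.0)):
    print(f"t_svm={row.t_svm:+.2f}  sensitivity={row.sensitivity:.4f}  "
          f"specificity={row.specificity:.4f}")

genome, truth = tm.generate_genome(
    5000, 0.42, [(1000, "+"), (3000, "-")], tm.SynthConfig(n_pos=1, n_neg=0, seed=1), seed=8
)
plus, minus = tm.scan_sequence(genome, model, sequence_id="demo")
print(tm.ntl_fraction([plus, minus]))
```

prints

```
t_svm=-2.50  sensitivity=1.0000  specificity=0.9615
t_svm=+0.00  sensitivity=1.0000  specificity=1.0000
t_svm=+1.00  sensitivity=0.2145  specificity=1.0000
{'NTL': 0.951989168923141, 'TIAR': 0.04801083107685899, 'UNSCORED': 0.0398,
 'scored_positions': 9602, 'total_positions': 10000}
```

At the permissive threshold every training TSS window is recognized
(sensitivity 1.0000) while 96% of random training windows are correctly
demarcated NTL; scanning a 5-kb synthetic genome masks ~95% of scored
positions as NTL, and both planted TSSs fall inside TIARs. The roughly 4%
UNSCORED positions are the sequence ends, where no full 200-nt window
exists.

The same functionality is available from the shell:

```sh
tssmask synth --n-pos 2000 --n-neg 2000 --seed 42 --out-prefix fix
tssmask train --positives fix.positives.fa --negatives fix.negatives.fa --out model.json
tssmask scan  --model model.json --fasta genome.fa --out-prefix tracks
```

## Layout

- `src/tssmask/seq_windows.py` — windows, coordinates, FASTA/BED I/O,
  evidence-based TSS compilation, negative sampling
- `src/tssmask/kmer_stage.py` — stage 1: k-mer occurrence envelopes
- `src/tssmask/pwm_stage.py` — stage 2: core PWMs (+ the generic PWM
  builder/scorer used by stages 3–4)
- `src/tssmask/ldf_stage.py` — stage 3: section features and Fisher LDFs
- `src/tssmask/svm_stage.py` — stage 4: RBF SVM
- `src/tssmask/pipeline.py` — daisy-chain orchestration, scanning, BED
  tracks, model persistence
- `src/tssmask/synth.py` — synthetic corpora and genomes
- `src/tssmask/evaluation.py` — sweeps, trade-off curves, cross-validation
- `src/tssmask/cli.py` — the `tssmask` command

See `docs/methods.md` for the modelling choices and their rationale.
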