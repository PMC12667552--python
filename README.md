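# eoskit

Tools for quantifying the quality of **enzymatic oligonucleotide synthesis
(EOS)** — template-independent, cycle-by-cycle DNA synthesis with a
terminal deoxynucleotidyl transferase (TdT) and 3′-blocked nucleotides —
and for using EOS products as a DNA information-storage medium.

It is written for people who run or evaluate solid-phase EOS experiments:
it simulates synthesis reads with a controllable per-cycle error channel,
extracts synthesized payloads from sequencing reads, classifies
deletion/insertion/substitution errors by global alignment, computes yield
statistics, recovers a stored message by majority vote, and fits the
enzyme-kinetics and assay calculations that accompany such experiments.

## The statistics at the core

For a target of `r` synthesis rounds and a set of extracted reads:

- **error rate per class** = `N_error / N_all`, where `N_error` counts
  deletions, insertions or substitutions assigned by a unit-cost global
  alignment of each payload to the target, and `N_all = S_all × r` with
  `S_all` the number of extracted reads;
- **full-length yield** `Y_total = S_right / S_all`, where `S_right`
  counts payloads exactly equal to the target;
- **average stepwise yield** = `Y_total^(1/r)`, the per-cycle success
  probability implied by the full-length yield.

Information storage uses a two-bits-to-one-base code (00→G, 01→T, 10→C,
11→A, MSB-first) and recovers the dominant sequence from a read
population either as the modal payload string or by a position-by-position
plurality vote conditioned on agreement at all earlier positions.

Kinetics follow the Michaelis–Menten model `V = Vmax·[S]/(Km+[S])`
(nonlinear or Lineweaver–Burk fitting), with scaffold comparisons reported
as percentage parameter gains and FRET efficiency as `E = 1 − I_DA/I_D`.

## Worked example

Simulate a 60-cycle synthesis of the bundled storage fragment at a 3.18%
per-cycle deletion rate, then analyze, vote and decode:

```bash
eoskit run-all --target storage_fragment --n 10000 --p-del 0.0318 \
    --seed 1 --out-dir run1
```

Output:

```
full_length=14.40% stepwise=96.82%
decoded 15 bytes
```

The full-length yield is the fraction of extracted reads that match the
60-nt target exactly; its 60th root, the stepwise yield of 96.82%, is the
implied per-cycle success probability (1 − 0.0318 = 96.82% was simulated).
`run1/message.bin` holds the decoded 15-byte message — the UTF-16BE code
units of three Chinese characters followed by the ASCII letters
`TanKahKee` — recovered exactly despite no read-level error correction,
because the conditional majority vote is robust at these error rates.

The same stages are available individually (`eoskit simulate`, `extract`,
`analyze`, `decode-reads`, `encode`, `decode`, `kinetics`) and as library
functions (`eoskit.simulate_run`, `eoskit.compute_metrics`,
`eoskit.conditional_consensus`, `eoskit.fit_michaelis_menten`, ...).

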