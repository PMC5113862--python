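# popmodes

Hidden Markov modeling of binary neural population activity with
tree-structured ("Chow-Liu") emission distributions, plus the full
surrounding analysis pipeline: Baum-Welch fitting with shrinkage
regularization, Viterbi mode decoding, cross-validated model-order
selection, emission/transition entropies, mode participation and Fisher-LDA
discriminability, repeat-based information efficiency with randomized null
controls, and stimulus-side STA / logistic-LN / mode-triggered-average
tools. Ground-truth synthetic generators make every stage testable without
any recorded data.

## Library overview

| Module                | Contents |
|-----------------------|----------|
| `popmodes.raster`     | spike binning (20 ms default, half-open bins), binary rasters, repeat sets, circular shuffling, word-frequency tables, TSV/CSV I/O |
| `popmodes.tree`       | Chow-Liu tree emission distributions: fitting (max-MI spanning tree), exact log-probability, ancestral sampling, closed-form entropy, spike-count distribution by tree DP, fixed-count max-entropy bound |
| `popmodes.hmm`        | the mode HMM: scaled forward-backward, Baum-Welch EM with eta-shrinkage toward global statistics and per-iteration tree reselection, Viterbi, stationary mixture weights (w = Pw), static word log-likelihood, contiguous-block cross-validation over mode counts, sampling |
| `popmodes.analysis`   | transition entropy (full and off-diagonal renormalized), dwell times, participation-threshold curves, pairwise Fisher-LDA d' with shuffle control |
| `popmodes.repro`      | information efficiency (S_out, S_noise), windowed event reproducibility (+/-80 ms default), Hamming noise, shuffled-means and random-partition controls, time-permutation chance baseline |
| `popmodes.stimulus`   | STA, 7x7 receptive-field masking, logistic LN fitting (convex ML in gain/offset), LN population simulation, mode-triggered averages, rank-1 separable decomposition |
| `popmodes.synthetic`  | ground-truth mode-HMM generators (silent mode + ~10-cell active modes, separation knob) and stimulus-locked repeat simulation with path jitter |

A typical in-memory session:

```python
import popmodes as pm

truth = pm.make_ground_truth_model(n_cells=30, n_modes=5, seed=1)
raster, path = pm.sample_hmm(truth, T=20_000, seed=2)
model = pm.baum_welch_fit(raster, n_modes=5, eta=0.002, seed=3)
decoded = pm.viterbi(model, raster)
weights = pm.stationary_weights(model)
```

## Command line

```bash
popmodes bin --input spikes.csv --bin-ms 20 --out raster.tsv
popmodes fit --raster raster.tsv --modes 8 --eta 0.002 --seed 1 --out model.json
popmodes decode --model model.json --raster raster.tsv --out path.tsv
popmodes select-m --raster raster.tsv --candidates 1,2,5,10 --folds 2
popmodes analyze --model model.json --raster raster.tsv --theta 3 --out report.json
popmodes repro --model model.json --repeats repdir/ --window-ms 80 --out repro.json
popmodes simulate --cells 50 --modes 8 --bins 20000 --repeats 20 --out simdir/
```

Rasters are plain TSV (rows = cells, 0/1 values; `.gz` also accepted),
models are JSON, spike input is a `cell_id,time_s` CSV.

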