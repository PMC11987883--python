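# farrowcast

Continuous prediction of sow farrowing onset from video-derived activity
time series.

Knowing *when* a sow will start farrowing — not just the due date — lets
farm staff intervene early, reduce stillbirths and dystocia losses, and
plan supervision. Sows reliably become more active in the final day before
parturition (nest-building, restlessness), and that activity can be
measured without sensors by running dense optical-flow estimation on
overhead video. `farrowcast` implements the full analysis chain for
researchers in precision livestock farming:

1. **Activity quantification** — for each frame pair, a dense flow field
   `F ∈ R^{H×W×2}` gives per-pixel displacements `(u, v)`. Frame activity
   is the mean displacement magnitude
   `A = (1/N) Σ_i √(u_i² + v_i²)` (pixels/frame); 5-minute segment
   activity is the frame-wise sum `A' = Σ_t A_t`; series are min–max
   rescaled to `[0, 100]`. Flow estimators are pluggable backends (a deep
   estimator such as RAFT in production; an exhaustive block-matching
   reference for tests), scored by end-point error and the Fl-all
   percentage.
2. **Dataset construction** — ROI cropping, 25 fps → 2 fps frame
   selection, sliding windows of 72 five-minute points (6 h) whose label
   is the remaining time to onset in minutes at the window's final point,
   and strict subject-level train/validation/test splits (12/4/4 sows)
   with 4-fold CV structure.
3. **CLA-PTNet** — a CNN–LSTM–attention regressor: Conv1d+BatchNorm+ELU
   feature blocks (CBE), an LSTM long-dependency encoder (LDE), and a
   **position-aware time-weighted self-attention** (PTW-SA) layer in which
   a learnable positional-encoding matrix `P ∈ R^{t×d}` is added to the
   hidden states (`H' = H + P`), queries/keys/values come from learned
   projections (`Q = H'W_Q`, `K = H'W_K`, `V = H'W_V`), each key row is
   rescaled by a learnable time weight (`K'[i,:] = w_i·K[i,:]`), and
   `O = softmax(QK'^T / √d) V`. Mean-pooled attention output feeds a
   fully connected head that emits predicted minutes to onset. The
   network and its training loop are implemented directly on NumPy with
   hand-written backpropagation, verified against finite differences and
   a brute-force attention oracle.
4. **Analysis** — cohort correlation structure (pairwise Pearson
   coefficients and per-sow average correlation, AACC), STL decomposition
   to separate the pre-farrowing trend from the 24-h diurnal cycle, daily
   distribution statistics, interval-wise MAE/RMSE/R² reports over the
   final 30 h, and a return-on-investment calculator.
5. **Synthetic cohorts** — farm video is not redistributable, so a
   seeded generator simulates 20-sow cohorts (96 h at 5-min resolution,
   stable diurnal baseline, calibrated sigmoid activity ramp over the
   final 24 h, inflated final-day variance) with known ground truth,
   making every stage testable offline.

## Worked example

Run the complete synthetic workflow — simulate a 20-sow cohort, smooth and
normalize, window, train CLA-PTNet on 12 sows with 4 for validation, and
evaluate on the 4 held-out sows:

```bash
farrowcast run --seed 1 --out runs/demo
```

which prints (abridged):

```json
{
  "n_parameters": 11881,
  "test_mae_18h_min": 72.679370963997,
  "test_rmse_18h_min": 99.19377800650345,
  "test_r2_18h": 0.9015074514994645,
  "baseline_mae_18h_min": 273.6986301369863,
  "mae_reduction_vs_baseline_pct": 73.44547507321431,
  "mean_offdiag_pcc": 0.8827653470618111,
  "max_aacc": 0.9105915223055762,
  "stl_trend_rise_final_24h": 45.180887575709676
}
```

Reading: over the final 18 h before onset the trained model predicts the
remaining time with a mean absolute error of ~73 minutes on unseen sows —
a 73% reduction against a predict-the-training-mean baseline (~274 min) —
and explains 90% of the label variance. Cohort activity curves correlate
strongly across sows (mean pairwise Pearson 0.88), and the STL trend of
the most representative sow rises ~45 normalized activity units over the
final 24 h. The interval report written to `runs/demo/interval_report.csv`
shows the characteristic error structure: far from onset (30–24 h) the
activity signal carries almost no information and R² collapses far below
zero, while the bins nearest onset approach R² ≈ 0.8.

Individual stages are available as subcommands (`simulate`, `extract`,
`window`, `train`, `predict`, `report`, `roi`; see `farrowcast --help`
and `farrowcast show-config`), and the same functionality is importable
from `farrowcast` as a library.

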