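# dynconn

Dynamic functional connectivity (dFC) between resting-state brain networks,
estimated as a *conditional correlation* rather than a sliding-window
statistic, and turned into interpretable temporal/spectral features for group
inference and subject-level prediction.

The package is aimed at functional-connectomics researchers who have
per-subject ROI/network BOLD time courses (e.g. seed-based network averages
at TR ≈ 2 s) and want to go beyond the static Pearson correlation: estimate
how the coupling between two networks evolves over the scan, quantify the
shape of that trajectory, and ask whether those quantities separate clinical
groups.

## The model

For a pair of network time courses `Z_t = (Z_1t, Z_2t)'` each margin follows
an ARMA(2,2) mean with a GARCH(1,1) conditional variance,

    Z_jt     = α_j + β_1j Z_j,t-1 + β_2j Z_j,t-2 − θ_1j ε_j,t-1 − θ_2j ε_j,t-2 + ε_jt
    σ²_jt    = ω_j + φ_j ε²_j,t-1 + ψ_j σ²_j,t-1

and the standardized innovations `u_t = D_t⁻¹ ε_t` drive Engle's dynamic
conditional correlation (DCC) recursion

    Q_t = (1 − η₁ − η₂) Ξ + η₁ u_{t-1} u'_{t-1} + η₂ Q_{t-1}
    R_t = diag(Q_t)^{-1/2} Q_t diag(Q_t)^{-1/2}

whose off-diagonal ρ_t ∈ [−1, 1] *is* the dFC trajectory. Estimation is the
standard two-step Gaussian quasi-maximum-likelihood: univariate ARMA-GARCH
fits per series, then (η₁, η₂) maximize the correlation part of the
likelihood with Ξ fixed at the sample correlation of the standardized
residuals.

The trajectory is summarized by 17 features: mean (MV), unbiased variance
(VAR), proportion of anticorrelated volumes (PAV), thresholded zero-crossing
rate (ZC), and thirteen descriptors of its Welch power spectrum — centroid
(SCO), spread (SPR), skewness (SKW), excess kurtosis (KURT), median
frequency (SMED), 85% rolloff (SRO), dominant frequency (PEAK), crest
(CREST), flux (FLUX), slope (SLOPE), flatness (FLAT), power spectral entropy
(PSE) and the low-frequency fluctuation amplitude ALFF-dFC over
0.01–0.08 Hz. Group differences get BCa bootstrap confidence intervals with
Benjamini–Hochberg FDR control; subject-level prediction uses repeated
stratified 5-fold cross-validated Random Forests with conditional
permutation importance, compared against static-FC and sliding-window
baselines under identical fold assignments.

## Worked example

```python
import numpy as np
import dynconn as dc

# simulate one subject whose true coupling oscillates at 0.01 Hz
spec = dc.SimulationSpec(T=450, tr=2.0,
                         correlation=dc.SinusoidCorrelation(0.6, 0.01, 0.0),
                         seed=7)
sub = dc.simulate_subject(spec)

est = dc.DCCGARCH(tr=2.0).fit(sub.series)
print("tracking r =", round(np.corrcoef(est.rho_, sub.true_correlation)[0, 1], 3))
print("eta1, eta2 =", round(est.dcc_fit_.eta1, 3), round(est.dcc_fit_.eta2, 3))

fv = dc.extract_feature_vector(est.dfc_)
print("MV  =", round(fv["MV"], 3), " VAR =", round(fv["VAR"], 3))
print("PAV =", round(fv["PAV"], 3), " PEAK =", round(fv["PEAK"], 4), "Hz")
```

prints

```
tracking r = 0.694
eta1, eta2 = 0.128 0.73
MV  = 0.011  VAR = 0.05
PAV = 0.498  PEAK = 0.0117 Hz
```

The estimated conditional correlation follows the prescribed sinusoid
(`r = 0.69` with the truth), the DCC loadings show persistent correlation
dynamics (η₂ large), the trajectory spends about half its time
anticorrelated (PAV ≈ 0.5, as a zero-mean oscillation should), and the
dominant dFC frequency lands on the generating 0.01 Hz.

The same workflow runs from the shell: `dynconn simulate`, `dynconn fit-dfc`,
`dynconn features`, `dynconn compare-groups`, `dynconn classify`, or
end-to-end with `dynconn report config.yaml`.

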