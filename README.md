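# bmpdiversity

Quantitative analysis of BMP target gene expression diversity in early
zebrafish embryos: spatial expression ranges from dorsal–ventral intensity
profiles, activation times from transcript time courses, induction–decay
kinetics of responses to optogenetic (Opto-BMP) signaling pulses, and
cross-gene spatial diversity statistics. A synthetic-data generator with
explicit ground truth stands in for raw imaging and NanoString data, so
every estimator is testable end to end.

The package is aimed at quantitative developmental biologists who want to
re-run, probe, or extend this style of analysis from Python.

## The models

**Spatial ranges.** Per-embryo dorsal–ventral intensity profiles (% embryo
length, ventral = 0) are averaged into 0.5% bins, background-subtracted,
trimmed of the outer 5%, and rescaled onto the across-embryo mean shape
with an affine model `I_n(x) = A_n·c̄(x) + b_n`. Each normalized profile is
fitted with a bounded Gaussian `A·exp(−(x−μ)²/ς)` and the expression range
is

    r = μ + √(ς/2),

the dorsal position where the profile drops to e^(−1/2) of its peak.

**Activation times.** Transcript counts sampled every 30 min from 2.75 to
7.25 hpf are fitted with the scaled normal CDF
`(A/2)(1 + erf((t−ν)/(τ√2))) + b`; the activation time is
`t_act = ν − 1.5·τ`, about two mean average deviations before the
inflection ν.

**Pulse kinetics.** A 30-min blue-light pulse in Opto-BMP embryos adds an
optogenetic pSmad1/5/9 component on top of the endogenous signal; sibling
subtraction (injected − uninjected) isolates the induced pSmad pulse
`P_o(t)` and transcript response `T_o(t)`. Two estimators of each gene's
induction rate σ (1/s) and decay rate λ (1/s):

* **Method 1** – `dT_o/dt = σ·P_o − λ·T_o`, with `P_o` a degree-5
  polynomial smoothing of the measured pulse; `(T_o(0), σ, λ)` fitted per
  repeat by bounded Nelder–Mead (σ, λ ∈ [1e−5, 0.1]/s, T_o(0) ∈ ±100 a.u.).
* **Method 2** – the linear 4-ODE system with a Heaviside light input
  (`dPe/dt = k1 − k2·Pe`, `dPo/dt = k3·[θ(t)−θ(t−t_L)] − k2·Po`,
  `dTe/dt = k4·Pe − k5·Te`, `dTo/dt = σ·Po − λ·To`), solved in closed form
  and fitted in two unconstrained stages (pSmad parameters first, then
  gene parameters with the pSmad stage fixed).

**Spatial diversity.** `cv(x) = σ(x)/μ(x)` across genes' normalized mean
profiles at each position; lower values mean less spatial diversity.

## Worked example

```bash
python examples/03_pulse_kinetics_method1.py
```

```
repeat 1: sigma=0.000328/s lambda=0.000665/s To(0)=  -3.26 a.u.  R2=0.9484
repeat 2: sigma=0.000334/s lambda=0.000756/s To(0)=   7.50 a.u.  R2=0.9074
repeat 3: sigma=0.000306/s lambda=0.000689/s To(0)=  13.85 a.u.  R2=0.9687

across repeats: sigma = 0.00032 +/- 0.00001/s  (truth 0.000327)
                lambda = 0.00070 +/- 0.00005/s  (truth 0.000671)
```

Three simulated experimental repeats of a bambia-like gene (2%-scale
noise) are each fitted individually; the across-repeat mean recovers the
generating induction and decay rates to within a few percent. The other
examples cover spatial ranges, activation times, the closed-form Method-2
fit, the cv statistic, and the bundled published kinetics table.

A CLI mirrors the pipeline stages for shell use:

```bash
bmpdiversity simulate --out-dir sim --seed 7
bmpdiversity fit-kinetics --out-dir kin --pulse sim/pulse.csv
```

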