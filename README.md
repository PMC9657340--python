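# gutwash

Washout modelling and engraftment inference for probiotic dosing experiments
in multi-compartment in vitro gut simulators (SHIME-type systems), plus the
community-diversity and short-chain-fatty-acid statistics that typically
accompany them.

## The problem

When a probiotic (e.g. *Lacticaseibacillus rhamnosus* GG) is dosed once into
the ascending-colon vessel of a continuous colon simulator, its
concentration falls over the following feeding cycles even if every cell
survives — fresh medium dilutes the vessel and transit carries cells
downstream and out to waste. Deciding whether the organism *engrafted*
(persisted or replicated) therefore requires comparing measured qPCR counts
against the null expectation of pure dilution and transit. gutwash is aimed
at researchers running such experiments: it provides that null model, the
estimators that quantify deviation from it, and the 16S/SCFA summary
statistics used to assess community-level impact.

## The model

The simulator is a chain of stirred vessels with working volumes
$V_1, \dots, V_k$ (defaults 500, 800, 600 mL for AC, TC, DC). Each feeding
cycle moves a transfer volume $u$ (default 140 mL, three cycles/day) into
every vessel; combining an inflow of volume $M_1$ at concentration $r_1$
with resident content $M_2$ at $r_2$ gives the mixed concentration

$$r = \frac{M_1 r_1 + M_2 r_2}{M_1 + M_2},$$

and discharging $u$ of the mixture restores the working volume. For a single
organism-free-fed vessel this yields geometric decay
$c_n = c_0 \left(V/(V+u)\right)^n$, the analytic oracle for the chain
simulation. The scheme conserves mass exactly: dosed cells resident in the
system plus cumulative waste always equal the dose.

A per-compartment net growth multiplier $g_i$ (resident cells multiplied by
$g_i$ each cycle before transit; $g_i = 1$ recovers the no-growth model)
extends the null to net replication or death. The engraftment module fits
$g_i$ by least squares on log concentrations (upstream vessels first, since
downstream inflow depends on upstream state), attaches a residual-bootstrap
confidence interval, and classifies each measured series by the geometric
mean of measured/predicted over the final cycles:
`ABOVE_EXPECTED` / `TRACKING` / `BELOW_EXPECTED` at a two-fold threshold.

On the quantification side, qPCR DNA mass converts to genome copies via

$$\text{copies} = \frac{\text{ng DNA} \times 6.0221\times10^{23}}
{3{,}010{,}111 \times 660 \times 10^9},$$

one copy is counted as one cell, and the endogenous pre-dose level is
subtracted from post-dose measurements. Community metrics cover probiotic-ASV
removal, Shannon diversity (nats), observed richness, Faith's phylogenetic
diversity, ANOVA with Tukey HSD, Firmicutes/Bacteroidetes ratios, Pearson
SCFA–taxon correlations and stratified pre/post Welch tests. A synthetic-data
module generates every input with the statistical structure the analysis
assumes, so the whole pipeline is testable without sequencing data.

## Worked example

```sh
python examples/01_washout_prediction.py
```

```
cycle        AC           TC           DC      (cells/mL)
    0        5e+06            0            0
    1    3.906e+06    5.533e+05    1.738e+05
    5    1.455e+06    1.232e+06     8.11e+05
    9    5.421e+05    9.971e+05    9.885e+05
   31         2374    4.967e+04    1.229e+05

peak cycles: {'AC': 0, 'TC': 5, 'DC': 9}  (downstream peaks come later, in chain order)
cells in system + waste at cycle 31: 2.5e+09 of 2.5e+09 dosed
```

The dosed AC decays monotonically from 5×10⁶ cells/mL while TC and DC rise to
successively later, lower peaks — the signature washout shape. Fitting noisy
synthetic qPCR data generated with AC growth 1.2×/cycle and downstream death
0.9×/cycle (`python examples/02_engraftment_inference.py`) recovers the
multipliers and calls the deviation:

```
compartment  phase   baseline    fold-change  fitted g (95% CI)   class
         AC  lumen   2.34e+03          278  1.197 (1.195-1.199) ABOVE_EXPECTED
         TC  lumen   3.79e+04         11.2  0.898 (0.887-0.911) ABOVE_EXPECTED
         DC  lumen    1.7e+04         29.3  0.905 (0.898-0.922) ABOVE_EXPECTED
```

Fitted multipliers match the generating values (1.2, 0.9, 0.9); the
endpoint concentrations sit 11- to 278-fold above the endogenous baselines.
The remaining examples cover diversity (`03`), SCFA statistics (`04`) and the
end-to-end pipeline (`05`); `gutwash --help` lists the equivalent shell
commands (`synth`, `predict`, `simulate`, `quantify`, `engraft`,
`diversity`, `scfa`, `run`).

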