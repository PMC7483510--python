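# freepol

Quantitative analysis of gene expression in *E. coli* under sublethal
translation inhibition (chloramphenicol), from raw plate-reader growth
curves to estimates of free RNA-polymerase concentration, ppGpp
inhibition, and translation processivity.

The package is aimed at microbial-physiology labs that measure reporter
expression (GFP, β-galactosidase, RFP–GFP operons) on plate readers and
want to turn those curves into the resource-allocation quantities of
bacterial growth laws. Because such experiments rarely ship with public
raw data, a seeded synthetic-data generator reproduces the statistical
structure of the measurement process so that every pipeline stage is
testable end to end.

## Models

**Growth and expression.** The growth rate μ (doublings/h) is the slope
of log₂OD₆₁₀ vs time in an exponential window bounded by OD thresholds;
the reporter concentration is the slope of background-subtracted
fluorescence vs OD in the same window, and the production rate is
Gpr = concentration × μ. β-galactosidase is quantified from ONPG
kinetics, OD₄₅₀(t) = A(1 − e^(−γt))/γ, as 2×10⁶·A/OD₆₁₀ Miller units.

**Free RNAP from promoter competition.** Transcription initiation at a
constitutive promoter is Michaelis–Menten in the free-RNAP concentration
c_f: TR = a·c_f/(c_f + K). With a shared GFP translation rate, the
production-rate ratio of a low-affinity (PLtet) and high-affinity (P5)
promoter,

    Gpr(PLtet)/Gpr(P5) = a (K₅ + c_f) / (K_Ltet + c_f),

is a monotone function of c_f with a closed-form inverse. Anchoring
no-drug ratios to the growth law log c_f = A·exp(−μ_r/μ)
(A = 6.82 log μm⁻³, μ_r = 0.11 dbl/h) fixes a and K₅; inverting the
ratio then reads out c_f under chloramphenicol. Promoter binding
energies can be scored from sequence (Berg–von Hippel-style hexamer +
spacer penalties) and mapped to dissociation constants via
K_j = K_i·e^(E_j−E_i).

**ppGpp.** The inhibition of the rRNA promoter P1 is the P1/P5
production-rate ratio divided by the promoter-activity ratio, modeled as
a Hill function b·k_pⁿ/(k_pⁿ + c_pⁿ) of the ppGpp concentration
c_p = c_p0·e^(−μ/μ_p).

**Processivity.** A ribosome translating a gene of L amino acids at
v aa/min is hit by chloramphenicol before finishing with probability

    P_hit = 1 − exp(−k_on [Cm] L / v),    k_on = 0.034 (μM·min)⁻¹,

and completes with probability exp(−(β₀ + k_on[Cm]/v)·L), where β₀ is a
baseline per-codon stall rate. Stalls trigger mRNA degradation, which
penalizes long genes and downstream operon positions; the
downstream/upstream operon ratio is C·(1 − y)·P_complete(upstream) with
terminator efficiency y.

## Worked example

```python
import freepol as fp
from freepol import synthetic_data as synth

truth = synth.SimulationTruth(seed=42)          # 4 media x 4 Cm grid, 2% noise
wells, record = synth.simulate_plate_reader(truth)
df = fp.estimate_free_rnap(wells, truth.ratio_constants)
print(df[df.medium == "cAA-glu"].round(3).to_string(index=False))
```

```
 medium  cm_um    mu  gpr_num  gpr_den  ratio     c_f
cAA-glu    0.0 1.632 7446.069 2730.995  2.727 579.920
cAA-glu    2.0 1.416 5913.081 2321.341  2.547 521.776
cAA-glu    4.0 1.209 4892.294 1872.973  2.612 542.485
cAA-glu    8.0 0.846 2689.898 1207.005  2.229 424.612
```

Each row is one growth condition: the fitted growth rate (doublings/h),
the PLtet and P5 production rates (RFU/OD/h), their ratio, and the
free-RNAP concentration (molecules/μm³) obtained by inverting the ratio
model — lower at higher drug because growth, and with it free RNAP,
slows.

```python
tp = fp.TranslationParams()                      # k_on = 0.034, v = 1050 aa/min
fp.p_hit(fp.GeneSpec("lacZ", 1024), 8.0, tp)     # 0.233  -> 23% of ribosomes hit
fp.p_hit(fp.GeneSpec("gfpmut2", 238), 8.0, tp)   # 0.0598 ->  6%
```

At 8 μM chloramphenicol roughly a quarter of ribosomes stall before
finishing the 1,024-aa β-galactosidase, versus 6% for the 238-aa GFP —
the length dependence that skews expression against long genes.

A `freepol` command-line tool exposes the same pipeline
(`simulate`, `fit-growth`, `score-promoters`, `estimate-rnap`,
`estimate-ppgpp`, `processivity`, `operon`); run `freepol --help`.

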