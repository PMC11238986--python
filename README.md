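# fmloop

A multistable neuroendocrine model of fibromyalgia (FM) pathogenesis,
implemented as a tested Python library with a thin command-line interface.

FM is a chronic widespread-pain syndrome with strong female prevalence and
stress correlation but no established pathogenic mechanism.  `fmloop`
implements a network-level hypothesis: chronic pain is a *stable dynamical
regime* of a pain-processing brain loop, reached when endocrine conditions
shift its synaptic couplings across a bifurcation.  The package is aimed at
computational/systems biologists who want to reproduce, probe or extend the
analysis: every published anchor value is recomputed from the equations at
run time.

## The models

**Thalamocortical loop** (`fmloop.thalamo`).  Mean firing rates of the
somatosensory cortex (S), thalamic reticular nucleus (T) and
ventroposterolateral thalamus (V) evolve as

```
τ Ṡ + θS = f₁(bV)
τ Ṫ + θT = f₂(b(V+S))
τ V̇ + θV = g(aT) · (bS)ʰ / (f_a(aT)ʰ + (bS)ʰ)
```

with increasing Hill curves f₁, f₂ (maxima m₁ = 100, m₂ = 80 Hz), a
decreasing Hill curve g, and f_a(aT) = e₀ + (m₂-Hill of aT); e = e₀ = 20 Hz,
h = 2.5, τ = 0.5 s.  The couplings a (GABAergic), b (glutamatergic) and θ
(self-limiting) live in (0, 1].  Below a critical GABAergic strength
â(b, θ) a saddle-node fold creates a high-firing attractor — the putative
chronic-pain state.  `bifurcation_point` locates â by bisection on the
count of stable equilibria: â(1, 1) ≈ 0.264, â(0.5, 1) ≈ 0.117,
â(0.6, 1) ≈ 0.155.

**Neurosteroid map** (`fmloop.steroid`).  Brain allopregnanolone A (ng/mL)
sets the GABAergic strength through two increasing Hill components,

```
a(A) = a_f·Aʰʷ/(e_wʰʷ + Aʰʷ) + (1−a_f)·Aʰᵍ/(e_gʰᵍ + Aʰᵍ)
```

a withdrawal (α4-subunit) term saturating at the follicular strength
a_f = 0.4 and a positive-allosteric term with EC₅₀ e_g = 18 ng/mL.  The full
calibration chain (a_f from the ~150% maximal GABA_A increase, the 3-fold
current depression at withdrawal, the finasteride-derived withdrawal level
1.6 ng/mL, and the 2-D root solve for (e_w, h_w) ≈ (1.8, 6.5)) is
reproducible via `calibration_chain()`.

**HPG–HPA endocrine loop** (`fmloop.endocrine`).  Axis activities on a
0–100 scale under mutual inhibition f(x) = 100/(1+(x/e_x)^h_x) and
self-limitation k(x) = 1 + 4/(1+(αx/e_k)^h_k):

```
τ ḢPA = f(HPG) − k(HPA)·HPA
τ ḢPG = f(HPA) − k(HPG)·HPG
```

with e_x = 28, h_x = 4.2, e_k = 25.57, h_k = 6.6, α = 0.48, τ = 30 min.
The system is tristable; `basin_map` labels basins of attraction on a grid.

**Scenario coupling** (`fmloop.scenario`).  The endocrine steady state is
mapped monotonically to (a, b) and the thalamocortical regime classified;
`prevalence()` computes the predicted female/male prevalence ratio
G = p_woman/p_man from one withdrawal episode per menstrual cycle.

## Worked example

```
$ python examples/pathogenesis_scenario.py
stress + withdrawal: endocrine -> (HPA=86.1, HPG=0.2), a=0.135, b=0.586, a_hat=0.150 -> BISTABLE
  high-firing attractor: S=79.1, T=77.6, V=58.1 Hz
balanced: endocrine -> (HPA=17.5, HPG=17.5), a=0.399, b=0.518, a_hat=0.125 -> MONOSTABLE

prevalence: p_woman=0.0341/day, G=6.81, 87.2% women among patients
```

A stress + neurosteroid-withdrawal history relaxes to the high-HPA/low-HPG
endocrine attractor; the mapped couplings (a = 0.135 < â = 0.150) put the
pain loop in its bistable regime with a high-firing attractor at V ≈ 58 Hz
— the pathogenic verdict.  A balanced history lands on the symmetric
endocrine state and the loop stays monostable.  The prevalence calculation
yields G ≈ 6.8, i.e. ≈ 87% women among patients, matching the reported
80–90% range.

The other examples (`examples/bifurcation_sweep.py`,
`examples/neurosteroid_calibration.py`, `examples/endocrine_basins.py`)
exercise each capability separately, and the same operations are available
from the shell, e.g.:

```
fmloop thalamo bifurcation --b 1.0
fmloop steroid map --A 18
fmloop endocrine basins --resolution 101 --out basins.csv
```

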