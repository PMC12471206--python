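# rtenergy

A bioenergetic ODE model of retrotransposon activity and the cellular
ATP balance, packaged as a tested simulator with steady-state and
stability analysis, parameter sensitivity, copy-number perturbation
scenarios, energy-budget decomposition, and free-parameter calibration.

## The problem

Retrotransposons — the autonomous LINE-1 (L1) and the nonautonomous
Alu — are the only mobile elements still active in the human genome,
and they are markedly re-activated in cancer cells. Every step of
their life cycle (transcription, translation, reverse transcription of
new genomic copies, replication of the lengthened genome) consumes
ATP in competition with housekeeping gene expression. Because a drop
of cellular ATP below roughly 30% of its homeostatic level is
associated with initiation of cell-death programs, deliberately
overloading the energy balance through retrotransposon activity is a
candidate anticancer strategy. This package implements a kinetic
model of that energy balance for an "average" eukaryotic cell so the
scenarios — extra element copies, perturbed silencing or transcription
rates — can be simulated and ranked quantitatively. It is aimed at
systems-biology modellers and computational cancer researchers.

## The model

Twelve concentrations (molecules per cell, m.p.c.) evolve under mass
action and Michaelis–Menten kinetics: free ATP *a*; housekeeping mRNA,
mRNA–ribosome complex and protein (*mq*, *cq*, *q*); L1 and Alu mRNA
(*mL*, *mS*); the L1 mRNA–ribosome complex *cL*; the L1 proteins ORF1p
(*O1*) and the mRNA–ORF2p reverse-transcriptase complexes (*bL*,
*bS*); and the genomic counts of active elements (*L*, *S*). ATP
obeys

```
da/dt = A0 − λ_a a − v_repl − N_nt (N_Q ω_q + N_L ω_L + N_S ω_S)
              − N_aa (N_q v_q + (N_L/3) v_L) − N_nt (N_L v_intL + N_S v_intS)
```

with transcription ω_x = copies · w_x · a/(θ_x + a), translation
v = (γ_max/ℓ) · c · a/(K_γ + a), insertion
v_intL = (χ_maxL/N_L) · bL · a/(K_χL + a) · K_L O1/(1 + K_L O1) (and
the ORF1p-independent analogue for Alu), and replication cost
v_repl = N_nt (N_g/τ + N_L v_intL + N_S v_intS). Alu encodes no
protein: its reverse-transcription complex *bS* forms only by
displacing the L1 mRNA from *bL*, which couples the two families into
a predator–prey-like pair. All ~45 constants ship as defaults
(`ParameterSet()`), alongside the reference stationary solution
(`reference_state()`).

## Worked example

```python
from rtenergy import (ParameterSet, reference_state, find_steady_state,
                      perturb_initial_state, simulate, drop_metrics,
                      reduced_model_experiment)

p = ParameterSet()                      # published constants
ss = find_steady_state(p, reference_state())
print(f"a* = {ss.state.a:.3e}  L* = {ss.state.L:.0f}  "
      f"S* = {ss.state.S:.0f}  stable = {ss.stable}")

init = perturb_initial_state(reference_state(), fold_L1=1000)
traj = simulate(p, init, 1e4)
m = drop_metrics(traj, threshold_fraction=0.30, a_ref=ss.state.a)
print(f"T_drop = {m.T_drop:.2f} min  a_min/a* = {m.a_min/ss.state.a:.3f}")

red = reduced_model_experiment(p, ref_ss=ss)
print(f"Alu-free energy ratio = {red.energy_ratio:.2f}")
```

prints

```
a* = 5.320e+09  L* = 1067  S* = 13361  stable = True
T_drop = 5.10 min  a_min/a* = 0.074
Alu-free energy ratio = 2.32
```

That is: the model settles at ~5.3 billion free ATP molecules with
~1.1k active L1 and ~13k active Alu copies; inserting a thousandfold
excess of L1 copies drives ATP below the 30% viability threshold for
about five minutes, more than tenfold deep; and deleting Alu — L1's
competitor for the ORF2p machinery — leaves a steady state with
2.3-fold less free energy.

The same experiments are available from the shell:

```
rtenergy steady --out-dir out/
rtenergy sweep-copies --which L1 --folds 1:10000:19 --out-dir out/
rtenergy reduced --out-dir out/
```

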