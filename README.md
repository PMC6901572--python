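# endplatesim

Stochastic spatial simulation of synapse elimination at developing
neuromuscular junctions (NMJs).

At birth, each muscle endplate is innervated by several motor axons; over
the first postnatal weeks all but one are eliminated. Electron-microscopy
reconstructions of developing NMJs show that the endplate is shared three
ways throughout this period — by axon terminals, by terminal Schwann cells
(tSCs), and by *vacancies* contacted by neither — and that the three
relative contact areas shift systematically with age. `endplatesim`
implements a site-based Markov model of this competition for researchers
studying synapse elimination, glia–axon interactions, or
winner-take-all dynamics on spatial substrates: the endplate is a disc
tiled by identical circular contact sites whose occupants evolve
stochastically, with all axon↔tSC territory exchange mediated by
vacancies.

## Model

Each iteration selects one site (uniformly, or with the sites of "active"
axons down-weighted by a divisor, default 2) and applies one transition
draw. In the vacancy-mediated chain, ordered over states (S, V, A) =
(tSC, vacancy, axon):

```
        S           V           A
  S   1 − P_SV     P_SV         0
  V    P_VS         0        1 − P_VS
  A     0          P_AV      1 − P_AV
```

Direct A↔S conversion is structurally absent. Requiring a measured
composition vector r = (r_S, r_V, r_A) to be stationary, r M = r, fixes
two of the three probabilities in terms of the free parameter P_VS:

```
P_SV = r_V · P_VS / r_S        P_AV = r_V · (1 − P_VS) / r_A
```

with P_VS = 0.6 by default (feasible for every measured stage
composition). When a vacancy converts to an axon site, the identity is
drawn in proportion to the number of adjacent sites each surviving axon
holds (total site counts when the vacancy has no axon neighbour), so
locally dominant axons reclaim territory preferentially. A run is
complete when exactly one axon identity survives — with tSCs and
vacancies still present, as observed in vivo.

Two reference variants — fully `random` per-step transition probabilities
and fixed `equal` (1/3) probabilities, both with neighbour-copy dynamics —
terminate only in homogeneous endplates (one axon everywhere, all tSC, or
all vacant) and serve as the contrast showing why composition-matched
constant probabilities are needed.

The measured stage compositions ship as fixtures
(`endplatesim.STAGE_RATIOS`): P0 31/17/52, P3 57/18/25, P7 55/5/40,
P16 41/6/53 (tSC/vacancy/axon, %).

## Worked example

```bash
python examples/activity_selection.py
```

```
active axons  mean iterations  active-set win rate
           0            10881                    -
           1             4556                  90%
           2            18724                 100%
           3            22142                 100%

One active axon accelerates elimination 2.4-fold and is
almost always the sole survivor; additional active axons protect each
other's competitors and slow completion.
```

Each row is a batch of 20 replicates (100-site newborn layouts, nine
axons, P3-derived probabilities) with that many active axons drawn afresh
per replicate. "Mean iterations" is the average least iteration at which
a single axon remained; the win rate is the fraction of completed runs
whose survivor belonged to the active set. One protected axon both wins
almost always and halves the time to single innervation; coherently
active groups shield one another and slow the endgame instead.

The other scripts in `examples/` each demonstrate one capability:
solving stage probabilities, watching a single run's composition series,
comparing developmental stages, correlating the composite area
r_S·r_V/r_A with elimination speed, and the random/equal contrast models.

A thin CLI wraps the same library calls:

```bash
endplatesim solve-probs --ratios 0.57,0.18,0.25 --pvs 0.6
endplatesim simulate --n-reps 100 --base-seed 1 --out-dir results/
endplatesim sweep stages --stages P3,P7,P16
```

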