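# worldviews

Reaction-network and chemical-organization-theory (COT) modelling of how
worldviews form, stabilise and change.

The package is for researchers in opinion dynamics, social simulation and
artificial chemistry who want to study belief systems the way origin-of-life
research studies metabolisms.  Belief attitudes and belief-change triggers
are chemical species; their interactions are reactions
`c_1 s_1 + … + c_n s_n → p_1 s_1 + … + p_n s_n`; and a *worldview* is an
**organization** of the network — a species set *X* that is

* **closed**: the reactions triggered by *X* (those whose reactants all lie
  in *X*) produce nothing outside *X*, and
* **self-maintaining**: some process vector **v** with `v_i > 0` on every
  triggered reaction gives non-negative net production `(S·v)_j ≥ 0` for all
  members, where `S[j,i] = p_ij − c_ij` is the stoichiometric matrix.

Self-maintenance is decided by linear programming; mass-action dynamics
`ds/dt = S·v(s)` with `v_i = k_i Π_j s_j^{c_ij}` connect structure to states
through the ε-abstraction Ω(s) — the species above a 10%-of-class-total
concentration threshold.  The library ships two models: a 5-species
single-theme belief network (attitudes S/U/D, triggers s/p) and a 40-species
two-theme network of compound beliefs (e.g. `Sp1Us2`), plus perturbation
protocols that drive irreversible worldview transitions by stochastic
external input of "problem" triggers.

## Worked example

```python
import worldviews as wv

net = wv.build_simple_model()          # S, U, D, s, p with rates k0..k9
lattice = wv.enumerate_organizations(net)
for org in lattice.organizations:
    print(org.size, sorted(org.members), sorted(org.reactive_triggers))

traj = wv.simulate(net, wv.make_instance(net, {"S", "s"}), horizon=500)
print({sp: round(x, 4) for sp, x in zip(traj.species, traj.values[-1])})
print(sorted(wv.abstraction(net, traj.values[-1])))
```

prints

```
2 ['S', 's'] ['s']
4 ['D', 'S', 'U', 'p'] ['p']
5 ['D', 'S', 'U', 'p', 's'] ['p', 's']
{'S': 1.0, 'U': 0.0, 'D': 0.0, 's': 1.3333, 'p': 0.0}
['S', 's']
```

The three organizations are the stable worldviews of the model: pure
satisfaction {S,s}, the discontent worldview {p,S,U,D}, and their join where
solution and problem perceptions coexist.  Simulating from a satisfaction
instance converges to the fixed point S = 1, s = k2/k9 = 4/3, and the
end-state abstraction recovers the organization {S,s} — the
structure–dynamics correspondence at the heart of the method.

The same is available from the shell:

```sh
worldviews orgs --model simple --out-dir out/         # JSON report + Hasse DOT/CSV
worldviews orgs --model two-theme                     # the 8 published organizations
worldviews perturb --model simple --instance S,s --horizon 3000 \
    --stop-discontent --seed 7 --out-dir out/         # emergence of discontent
worldviews sweep --k-values 0.15,0.10,0.05 --n 200 --seed 1 --out-dir out/
```

`perturb` injects problem triggers at random intervals (Normal(7, 1) days,
amounts uniform below 0.25 by default) and, with `--stop-discontent`, halts
the input once discontent doubles satisfaction (D > 2S) — showing that the
discontent worldview, once reached, persists without further input.
`sweep` tabulates end-state abstraction frequencies as the trigger-decay
("memory") constants k8 = k9 shrink, shifting mass from the satisfaction to
the discontent basin.

See `docs/methods.md` for the model definitions, the two-theme
reconstruction and its structural validation, thresholds, integrator
settings and the experiment defaults.

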