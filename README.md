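# hdexc — history-dependent excitability of linear neuron models

`hdexc` studies how much of its recent input history a neuron "remembers",
and how well a downstream observer could tell two input histories apart, for
two exactly solvable subthreshold models:

- **IF** — a leaky integrator, `dv/dt = -alpha * v`, whose voltage relaxes
  monotonically (canonical `alpha = 1`);
- **GIF** — a generalized integrate-and-fire model with a recovery variable,
  whose eigenvalues `-lam ± i*omega` produce damped intrinsic oscillations
  (canonical `lam = 1`, `omega = 2`, i.e. eigenvalues `-1 ± 2i`).

Inputs are trains of instantaneous EPSPs (voltage jumps of amplitude `s`).
Because the subthreshold dynamics are linear, everything is computed in
closed form: propagation uses the exact matrix exponential, and the central
quantity — the **cumulative discriminability**

    D = ∫₀^∞ (v_A(t) − v_B(t))² dt

between the free trajectories following two input trains A and B — is a
quadratic form in the post-input state difference.  The companion quantity,
**history-dependent excitability (HDE)**, is the minimal EPSP amplitude that
would make the neuron fire at a given moment; for a fixed voltage threshold
`theta` it is `theta − v(t)` along the free evolution, so excitability
differences are exactly voltage differences.

The scientific picture the package operationalizes:

- An IF neuron forgets monotonically; its discriminability between two
  doublets only grows with the rate difference, and appending a shared
  interval `L` to both trains multiplies D by exactly `e^(−2·alpha·L)`.
- A GIF neuron carries a *temporal* code: the instantaneous
  discriminability oscillates (zeros every `pi/omega`, an optimal readout
  time can be strictly after the last input), the doublet map develops an
  off-diagonal ridge maximum near ISIs slightly shorter than the intrinsic
  period `2*pi/omega`, and each intrinsic period erases memory by exactly
  the squared damping coefficient `Q² = e^(−4*pi*lam/omega)`.
- Over random (exponential-ISI) input ensembles, the mean discriminability
  admits a closed form, so Monte-Carlo estimates can be validated exactly.

## Worked example

```python
import numpy as np
from hdexc import (
    HDEConfig, NeuronState, SpikeTrain, gif_model, hde_trajectory,
    propagate_train, train_discriminability, damping_coefficient,
    locate_doublet_maximum,
)

model = gif_model(1.0, 2.0)          # eigenvalues -1 +/- 2i
print("damping coefficient Q =", round(damping_coefficient(model), 6))

# two doublets that differ only in their single interspike interval
a = SpikeTrain([-1.0, 0.0])
b = SpikeTrain([-2.0, 0.0])
res = train_discriminability(model, a, b)
print("cumulative discriminability D =", round(res.cumulative, 6))
print("optimal readout time t* =", round(res.t_max, 6))

# excitability after the doublet {-1, 0}: theta - v(t)
state = propagate_train(model, a)
traj = hde_trajectory(model, NeuronState(state.v, state.w),
                      np.linspace(0.0, 3.0, 4), HDEConfig(theta=3.0))
print("HDE samples:", np.round(traj.values, 4))

# the resonance fingerprint of the doublet map
print("ridge maximum (isi1, isi2):",
      tuple(round(x, 4) for x in locate_doublet_maximum(model)))
```

prints exactly:

```
damping coefficient Q = 0.043214
cumulative discriminability D = 0.045083
optimal readout time t* = 0.480147
HDE samples: [2.1531 3.2416 3.0407 2.9549]
ridge maximum (isi1, isi2): (0.7854, 2.3562)
```

Note the oscillation: right after the doublet the neuron is *more* excitable
than at rest (HDE 2.15 < 3), half a period later less (3.24 > 3).  The ridge
maximum sits at `(pi/4, 3*pi/4)` — both ISIs below the intrinsic period `pi`.

## Command-line interface

The `hdexc` entry point wraps the library pipelines; every output embeds the
resolved configuration (and seed, where randomness is involved):

```
$ printf -- "-1.0 1.0\n0.0 1.0\n" > a.txt
$ printf -- "-2.0 1.0\n0.0 1.0\n" > b.txt
$ hdexc --quiet discriminate a.txt b.txt --kind GIF --out out.json
$ cat out.json
{
  "cumulative": 0.04508327059530561,
  "divergent": false,
  "t_max": 0.48014730486596147,
  "d_max": 0.05974076073339864,
  ...
}
```

Subcommands: `hde-trace`, `discriminate`, `doublet-map`,
`triplet-sensitivity`, `ensemble`, `sweep`.  Tables are CSV with a
`#`-commented metadata header; scalars are JSON.

## Reproduction

- `python -m pytest -q tests/` runs the full suite, including one acceptance
  test per headline scientific property (exact nulls, closed-form vs
  quadrature, shape laws, exponential forgetting, sensitivity and ensemble
  consistency, rate-vs-timing contrast, mean-ISI profiles, doublet-map
  structure).  Takes about half a minute on one CPU.
- `python scripts/acceptance.py --seed 1 --out results/acceptance.json`
  recomputes the headline quantities from scratch (~10 s) and writes them as
  JSON; all randomness derives from `--seed`, and identical seeds give
  byte-identical output.

See `docs/methods.md` for the model realization, parameter defaults,
numerical choices, and known limitations.
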