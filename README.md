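# genosc

Deterministic models of a **single-gene autoinhibitory circuit** — a gene
whose protein product represses its own transcription, the core motif of
the vertebrate segmentation clock — at every level of mechanistic detail,
with the stability and oscillation analyses that show *why the detail level
matters*.

The same biological assumptions, described more or less finely, predict
different phenotypes:

* the instantaneous two-variable model (`I`) can never oscillate
  (Bendixson–Dulac: its divergence −γm − γ is negative everywhere);
* resolving transcription/translation into stages (`II`, `chain`) turns the
  fixed point into a damped spiral;
* lumping the stages into discrete delays (`III`) yields sustained
  oscillations;
* replacing the phenomenological Hill function
  R(c) = 1/(1 + (c/K_d)^{n_H}) by explicit promoter kinetics — three
  identical binding sites evolving by mass action (`IV`, `V`, and the
  delayed-CRS reduction) — reveals that two cooperative-binding mechanisms
  compatible with the *same* equilibrium regulatory function behave
  differently: **recruitment** (bound TFs raise binding rates by ε^i) and
  **stabilization** (bound TFs lower unbinding rates by ε^i) share the
  Adair curve

  R(c) = (1 + cK₁ + c²K₁K₂ + c³K₁K₂K₃)⁻¹,  Kᵢ = k_{i−1,i}/k_{i,i−1},

  and hence the same fixed point and the same effective (K_d, n_H), yet at
  slow promoter kinetics the recruitment circuit oscillates while the
  stabilization circuit spirals in, and where both oscillate the
  recruitment oscillator is the faster one.

The package provides: cooperative rate laws and the Adair↔Hill
phenomenological map; all model variants with analytic Jacobians and fixed
points; Erlang ("weak"/"strong") and discrete delay kernels with an exact
linear-chain-trick expansion; a fixed-step RK4 method-of-steps DDE
integrator; transcendental characteristic-root finding, fixed-point
classification and Hopf-threshold bisection; oscillation summaries
(period, amplitude, decay ratio); a registry of the published parameter
regimes; synthetic parameter fixtures; and a small CLI.

## Worked example

The CRS with p = 0.1 /min, q = 43 /min, ε = 8.5 maps to its
phenomenological parameters:

```bash
$ genosc effective-hill -p 0.1 -q 43 -e 8.5
Kd_eff = 40.1073 molecules, nH_eff = 2.21852
```

i.e. half-repression at ≈ 40.1 molecules with an effective Hill exponent
≈ 2.22 — identical for both cooperativity mechanisms, because they share
every equilibrium constant.  The *dynamics* do not coincide.  Scaling the
same promoter's kinetics with p = f·0.1, q = f·43 (which leaves the
regulatory curve and fixed point untouched) and driving the delayed-CRS
model with a 3.5-min discrete lag at f = 0.09:

```python
from genosc import run_scenario

res = run_scenario("fig6_c")          # f = 0.09, both mechanisms
for mech in ("RM", "SM"):
    s, r = res.oscillation[mech], res.stability[mech]
    print(mech, r.classification, f"period={s.period:.3f} min amp={s.amplitude:.1f}")
```

```
RM unstable_oscillatory period=12.337 min amp=87.7
SM unstable_oscillatory period=14.639 min amp=41.9
```

Both mechanisms sustain oscillations at this TF residence time
(q⁻¹ = 15.5 s), but the recruitment circuit runs ~19% faster and with
twice the amplitude of the stabilization circuit — a difference invisible
to any model that summarizes the promoter by the Hill function.  At
f = 0.03 (q⁻¹ = 46.5 s) the split is qualitative: `run_scenario("fig6_a")`
classifies RM as `unstable_oscillatory` and SM as `stable_spiral`.

Other entry points: `registry()` lists the scenario specs (each numeric
field carries a provenance tag); `genosc repro <name>` re-runs one from the
shell and writes CSV/JSON artifacts with `--out-dir`; `hopf_scan` bisects
stability thresholds (e.g. the equal-rate 4-stage loop needs n_H ≥ 4 to
oscillate, threshold ≈ 4.13); `sample_crs_params` draws seeded parameter
batches with TF residence times spanning 2–100 s.

See `docs/methods.md` for the model equations, numerical choices, and the
assumptions behind each registered scenario.

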