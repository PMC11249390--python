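# stallflow

Tools for linking **cerebral capillary stalling** to **arteriovenous transit
time** in the cortical microcirculation. The package reimplements, as a tested
and reusable pipeline, three measurements that are usually scattered across
ad-hoc scripts:

1. **Stall detection** in OCT-angiogram frame stacks. Capillary stalls —
   transient stoppages of red-blood-cell flow — appear as intensity dropouts
   in single capillary segments. The pipeline flattens 4-D volumes by maximum
   intensity projection, enhances tubular structure with a multiscale
   vesselness filter, segments the capillary bed (skeletonize, cut at branch
   points, grow back to the mask), extracts per-segment intensity traces, and
   calls stall events with a per-capillary threshold (a fraction α of that
   segment's temporal median) and a minimum-duration rule of 3 frames (~27 s
   at 9 s/frame). Summary metrics: the proportion of segments with ≥1 true
   stall event, and pooled event durations.

2. **Bolus-tracking kinetics** from fluorescence dye passage (e.g.
   FITC-dextran). From arterial and venous ROI traces it estimates arrival
   (I/T_arrival), peak (I/T_peak), the half-maximum rise time t½, the blood
   flow index

   `BFI = (I_peak − I_arrival) / (T_peak − T_arrival)`,

   and the arteriovenous mean transit time

   `MTT = t½(vein) − t½(artery)`.

3. **Network flow simulation** on cortex-like vascular graphs. Steady
   Poiseuille flow (`g = π d⁴ / 128 μ L` per vessel segment) is solved
   sparsely with fixed boundary pressures; random capillary blockage at a
   chosen stall fraction scales the affected conductances by 10⁻⁶; a tracer
   bolus is advected through the solved field (plug-flow delay lines with
   complete flow-weighted mixing at nodes); and arteriovenous transit is
   measured between six arterial and six venous measurement points with the
   *same* half-max-rise estimator used for the experimental traces.

A synthetic-data module generates angiogram stacks with known stall
schedules, bolus pairs with known delays, and vascular network graphs — so
every stage is verifiable against ground truth without any animal data.
Group-level statistics (two-sample and paired t-tests, OLS fits of MTT
against stall metrics) and a one-command pipeline orchestrator round out the
package.

## Worked example

```python
from stallflow import (
    AngiogramSpec, BolusSpec, NetworkSpec,
    generate_angiogram, generate_bolus, generate_network,
    detect_stalls_in_stack, arteriovenous_mtt,
    apply_stalls, transit_summary,
)

# 1. angiogram with 10% programmed stalls -> detection
stack, truth_map, schedule = generate_angiogram(AngiogramSpec(stall_fraction=0.10, seed=1))
seg, record, metrics = detect_stalls_in_stack(stack, alpha=0.5, min_duration=3)
print(f"segments detected: {seg.n_segments}")
print(f"stall proportion:  {metrics.proportion_stalled:.3f} (programmed 0.100)")

# 2. bolus pair with a known 1.5 s arteriovenous delay -> MTT
artery, vein, truth = generate_bolus(BolusSpec(av_delay_s=1.5, noise_sd=0.02, seed=1))
print(f"MTT estimate: {arteriovenous_mtt(artery, vein).mtt_s:.3f} s")

# 3. network flow with and without 8% capillary blockage
net = generate_network(NetworkSpec(seed=1))
base, _ = transit_summary(net)
stalled, _ = apply_stalls(net, 0.08, seed=1)
res, _ = transit_summary(stalled)
print(f"transit: {base.mean_transit_s:.3f} s -> {res.mean_transit_s:.3f} s")
```

Output:

```
segments detected: 261
stall proportion:  0.103 (programmed 0.100)
MTT estimate: 1.517 s
transit: 0.615 s -> 0.677 s
```

The detector recovers the programmed 10% stall fraction to three tenths of a
percentage point on a 512×512×60 stack with ~260 segmented capillaries; the
MTT estimator recovers the 1.5 s delay to under one sample at realistic
noise; and blocking 8% of the 1168 lattice capillaries lengthens the
simulated arteriovenous transit by about 10%.

## Command line

```bash
stallflow synth angiogram|bolus|network --out DIR --seed N   # synthetic data
stallflow stalls --in stack.tif --alpha 0.5 --min-frames 3 --out DIR
stallflow bolus --traces traces.csv --out kinetics.csv
stallflow mtt --artery a.csv --vein v.csv
stallflow sim --network net.json --fractions 0,0.03,0.10 --seeds 20 --out sweep.csv
stallflow stats --table cohort.csv --out DIR
stallflow run --config config.yaml --out results/                # everything
```

`stallflow run` executes all five stages (synthesis, detection, kinetics,
simulation sweep, cohort statistics) from one YAML config with fully seeded
randomness and writes per-stage CSV/JSON artifacts plus a manifest; identical
configs reproduce identical numbers.

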