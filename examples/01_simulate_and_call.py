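"""Simulate a sequencing batch with planted CNVs and call them back.

A 32-sample exome batch at ~200 reads per target is drawn with three CNVs
planted in different samples: a 5-target heterozygous deletion, a 12-target
duplication, and a 58%-mosaic duplication (depth ratio 1.29).  Each carrier
is then called against a reference aggregated from its own batch.
"""

from exocnv import SimSpec, Spike, call_segments, select_reference, simulate_batch

spikes = [
    Spike(sample=0, first_target=100, last_target=104, copy_number=1),
    Spike(sample=1, first_target=400, last_target=411, copy_number=3),
    Spike(sample=2, first_target=700, last_target=729, copy_number=3,
          mosaic_fraction=0.58),
]
res = simulate_batch(SimSpec(seed=20210727, spikes=spikes))

print(f"batch: {res.batch.n_samples} samples x {res.batch.n_targets} targets")
print(f"planted:\n{res.truth.to_string(index=False)}\n")

for sample in ("S000", "S001", "S002"):
    model = select_reference(sample, res.batch)
    calls = call_segments(sample, res.batch, model, res.grid)
    print(f"{sample}: reference = {len(model.reference_ids)} samples, "
          f"rho = {model.rho:.2e}")
    for c in calls:
        mosaic = (f", mosaic {c.mosaic_fraction:.0%}"
                  if c.mosaic_fraction is not None and c.mosaic_fraction < 0.95
                  else "")
        print(f"  {c.type} targets {c.first_target}-{c.last_target} "
              f"(copy {c.copy_number}, ratio {c.mean_ratio:.2f}, "
              f"quality {c.quality:.1f}{mosaic})")
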