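"""Generate a small labeled synthetic ECG dataset and inspect it.

Builds 1% of the reference beat distribution (973 beats across the five
classes A, L, N, R, V), with the three canonical noise sources layered on,
and prints the per-class counts plus basic signal statistics.
"""

from ecgbeats import DatasetSpec, NoiseSpec, generate_dataset, scaled_counts

spec = DatasetSpec(scale=0.01, seed=7)
records, beats = generate_dataset(spec, NoiseSpec())

print("per-class beat counts:", scaled_counts(spec))
print(f"{len(records)} record(s), {len(beats)} beats total")
rec = records[0]
print(f"record {rec.record_id}: {len(rec.samples)} samples at {rec.fs} Hz, "
      f"{len(rec.annotations)} annotated R-peaks")
print(f"signal range [{rec.samples.min():.2f}, {rec.samples.max():.2f}] mV")
# Every beat is the 300-sample window [p-99, p+200] around its R-peak;
# counts follow the published class distribution scaled by 1%.
print("beat length:", len(beats[0].samples), "samples; labels:",
      sorted({b.label for b in beats}))
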