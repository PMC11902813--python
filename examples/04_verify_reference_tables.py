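"""Recompute every printed metric of the shipped reference confusion tables.

The package ships the three published confusion matrices it reproduces
(arrhythmia, supraventricular, and the no-preprocessing run) as CSV
fixtures.  This script recomputes overall accuracy and per-class
sensitivity/precision from the raw counts and flags the handful of printed
cells that are truncated or inconsistent with their own matrix.
"""

from ecgbeats.io import verify_reference_tables

df = verify_reference_tables()
print(df.to_string(index=False))
bad = df[~df["match"]]
print(f"\n{int(df['match'].sum())}/{len(df)} printed cells reproduce exactly.")
print("flagged cells (printed value inconsistent with the matrix):")
print(bad[["table", "metric", "class", "printed", "computed"]]
      .to_string(index=False))
# Sensitivity is the column ratio and precision the row ratio of each
# matrix - the only orientation that reproduces the printed values.
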