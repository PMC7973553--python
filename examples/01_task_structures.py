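"""Build and inspect the fixed-sequence task structures.

Validates the two 12-element second-order conditional (SOC) sequences,
derives the pair->successor map, constructs the 8-block stimulus stream,
and prints the prefix semantics table that drives anticipation labeling.
"""

import osrt

report_a = osrt.validate_soc(osrt.SEQUENCE_A)
report_b = osrt.validate_soc(osrt.SEQUENCE_B)
print(f"sequence A {osrt.SEQUENCE_A} valid: {report_a.ok}")
print(f"sequence B {osrt.SEQUENCE_B} valid: {report_b.ok}")

succ = osrt.successor_map(osrt.SEQUENCE_A)
print(f"\nafter targets 3 then 4, sequence A always continues with {succ[(3, 4)]}")

stream = osrt.build_fs_stream()
print(f"\nFS stream: {len(stream)} targets in {stream.n_blocks} blocks of 108")
print(f"block labels: {stream.block_labels}")
print(f"back-to-back repeats (one crosses a block boundary): {stream.repeat_count()}")

table = osrt.semantic_table(osrt.SEQUENCE_A, osrt.SEQUENCE_B)
print("\nprefix -> (main, interference, stuck, alternative):")
for prefix, sem in sorted(table.entries.items()):
    print(f"  {prefix} -> {tuple(sem.as_dict().values())}")
print("each row is a permutation of the four locations, so every fixated")
print("region after a valid prefix receives exactly one semantic label")
print(f"\nprefixes whose alternative is a gaze reversal: "
      f"{table.alternative_reversal_count()} of 12")
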