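"""Maximum-weight periodic blocks and their equivalence classes.

A periodic block of size T is valid for n_m mismatches when no n_m of
its cyclic rotations OR to the all-ones vector.  Rotating or reversing a
block preserves validity, so blocks are reported one canonical
representative per equivalence class.
"""

from spacedseeds import (
    BlockSearchSpec,
    PeriodicBlock,
    equivalence_class,
    max_weight_blocks,
    validate_block,
)

blocks = max_weight_blocks(BlockSearchSpec(T=11, n_m=2))
print(f"T=11, n_m=2: weight {blocks[0].n_1}, {len(blocks)} classes")
for b in blocks:
    print("  ", b)
# five classes of weight 7 exist; every valid block carries a cyclic run
# of at least n_m zeros, which the canonical form shows at its start.

b = PeriodicBlock.from_text("1011100")
members = equivalence_class(b)
print(f"block {b}: class of {len(members)} members, "
      f"all valid for n_m=2: {all(validate_block(m, 2) for m in members)}")
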