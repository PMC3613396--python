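"""Validate Dps identity from secondary structure and classify tails.

Dps mini-ferritins show five alpha helices with a short central BC helix;
ferritins/bacterioferritins lack it. Tail lengths (residues before the first
and after the last helix) sort proteins into short/short, long-N, long-C or
long/long classes.
"""

from dpsevolve import classify
from dpsevolve.simulate import FAMILY_TAILS, make_ss

for family in ("dpsA", "dpsB", "dpsC", "bfr"):
    n, c = FAMILY_TAILS[family]
    ss = make_ss(family, n, c)
    segs = classify.helix_segments(ss)
    is_dps, has_bc = classify.is_dps_signature(segs)
    n_tail, c_tail = classify.tail_lengths(ss)
    category = classify.classify_tails(n_tail, c_tail)
    print(f"{family}: {len(segs)} helices "
          f"(lengths {[s.length for s in segs]}), "
          f"Dps signature={is_dps}, BC helix={has_bc}, "
          f"tails N={n_tail}/C={c_tail} -> {category}")

print("\nThe bfr profile (four helices, no BC) is what the pipeline excludes"
      "\nwhen a sequence also groups with bacterioferritin in the tree;"
      "\nthe three dps families differ only in their tail classes.")
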