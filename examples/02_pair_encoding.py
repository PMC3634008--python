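"""Build the staged 1747-element input coding for a residue pair.

Constructs a small MSA for a synthetic protein and encodes the pair
(i, j) = (5, 40): 210 amino-acid pair frequencies grow to a 218 base
block (conservation + secondary structure), five content-window blocks
(1090), three segment-window blocks (1744) and three global descriptors
(1747).
"""

from contactcascade import encode_pair, pair_category_index
from contactcascade.synthetic_data import synth_chain, synth_msa

chain, _ = synth_chain(80, seed=0)
aln = synth_msa(chain.sequence, n_rows=20, mutation_rate=0.25, seed=0)
enc = encode_pair(aln, 5, 40, 80)

print(f"vector length: {len(enc.vector)}")
for name, (lo, hi) in enc.layout.items():
    print(f"  {name:12s} [{lo:4d}:{hi:4d})  sum {enc.vector[lo:hi].sum():7.3f}")
base = enc.block("base")
print(f"pair-frequency part sums to {base[:210].sum():.3f} "
      "(< 1 when alignment rows are gapped or non-standard)")
i_aa, j_aa = chain.sequence[4], chain.sequence[39]
print(f"target pair ({i_aa},{j_aa}) sits in category "
      f"{pair_category_index(i_aa, j_aa)} of 210")
print(f"global descriptors (sep, length, segment)/450: {enc.block('global')}")
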