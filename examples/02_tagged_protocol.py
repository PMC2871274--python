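"""Map a tagged, non-directional library (four read forms).

The non-directional protocol emits all four read forms (+FW, +RC, -FW,
-RC), each prefixed with a 5-nt tag whose pattern says whether the read
is a forward or reverse-complement form. The mapper classifies and
trims the tag, then searches only the two reference spaces consistent
with the tag class (four logical spaces overall - four alignment
passes, versus two for the directional protocol).
"""
from collections import Counter

from bsmapper import simulate_and_map, synthetic_genome

genome = synthetic_genome(200_000, seed=42)
result, truth, metrics = simulate_and_map(
    genome, n_reads=5_000, protocol="cokus", p_CG=0.72, seed=2,
)

forms = Counter(m.form for m in result.mapped)
print(result.report())
print("forms among uniquely mapped reads:",
      dict(sorted(forms.items())))
print(f"accuracy against truth: {metrics.accuracy}")
print()
print("All four forms appear in roughly equal numbers, reads are 36 nt of")
print("which 31 are genomic after tag trimming, and error-free accuracy is")
print("still exactly 100 because tags remove the FW/RC ambiguity.")
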