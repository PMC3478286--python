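"""Encode a short fragment with CKSAAP and read off its pair components.

The composition of k-spaced amino acid pairs counts, for each spacing k,
every ordered residue pair (a, b) at positions (i, i+k+1) in the window.
"""

from phoskit import cksaap_encode, feature_label

vec = cksaap_encode("AAACD", k_max=3)

print("fragment AAACD, k_max=3 ->", vec.values.shape[0], "components")
for j, count in enumerate(vec.values):
    if count:
        print(f"  {feature_label(j, 3):>6s} = {count}")

# Each nonzero line is one k-spaced pair: AA appears twice at spacing 0,
# A×A once at spacing 1 (A-A with one residue between), and so on; per
# spacing k the counts always sum to len(fragment) - k - 1.
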