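"""Build a per-position conservation profile from a stacked homolog alignment.

Each query position gets a pseudocounted residue frequency vector (gaps
excluded, so the 20 fractions sum to 1) and a Shannon entropy in bits:
0 bits = perfectly conserved, log2(20) ~ 4.32 bits = no conservation.
"""

import math

from dmsimpact import build_profile

query = "MKTAYIAKQR"
homologs = [
    "MKTAYIAKQR",
    "MKSAYIGKQR",
    "MKTAFIAKHR",
    "MRTAYLAKQR",
    "MKTAY-AKQR",  # a gap contributes nothing at position 6
]

profile = build_profile("toy_query", query, alignment_rows=homologs)

print("pos wt  entropy(bits)  depth  top frequencies")
for p in range(1, profile.length + 1):
    freqs = {aa: profile.frequency(p, aa) for aa in "ACDEFGHIKLMNPQRSTVWY"}
    top = sorted(freqs.items(), key=lambda kv: -kv[1])[:2]
    shown = "  ".join(f"{aa}:{f:.2f}" for aa, f in top)
    print(
        f"{p:>3} {query[p - 1]}   {profile.entropy[p - 1]:.3f}       "
        f"{profile.depth[p - 1]}    {shown}"
    )
print(
    f"\nmax possible entropy log2(20) = {math.log2(20):.3f} bits;"
    "\ninvariant columns (M1, A4, K8, R10) sit near 0 — strongly conserved —"
    "\nwhile columns with several residues (3, 5, 7, 9) carry more entropy."
)
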