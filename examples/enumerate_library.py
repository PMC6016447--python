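"""Enumerate the combinatorial cap-AA(-AA) virtual library.

Builds every N-capped mono- and dipeptide from the packaged building blocks
(10 caps x 8 amino acids) by amide coupling, and shows the count formula
n_caps * (n_aa + n_aa^2) at work.
"""

from gelscreen import assemble, default_building_blocks, enumerate_library

blocks = default_building_blocks()
caps = [b for b in blocks if b.kind == "cap"]
aas = [b for b in blocks if b.kind == "amino_acid"]

library = enumerate_library(caps, aas, include_monopeptides=True)
print(f"{len(caps)} caps x {len(aas)} amino acids")
print(f"enumerated products (pre-merge): {library.n_enumerated}  "
      f"[= {len(caps)} * ({len(aas)} + {len(aas)}**2)]")
print(f"unique structures after canonicalization: {len(library)}")

nap = next(c for c in caps if c.id == "nap2ox")
gly = next(a for a in aas if a.id == "gly")
ala = next(a for a in aas if a.id == "ala")
print("\nexample product, 2-naphthoxyacetyl-Gly-Ala (free C-terminal acid):")
print(" ", assemble(nap, [gly, ala]))
# Each product is a candidate low-molecular-weight gelator: an aromatic or
# alkyl cap amide-bonded to one or two amino acids.
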