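"""Derive the minimal primer key for the validated five-species gel pattern.

The amplification matrix records which of the six cross-validation primer
pairs produce a band for which species; the key is the smallest pair subset
whose joint presence/absence signature is unique per species.
"""

from barcodekey import minimal_key, render_key
from barcodekey.fixtures import reference_matrix

matrix = reference_matrix()
key = minimal_key(matrix)
print(f"minimal key uses {len(key.pairs)} of {len(matrix.pairs)} pairs\n")
print(render_key(key, matrix))
# Four pairs suffice: one species is recognised by the all-negative
# signature, the others each by a distinct band combination.
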