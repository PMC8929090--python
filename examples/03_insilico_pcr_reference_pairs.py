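"""Predict products of the seven validated Scutellaria primer pairs.

Each pair is run against a synthetic template embedding its exact binding
sites at the recorded spacing (the real GenBank records are not packaged);
the predicted amplicon must reproduce the published product size.
"""

from barcodekey import predict_amplicons
from barcodekey.fixtures import load_reference_pairs, synthetic_pair_template

print(f"{'pair':5} {'target species':24} {'recorded':>8} {'predicted':>9}")
for pair in load_reference_pairs():
    template = synthetic_pair_template(pair, seed=1)
    amps = predict_amplicons(pair, template, max_score=3)
    predicted = ",".join(str(a.length) for a in amps) or "none"
    print(f"{pair.name:5} {pair.target_species:24} {pair.product_length:>8} {predicted:>9}")
# Product length counts both primer footprints inclusively, so e.g. the SP
# pair (two 20-mers) at its recorded spacing yields exactly 173 bp.
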