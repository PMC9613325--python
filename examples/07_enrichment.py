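"""Two-list hypergeometric overrepresentation of annotation keywords."""

import pandas as pd

import milknet as mn

background = [f"P{i:03d}" for i in range(100)]
annotation = pd.DataFrame(
    {
        "protein_id": background[:20] + background[20:50],
        "keyword": ["ribosome"] * 20 + ["transport"] * 30,
    }
)
# a selection heavily enriched for the ribosome keyword
target = background[:12] + background[60:64]

result = mn.overrepresentation_test(target, background, annotation)
print(result.to_string(index=False))
# 'ribosome': 12 of 16 selected proteins among 20 of 100 background carriers;
# the upper-tail hypergeometric p is tiny and survives BH. 'transport' has
# zero overlap, so its p is 1.
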