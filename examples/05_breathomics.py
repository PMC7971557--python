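"""CO2-normalized breath comparison between saline and treated animals.

Simulates canister samples (1, 5 and 10 minutes post-injection, 3 animals
per group) plus room-air backgrounds, subtracts background, divides each
species' excess by the canister's excess CO2 to remove minute-volume
differences, pools timepoints per animal, and compares groups per species.
"""

from purinomics import background_subtract, normalize_by_co2, pool_and_compare
from purinomics.synthetic import simulate_breath, study_breath_spec

samples = simulate_breath(study_breath_spec(seed=1))
excess = background_subtract(samples)
normalized = normalize_by_co2(excess)
table = pool_and_compare(normalized, "saline", "ATP")

print(table.round(4).to_string(index=False))
# Values are ppb of excess species per ppm of excess CO2; a species with
# FDR < 0.05 is elevated beyond what minute-volume differences explain.
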