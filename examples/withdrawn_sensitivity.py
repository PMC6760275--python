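"""Withdrawn-drug sensitivity of the two screening models.

Cross-tabulates the reference detection calls for the 18 market-withdrawn
cardiotoxic drugs (shipped with the package) into per-model sensitivities,
overall and by ATC therapeutic subgroup.
"""

from cardioscreen.calls import withdrawn_summary

summary = withdrawn_summary()
print(summary.to_string(index=False))
print("\nSensitivity = detected / total among withdrawn drugs; the reported "
      "integer percentages use half-up rounding.")
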