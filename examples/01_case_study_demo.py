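"""Run the packaged P63 antiaging case study end to end.

Prints the treatment ranking and a line-by-line comparison of every
published index value with its recomputation from the published summary
means; lines marked DISCREPANT are published values that the published
tables do not support.
"""

from mei import demo_paper

result = demo_paper()
print(result.format())
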