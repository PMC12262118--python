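"""Build one full oddball session sequence and inspect its structure.

Prints the exact trial composition (counts are deterministic: 80% standards,
10% per deviant), the result of the exhaustive deviant-separation scan, and
the stimulus-onset-asynchrony range (200 ms sound + 440-520 ms ISI).
"""

import numpy as np

import erplearn as el

spec = el.SequenceSpec(seed=1)  # study defaults: 11,000 stimuli
seq = el.build_sequence(spec)

soa = np.diff(seq.onsets_ms)
print(f"total stimuli:       {len(seq)}")
print(f"standards:           {seq.count('standard')}")
print(f"small deviants:      {seq.count('dev_small')}")
print(f"large deviants:      {seq.count('dev_large')}")
print(f"separation violations (min 2 standards between deviants): "
      f"{seq.separation_violations(spec.min_separation)}")
print(f"SOA range:           {soa.min():.1f} - {soa.max():.1f} ms")
print(f"session duration:    {seq.onsets_ms[-1] / 60000:.1f} min")
# Counts are exact because randomization is over order only; a zero
# violation count means every consecutive deviant pair is buffered by at
# least two standards, as the paradigm requires.
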