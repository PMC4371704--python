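"""Extract the full 30-entry feature vector from one segment.

Features come in six blocks of five (one value per clinical sub-band,
delta..gamma): total variation of the sub-band signals, FFT relative band
power, DWT coefficient standard deviation, DWT relative power, correlation
dimension, and largest Lyapunov exponent. Higher ictal delta-band total
variation and lower attractor dimensions are the kind of contrast the
classifier exploits.
"""

from eegspike import assemble_feature_vector, default_profiles, generate_segment
from eegspike.linear_features import FEATURE_DESCRIPTIONS

seg = generate_segment(default_profiles()[2], seed=7)  # an ictal-like segment
fv = assemble_feature_vector(seg)
for name, value in fv.as_dict().items():
    print(f"{name:>4}  {FEATURE_DESCRIPTIONS[name]:<32} {value:10.4f}")
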