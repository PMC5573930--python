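"""Counter-based random streams for common-random-number scenario comparison.

Every stochastic decision in the simulator draws from a stream keyed by
(master seed, channel, cycle), with person *slot* as the index into the
drawn array.  Two scenario runs over the same cohort therefore consume
identical uniforms everywhere the intervention does not touch, so
incremental differences reflect only the intervention (common random
numbers).  Philox is used because its streams are defined by the key, not
by draw order.
"""

from __future__ import annotations

import numpy as np

# Channel registry.  Adding a channel is backward compatible; renumbering
# an existing one silently changes every simulated history — don't.
CHANNELS = {
    "gp_diabetes": 0,
    "gp_hypertension": 1,
    "gp_dyslipidaemia": 2,
    "cvd": 3,
    "cvd_fatal": 4,
    "chf": 5,
    "foot_ulcer": 6,
    "amputation": 7,
    "blindness": 8,
    "renal_failure": 9,
    "breast_cancer": 10,
    "colon_cancer": 11,
    "osteoarthritis": 12,
    "depression": 13,
    "cancer_death": 14,
    "other_death": 15,
    "enrol": 16,
    "coverage": 17,
    "bundle_0": 18,
    "bundle_1": 19,
    "screen_attend": 20,
    "screen_uptake": 21,
    "slopes": 30,
}


def uniforms(seed: int, channel: str, cycle: int, n: int) -> np.ndarray:
    """n uniforms on [0, 1) for one (seed, channel, cycle) key.

    Person slot i always receives element i, whatever else has been drawn.
    """
    key = (int(seed) << 64) | (CHANNELS[channel] << 40) | int(cycle)
    gen = np.random.Generator(np.random.Philox(key=key))
    return gen.random(n)


def generator(seed: int, channel: str, cycle: int = 0) -> np.random.Generator:
    """A full Generator on the same keying scheme (for normal draws etc.)."""
    key = (int(seed) << 64) | (CHANNELS[channel] << 40) | int(cycle)
    return np.random.Generator(np.random.Philox(key=key))
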