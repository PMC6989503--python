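"""Package-level constants for the empirical predictability law.

``H* = EMPIRICAL_SLOPE * L* + EMPIRICAL_INTERCEPT`` is the linear law fitted
across the twelve benchmark networks (slope standard deviation 0.06,
R^2 = 0.93).  Both constants are overridable wherever they are consumed, for
re-fitted laws.
"""

EMPIRICAL_SLOPE: float = 1.63
EMPIRICAL_INTERCEPT: float = -0.63
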