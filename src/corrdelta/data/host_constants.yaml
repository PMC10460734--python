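# Host maintenance-growth rate ratio m (1/day) and growth energy-investment
# ratio g (dimensionless) of the DEB-TGI host, fixed during model fitting.
# Only the product m*g enters the derived metrics (lambda, TVDT, C_T).
# These defaults fix g at a conventional value and calibrate m so that the
# product gives a tumor volume doubling time of 1.31 day at the typical
# parameter values, matching the center of the doubling-time distribution of
# the reference xenograft data set (see docs/methods.md). Replace both values
# with the ones used in your own model identification when available.
m: 0.541169188930534
g: 0.8
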