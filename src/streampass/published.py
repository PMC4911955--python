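"""Published proof-of-concept numbers for two Kodiak Island streams.

The method was first deployed on Meadow Creek (a Karluk Lake tributary,
mean width 4.50 m, depth 13 cm) and Southeast Creek (a Red Lake tributary,
width 3.90 m, depth 9.1 cm) during the 2014 sockeye run.  The published
escapement estimates from the four candidate passage models, the selected
top models, and the predicted stream-life parameters are recorded here so
that desk-scale consistency checks (e.g. how far the candidate models
disagree on each stream) can be recomputed without the raw field data.

Escapement values are fish; stream-life means/SEs are days.
"""

#: escapement estimate by candidate model form, Meadow Creek 2014
MEADOW_MODEL_ESTIMATES = {
    "segmented_first": 30_509,
    "segmented_poly": 30_064,
    "first_order": 41_539,
    "polynomial": 31_830,
}

#: escapement estimate by candidate model form, Southeast Creek 2014
SOUTHEAST_MODEL_ESTIMATES = {
    "segmented_first": 68_253,
    "segmented_poly": 66_303,
    "first_order": 65_355,
    "polynomial": 66_610,
}

#: selected top model and its slope coefficients (signed-basis order)
MEADOW_TOP_MODEL = ("segmented_first", (15.242, 18.920))
SOUTHEAST_TOP_MODEL = ("first_order", (22.505,))

#: published bootstrap 95% CI half-widths for the top-model escapements
MEADOW_CI_HALF_WIDTH = 9_494
SOUTHEAST_CI_HALF_WIDTH = 4_305

#: predicted mean stream life (days) and printed SE for each stream
MEADOW_STREAM_LIFE = (7.1, 3.5)
SOUTHEAST_STREAM_LIFE = (5.9, 3.0)

#: ratio tying stream-life SD to its mean (pooled-SD regression on external
#: stream-life data): SD = 0.499 · mean
STREAM_LIFE_SD_RATIO = 0.499

#: field-measured stream morphology used to predict stream life
MEADOW_DEPTH_CM = 13.0
SOUTHEAST_DEPTH_CM = 9.1
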