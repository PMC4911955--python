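# Synthetic run scenario: a single sharp pulse in a short season.
# All fields are optional; omitted ones take the package defaults.
season_days: 30
start: "2015-07-01"
pulses:
  - [8, 6000, 1.5]
  - [18, 3000, 2.0]
excursion_rate: 0.08
stream_life_mean: 7.1
stream_life_sd: 3.543
p_up: 0.065
p_down: 0.053
subsample_hours: 70
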