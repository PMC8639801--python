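# Special-weather-report criteria restated at daily resolution, two severity
# tiers per element.  direction "above": value >= threshold triggers;
# "below": value <= threshold triggers.  A tier is met on a day only if it is
# met on `persistence_days` consecutive days ending at that day.  Daily points:
# warning if the warning tier is met, else advisory if the advisory tier is
# met, else 0.
elements:
  tmax:        # heat wave
    direction: above
    advisory: 33.0
    warning: 35.0
    persistence_days: 2
    advisory_points: 1.0
    warning_points: 2.0
  tmin:        # cold wave
    direction: below
    advisory: -12.0
    warning: -15.0
    persistence_days: 2
    advisory_points: 1.0
    warning_points: 2.0
  humidity:    # dryness
    direction: below
    advisory: 35.0
    warning: 25.0
    persistence_days: 2
    advisory_points: 1.0
    warning_points: 2.0
  rainfall:    # heavy rain (daily accumulation)
    direction: above
    advisory: 80.0
    warning: 150.0
    persistence_days: 1
    advisory_points: 1.0
    warning_points: 2.0
  pm10:        # fine-dust advisory/warning
    direction: above
    advisory: 150.0
    warning: 300.0
    persistence_days: 1
    advisory_points: 1.0
    warning_points: 2.0
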