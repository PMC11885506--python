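# Default particle-transport clearance parameters, ICRP-66-style.
# Rates are first-order (per day); each generation inherits the compartment
# structure of its region.  "parent" routes mass up the mucociliary
# escalator (generation g -> g-1, generation 1 -> ET, ET -> out);
# "out" removes mass from the model (lymph / GI tract).
et:
  compartments:
    - {name: fast, fraction: 1.0, rate_per_day: 100.0, to: out}
regions:
  BB:
    generations: [1, 8]
    compartments:
      - {name: fast, fraction: 0.793, rate_per_day: 10.0, to: parent}
      - {name: slow, fraction: 0.2, rate_per_day: 0.03, to: parent}
      - {name: seq, fraction: 0.007, rate_per_day: 0.01, to: out}
  bb:
    generations: [9, 15]
    compartments:
      - {name: fast, fraction: 0.793, rate_per_day: 2.0, to: parent}
      - {name: slow, fraction: 0.2, rate_per_day: 0.03, to: parent}
      - {name: seq, fraction: 0.007, rate_per_day: 0.01, to: out}
  AI:
    generations: [16, 23]
    compartments:
      - {name: fast, fraction: 0.3, rate_per_day: 0.02, to: parent}
      - {name: slow, fraction: 0.6, rate_per_day: 0.001, to: parent}
      - {name: seq, fraction: 0.1, rate_per_day: 0.0001, to: parent}
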