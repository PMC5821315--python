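# Named prey grouping schemes: species label -> group name.
# three_source is the ecological partition used for the main diet models;
# the six-source partition is recomputed by Ward clustering at run time.
three_source:
  longfin squid: squid
  shortfin squid: squid
  sand lance: sand lance
  Atlantic cod: demersal fishes
  red hake: demersal fishes
  silver hake: demersal fishes
  thorny skate: demersal fishes
  white hake: demersal fishes
  winter flounder: demersal fishes
  winter skate: demersal fishes
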