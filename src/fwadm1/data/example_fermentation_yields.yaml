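# Example fermentation yields for the platform COD balance, per scenario.
# Units: g of product per gCOD of liquid extract fed to the fermenter.
# These are illustrative values chosen so that the two-scenario balance of
# the shipped characterizations lands at ~31 / ~69 gCOD of VFA per kg of
# raw feedstock (the liquid streams carry 37 and 98 gCOD respectively).
raw:
  acetic: 0.350
  butyric: 0.180
  caproic: 0.0615
pretreated:
  acetic: 0.300
  butyric: 0.120
  caproic: 0.0745
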