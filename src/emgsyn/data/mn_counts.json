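{
 "_note": "Approximate relative alpha-motoneuron counts per lumbosacral segment, literature-derived defaults; replaceable data, not measured values.",
 "L2": 2500,
 "L3": 4500,
 "L4": 5500,
 "L5": 6500,
 "S1": 6000,
 "S2": 4000,
 "S3": 1500
}
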