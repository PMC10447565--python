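{
  "comment": "Best-effort maize path topology (editable): diversity and network complexity act on SOC residual directly and through microbial biomass C and necromass C; one omitted path (diversity -> mnc) gives df = 1.",
  "variables": ["diversity", "network", "mbc", "mnc", "soc"],
  "edges": [
    ["diversity", "mbc"],
    ["network", "mbc"],
    ["network", "mnc"],
    ["mbc", "mnc"],
    ["diversity", "soc"],
    ["network", "soc"],
    ["mbc", "soc"],
    ["mnc", "soc"]
  ],
  "covariances": [["diversity", "network"]]
}
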