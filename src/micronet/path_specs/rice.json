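{
  "comment": "Best-effort rice path topology (editable): network complexity acts on SOC residual directly and via diversity and necromass C; biomass C carries a (weak) direct path; df = 5.",
  "variables": ["diversity", "network", "mbc", "mnc", "soc"],
  "edges": [
    ["network", "diversity"],
    ["diversity", "mnc"],
    ["network", "soc"],
    ["mnc", "soc"],
    ["mbc", "soc"]
  ],
  "covariances": []
}
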