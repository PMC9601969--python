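{
  "J": 50,
  "bd1": 222.16296967382866,
  "bd1_b": 249.13866251034744,
  "bd1_k": 226.16296967382866,
  "bd2": 239.06622383103593,
  "bd2_b": 283.7392391106047,
  "bd2_k": 245.06622383103593,
  "bdcp": 0.8,
  "bdcp_b": 1.0,
  "bdcp_k": 1.0,
  "n_rejected": 0,
  "seed": 123,
  "version": "0.1.0"
}
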