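{
  "table1.csv": "d980f727e2e16d4a4301d62d1f7cb063a9581c4a1c8e42984f058422b1706ff3",
  "table2.csv": "516a5fd438f7b50b182d3f94bfcc8db1c82b6efca42784c2ffa9debe3c1628ff",
  "table3.csv": "5e589a0c0561f9a455e1a2a1aa7551b90f8937df4b7f99d42c55959ee7ecd722",
  "table4.csv": "0829ee024dab8540d07518314297f9817eb14afee5838679bceba9fb9393448c"
}
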