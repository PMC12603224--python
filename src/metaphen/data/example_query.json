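{
 "age": 50,
 "findings": [
  {"term": "HP:0002322", "status": "present"},
  {"term": "HP:0001278", "status": "present"},
  {"term": "HP:0033696", "status": "present"}
 ],
 "tests": [],
 "differential": ["PD", "MSA", "PSP", "DLB", "CBD"]
}
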