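# Four-gene teaching network: A positively regulates B and negatively
# regulates C; B up- and C down-regulates D.
name: example-abcd
nodes:
  - {name: A, role: regulator}
  - {name: B, role: regulator}
  - {name: C, role: regulator}
  - {name: D, role: reporter}
edges:
  - {parent: A, child: B, sign: "+"}
  - {parent: A, child: C, sign: "-"}
  - {parent: B, child: D, sign: "+"}
  - {parent: C, child: D, sign: "-"}
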