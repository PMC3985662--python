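# Deposited structures

Place downloaded PDB files here for the structure-based checks. The test
suite and the `structure` CLI examples expect:

* `4h9n.pdb` — the histone H3.3/H4/chaperone ternary complex, e.g.

```bash
curl -o data/structures/4h9n.pdb https://files.rcsb.org/download/4H9N.pdb
```

Structures are not redistributed with the package.
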