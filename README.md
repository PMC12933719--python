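# fragspace

Similarity search in topological chemical fragment spaces with weighted
fingerprints.

A fragment space encodes a combinatorial compound library as building-block
fragments plus connection rules (topology graphs), so products are never
enumerated up front. `fragspace` finds the N products most similar to a
query molecule by fingerprint similarity, and can *focus* the search on
user-marked substructures: fingerprint features lying entirely inside the
marked atoms get their weight raised in the Tanimoto comparison, marked
atoms count as extra atoms in the combination score, and the final hit list
is re-ranked by weighted global similarity. The result is a hit list
enriched in molecules that preserve the marked substructure while staying
globally similar to the query.

## Layout

| module                  | contents                                                              |
|-------------------------|-----------------------------------------------------------------------|
| `fragspace.molgraph`    | labeled molecule graphs with linker/ring placeholder atoms            |
| `fragspace.space`       | fragment-space model, JSON I/O, product assembly, brute-force enumeration |
| `fragspace.fingerprints`| connected-subgraph (csfpA.B) and circular (ecfpD) count fingerprints, marked features, (weighted) Tanimoto |
| `fragspace.search`      | query partitioning, topology matching, per-node ranking, lazy k-best combination, weighted global re-rank |
| `fragspace.benchmark`   | synthetic space generation, query/SMARTS sampling, preservation-score benchmark |
| `fragspace.cli`         | `fragspace build-space / search / benchmark`                          |

Spaces are stored in a small versioned JSON dialect (see the
`fragspace.space` module docstring): fragments are SMILES in which a mapped
dummy atom `[*:1]` is linker `R1` and an unmapped dummy `*` is a ring
placeholder.

## CLI

```bash
# build a synthetic space from the bundled drug-like molecules
fragspace build-space --seed 1 --out space.json

# unweighted search
fragspace search --space space.json --query 'CC(=O)Oc1ccccc1C(=O)O' \
    --nof-results 10 --out hits

# weighted search: boost the carboxylic acid, factor 10
fragspace search --space space.json --query 'CC(=O)Oc1ccccc1C(=O)O' \
    --smarts 'C(=O)O' --weight 10 --out hits_weighted

# preservation benchmark over sampled query/SMARTS cases
fragspace benchmark --space space.json --cases 25 --k 1,5,10,20 \
    --seed 1 --out report
```

Key search flags: `--weight` (factor k for marked features), `--correction`
(adjusted-atom-count divisor, default 3), `--min-feature-size`,
`--weight-by-size`, `--descriptor` (`csfp1.4` default, `csfp2.2`, `ecfp4`,
...), `--slack` (size-filter slack, default 5). A YAML config file can
supply per-subcommand defaults via `fragspace --config cfg.yaml ...`.

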