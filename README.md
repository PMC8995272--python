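# mrfviz

Visualize and quantify the **encoding capability** of magnetic resonance
fingerprinting (MRF) dictionaries.

MRF estimates tissue relaxation times (T1, T2) by matching a measured
signal evolution against a precomputed dictionary of simulated evolutions,
one per (T1, T2) combination. How well a given flip-angle train *encodes*
tissue — how distinguishable its dictionary entries are — determines the
quality of the resulting parameter maps, and is hard to judge from the
train itself. `mrfviz` makes it visible and measurable:

1. **Simulate** a dictionary from a flip-angle train with the
   extended-phase-graph (EPG) formalism for an unbalanced FISP sequence
   (default grid: T1 20–2000 ms / 30 ms, T2 10–300 ms / 10 ms, T1 > T2 —
   1855 entries × 1000 timepoints).
2. **Embed** the entries into 2D/3D with Barnes–Hut t-SNE (PCA init,
   perplexity 750/200) or truncated SVD.
3. **Register** embeddings to a common reference with a closed-form
   similarity transform (scale + rotation/reflection + translation),
   exploiting the known point correspondences.
4. **Color-code** each entry via CIE L\*a\*b\* and render a dictionary map
   in the (T1, T2) plane — similar colors mean similar signals.
5. **Measure** encoding with ε = ‖I − S‖₁ / M, where S is the rescaled
   pairwise-Euclidean similarity matrix restricted to a tissue slice
   (white matter T2 = 80 ms, gray matter T2 = 110 ms). Lower ε = better
   encoding.

Intended users: MR physicists designing or optimizing MRF flip-angle
sequences who want a global, per-tissue picture of encoding capability
rather than a single cost-function number.

## Worked example

Compare the full dictionary against its 2D and 3D SVD embeddings for a
smooth lobed train with inversion pulse:

```python
import mrfviz as mv

grid = mv.make_grid(20, 2000, 30, 10, 300, 10)   # 1855 (T1, T2) pairs
train = mv.jiang_like_pattern(length=1000, seed=0)
dictionary = mv.build_dictionary(grid, train)     # 1855 x 1000 EPG signals

embeddings = [mv.svd_embed(dictionary, n_dim=k) for k in (2, 3)]
table = mv.measure_table(dictionary, embeddings)
print(table.to_string(index=False))
```

```
source  dimensionality tissue axis  value_ms    variant  epsilon
  full            1000     WM   T2      80.0 induced_l1 0.821188
  full            1000     GM   T2     110.0 induced_l1 0.836918
svd-2d               2     WM   T2      80.0 induced_l1 0.855434
svd-2d               2     GM   T2     110.0 induced_l1 0.873526
svd-3d               3     WM   T2      80.0 induced_l1 0.820386
svd-3d               3     GM   T2     110.0 induced_l1 0.835896
```

Reading the numbers: ε ≈ 0.82 for the full dictionary means the white
matter slice's similarity matrix is far from the identity — neighboring T1
entries at fixed T2 produce similar signals. The 3D SVD embedding
reproduces the full-dictionary measure almost exactly (0.820 vs 0.821), so
three linear components already capture the encoding structure, while the
2D SVD loses information (ε rises to 0.855). Dropping the inversion pulse
(`mv.without_inversion(train)`) raises ε for both tissues — the inversion
is what provides most of the T1 contrast.

The same analysis runs from the shell:

```bash
mrfviz seq make --kind jiang --length 1000 --seed 0 --out train.csv
mrfviz dict build --seq train.csv --out dict.h5
mrfviz embed --dict dict.h5 --method tsne --dim 2 --seed 0 --out emb.h5
mrfviz colormap --embedding emb.h5 --dict dict.h5 --out map
mrfviz measure --dict dict.h5 --embedding emb.h5 --out measures
```

and end-to-end comparison/iteration workflows are driven by a YAML config
(`mrfviz run compare CONFIG`, `mrfviz run iterations CONFIG`).

See `docs/methods.md` for the signal model, parameter defaults, and the
scope of what the synthetic sequence generators do and do not emulate.

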