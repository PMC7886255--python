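# boolobs — attractor observability in Boolean networks

`boolobs` answers a question arising when Boolean networks are used as
models of gene regulation: the attractors of the network (fixed points
and cycles of the synchronous dynamics) represent cell types or disease
states, and an experimenter who can only read a *contiguous* stretch of
genes wants the shortest such stretch that still tells every attractor
apart. The minimal window is a candidate biomarker panel.

## The problem and the algorithm

A Boolean network G(V, F) over n genes updates synchronously,
v_i(t+1) = f_i(v(t)); every trajectory falls into an attractor — a
singleton (period 1) or a cyclic attractor of period p. Given the m
attractors S = {S_1, …, S_m} with periods l_1, …, l_m, the
*attractor observability* problem asks for the minimum w such that some
window of w consecutive genes [a, a+w−1] yields pairwise-distinct
patterns across the attractors.

For cyclic attractors a *phase combination* picks one state from each
attractor; there are L = l_1⋯l_m combinations, and a window counts as
distinguishing if it works for at least one combination. Per
combination A (an m×n binary matrix) the solver:

1. XORs every unordered row pair into a C(m,2)×n difference matrix;
   a 0 marks a column where that pair of attractors agrees.
2. Collects every maximal run of consecutive zeros of length at least
   ⌈log₂ m⌉ (shorter runs cannot contain a candidate window).
3. If some column is covered by no run, the answer for A is exactly
   the lower bound ⌈log₂ m⌉.
4. Otherwise it sorts the runs, discards runs contained in another,
   and over adjacent survivors j, j+1 computes
   max( min_j [ end_j − start_{j+1} + 3 ], ⌈log₂ m⌉ ) —
   the inner term is the shortest window poking out of both runs.

The overall answer is the minimum over combinations; the scan stops
early once some combination attains ⌈log₂ m⌉. The cost is O(P^m · n)
for maximum period P, so large n is cheap and the usual small m keeps
L manageable. An independent brute-force oracle
(`boolobs.brute_force_min`) checks every window directly and is used
throughout the test suite to validate the run-based solver.

## Worked example

The package bundles the ten published steady states of the 60-variable
Boolean model of the Drosophila melanogaster segment-polarity network
(four cell compartments × 15 genes/proteins). Each steady state is a
stable expression pattern of the embryonic parasegment:

```python
>>> import boolobs as bo
>>> aset = bo.load_fixture("drosophila")
>>> result = bo.solve(aset)
>>> result.min_length
22
>>> result.windows
((1, 3, 24),)
>>> bo.name_window((3, 24), bo.drosophila_gene_map())[:3]
['compartment 1 WG', 'compartment 1 en', 'compartment 1 EN']
```

Reading any fewer than 22 contiguous variables cannot separate all ten
states, and the unique 22-wide window is x3..x24: the 13 variables
WG … CIR of compartment 1 followed by SLP … PTC of compartment 2.
The same one-shot analysis is available from the shell:

```
$ boolobs drosophila          # JSON report with the gene labels
$ boolobs solve my_set.tsv --exhaustive --oracle
$ boolobs simulate --n 200 --m 20 --trials 10 --seed 1
```

Small worked instances are bundled too — `load_fixture("example3_attractors")`
is a mixed set (two fixed points, two 2-cycles over six genes) whose
four phase combinations have per-combination minima 4, 6, 3 and 2:

```python
>>> bo.solve(bo.load_fixture("example3_attractors"), exhaustive=True).per_combination
(4.0, 6.0, 3.0, 2.0)
```

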